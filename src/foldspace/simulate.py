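"""Ground-truth models and simulated measurement tables.

The generator emulates the statistical structure of combinatorial deep
mutational scanning data: genotypes drawn from a 2^K biallelic space,
fitness equal to an affine transform of Boltzmann state probabilities
computed from additive free energies plus sparse pairwise couplings, and
heteroscedastic Gaussian measurement noise with a per-variant sigma.

Default energy distributions follow the empirical pattern of inferred
energies: first-order folding terms are destabilization-biased
(Normal(+1.0, 1.0) kcal/mol) while pairwise couplings are milder and
centred on zero (sparse Normal(0, 0.25)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .constants import RT, PHENOTYPE_ABUNDANCE, PHENOTYPE_BINDING, TRAIT_FOLDING, TRAIT_BINDING
from .genotypes import GenotypeTable
from .model import EnergyModel, pair_index
from .states import fraction_folded

# Deliberately >= 1 so the sign convention (positive = destabilizing) shows
# up in every simulated library.
DEFAULT_DDG_F = (1.0, 1.0)      # location, scale, kcal/mol
DEFAULT_DDG_B = (0.5, 0.5)
DEFAULT_COUPLING_SCALE = 0.25   # kcal/mol, zero-centred


@dataclass
class TruthSpec:
    """Specification of a ground-truth energy model and its noise regime.

    ``coupling_sparsity`` is the fraction of pairs with a nonzero coupling.
    Noise: per-replicate sigma_v = sigma0 + sigma1 * min(p, 1 - p) * 2, a
    bounded-assay heteroscedasticity that is largest mid-transition;
    ``sigma1 = 0`` gives the constant-sigma mode used for clean oracles.
    """

    k: int = 10
    ddg_f_loc: float = DEFAULT_DDG_F[0]
    ddg_f_scale: float = DEFAULT_DDG_F[1]
    coupling_scale: float = DEFAULT_COUPLING_SCALE
    coupling_sparsity: float = 0.2
    binding: bool = False
    ddg_b_loc: float = DEFAULT_DDG_B[0]
    ddg_b_scale: float = DEFAULT_DDG_B[1]
    dg_wt_f: float = -2.5
    dg_wt_b: float = -1.5
    affine_abundance: tuple[float, float] = (0.0, 1.0)
    affine_binding: tuple[float, float] = (0.0, 1.0)
    sigma0: float = 0.05
    sigma1: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("K must be >= 2")
        if not 0.0 <= self.coupling_sparsity <= 1.0:
            raise ValueError("coupling sparsity must be in [0, 1]")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")


def _combinatorial_spec(cls, k: int = 15, **kwargs) -> "TruthSpec":
    """Mild-effect truth emulating a designed combinatorial library.

    Fold-preserving combinatorial libraries are deliberately assembled from
    substitutions with mild individual effects so that multi-mutants stay
    near the folding transition rather than collapsing onto the unfolded
    plateau; this preset reduces the first-order energy distribution to
    Normal(+0.4, 0.4) kcal/mol (binding Normal(+0.2, 0.3)) accordingly.
    """
    defaults = dict(k=k, ddg_f_loc=0.4, ddg_f_scale=0.4,
                    ddg_b_loc=0.2, ddg_b_scale=0.3)
    defaults.update(kwargs)
    return cls(**defaults)


TruthSpec.combinatorial = classmethod(_combinatorial_spec)


def _strong_nonlinearity_spec(cls, k: int = 14, **kwargs) -> "TruthSpec":
    """Purely additive truth with pronounced global epistasis.

    Every substitution is firmly destabilizing (Normal(+1.2, 0.6) kcal/mol,
    no couplings), so multi-mutants sweep from the folded plateau through
    the transition onto the unfolded plateau: the regime in which a linear
    fitness model is systematically biased while a two-state energy model
    is not.
    """
    defaults = dict(k=k, ddg_f_loc=1.2, ddg_f_scale=0.6, coupling_sparsity=0.0)
    defaults.update(kwargs)
    return cls(**defaults)


TruthSpec.strong_nonlinearity = classmethod(_strong_nonlinearity_spec)


def generate_truth(spec: TruthSpec) -> EnergyModel:
    """Draw a ground-truth EnergyModel from the spec's distributions."""
    rng = np.random.default_rng(spec.seed)
    n_pairs = spec.k * (spec.k - 1) // 2

    def draw_couplings():
        c = rng.normal(0.0, spec.coupling_scale, size=n_pairs)
        mask = rng.random(n_pairs) < spec.coupling_sparsity
        return c * mask

    traits = [TRAIT_FOLDING]
    dg_wt = {TRAIT_FOLDING: spec.dg_wt_f}
    ddg = {TRAIT_FOLDING: rng.normal(spec.ddg_f_loc, spec.ddg_f_scale, size=spec.k)}
    couplings = {TRAIT_FOLDING: draw_couplings()}
    affine = {PHENOTYPE_ABUNDANCE: spec.affine_abundance}
    if spec.binding:
        traits.append(TRAIT_BINDING)
        dg_wt[TRAIT_BINDING] = spec.dg_wt_b
        ddg[TRAIT_BINDING] = rng.normal(spec.ddg_b_loc, spec.ddg_b_scale, size=spec.k)
        couplings[TRAIT_BINDING] = draw_couplings()
        affine[PHENOTYPE_BINDING] = spec.affine_binding
    return EnergyModel(traits=tuple(traits), dg_wt=dg_wt, ddg=ddg,
                       couplings=couplings, affine=affine)


def sample_genotype_library(
    k: int,
    n: int | None = None,
    scheme: str = "uniform_space",
    seed: int = 0,
    include_wildtype: bool = True,
) -> np.ndarray:
    """Sample distinct genotypes from the 2^K space.

    Schemes: ``uniform_space`` (distinct uniform draws), ``per_order``
    (equal counts per Hamming order where possible) and ``exhaustive``
    (all 2^K rows in integer order).
    """
    rng = np.random.default_rng(seed)
    if scheme == "exhaustive":
        if k > 24:
            raise ValueError("exhaustive enumeration limited to K <= 24")
        ints = np.arange(2 ** k, dtype=np.int64)
        return ((ints[:, None] >> np.arange(k)) & 1).astype(np.int8)
    if n is None:
        raise ValueError("n is required for sampled schemes")
    if k <= 62 and n > 2 ** k:
        raise ValueError(f"cannot draw {n} distinct genotypes from a 2^{k} space")
    if scheme == "uniform_space":
        seen = set()
        rows = []
        if include_wildtype:
            seen.add(0)
            rows.append(0)
        while len(rows) < n:
            batch = rng.integers(0, 2 ** k, size=2 * (n - len(rows)), dtype=np.int64)
            for v in batch:
                v = int(v)
                if v not in seen:
                    seen.add(v)
                    rows.append(v)
                    if len(rows) == n:
                        break
        ints = np.array(rows, dtype=np.int64)
        return ((ints[:, None] >> np.arange(k)) & 1).astype(np.int8)
    if scheme == "per_order":
        from math import comb
        # equal counts per order where possible: allocate fairly, letting
        # sparse orders (wild type, full mutant) cede their surplus
        avail = {o: comb(k, o) for o in range(k + 1)}
        quota = {}
        remaining = n
        for i, o in enumerate(sorted(avail, key=avail.get)):
            share = remaining // (k + 1 - i)
            quota[o] = min(avail[o], share)
            remaining -= quota[o]
        rows = []
        for order in range(k + 1):
            n_avail = avail[order]
            take = quota[order]
            if n_avail <= 10000:
                combos = list(itertools.combinations(range(k), order))
                chosen = [combos[i] for i in rng.choice(n_avail, size=take, replace=False)]
            else:
                chosen_set = set()
                while len(chosen_set) < take:
                    chosen_set.add(tuple(sorted(rng.choice(k, size=order, replace=False))))
                chosen = list(chosen_set)
            for c in chosen:
                row = np.zeros(k, dtype=np.int8)
                row[list(c)] = 1
                rows.append(row)
        return np.array(rows, dtype=np.int8)
    raise ValueError(f"unknown scheme {scheme!r}")


def simulate_measurements(
    truth: EnergyModel,
    genotypes: np.ndarray,
    sigma0: float = 0.05,
    sigma1: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> GenotypeTable:
    """Simulate a measurement table from a ground-truth model.

    Each replicate fitness is the model prediction plus independent
    Normal(0, sigma_v) noise with sigma_v = sigma0 + 2 sigma1 min(p, 1-p);
    the aggregate fitness is the replicate mean and the reported standard
    error is sigma_v / sqrt(R).
    """
    rng = np.random.default_rng(seed)
    genotypes = np.asarray(genotypes)
    table = GenotypeTable(genotypes=genotypes)
    X = genotypes.astype(float)
    for ph in truth.phenotypes:
        p = truth.state_probability(X, ph)
        mu = truth.predict_fitness(X, ph)
        sigma_v = sigma0 + 2.0 * sigma1 * np.minimum(p, 1.0 - p)
        reps = mu[:, None] + rng.normal(0.0, sigma_v[:, None],
                                        size=(len(mu), replicates))
        table.replicates[ph] = reps
        table.fitness[ph] = reps.mean(axis=1)
        table.sigma[ph] = sigma_v / np.sqrt(replicates)
    return table


def synthetic_pair_features(
    n: int,
    seed: int = 0,
    beta: np.ndarray | None = None,
    noise_sd: float = 0.02,
    intercept: float = 0.2,
):
    """Synthetic structural pair-feature table with a known linear response.

    Emulates the 12-feature table used to model coupling strength: distance
    metrics, residue-class counts and bond counts with realistic ranges.
    When ``beta`` (length 12, units of kcal/mol per standardized feature) is
    given, strength = intercept + Z beta + noise on z-scored features;
    otherwise the response is feature-independent noise (a null table).
    Returns (DataFrame, beta_used).
    """
    import pandas as pd
    from .structure import FEATURE_COLUMNS

    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "pos_i": np.arange(n, dtype=int),
        "pos_j": np.arange(n, dtype=int) + 10_000,
        "backbone_distance": rng.integers(1, 50, n).astype(float),
        "scha_distance": rng.uniform(2.0, 25.0, n),
        "n_core": rng.integers(0, 3, n).astype(float),
        "n_interface": rng.integers(0, 3, n).astype(float),
        "n_strand": rng.integers(0, 3, n).astype(float),
        "hbond_bb_bb": rng.poisson(0.5, n).astype(float),
        "hbond_sb": rng.poisson(0.4, n).astype(float),
        "hbond_ss": rng.poisson(0.4, n).astype(float),
        "pi_cation": rng.poisson(0.3, n).astype(float),
        "pi_stacking": rng.poisson(0.3, n).astype(float),
        "salt_bridge": rng.poisson(0.3, n).astype(float),
        "vdw": rng.poisson(2.0, n).astype(float),
    })
    # standardize by the population moments of the sampling distributions,
    # so the same linear truth transports across independent tables
    pop = {
        "backbone_distance": (25.0, np.sqrt((49 ** 2 - 1) / 12.0)),
        "scha_distance": (13.5, 23.0 / np.sqrt(12.0)),
        "n_core": (1.0, np.sqrt(2.0 / 3.0)),
        "n_interface": (1.0, np.sqrt(2.0 / 3.0)),
        "n_strand": (1.0, np.sqrt(2.0 / 3.0)),
        "hbond_bb_bb": (0.5, np.sqrt(0.5)),
        "hbond_sb": (0.4, np.sqrt(0.4)),
        "hbond_ss": (0.4, np.sqrt(0.4)),
        "pi_cation": (0.3, np.sqrt(0.3)),
        "pi_stacking": (0.3, np.sqrt(0.3)),
        "salt_bridge": (0.3, np.sqrt(0.3)),
        "vdw": (2.0, np.sqrt(2.0)),
    }
    X = df[FEATURE_COLUMNS].to_numpy(float)
    mu = np.array([pop[c][0] for c in FEATURE_COLUMNS])
    sd = np.array([pop[c][1] for c in FEATURE_COLUMNS])
    Z = (X - mu) / sd
    if beta is None:
        df["strength"] = np.abs(intercept + rng.normal(0.0, noise_sd, n))
    else:
        beta = np.asarray(beta, float)
        df["strength"] = intercept + Z @ beta + rng.normal(0.0, noise_sd, n)
    return df, beta


def folded_fraction_by_order(
    ddg_f: np.ndarray,
    dg_wt: float,
    orders: np.ndarray | list[int],
    n_per_order: int = 100_000,
    threshold: float = 0.5,
    seed: int = 0,
    rt: float = RT,
) -> dict[int, float]:
    """Percentage of random k-mutants predicted folded, assuming additivity.

    For each order k, draws ``n_per_order`` random k-subsets of the single
    substitution folding energies, sums them onto the wild-type dG and
    reports 100 x the fraction with fraction-folded > ``threshold``.
    """
    ddg_f = np.asarray(ddg_f, dtype=float)
    rng = np.random.default_rng(seed)
    out = {}
    for k in orders:
        if k > len(ddg_f):
            raise ValueError(f"order {k} exceeds table size {len(ddg_f)}")
        if k == 0:
            p = fraction_folded(np.array([dg_wt]), rt)
            out[0] = 100.0 * float(p[0] > threshold)
            continue
        idx = np.argsort(rng.random((n_per_order, len(ddg_f))), axis=1)[:, :k]
        dg = dg_wt + ddg_f[idx].sum(axis=1)
        out[int(k)] = 100.0 * float(np.mean(fraction_folded(dg, rt) > threshold))
    return out
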