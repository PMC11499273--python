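"""Fold-and-function-preserving combinatorial library design.

A greedy heuristic selects single substitutions whose combination is
predicted to preserve the molecular phenotypes: starting from a given
substitution, at each step the candidate (at a not-yet-mutated position)
maximizing the objective of the cumulative mutant is appended. The
objective is the geometric mean of the model-predicted growth rates over
the declared phenotypes (a single phenotype reduces to that growth rate).
Candidate sets are pre-filtered to confidently inferred, frequently
observed, single-nucleotide-reachable substitutions. Library viability is
assessed by simulating the median growth rates of a random sample of
variants, a library being viable when it preserves both phenotypes above
70% of the maximal (wild-type) value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import GROWTH_EPS
from .genotypes import SubstitutionEffect, single_nt_reachable
from .model import EnergyModel

logger = logging.getLogger(__name__)


def _sub_key(e: SubstitutionEffect) -> tuple[int, str]:
    """Deterministic tie-break order: position, then mutant aa."""
    return (e.position, e.mut_aa)


@dataclass
class DesignTrajectory:
    """One greedy run: a starting substitution and its ordered additions."""

    start: str
    steps: list[str] = field(default_factory=list)
    objectives: list[float] = field(default_factory=list)
    predicted: list[dict[str, float]] = field(default_factory=list)
    simulated_medians: list[dict[str, float]] = field(default_factory=list)
    viable: list[bool] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.steps)

    def mutation_set(self, size: int | None = None) -> list[str]:
        return self.steps[: self.size if size is None else size]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, code in enumerate(self.steps):
            row = {"start": self.start, "step": i + 1, "id": code,
                   "objective": self.objectives[i]}
            for ph, v in self.predicted[i].items():
                row[f"predicted_{ph}"] = v
            if i < len(self.simulated_medians):
                for ph, v in self.simulated_medians[i].items():
                    row[f"median_{ph}"] = v
            if i < len(self.viable):
                row["viable"] = self.viable[i]
            rows.append(row)
        return pd.DataFrame(rows)


def filter_candidates(
    effects: Sequence[SubstitutionEffect],
    wt_nt_seq: str,
    min_backgrounds: int = 20,
    max_ci: float = 1.0,
    genetic_code: dict[str, str] | None = None,
    traits: Sequence[str] = ("f",),
) -> list[SubstitutionEffect]:
    """Restrict candidates to confident, well-observed, nt-reachable effects.

    Kept iff every used trait's 95% CI width is < ``max_ci`` kcal/mol, the
    effect was measured in at least ``min_backgrounds`` genetic backgrounds,
    and the mutant aa is reachable by a single nucleotide substitution of
    the wild-type codon.
    """
    kept = []
    for e in effects:
        ok = True
        for tr in traits:
            ci = getattr(e, f"ci95_{tr}")
            if ci is None:
                raise ValueError(f"{e.code}: missing ci95_{tr}")
            if not ci < max_ci:
                ok = False
        if e.n_backgrounds < min_backgrounds:
            ok = False
        if ok:
            codon = wt_nt_seq[3 * (e.position - 1): 3 * e.position]
            ok = single_nt_reachable(codon, e.mut_aa, genetic_code)
        if ok:
            kept.append(e)
    return kept


class AdditiveDesignModel:
    """Additive predictor over candidate substitutions for design scoring.

    Wraps an EnergyModel's wild-type energies and affine transforms but
    sums the candidates' tabulated single-substitution energies (the design
    setting: energies inferred from a prior shallow library).
    """

    def __init__(self, model: EnergyModel, effects: Sequence[SubstitutionEffect]):
        self.model = model
        self.by_code = {e.code: e for e in effects}

    def growth_rates(self, codes: Sequence[str]) -> dict[str, float]:
        from .constants import TRAIT_FOLDING, TRAIT_BINDING, PHENOTYPE_ABUNDANCE, PHENOTYPE_BINDING
        from .states import fraction_folded, fraction_bound
        dg_f = self.model.dg_wt[TRAIT_FOLDING] + sum(
            self.by_code[c].ddg_f for c in codes)
        out = {}
        if PHENOTYPE_ABUNDANCE in self.model.affine:
            a, b = self.model.affine[PHENOTYPE_ABUNDANCE]
            out[PHENOTYPE_ABUNDANCE] = float(a + b * fraction_folded(dg_f, self.model.rt))
        if PHENOTYPE_BINDING in self.model.affine:
            dg_b = self.model.dg_wt[TRAIT_BINDING] + sum(
                (self.by_code[c].ddg_b or 0.0) for c in codes)
            a, b = self.model.affine[PHENOTYPE_BINDING]
            out[PHENOTYPE_BINDING] = float(
                a + b * fraction_bound(dg_f, dg_b, self.model.ligand_concentration,
                                       self.model.rt))
        return out


def design_objective(growth_rates: dict[str, float]) -> float:
    """Geometric mean of predicted growth rates, floored at GROWTH_EPS."""
    vals = np.maximum(list(growth_rates.values()), GROWTH_EPS)
    return float(np.exp(np.mean(np.log(vals))))


def greedy_design(
    start: SubstitutionEffect | str,
    candidates: Sequence[SubstitutionEffect],
    model: AdditiveDesignModel | EnergyModel,
    effects: Sequence[SubstitutionEffect] | None = None,
) -> DesignTrajectory:
    """Greedy trajectory from one starting substitution.

    At each step, among candidates at not-yet-mutated positions, append the
    one maximizing the objective of the cumulative mutant; ties break by
    (position, mutant aa). Several candidates may share a position; the
    argmax is over all of them, after which that position is closed.
    """
    if isinstance(model, EnergyModel):
        model = AdditiveDesignModel(model, effects if effects is not None else candidates)
    candidates = sorted(candidates, key=_sub_key)
    if not candidates:
        raise ValueError("empty candidate set")
    if isinstance(start, str):
        start = next(e for e in candidates if e.code == start)
    traj = DesignTrajectory(start=start.code)
    chosen = [start.code]
    used_positions = {start.position}
    gr = model.growth_rates(chosen)
    traj.steps.append(start.code)
    traj.objectives.append(design_objective(gr))
    traj.predicted.append(gr)
    while True:
        avail = [e for e in candidates if e.position not in used_positions]
        if not avail:
            break
        best, best_obj, best_gr = None, -np.inf, None
        for e in avail:  # sorted => first strict max implements the tie-break
            gr = model.growth_rates(chosen + [e.code])
            obj = design_objective(gr)
            if obj > best_obj:
                best, best_obj, best_gr = e, obj, gr
        chosen.append(best.code)
        used_positions.add(best.position)
        traj.steps.append(best.code)
        traj.objectives.append(best_obj)
        traj.predicted.append(best_gr)
    return traj


def simulate_library_growth(
    mutation_set: Sequence[str],
    model: AdditiveDesignModel,
    n: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Median predicted growth rates over a random sample of the 2^m library.

    Samples ``n`` genotypes uniformly (with replacement across the space;
    exhaustive when 2^m <= n) and returns the per-phenotype median of the
    predicted growth rate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    m = len(mutation_set)
    rng = np.random.default_rng(seed)
    if 2 ** m <= n:
        ints = np.arange(2 ** m, dtype=np.int64)
    else:
        ints = rng.integers(0, 2 ** m, size=n, dtype=np.int64)
    rows = ((ints[:, None] >> np.arange(m)) & 1).astype(bool)
    phenotypes = list(model.growth_rates([]).keys())
    rates = {ph: [] for ph in phenotypes}
    for row in rows:
        codes = [c for c, bit in zip(mutation_set, row) if bit]
        gr = model.growth_rates(codes)
        for ph in phenotypes:
            rates[ph].append(gr[ph])
    return {ph: float(np.median(v)) for ph, v in rates.items()}


def design_all_starts(
    candidates: Sequence[SubstitutionEffect],
    model: AdditiveDesignModel | EnergyModel,
    effects: Sequence[SubstitutionEffect] | None = None,
    simulate_n: int = 10_000,
    seed: int = 0,
) -> list[DesignTrajectory]:
    """Run the greedy search from every possible starting mutation."""
    if isinstance(model, EnergyModel):
        model = AdditiveDesignModel(model, effects if effects is not None else candidates)
    trajectories = []
    for i, start in enumerate(sorted(candidates, key=_sub_key)):
        traj = greedy_design(start, candidates, model)
        for size in range(1, traj.size + 1):
            traj.simulated_medians.append(simulate_library_growth(
                traj.mutation_set(size), model, n=simulate_n,
                seed=seed * 100003 + i * 101 + size))
        trajectories.append(traj)
    return trajectories


def select_largest_viable(
    trajectories: Sequence[DesignTrajectory],
    model: AdditiveDesignModel,
    threshold: float = 0.7,
    reference: str = "wildtype",
) -> tuple[list[str], DesignTrajectory, int]:
    """Largest library preserving both phenotypes above the 70% rule.

    A size-m prefix of a trajectory is viable iff the geometric mean of its
    simulated median growth rates is >= ``threshold`` x the maximal value.
    ``reference='wildtype'`` (default) takes the maximal value as the
    geometric mean of the wild-type predicted growth rates;
    ``reference='max'`` uses the maximum geometric mean over all simulated
    prefixes. Ties between trajectories break deterministically by start
    code order.
    """
    if reference == "wildtype":
        ref = design_objective(model.growth_rates([]))
    elif reference == "max":
        ref = max(design_objective(m) for t in trajectories
                  for m in t.simulated_medians)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    best_traj, best_size = None, 0
    for traj in sorted(trajectories, key=lambda t: t.start):
        traj.viable = [design_objective(m) >= threshold * ref
                       for m in traj.simulated_medians]
        size = 0
        for i, ok in enumerate(traj.viable):
            if ok:
                size = i + 1
        if size > best_size:
            best_traj, best_size = traj, size
    if best_traj is None:
        raise ValueError("no viable library at any size")
    return best_traj.mutation_set(best_size), best_traj, best_size


def exhaustive_best_subset(
    candidates: Sequence[SubstitutionEffect],
    model: AdditiveDesignModel,
    size: int,
) -> tuple[list[str], float]:
    """Exact best size-m subset by enumeration (small instances only).

    Used to report the greedy optimality gap; one candidate per position is
    enforced as in the greedy search.
    """
    best, best_obj = None, -np.inf
    for combo in combinations(sorted(candidates, key=_sub_key), size):
        if len({e.position for e in combo}) != size:
            continue
        obj = design_objective(model.growth_rates([e.code for e in combo]))
        if obj > best_obj:
            best, best_obj = [e.code for e in combo], obj
    logger.info("exhaustive best size-%d objective: %.6g", size, best_obj)
    return best, best_obj


def window_design_filter(
    candidate_positions: Sequence[int],
    protein_length: int,
    widths: Sequence[int] = (20, 21, 22),
    required_count: int | None = None,
) -> pd.DataFrame:
    """Sliding-window counts of candidate positions (library-3-style design).

    ``candidate_positions`` are 1-based positions already flagged as
    mild-effect, nt-reachable and non-interface. For each window width and
    start, counts flagged positions inside the window; when
    ``required_count`` is given only windows attaining it are returned.
    """
    flags = np.zeros(protein_length, dtype=bool)
    for p in candidate_positions:
        flags[p - 1] = True
    rows = []
    for w in widths:
        if w > protein_length:
            raise ValueError(f"window width {w} exceeds protein length {protein_length}")
        counts = np.convolve(flags.astype(int), np.ones(w, dtype=int), mode="valid")
        for start0, c in enumerate(counts):
            if required_count is None or c >= required_count:
                rows.append({"start": start0 + 1, "width": w, "count": int(c)})
    return pd.DataFrame(rows, columns=["start", "width", "count"])
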