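"""Thermodynamic genotype-phenotype models and their training protocol.

The model maps a binary genotype x (presence/absence of K library
substitutions) to per-trait free energies by additivity,

    dG_t(x) = dG_t^wt + sum_i x_i ddG_t,i  [+ sum_{i<j} x_i x_j dddG_t,ij],

pushes them through the Boltzmann state probabilities (fraction folded for
the abundance phenotype, fraction folded-and-bound for the binding
phenotype) and applies a per-phenotype affine transform a + b p to obtain
predicted fitness. Parameters are trained by Adam on a weighted, L2
regularized mean absolute error, with a 70/20/10 train/validation/test
split, exponential learning-rate decay on validation plateau, and early
stopping when the wild-type free energies stabilize.

Internally all energies are dimensionless (theta = dG/RT); reported
energies are theta * RT with R = 0.001987 kcal/K/mol, T = 303 K.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .constants import (
    RT,
    PHENOTYPE_ABUNDANCE,
    PHENOTYPE_BINDING,
    TRAIT_FOLDING,
    TRAIT_BINDING,
    PHENOTYPE_TRAITS,
)
from .genotypes import GenotypeTable, LibraryDefinition
from .states import fraction_folded, fraction_bound, state_probabilities

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def pair_index(k: int) -> list[tuple[int, int]]:
    """Upper-triangular (i < j) pair order used for coupling vectors."""
    return list(itertools.combinations(range(k), 2))


def pairwise_design(x: np.ndarray) -> np.ndarray:
    """(n, K(K-1)/2) matrix of products x_i x_j, i < j, in pair_index order."""
    x = np.asarray(x)
    pairs = pair_index(x.shape[1])
    if not pairs:
        return np.zeros((x.shape[0], 0), dtype=x.dtype)
    ii, jj = zip(*pairs)
    return x[:, list(ii)] * x[:, list(jj)]


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class EnergyModel:
    """Fitted (or ground-truth) energy model.

    Energies in kcal/mol. ``couplings`` entries are None for first-order
    models, otherwise length K(K-1)/2 vectors in :func:`pair_index` order.
    ``affine`` maps phenotype -> (intercept a, scale b).
    """

    traits: tuple[str, ...]
    dg_wt: dict[str, float]
    ddg: dict[str, np.ndarray]
    couplings: dict[str, np.ndarray | None]
    affine: dict[str, tuple[float, float]]
    ligand_concentration: float = 1.0
    rt: float = RT

    def __post_init__(self):
        for tr in self.traits:
            self.ddg[tr] = np.asarray(self.ddg[tr], dtype=float)
            if self.couplings.get(tr) is not None:
                self.couplings[tr] = np.asarray(self.couplings[tr], dtype=float)
        for ph, (a, b) in self.affine.items():
            if b == 0:
                raise ValueError(f"affine scale b must be nonzero for {ph}")

    @property
    def k(self) -> int:
        return len(self.ddg[self.traits[0]])

    @property
    def max_interaction_order(self) -> int:
        return 2 if any(self.couplings.get(t) is not None for t in self.traits) else 1

    @property
    def phenotypes(self) -> list[str]:
        phs = [PHENOTYPE_ABUNDANCE]
        if TRAIT_BINDING in self.traits:
            phs.append(PHENOTYPE_BINDING)
        return [p for p in phs if p in self.affine]

    def free_energy(self, x: np.ndarray, trait: str) -> np.ndarray:
        """Total dG of the variant(s) ``x`` for one trait, kcal/mol."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.k:
            raise ValueError(f"genotype length {x.shape[1]} != K={self.k}")
        dg = self.dg_wt[trait] + x @ self.ddg[trait]
        cpl = self.couplings.get(trait)
        if cpl is not None:
            dg = dg + pairwise_design(x) @ cpl
        return dg

    def state_probability(self, x: np.ndarray, phenotype: str) -> np.ndarray:
        """p_f (abundance) or p_fb (binding) for variant(s) ``x``."""
        if phenotype == PHENOTYPE_ABUNDANCE:
            return fraction_folded(self.free_energy(x, TRAIT_FOLDING), self.rt)
        if phenotype == PHENOTYPE_BINDING:
            return fraction_bound(
                self.free_energy(x, TRAIT_FOLDING),
                self.free_energy(x, TRAIT_BINDING),
                self.ligand_concentration, self.rt)
        raise ValueError(f"unknown phenotype {phenotype!r}")

    def predict_fitness(self, x: np.ndarray, phenotype: str) -> np.ndarray:
        """Affine-transformed state probability, a + b p."""
        if phenotype not in self.affine:
            raise ValueError(f"phenotype {phenotype!r} not declared in model")
        a, b = self.affine[phenotype]
        return a + b * self.state_probability(x, phenotype)

    def n_parameters(self) -> int:
        n = 0
        for tr in self.traits:
            n += 1 + self.k
            if self.couplings.get(tr) is not None:
                n += len(self.couplings[tr])
        return n + 2 * len(self.affine)

    # -- serialization -----------------------------------------------------

    def to_dict(self, lib: LibraryDefinition | None = None) -> dict:
        def key(i):
            return lib.codes[i] if lib is not None else str(i)

        d = {
            "version": __version__,
            "traits": list(self.traits),
            "constants": {"rt": self.rt, "ligand_concentration": self.ligand_concentration},
            "dg_wt": dict(self.dg_wt),
            "affine": {ph: {"a": a, "b": b} for ph, (a, b) in self.affine.items()},
            "ddg": {tr: {key(i): float(v) for i, v in enumerate(self.ddg[tr])}
                    for tr in self.traits},
            "couplings": {},
        }
        for tr in self.traits:
            cpl = self.couplings.get(tr)
            if cpl is None:
                d["couplings"][tr] = None
            else:
                d["couplings"][tr] = {
                    f"{key(i)}:{key(j)}": float(v)
                    for (i, j), v in zip(pair_index(self.k), cpl)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyModel":
        traits = tuple(d["traits"])
        ddg, couplings = {}, {}
        for tr in traits:
            items = list(d["ddg"][tr].items())
            ddg[tr] = np.array([v for _, v in items], dtype=float)
            c = d["couplings"].get(tr)
            couplings[tr] = None if c is None else np.array(list(c.values()), dtype=float)
        return cls(
            traits=traits,
            dg_wt={tr: float(d["dg_wt"][tr]) for tr in traits},
            ddg=ddg, couplings=couplings,
            affine={ph: (float(v["a"]), float(v["b"])) for ph, v in d["affine"].items()},
            ligand_concentration=float(d["constants"].get("ligand_concentration", 1.0)),
            rt=float(d["constants"].get("rt", RT)),
        )

    def save(self, path, lib: LibraryDefinition | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(lib), fh, indent=1)

    @classmethod
    def load(cls, path) -> "EnergyModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def canonicalized(self) -> "EnergyModel":
        """Resolve the two-state orientation degeneracy.

        For folding-only models, negating every folding energy while mapping
        (a, b) -> (a + b, -b) leaves all predictions unchanged. The
        canonical orientation has b > 0 for the abundance phenotype
        (fitness increases with the fraction folded). Joint folding+binding
        models have no such symmetry and are returned unchanged.
        """
        if set(self.traits) != {TRAIT_FOLDING}:
            return self
        a, b = self.affine[PHENOTYPE_ABUNDANCE]
        if b > 0:
            return self
        return EnergyModel(
            traits=self.traits,
            dg_wt={TRAIT_FOLDING: -self.dg_wt[TRAIT_FOLDING]},
            ddg={TRAIT_FOLDING: -self.ddg[TRAIT_FOLDING]},
            couplings={TRAIT_FOLDING: None if self.couplings.get(TRAIT_FOLDING) is None
                       else -self.couplings[TRAIT_FOLDING]},
            affine={PHENOTYPE_ABUNDANCE: (a + b, -b)},
            ligand_concentration=self.ligand_concentration, rt=self.rt,
        )


# ---------------------------------------------------------------------------
# Training configuration
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Hyperparameters of the training protocol."""

    max_interaction_order: int = 1
    initial_lr: float = 0.05
    lr_decay: float = 0.98
    max_epochs: int = 1000
    hyperparameter_epochs: int = 100
    batch_size_grid: tuple[int, ...] = (512, 1024, 2048)
    l2: float = 1e-6
    split_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    n_mc_models: int = 10
    seed: int = 0
    early_stop_sd: float = 1e-3
    early_stop_window: int = 10
    ligand_concentration: float = 1.0
    resample_training: bool = False

    def __post_init__(self):
        if self.max_interaction_order not in (1, 2):
            raise ValueError("max_interaction_order must be 1 or 2")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.early_stop_sd <= 0 or self.initial_lr <= 0:
            raise ValueError("tolerances and learning rate must be > 0")


# ---------------------------------------------------------------------------
# Loss, splits, resampling
# ---------------------------------------------------------------------------

def weighted_mae_loss(predicted, observed, sigmas, theta=None, l2: float = 0.0) -> float:
    """Weighted, L2-regularized mean absolute error.

    L = (1/N) sum_n |y_n - yhat_n| / sigma_n + l2 ||theta||^2.
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    sigmas = np.asarray(sigmas, float)
    if predicted.shape != observed.shape or predicted.shape != sigmas.shape:
        raise ValueError("predicted, observed and sigmas must have equal shapes")
    if np.any(sigmas <= 0):
        raise ValueError("sigmas must be > 0")
    loss = float(np.mean(np.abs(observed - predicted) / sigmas))
    if theta is not None and l2:
        theta = np.asarray(theta, float)
        loss += l2 * float(theta @ theta)
    return loss


def split_variants(
    n_or_table,
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
    wildtype_index: int | None = None,
) -> np.ndarray:
    """Assign each variant to train/val/test, reproducibly.

    The wild-type row (all-zero genotype, located automatically when a
    GenotypeTable is given) is always placed in the training set.
    """
    if isinstance(n_or_table, GenotypeTable):
        table = n_or_table
        n = table.n
        if wildtype_index is None:
            try:
                wildtype_index = table.wildtype_index()
            except ValueError:
                wildtype_index = None
    else:
        n = int(n_or_table)
    if n < 10:
        raise ValueError(f"need at least 10 variants to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    labels = np.full(n, "train", dtype=object)
    labels[order[:n_val]] = "val"
    labels[order[n_val:n_val + n_test]] = "test"
    if wildtype_index is not None:
        labels[wildtype_index] = "train"
    return labels


def resample_training(
    table: GenotypeTable,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> GenotypeTable:
    """Replace fitness with a draw from each variant's error distribution.

    fitness' = fitness + Normal(0, sigma), independently per variant and
    phenotype (Gaussian form assumed for the error distribution). When
    ``mask`` is given only those rows (the training set) are perturbed;
    validation and test data are left unaltered.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    for ph in out.phenotypes:
        noise = rng.normal(0.0, out.sigma[ph])
        if mask is not None:
            noise = np.where(mask, noise, 0.0)
        out.fitness[ph] = out.fitness[ph] + noise
    return out


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

class _ParamPack:
    """Index bookkeeping for the flat parameter vector theta."""

    def __init__(self, k: int, traits: Sequence[str], phenotypes: Sequence[str], order: int):
        self.k = k
        self.traits = list(traits)
        self.phenotypes = list(phenotypes)
        self.order = order
        self.n_pairs = k * (k - 1) // 2 if order == 2 else 0
        self.slices: dict[str, slice] = {}
        pos = 0
        for tr in self.traits:
            self.slices[f"wt_{tr}"] = slice(pos, pos + 1); pos += 1
            self.slices[f"ddg_{tr}"] = slice(pos, pos + k); pos += k
            if order == 2:
                self.slices[f"cpl_{tr}"] = slice(pos, pos + self.n_pairs); pos += self.n_pairs
        for ph in self.phenotypes:
            self.slices[f"affine_{ph}"] = slice(pos, pos + 2); pos += 2
        self.size = pos

    def get(self, theta: np.ndarray, name: str) -> np.ndarray:
        return theta[self.slices[name]]


class ThermoModelRegressor(BaseEstimator, RegressorMixin):
    """Two- or three-state Boltzmann genotype-phenotype model.

    scikit-learn style estimator. ``X`` is an (n, K) binary genotype matrix;
    ``y`` is (n,) fitness for a single abundance phenotype or (n, 2) columns
    (abundance, binding) for the joint three-state fit (NaN marks variants
    unmeasured in a phenotype). Per-variant standard errors are passed to
    ``fit`` as ``sigma`` (same shape as y; defaults to 1).

    Parameters mirror the training protocol: Adam with initial learning
    rate ``initial_lr``, exponential decay (``lr_decay``) when the
    validation loss has not improved over the last ``early_stop_window``
    epochs versus the preceding window, early stopping once the wild-type
    free energies have stabilized (sd <= ``early_stop_sd`` kcal/mol over the
    window), batch size tuned over ``batch_size_grid`` by validation loss
    after ``hyperparameter_epochs`` epochs, loss = weighted MAE + ``l2``
    ||theta||^2.

    Attributes (after fit): ``model_`` (EnergyModel, canonicalized),
    ``history_`` (DataFrame: epoch, train_loss, val_loss, lr),
    ``split_labels_``, ``r2_`` (test-split R^2 per phenotype),
    ``batch_size_``.
    """

    def __init__(
        self,
        max_interaction_order: int = 1,
        phenotypes: tuple[str, ...] = (PHENOTYPE_ABUNDANCE,),
        initial_lr: float = 0.05,
        lr_decay: float = 0.98,
        max_epochs: int = 1000,
        hyperparameter_epochs: int = 100,
        batch_size_grid: tuple[int, ...] = (512, 1024, 2048),
        l2: float = 1e-6,
        split_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
        seed: int = 0,
        early_stop_sd: float = 1e-3,
        early_stop_window: int = 10,
        ligand_concentration: float = 1.0,
        resample_training: bool = False,
        rt: float = RT,
    ):
        self.max_interaction_order = max_interaction_order
        self.phenotypes = phenotypes
        self.initial_lr = initial_lr
        self.lr_decay = lr_decay
        self.max_epochs = max_epochs
        self.hyperparameter_epochs = hyperparameter_epochs
        self.batch_size_grid = batch_size_grid
        self.l2 = l2
        self.split_fractions = split_fractions
        self.seed = seed
        self.early_stop_sd = early_stop_sd
        self.early_stop_window = early_stop_window
        self.ligand_concentration = ligand_concentration
        self.resample_training = resample_training
        self.rt = rt

    # -- internals ---------------------------------------------------------

    def _traits(self) -> list[str]:
        phs = list(self.phenotypes)
        if PHENOTYPE_BINDING in phs and PHENOTYPE_ABUNDANCE not in phs:
            raise ValueError(
                "binding phenotype requires the abundance phenotype as well "
                "(joint three-state fit)")
        traits = [TRAIT_FOLDING]
        if PHENOTYPE_BINDING in phs:
            traits.append(TRAIT_BINDING)
        return traits

    def _forward(self, theta, pack, X, Xp):
        """Predicted fitness per phenotype plus cached state quantities."""
        tf = pack.get(theta, f"wt_{TRAIT_FOLDING}")[0] + X @ pack.get(theta, f"ddg_{TRAIT_FOLDING}")
        if pack.order == 2:
            tf = tf + Xp @ pack.get(theta, f"cpl_{TRAIT_FOLDING}")
        cache = {"tf": tf}
        preds = {}
        if PHENOTYPE_ABUNDANCE in pack.phenotypes:
            p_f = expit(-tf)
            a, b = pack.get(theta, f"affine_{PHENOTYPE_ABUNDANCE}")
            preds[PHENOTYPE_ABUNDANCE] = a + b * p_f
            cache["p_f"] = p_f
        if PHENOTYPE_BINDING in pack.phenotypes:
            tb = pack.get(theta, f"wt_{TRAIT_BINDING}")[0] + X @ pack.get(theta, f"ddg_{TRAIT_BINDING}")
            if pack.order == 2:
                tb = tb + Xp @ pack.get(theta, f"cpl_{TRAIT_BINDING}")
            p_uu, p_fu, p_fb = state_probabilities(
                tf * self.rt, tb * self.rt, self.ligand_concentration, self.rt)
            a, b = pack.get(theta, f"affine_{PHENOTYPE_BINDING}")
            preds[PHENOTYPE_BINDING] = a + b * p_fb
            cache.update(tb=tb, p_uu=p_uu, p_fb=p_fb)
        return preds, cache

    def _loss_grad(self, theta, pack, X, Xp, y, sig, valid):
        """Loss and analytic gradient of the weighted MAE + L2 objective."""
        preds, cache = self._forward(theta, pack, X, Xp)
        grad = 2.0 * self.l2 * theta
        loss = self.l2 * float(theta @ theta)
        g_tf = np.zeros(X.shape[0])
        g_tb = np.zeros(X.shape[0]) if PHENOTYPE_BINDING in pack.phenotypes else None
        for ph in pack.phenotypes:
            v = valid[ph]
            n_v = max(int(v.sum()), 1)
            resid = preds[ph] - y[ph]
            w = np.where(v, np.sign(resid) / sig[ph] / n_v, 0.0)
            loss += float(np.sum(np.where(v, np.abs(resid) / sig[ph], 0.0))) / n_v
            a_sl = pack.slices[f"affine_{ph}"]
            b = theta[a_sl][1]
            if ph == PHENOTYPE_ABUNDANCE:
                p = cache["p_f"]
                grad[a_sl.start] += w.sum()
                grad[a_sl.start + 1] += w @ p
                g_tf += w * b * (-p * (1.0 - p))
            else:
                p = cache["p_fb"]
                grad[a_sl.start] += w.sum()
                grad[a_sl.start + 1] += w @ p
                g_tf += w * b * (-p * cache["p_uu"])
                g_tb += w * b * (-p * (1.0 - p))
        for tr, g in ((TRAIT_FOLDING, g_tf), (TRAIT_BINDING, g_tb)):
            if tr not in pack.traits:
                continue
            grad[pack.slices[f"wt_{tr}"].start] += g.sum()
            grad[pack.slices[f"ddg_{tr}"]] += X.T @ g
            if pack.order == 2:
                grad[pack.slices[f"cpl_{tr}"]] += Xp.T @ g
        return loss, grad

    def _eval_loss(self, theta, pack, X, Xp, y, sig, valid):
        preds, _ = self._forward(theta, pack, X, Xp)
        loss = self.l2 * float(theta @ theta)
        for ph in pack.phenotypes:
            v = valid[ph]
            n_v = max(int(v.sum()), 1)
            loss += float(np.sum(np.where(
                v, np.abs(preds[ph] - y[ph]) / sig[ph], 0.0))) / n_v
        return loss

    def _init_theta(self, pack, X, Xp, y, valid, rng):
        """Initialize near the relevant basin of the loss surface.

        The affine transform starts at the empirical fitness plateaus; the
        energy terms start from a weighted least-squares solve of the
        logit-inverted state probabilities on the genotype design. This
        avoids the sloppy valley where the affine scale and the energy
        scale partially compensate, which plain random initialization
        tends to fall into.
        """
        theta = rng.normal(0.0, 0.05, size=pack.size)
        affine0 = {}
        for ph in pack.phenotypes:
            vals = y[ph][valid[ph]]
            lo, hi = np.percentile(vals, [5, 95])
            sl = pack.slices[f"affine_{ph}"]
            theta[sl.start] = lo
            theta[sl.start + 1] = max(hi - lo, 0.1)
            affine0[ph] = (theta[sl.start], theta[sl.start + 1])

        D = np.column_stack([np.ones(X.shape[0]), X] + ([Xp] if Xp is not None else []))

        def wls(target, w):
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(D * sw[:, None], target * sw, rcond=None)
            return coef

        eps = 1e-3
        ph = PHENOTYPE_ABUNDANCE
        if ph in pack.phenotypes and valid[ph].any():
            a0, b0 = affine0[ph]
            p = np.clip((y[ph] - a0) / b0, eps, 1 - eps)
            w = valid[ph] * (0.1 + 0.9 * ((p > 0.02) & (p < 0.98)))
            coef = wls(-logit(p), w)
            theta[pack.slices[f"wt_{TRAIT_FOLDING}"]] = coef[0]
            theta[pack.slices[f"ddg_{TRAIT_FOLDING}"]] = coef[1:1 + pack.k]
            if pack.order == 2:
                theta[pack.slices[f"cpl_{TRAIT_FOLDING}"]] = coef[1 + pack.k:]
            if PHENOTYPE_BINDING in pack.phenotypes and valid[PHENOTYPE_BINDING].any():
                # invert p_fb given the folding-energy init
                tf = D @ coef
                kf = np.exp(-np.clip(tf, -30, 30))
                a0, b0 = affine0[PHENOTYPE_BINDING]
                pb = np.clip((y[PHENOTYPE_BINDING] - a0) / b0, eps, 1 - eps)
                kbc = pb * (1.0 + kf) / (kf * (1.0 - pb))
                tb = -np.log(np.clip(kbc / self.ligand_concentration, 1e-12, 1e12))
                w = valid[PHENOTYPE_BINDING] * (0.1 + 0.9 * ((pb > 0.02) & (pb < 0.98)))
                coef_b = wls(tb, w)
                theta[pack.slices[f"wt_{TRAIT_BINDING}"]] = coef_b[0]
                theta[pack.slices[f"ddg_{TRAIT_BINDING}"]] = coef_b[1:1 + pack.k]
                if pack.order == 2:
                    theta[pack.slices[f"cpl_{TRAIT_BINDING}"]] = coef_b[1 + pack.k:]
        return theta

    def _l2_polish(self, theta, pack, X, Xp, y, sig, valid, max_nfev: int = 60,
                   ridge: float = 1.0):
        """Gauss-Newton warm start: weighted least squares on the residuals.

        Polishes the logit-inversion initializer against the smooth L2
        analogue of the training objective before the Adam protocol runs;
        keeps the subsequent stochastic optimization inside the relevant
        basin instead of the sloppy affine-versus-energy valley. A small
        ridge term pins coefficients the data leave flat (for example
        couplings of pairs never co-observed in the folding transition)
        near zero instead of letting them run off along zero-curvature
        directions; it is negligible for well-identified coefficients and
        applies to the warm start only, not to the training objective.
        """
        from scipy.optimize import least_squares

        rows = {ph: np.flatnonzero(valid[ph]) for ph in pack.phenotypes}
        sqrt_ridge = np.sqrt(ridge)

        def residuals(th):
            preds, _ = self._forward(th, pack, X, Xp)
            return np.concatenate([
                (preds[ph][rows[ph]] - y[ph][rows[ph]]) / sig[ph][rows[ph]]
                for ph in pack.phenotypes] + [sqrt_ridge * th])

        def jacobian(th):
            preds, cache = self._forward(th, pack, X, Xp)
            blocks = []
            for ph in pack.phenotypes:
                idx = rows[ph]
                J = np.zeros((len(idx), pack.size))
                b = th[pack.slices[f"affine_{ph}"]][1]
                if ph == PHENOTYPE_ABUNDANCE:
                    p = cache["p_f"][idx]
                    g_tf = -b * p * (1.0 - p)
                    g_tb = None
                else:
                    p = cache["p_fb"][idx]
                    g_tf = -b * p * cache["p_uu"][idx]
                    g_tb = -b * p * (1.0 - p)
                for tr, g in ((TRAIT_FOLDING, g_tf), (TRAIT_BINDING, g_tb)):
                    if tr not in pack.traits or g is None:
                        continue
                    J[:, pack.slices[f"wt_{tr}"].start] = g
                    J[:, pack.slices[f"ddg_{tr}"]] = X[idx] * g[:, None]
                    if pack.order == 2:
                        J[:, pack.slices[f"cpl_{tr}"]] = Xp[idx] * g[:, None]
                a_sl = pack.slices[f"affine_{ph}"]
                J[:, a_sl.start] = 1.0
                J[:, a_sl.start + 1] = p
                blocks.append(J / sig[ph][idx][:, None])
            blocks.append(sqrt_ridge * np.eye(pack.size))
            return np.vstack(blocks)

        try:
            res = least_squares(residuals, theta, jac=jacobian,
                                max_nfev=max_nfev, method="trf")
            if np.all(np.isfinite(res.x)):
                return res.x
        except Exception:  # fall back to the unpolished initializer
            logger.debug("least-squares warm start failed", exc_info=True)
        return theta

    def _train(self, theta0, pack, data, batch_size, n_epochs, rng):
        """Adam loop over minibatches; returns theta and history."""
        Xtr, Xptr, ytr, sigtr, vtr = data["train"]
        theta = theta0.copy()
        m = np.zeros_like(theta)
        v = np.zeros_like(theta)
        t_step = 0
        lr = self.initial_lr
        n = Xtr.shape[0]
        hist = {"train_loss": [], "val_loss": [], "lr": []}
        wt_track = []
        w = self.early_stop_window
        for epoch in range(n_epochs):
            perm = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, batch_size):
                idx = perm[start:start + batch_size]
                loss, grad = self._loss_grad(
                    theta, pack, Xtr[idx], Xptr[idx] if Xptr is not None else None,
                    {ph: ytr[ph][idx] for ph in pack.phenotypes},
                    {ph: sigtr[ph][idx] for ph in pack.phenotypes},
                    {ph: vtr[ph][idx] for ph in pack.phenotypes})
                t_step += 1
                m = 0.9 * m + 0.1 * grad
                v = 0.999 * v + 0.001 * grad * grad
                mhat = m / (1 - 0.9 ** t_step)
                vhat = v / (1 - 0.999 ** t_step)
                theta -= lr * mhat / (np.sqrt(vhat) + 1e-8)
                epoch_loss += loss
                n_batches += 1
            if not np.isfinite(epoch_loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) with config "
                    f"{self.get_params()}")
            val_loss = self._eval_loss(theta, pack, *data["val"])
            hist["train_loss"].append(epoch_loss / max(n_batches, 1))
            hist["val_loss"].append(val_loss)
            hist["lr"].append(lr)
            # lr decay: validation loss not improved in the last window
            # of epochs compared with the preceding window
            vl = hist["val_loss"]
            if len(vl) >= 2 * w and np.mean(vl[-w:]) >= np.mean(vl[-2 * w:-w]):
                lr *= self.lr_decay
            # early stop: wild-type free energies stabilized
            wt_track.append([pack.get(theta, f"wt_{tr}")[0] * self.rt
                             for tr in pack.traits])
            if len(wt_track) >= w:
                recent = np.array(wt_track[-w:])
                if np.all(recent.std(axis=0) <= self.early_stop_sd):
                    break
        return theta, hist

    # -- public API --------------------------------------------------------

    def fit(self, X, y, sigma=None, split_labels=None):
        X = check_array(X, dtype=float)
        n, k = X.shape
        phenotypes = list(self.phenotypes)
        traits = self._traits()
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if y.shape != (n, len(phenotypes)):
            raise ValueError(f"y must have shape (n, {len(phenotypes)})")
        if sigma is None:
            sigma = np.ones_like(y)
        sigma = np.asarray(sigma, dtype=float)
        if sigma.ndim == 1:
            sigma = sigma[:, None]
        valid = {ph: np.isfinite(y[:, i]) & np.isfinite(sigma[:, i]) & (sigma[:, i] > 0)
                 for i, ph in enumerate(phenotypes)}
        ydict = {ph: np.nan_to_num(y[:, i]) for i, ph in enumerate(phenotypes)}
        sigdict = {ph: np.where(valid[ph], sigma[:, i], 1.0)
                   for i, ph in enumerate(phenotypes)}

        pack = _ParamPack(k, traits, phenotypes, self.max_interaction_order)
        if n < pack.size:
            raise ValueError(
                f"unidentifiable model: {n} variants < {pack.size} parameters")

        rng = np.random.default_rng(self.seed)
        if split_labels is None:
            wt_idx = np.flatnonzero(X.sum(axis=1) == 0)
            split_labels = split_variants(
                n, self.split_fractions, seed=int(rng.integers(2 ** 31)),
                wildtype_index=int(wt_idx[0]) if wt_idx.size else None)
        split_labels = np.asarray(split_labels, dtype=object)

        if self.resample_training:
            tr_mask = split_labels == "train"
            for ph in phenotypes:
                noise = rng.normal(0.0, sigdict[ph])
                ydict[ph] = ydict[ph] + np.where(tr_mask & valid[ph], noise, 0.0)

        Xp = pairwise_design(X) if self.max_interaction_order == 2 else None

        def subset(label):
            mask = split_labels == label
            return (X[mask], Xp[mask] if Xp is not None else None,
                    {ph: ydict[ph][mask] for ph in phenotypes},
                    {ph: sigdict[ph][mask] for ph in phenotypes},
                    {ph: valid[ph][mask] for ph in phenotypes})

        data = {"train": subset("train"), "val": subset("val")}

        theta0 = self._init_theta(pack, X, Xp, ydict, valid, rng)
        Xtr, Xptr, ytr, sigtr, vtr = data["train"]
        theta0 = self._l2_polish(theta0, pack, Xtr, Xptr, ytr, sigtr, vtr)
        n_train = data["train"][0].shape[0]
        grid = [min(b, n_train) for b in self.batch_size_grid]
        grid = sorted(set(grid))
        if len(grid) > 1:
            val_losses = []
            for bs in grid:
                th, _ = self._train(theta0, pack, data, bs,
                                    self.hyperparameter_epochs,
                                    np.random.default_rng(int(rng.integers(2 ** 31))))
                val_losses.append(self._eval_loss(th, pack, *data["val"]))
            batch_size = grid[int(np.argmin(val_losses))]
            logger.info("selected batch size %d (val losses %s)", batch_size,
                        dict(zip(grid, val_losses)))
        else:
            batch_size = grid[0]

        theta, hist = self._train(theta0, pack, data, batch_size,
                                  self.max_epochs,
                                  np.random.default_rng(int(rng.integers(2 ** 31))))

        model = EnergyModel(
            traits=tuple(traits),
            dg_wt={tr: float(pack.get(theta, f"wt_{tr}")[0] * self.rt) for tr in traits},
            ddg={tr: pack.get(theta, f"ddg_{tr}") * self.rt for tr in traits},
            couplings={tr: (pack.get(theta, f"cpl_{tr}") * self.rt
                            if self.max_interaction_order == 2 else None)
                       for tr in traits},
            affine={ph: (float(pack.get(theta, f"affine_{ph}")[0]),
                         float(pack.get(theta, f"affine_{ph}")[1]))
                    for ph in phenotypes},
            ligand_concentration=self.ligand_concentration, rt=self.rt,
        ).canonicalized()

        self.model_ = model
        self.history_ = pd.DataFrame(
            {"epoch": np.arange(len(hist["train_loss"])), **hist})
        self.split_labels_ = split_labels
        self.batch_size_ = batch_size
        self.n_features_in_ = k
        test = split_labels == "test"
        self.r2_ = {}
        for i, ph in enumerate(phenotypes):
            mask = test & valid[ph]
            if mask.sum() >= 2:
                self.r2_[ph] = variance_explained(
                    model, X[mask], {ph: y[:, i][mask]})[ph]
        return self

    def predict(self, X, phenotype: str | None = None):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float)
        if phenotype is not None:
            return self.model_.predict_fitness(X, phenotype)
        preds = [self.model_.predict_fitness(X, ph) for ph in self.phenotypes]
        return preds[0] if len(preds) == 1 else np.column_stack(preds)


class LinearInteractionRegressor(BaseEstimator, RegressorMixin):
    """Linear genotype-fitness baseline with interaction terms up to order 3.

    Weighted least squares of fitness on products of genotype indicators up
    to ``max_order`` (1 + sum_k C(K, k) parameters), with 1/sigma weights to
    match the energy model's downweighting of uncertain measurements.
    """

    def __init__(self, max_order: int = 1):
        if max_order not in (1, 2, 3):
            raise ValueError("max_order must be 1, 2 or 3")
        self.max_order = max_order

    def _design(self, X: np.ndarray) -> np.ndarray:
        cols = [np.ones(X.shape[0]), X]
        if self.max_order >= 2:
            cols.append(pairwise_design(X))
        if self.max_order >= 3:
            triples = list(itertools.combinations(range(X.shape[1]), 3))
            if triples:
                ii, jj, kk = zip(*triples)
                cols.append(X[:, list(ii)] * X[:, list(jj)] * X[:, list(kk)])
        return np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c
                                for c in cols])

    def fit(self, X, y, sigma=None):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float)
        D = self._design(X)
        if D.shape[0] < D.shape[1]:
            raise ValueError(
                f"underdetermined design: {D.shape[0]} rows < {D.shape[1]} parameters")
        w = np.ones_like(y) if sigma is None else 1.0 / np.asarray(sigma, float)
        sw = np.sqrt(w)
        coef, _, rank, _ = np.linalg.lstsq(D * sw[:, None], y * sw, rcond=None)
        self.coef_ = coef
        self.rank_ = int(rank)
        self.n_features_in_ = X.shape[1]
        self.n_parameters_ = D.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return self._design(X) @ self.coef_


# ---------------------------------------------------------------------------
# Functional wrappers and analyses
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted model plus its training diagnostics."""

    model: EnergyModel
    history: pd.DataFrame
    split_labels: np.ndarray
    r2: dict[str, float]
    config: FitConfig
    batch_size: int | None = None

    def __post_init__(self):
        if len(self.history) == 0:
            raise ValueError("training history must be non-empty")


def _table_xy(table: GenotypeTable, phenotypes: Sequence[str]):
    y = np.column_stack([
        table.fitness[ph] if ph in table.fitness else np.full(table.n, np.nan)
        for ph in phenotypes])
    sig = np.column_stack([
        table.sigma[ph] if ph in table.sigma else np.full(table.n, np.nan)
        for ph in phenotypes])
    return table.genotypes.astype(float), y, sig


def fit_energy_model(
    table: GenotypeTable,
    config: FitConfig | None = None,
    phenotypes: Sequence[str] | None = None,
    split_labels: np.ndarray | None = None,
) -> FitResult:
    """Fit a thermodynamic model to a variant table with the full protocol."""
    config = config or FitConfig()
    if phenotypes is None:
        phenotypes = [ph for ph in (PHENOTYPE_ABUNDANCE, PHENOTYPE_BINDING)
                      if ph in table.fitness]
    est = ThermoModelRegressor(
        max_interaction_order=config.max_interaction_order,
        phenotypes=tuple(phenotypes),
        initial_lr=config.initial_lr, lr_decay=config.lr_decay,
        max_epochs=config.max_epochs,
        hyperparameter_epochs=config.hyperparameter_epochs,
        batch_size_grid=tuple(config.batch_size_grid), l2=config.l2,
        split_fractions=tuple(config.split_fractions), seed=config.seed,
        early_stop_sd=config.early_stop_sd,
        early_stop_window=config.early_stop_window,
        ligand_concentration=config.ligand_concentration,
        resample_training=config.resample_training,
    )
    X, y, sig = _table_xy(table, phenotypes)
    est.fit(X, y, sigma=sig, split_labels=split_labels)
    return FitResult(model=est.model_, history=est.history_,
                     split_labels=est.split_labels_, r2=est.r2_,
                     config=config, batch_size=est.batch_size_)


def fit_linear_baseline(
    table: GenotypeTable,
    max_order: int = 1,
    phenotype: str = PHENOTYPE_ABUNDANCE,
    split_labels: np.ndarray | None = None,
    seed: int = 0,
) -> dict:
    """Least-squares baseline on the same splits as the energy model.

    Returns a dict with the estimator, split labels, test-split R^2 and the
    parameter count 1 + sum_{k<=order} C(K, k).
    """
    if split_labels is None:
        split_labels = split_variants(table, seed=seed)
    est = LinearInteractionRegressor(max_order=max_order)
    train = split_labels == "train"
    est.fit(table.genotypes[train].astype(float), table.fitness[phenotype][train],
            sigma=table.sigma[phenotype][train] if phenotype in table.sigma else None)
    test = split_labels == "test"
    yhat = est.predict(table.genotypes[test].astype(float))
    yobs = table.fitness[phenotype][test]
    ss_res = float(np.sum((yobs - yhat) ** 2))
    ss_tot = float(np.sum((yobs - yobs.mean()) ** 2))
    return {"estimator": est, "split_labels": split_labels,
            "r2": {phenotype: 1.0 - ss_res / ss_tot},
            "n_parameters": est.n_parameters_}


def variance_explained(model: EnergyModel, X, fitness: dict[str, np.ndarray]) -> dict[str, float]:
    """R^2 = 1 - SS_res/SS_tot of model predictions on observed fitness."""
    out = {}
    for ph, yobs in fitness.items():
        yobs = np.asarray(yobs, float)
        if len(yobs) == 0:
            raise ValueError("empty subset")
        if np.allclose(yobs.var(), 0):
            raise ValueError("zero-variance subset")
        yhat = model.predict_fitness(X, ph)
        out[ph] = 1.0 - float(np.sum((yobs - yhat) ** 2) / np.sum((yobs - yobs.mean()) ** 2))
    return out


def classify_and_test(
    table: GenotypeTable,
    model: EnergyModel,
    wildtype_index: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variant folded/bound flags and wild-type indistinguishability.

    folded = predicted p_f > 0.5 (strict; ties classify negative), bound =
    predicted p_fb > 0.5, and per phenotype a two-sided z-test against the
    wild-type fitness, z = (y_v - y_wt) / sqrt(sigma_v^2 + sigma_wt^2),
    indistinguishable iff p = 2 Phi(-|z|) > alpha.
    """
    if wildtype_index is None:
        wildtype_index = table.wildtype_index()
    X = table.genotypes.astype(float)
    out = pd.DataFrame({"order": table.order})
    out["folded"] = model.state_probability(X, PHENOTYPE_ABUNDANCE) > 0.5
    if PHENOTYPE_BINDING in model.phenotypes:
        out["bound"] = model.state_probability(X, PHENOTYPE_BINDING) > 0.5
    for ph in table.phenotypes:
        if ph not in table.sigma:
            raise ValueError(f"missing sigma for phenotype {ph}")
        y, s = table.fitness[ph], table.sigma[ph]
        y_wt, s_wt = y[wildtype_index], s[wildtype_index]
        z = (y - y_wt) / np.sqrt(s ** 2 + s_wt ** 2)
        p = 2.0 * norm.cdf(-np.abs(z))
        out[f"z_{ph}"] = z
        out[f"p_{ph}"] = p
        out[f"wt_indistinguishable_{ph}"] = p > alpha
    return out


def monte_carlo_uncertainty(
    table: GenotypeTable,
    config: FitConfig | None = None,
    phenotypes: Sequence[str] | None = None,
    ci_threshold: float = 1.0,
) -> dict:
    """Monte Carlo confidence intervals from repeated refits.

    Fits ``config.n_mc_models`` models, each with an independent random
    train/validation/test split and the training fitness replaced by an
    independent draw from each variant's error distribution. Per-coefficient
    mean, sd and 95% CI (2.5-97.5 percentile span across refits) are
    reported; a coefficient is ``confident`` iff its CI width is below
    ``ci_threshold`` (1 kcal/mol). Failed member fits are reported; CIs are
    computed on survivors only if at least 8 remain.
    """
    config = config or FitConfig()
    if config.n_mc_models < 2:
        raise ValueError("n_mc_models must be >= 2")
    rng = np.random.default_rng(config.seed)
    models, failures = [], []
    for i in range(config.n_mc_models):
        sub = FitConfig(**{**asdict(config),
                           "seed": int(rng.integers(2 ** 31)),
                           "resample_training": True})
        try:
            models.append(fit_energy_model(table, sub, phenotypes).model)
        except (RuntimeError, ValueError) as exc:  # divergence of one member
            failures.append(str(exc))
    min_survivors = min(8, config.n_mc_models) if config.n_mc_models >= 8 else 2
    if len(models) < min_survivors:
        raise RuntimeError(
            f"only {len(models)}/{config.n_mc_models} Monte Carlo fits "
            f"succeeded: {failures}")

    def summarize(values: np.ndarray) -> pd.DataFrame:
        lo, hi = np.percentile(values, [2.5, 97.5], axis=0)
        return pd.DataFrame({
            "mean": values.mean(axis=0), "sd": values.std(axis=0, ddof=1),
            "ci95_lo": lo, "ci95_hi": hi, "ci95_width": hi - lo,
            "confident": (hi - lo) < ci_threshold})

    out = {"n_models": len(models), "failures": failures, "models": models}
    for tr in models[0].traits:
        out[f"ddg_{tr}"] = summarize(np.array([m.ddg[tr] for m in models]))
        if models[0].couplings.get(tr) is not None:
            out[f"couplings_{tr}"] = summarize(
                np.array([m.couplings[tr] for m in models]))
    return out


def export_coefficients(mc: dict, lib: LibraryDefinition | None, path) -> pd.DataFrame:
    """Coefficient table (ids, trait, mean, sd, CI, confident), tab-separated."""
    k = mc["models"][0].k
    names = (lib.codes if lib is not None else [str(i) for i in range(k)])
    rows = []
    for tr in mc["models"][0].traits:
        for i, row in mc[f"ddg_{tr}"].iterrows():
            rows.append({"id": names[i], "trait": tr, **row.to_dict()})
        key = f"couplings_{tr}"
        if key in mc:
            for (i, j), (_, row) in zip(pair_index(k), mc[key].iterrows()):
                rows.append({"id": f"{names[i]}:{names[j]}", "trait": tr,
                             **row.to_dict()})
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
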