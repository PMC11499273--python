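"""Structural analysis of energetic couplings.

Relates inferred pairwise energetic couplings to protein structure:
minimal side-chain heavy-atom distances and contact maps from a PDB
structure, a 12-feature ordinary-least-squares model of coupling strength
(|coupling| regressed on five distance/position metrics and seven
GetContacts bond counts), and coupling-strength-versus-distance
statistics (Spearman correlations, binned means with Monte Carlo
confidence bands).

RSASA, secondary structure, ligand distances and bond counts are consumed
as input tables; they are not recomputed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio.PDB import PDBParser
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: The 12 feature columns, in canonical order.
FEATURE_COLUMNS = [
    "backbone_distance", "scha_distance", "n_core", "n_interface", "n_strand",
    "hbond_bb_bb", "hbond_sb", "hbond_ss", "pi_cation", "pi_stacking",
    "salt_bridge", "vdw",
]

#: GetContacts interaction-type labels -> feature columns.
CONTACT_TYPE_MAP = {
    "hbbb": "hbond_bb_bb",
    "hbsb": "hbond_sb",
    "hbss": "hbond_ss",
    "pc": "pi_cation",
    "ps": "pi_stacking",
    "sb": "salt_bridge",
    "vdw": "vdw",
}


@dataclass
class ResidueAnnotation:
    """Per-residue structural annotation (inputs, not computed here)."""

    position: int
    rsasa: float
    secondary_structure: str
    ligand_distance: float

    def __post_init__(self):
        if not 0.0 <= self.rsasa <= 1.0:
            raise ValueError(f"rsasa must be in [0, 1], got {self.rsasa}")
        if self.ligand_distance < 0:
            raise ValueError("distances must be >= 0")


def read_annotations(path) -> pd.DataFrame:
    """Annotation file: tab-separated position, rsasa, ss, ligand_distance."""
    df = pd.read_csv(path, sep="\t")
    for col in ("position", "rsasa", "ss", "ligand_distance"):
        if col not in df.columns:
            raise ValueError(f"annotation file missing column {col}")
    for _, row in df.iterrows():
        ResidueAnnotation(int(row["position"]), float(row["rsasa"]),
                          str(row["ss"]), float(row["ligand_distance"]))
    return df.set_index("position", drop=False)


# ---------------------------------------------------------------------------
# Distances and contact maps
# ---------------------------------------------------------------------------

def load_structure(path, chain: str | None = None):
    """First model of a PDB file, optionally restricted to one chain."""
    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", path)[0]
    if chain is not None:
        return model[chain]
    return next(iter(model))


def _sidechain_coords(chain, pdb_resnum: int) -> np.ndarray:
    """Heavy side-chain atom coordinates; Cα fallback for glycine.

    Glycine has no side-chain heavy atoms, so its Cα stands in (flagged at
    DEBUG level).
    """
    try:
        res = chain[pdb_resnum]
    except KeyError:
        raise KeyError(f"residue {pdb_resnum} missing from structure") from None
    coords = [a.coord for a in res.get_atoms()
              if a.element != "H" and a.get_name() not in BACKBONE_ATOMS]
    if not coords:
        if "CA" not in res:
            raise ValueError(f"residue {pdb_resnum} has no side-chain atoms or CA")
        logger.debug("residue %d: no side-chain heavy atoms, Cα fallback", pdb_resnum)
        coords = [res["CA"].coord]
    return np.asarray(coords, dtype=float)


def min_sidechain_distance(
    chain,
    res_i: int,
    res_j: int,
    offset_map: dict[int, int] | None = None,
) -> float:
    """Minimal side-chain heavy-atom distance between two residues (Å).

    ``res_i``/``res_j`` are 1-based sequence positions; ``offset_map``
    translates them to PDB residue numbers (identity by default).
    Symmetric; 0 for a residue with itself.
    """
    to_pdb = (lambda p: offset_map.get(p, p)) if offset_map else (lambda p: p)
    ci = _sidechain_coords(chain, to_pdb(res_i))
    cj = _sidechain_coords(chain, to_pdb(res_j))
    d = np.linalg.norm(ci[:, None, :] - cj[None, :, :], axis=-1)
    return float(d.min())


def contact_map(
    chain,
    positions: list[int],
    threshold: float = 8.0,
    long_range_cutoff: int = 5,
    offset_map: dict[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean contact matrix over ``positions`` plus a long-range mask.

    Contact iff minimal side-chain heavy-atom distance < ``threshold`` Å
    (8 Å default); diagonal excluded. The mask flags pairs distal in the
    primary sequence (|i - j| > ``long_range_cutoff`` residues).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    n = len(positions)
    contacts = np.zeros((n, n), dtype=bool)
    long_range = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            d = min_sidechain_distance(chain, positions[a], positions[b], offset_map)
            contacts[a, b] = contacts[b, a] = d < threshold
            lr = abs(positions[a] - positions[b]) > long_range_cutoff
            long_range[a, b] = long_range[b, a] = lr
    return contacts, long_range


# ---------------------------------------------------------------------------
# GetContacts-style bond counts
# ---------------------------------------------------------------------------

def read_contacts(path) -> pd.DataFrame:
    """Read a GetContacts-style tab-separated contacts file.

    Rows: frame, interaction_type, atom1, atom2 with atoms formatted
    ``chain:RES:number:atom``. Returns per-pair bond-type counts (every
    listed row counts once; repeated rows accumulate). Unknown interaction
    labels are ignored with a warning.
    """
    counts: dict[tuple[int, int], dict[str, int]] = {}
    unknown = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                continue
            _, itype, atom1, atom2 = parts[:4]
            col = CONTACT_TYPE_MAP.get(itype)
            if col is None:
                unknown.add(itype)
                continue
            r1 = int(atom1.split(":")[2])
            r2 = int(atom2.split(":")[2])
            if r1 == r2:
                continue
            key = (min(r1, r2), max(r1, r2))
            counts.setdefault(key, {c: 0 for c in CONTACT_TYPE_MAP.values()})
            counts[key][col] += 1
    if unknown:
        warnings.warn(f"ignoring unknown interaction types: {sorted(unknown)}")
    rows = [{"pos_i": i, "pos_j": j, **c} for (i, j), c in sorted(counts.items())]
    cols = ["pos_i", "pos_j", *CONTACT_TYPE_MAP.values()]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Pair feature table and the 12-feature model
# ---------------------------------------------------------------------------

def build_pair_features(
    couplings: pd.DataFrame,
    annotations: pd.DataFrame,
    chain=None,
    contacts: pd.DataFrame | None = None,
    offset_map: dict[int, int] | None = None,
    scha_distances: dict[tuple[int, int], float] | None = None,
    core_rsasa: float = 0.25,
    interface_distance: float = 5.0,
) -> pd.DataFrame:
    """Assemble the 12-feature table for coupled residue pairs.

    ``couplings`` needs columns pos_i, pos_j, strength (|coupling|,
    kcal/mol). Distance features come from ``chain`` or, alternatively, a
    precomputed ``scha_distances`` dict keyed by sorted position pairs.
    Pairs absent from the contacts table get zero bond counts.
    """
    if contacts is not None and len(contacts):
        contact_idx = contacts.set_index(["pos_i", "pos_j"])
    else:
        contact_idx = None
    rows = []
    for _, cpl in couplings.iterrows():
        i, j = int(cpl["pos_i"]), int(cpl["pos_j"])
        i, j = min(i, j), max(i, j)
        for p in (i, j):
            if p not in annotations.index:
                raise ValueError(f"coupling pair ({i},{j}): no annotation for residue {p}")
        if scha_distances is not None:
            d3 = scha_distances[(i, j)]
        elif chain is not None:
            d3 = min_sidechain_distance(chain, i, j, offset_map)
        else:
            raise ValueError("either a structure chain or scha_distances is required")
        ann_i, ann_j = annotations.loc[i], annotations.loc[j]
        row = {
            "pos_i": i, "pos_j": j,
            "backbone_distance": abs(j - i),
            "scha_distance": d3,
            "n_core": int(ann_i["rsasa"] < core_rsasa) + int(ann_j["rsasa"] < core_rsasa),
            "n_interface": int(ann_i["ligand_distance"] < interface_distance)
                           + int(ann_j["ligand_distance"] < interface_distance),
            "n_strand": int(ann_i["ss"] == "strand") + int(ann_j["ss"] == "strand"),
        }
        for col in CONTACT_TYPE_MAP.values():
            row[col] = 0
        if contact_idx is not None and (i, j) in contact_idx.index:
            for col in CONTACT_TYPE_MAP.values():
                row[col] = int(contact_idx.loc[(i, j), col])
        row["strength"] = float(cpl["strength"])
        rows.append(row)
    df = pd.DataFrame(rows)
    assert list(df.columns[2:-1]) == FEATURE_COLUMNS, "feature layout violated"
    return df


class CouplingStrengthModel:
    """OLS of coupling strength on the 12 standardized structural features.

    Features are z-scored with the training mean/sd (scale-free coefficient
    ranking); the response is left in kcal/mol. Exposes statsmodels-style
    ``coef_``, ``pvalues_`` (uncorrected two-sided t-tests) and
    ``summary_``.
    """

    def __init__(self):
        pass

    def _check_features(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        X = table[FEATURE_COLUMNS].to_numpy(float)
        if X.shape[1] != 12:
            raise AssertionError("feature matrix must have exactly 12 columns")
        return X

    def fit(self, table: pd.DataFrame, min_pairs: int = 20):
        X = self._check_features(table)
        if len(table) < min_pairs:
            raise ValueError(f"need >= {min_pairs} training pairs, got {len(table)}")
        y = table["strength"].to_numpy(float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        degenerate = sd == 0
        if degenerate.any():
            bad = [c for c, d in zip(FEATURE_COLUMNS, degenerate) if d]
            raise ValueError(f"constant (rank-deficient) feature columns: {bad}")
        self.sd_ = sd
        Z = (X - self.mean_) / self.sd_
        rank = np.linalg.matrix_rank(Z)
        if rank < Z.shape[1]:
            # identify offending columns by dropping each in turn
            bad = [FEATURE_COLUMNS[c] for c in range(Z.shape[1])
                   if np.linalg.matrix_rank(np.delete(Z, c, axis=1)) == rank]
            raise ValueError(f"collinear feature columns: {bad}")
        res = sm.OLS(y, sm.add_constant(Z)).fit()
        self.result_ = res
        self.intercept_ = float(res.params[0])
        self.coef_ = pd.Series(res.params[1:], index=FEATURE_COLUMNS)
        self.pvalues_ = pd.Series(res.pvalues[1:], index=FEATURE_COLUMNS)
        self.train_pairs_ = set(map(tuple, table[["pos_i", "pos_j"]].to_numpy()))
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = self._check_features(table)
        Z = (X - self.mean_) / self.sd_
        return self.intercept_ + Z @ self.coef_.to_numpy()

    def ranked_features(self) -> pd.DataFrame:
        """Features ranked by coefficient significance (ascending p)."""
        return pd.DataFrame({"coefficient": self.coef_, "p_value": self.pvalues_}
                            ).sort_values("p_value")


def fit_coupling_strength_model(train: pd.DataFrame) -> CouplingStrengthModel:
    """Fit the 12-feature linear model of |coupling| (see Fig.-style report)."""
    return CouplingStrengthModel().fit(train)


def evaluate_coupling_model(model: CouplingStrengthModel, test: pd.DataFrame) -> dict:
    """Pearson r and R^2 on a held-out pair set, disjoint from training."""
    test_pairs = set(map(tuple, test[["pos_i", "pos_j"]].to_numpy()))
    overlap = test_pairs & model.train_pairs_
    if overlap:
        raise ValueError(f"test pairs overlap training pairs: {sorted(overlap)[:5]}")
    yhat = model.predict(test)
    yobs = test["strength"].to_numpy(float)
    r = float(np.corrcoef(yobs, yhat)[0, 1])
    r2 = 1.0 - float(np.sum((yobs - yhat) ** 2) / np.sum((yobs - yobs.mean()) ** 2))
    return {"pearson_r": r, "r2": r2, "n_pairs": len(test)}


# ---------------------------------------------------------------------------
# Coupling strength vs distance statistics
# ---------------------------------------------------------------------------

def coupling_distance_stats(
    strengths: np.ndarray,
    scha_distances: np.ndarray,
    backbone_distances: np.ndarray,
    mc_strengths: np.ndarray | None = None,
    backbone_cutoff: int = 5,
    contact_cutoff: float = 5.0,
    bins: np.ndarray | None = None,
) -> dict:
    """Spearman correlations and binned means of coupling strength.

    Reports rho(strength, 3D side-chain distance) over all pairs and
    restricted to backbone-distal pairs (> ``backbone_cutoff`` residues),
    and rho(strength, backbone distance) over all pairs and excluding
    direct physical contacts (< ``contact_cutoff`` Å). When per-Monte-Carlo
    replicate strengths (n_models, n_pairs) are given, binned means carry
    2.5/97.5 percentile bands across the replicates.
    """
    strengths = np.asarray(strengths, float)
    scha = np.asarray(scha_distances, float)
    bb = np.asarray(backbone_distances, float)

    def rho(x, y, mask=None):
        if mask is not None:
            x, y = x[mask], y[mask]
        if len(x) < 3:
            raise ValueError("fewer than 3 pairs after restriction")
        return float(spearmanr(x, y).statistic)

    out = {
        "rho_scha_all": rho(strengths, scha),
        "rho_scha_backbone_distal": rho(strengths, scha, bb > backbone_cutoff),
        "rho_backbone_all": rho(strengths, bb),
        "rho_backbone_no_contacts": rho(strengths, bb, scha >= contact_cutoff),
    }
    if bins is None:
        bins = np.quantile(scha, np.linspace(0, 1, 6))
        bins[-1] += 1e-9
    idx = np.clip(np.digitize(scha, bins) - 1, 0, len(bins) - 2)
    binned = []
    for b in range(len(bins) - 1):
        mask = idx == b
        if not mask.any():
            continue
        row = {"bin_lo": float(bins[b]), "bin_hi": float(bins[b + 1]),
               "n": int(mask.sum()), "mean_strength": float(strengths[mask].mean())}
        if mc_strengths is not None:
            means = np.asarray(mc_strengths, float)[:, mask].mean(axis=1)
            row["ci95_lo"], row["ci95_hi"] = map(float, np.percentile(means, [2.5, 97.5]))
        binned.append(row)
    out["binned"] = pd.DataFrame(binned)
    return out
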