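"""Genotype and substitution encoding for combinatorial mutagenesis libraries.

A library is defined by K single amino-acid substitutions, at most one per
residue position; a variant is a subset of those substitutions, encoded
internally as a length-K binary vector (the canonical representation).
Variant fitness tables follow a DiMSum-style layout: one row per variant
with per-phenotype aggregate fitness, a standard error, and optionally
per-replicate fitness values.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_CODE_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def standard_genetic_code() -> dict[str, str]:
    """Standard genetic code as a 64-entry codon -> aa dict ('*' = stop)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for codon in table.stop_codons:
        code[codon] = "*"
    return code


def read_genetic_code(path) -> dict[str, str]:
    """Read a codon table override: 64 rows of ``codon<TAB>aa``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["codon", "aa"], comment="#")
    code = {str(c).upper(): str(a).upper() for c, a in zip(df["codon"], df["aa"])}
    if len(code) != 64:
        raise ValueError(f"genetic code file must define 64 codons, got {len(code)}")
    return code


@dataclass
class SubstitutionEffect:
    """A single amino-acid substitution and its inferred free-energy changes.

    Energies are in kcal/mol; ``ci95_*`` are 95% confidence-interval widths.
    ``n_backgrounds`` counts the genetic backgrounds in which the effect was
    measured. ``nt_reachable`` is None when undetermined.
    """

    position: int
    wt_aa: str
    mut_aa: str
    ddg_f: float | None = None
    ddg_b: float | None = None
    ci95_f: float | None = None
    ci95_b: float | None = None
    n_backgrounds: int = 0
    nt_reachable: bool | None = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"identity substitution {self.wt_aa}{self.position}{self.mut_aa}")
        for name in ("ci95_f", "ci95_b"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_backgrounds < 0:
            raise ValueError("n_backgrounds must be >= 0")

    @property
    def code(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    def __str__(self) -> str:
        return self.code


def parse_substitution(code: str) -> SubstitutionEffect:
    """Parse a substitution code such as ``"P11A"`` (wt aa, position, mutant aa).

    Energies are left unset. Raises ``ValueError`` on malformed codes and on
    identity substitutions such as ``"P11P"``.
    """
    m = _CODE_RE.match(code.strip())
    if m is None:
        raise ValueError(f"malformed substitution code: {code!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return SubstitutionEffect(position=pos, wt_aa=wt, mut_aa=mut)


@dataclass
class LibraryDefinition:
    """K single substitutions over a wild-type sequence, one per position."""

    wt_aa_seq: str
    substitutions: list[SubstitutionEffect]
    wt_nt_seq: str | None = None
    phenotypes: tuple[str, ...] = ("abundance",)

    def __post_init__(self):
        if len(self.substitutions) < 1:
            raise ValueError("library needs at least one substitution")
        positions = [s.position for s in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValueError("substitution positions must be distinct")
        for s in self.substitutions:
            if s.position > len(self.wt_aa_seq):
                raise ValueError(f"position {s.position} beyond sequence length")
            if self.wt_aa_seq[s.position - 1] != s.wt_aa:
                raise ValueError(
                    f"{s.code}: wild-type sequence has "
                    f"{self.wt_aa_seq[s.position - 1]} at position {s.position}"
                )
        if self.wt_nt_seq is not None and len(self.wt_nt_seq) != 3 * len(self.wt_aa_seq):
            raise ValueError("wt_nt_seq length must be 3x the aa sequence length")

    @property
    def k(self) -> int:
        return len(self.substitutions)

    @property
    def codes(self) -> list[str]:
        return [s.code for s in self.substitutions]

    def index_of(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"substitution {code} not in library") from None

    def wt_codon(self, position: int) -> str:
        if self.wt_nt_seq is None:
            raise ValueError("library has no nucleotide sequence")
        return self.wt_nt_seq[3 * (position - 1): 3 * position].upper()

    def variant_sequence(self, row: np.ndarray) -> str:
        """Amino-acid sequence of the variant encoded by a binary row."""
        seq = list(self.wt_aa_seq)
        for j, bit in enumerate(row):
            if bit:
                s = self.substitutions[j]
                seq[s.position - 1] = s.mut_aa
        return "".join(seq)


@dataclass
class GenotypeTable:
    """Binary genotype matrix with per-phenotype fitness and uncertainty.

    ``genotypes`` is an (n, K) 0/1 matrix; ``fitness[ph]`` and ``sigma[ph]``
    are length-n arrays; ``replicates[ph]`` is an optional (n, R) array that
    may contain NaN for replicates missing in a subset of variants.
    """

    genotypes: np.ndarray
    fitness: dict[str, np.ndarray] = field(default_factory=dict)
    sigma: dict[str, np.ndarray] = field(default_factory=dict)
    replicates: dict[str, np.ndarray] = field(default_factory=dict)
    library: LibraryDefinition | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D")
        uniq = {tuple(r) for r in self.genotypes.tolist()}
        if len(uniq) != self.genotypes.shape[0]:
            raise ValueError("duplicate genotype rows")
        for ph, s in self.sigma.items():
            s = np.asarray(s, float)
            if np.any(s <= 0):
                raise ValueError(f"sigma for phenotype {ph} must be > 0 on retained rows")
            self.sigma[ph] = s

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def k(self) -> int:
        return self.genotypes.shape[1]

    @property
    def order(self) -> np.ndarray:
        """Hamming distance from wild type (number of substitutions) per row."""
        return self.genotypes.sum(axis=1).astype(int)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.fitness)

    def wildtype_index(self) -> int:
        idx = np.flatnonzero(self.order == 0)
        if idx.size == 0:
            raise ValueError("table contains no wild-type (all-zero) row")
        return int(idx[0])

    def subset(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            genotypes=self.genotypes[mask],
            fitness={p: v[mask] for p, v in self.fitness.items()},
            sigma={p: v[mask] for p, v in self.sigma.items()},
            replicates={p: v[mask] for p, v in self.replicates.items()},
            library=self.library,
        )

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            genotypes=self.genotypes.copy(),
            fitness={p: v.copy() for p, v in self.fitness.items()},
            sigma={p: v.copy() for p, v in self.sigma.items()},
            replicates={p: v.copy() for p, v in self.replicates.items()},
            library=self.library,
        )

    def decode(self, row_index: int) -> list[str]:
        """Substitution codes present in one variant row."""
        if self.library is None:
            raise ValueError("table has no library definition")
        row = self.genotypes[row_index]
        return [self.library.codes[j] for j in np.flatnonzero(row)]


def encode_genotypes(
    variants: Iterable[Iterable[str | SubstitutionEffect]],
    lib: LibraryDefinition,
) -> GenotypeTable:
    """Encode substitution sets as a binary genotype matrix over ``lib``.

    Each element of ``variants`` is a collection of substitution codes (or
    SubstitutionEffect objects) that must all belong to the library; the
    empty set encodes the wild type.
    """
    variants = list(variants)
    mat = np.zeros((len(variants), lib.k), dtype=np.int8)
    for i, var in enumerate(variants):
        for s in var:
            code = s.code if isinstance(s, SubstitutionEffect) else str(s)
            mat[i, lib.index_of(code)] = 1
    return GenotypeTable(genotypes=mat, library=lib)


def single_nt_reachable(
    wt_codon: str,
    target_aa: str,
    code: dict[str, str] | None = None,
) -> bool:
    """Whether one nucleotide change of ``wt_codon`` yields ``target_aa``.

    Synonymous targets (target equal to the codon's own amino acid) return
    False: candidates are amino-acid substitutions, not codon changes. Stop
    codons are rejected as targets.
    """
    code = standard_genetic_code() if code is None else code
    wt_codon = wt_codon.upper()
    if len(wt_codon) != 3 or any(b not in "ACGT" for b in wt_codon):
        raise ValueError(f"invalid codon {wt_codon!r}")
    target_aa = target_aa.upper()
    if target_aa == "*":
        raise ValueError("stop codon is not a valid substitution target")
    if code.get(wt_codon, "*") == target_aa:
        return False
    for i in range(3):
        for b in "ACGT":
            if b == wt_codon[i]:
                continue
            neighbour = wt_codon[:i] + b + wt_codon[i + 1:]
            if code[neighbour] == target_aa:
                return True
    return False


def annotate_reachability(
    effects: Sequence[SubstitutionEffect],
    wt_nt_seq: str,
    code: dict[str, str] | None = None,
) -> list[SubstitutionEffect]:
    """Return copies of ``effects`` with ``nt_reachable`` filled in."""
    out = []
    for e in effects:
        codon = wt_nt_seq[3 * (e.position - 1): 3 * e.position].upper()
        out.append(replace(e, nt_reachable=single_nt_reachable(codon, e.mut_aa, code)))
    return out


# ---------------------------------------------------------------------------
# Tab-separated variant tables
# ---------------------------------------------------------------------------

def _parse_variant_field(value: str, lib: LibraryDefinition) -> list[str]:
    """Interpret the ``variant`` column: aa sequence or comma-separated codes."""
    value = str(value).strip()
    if value in ("", "WT", "wt"):
        return []
    if "," in value or _CODE_RE.match(value):
        return [parse_substitution(c).code for c in value.split(",") if c.strip()]
    if len(value) == len(lib.wt_aa_seq):
        codes = []
        by_pos = {s.position: s for s in lib.substitutions}
        for i, (a, b) in enumerate(zip(lib.wt_aa_seq, value.upper()), start=1):
            if a == b:
                continue
            s = by_pos.get(i)
            if s is None or s.mut_aa != b:
                raise ValueError(
                    f"sequence differs from wild type at non-library position {i} ({a}->{b})"
                )
            codes.append(s.code)
        return codes
    raise ValueError(f"cannot interpret variant field {value!r}")


def read_variant_table(
    path,
    lib: LibraryDefinition,
    phenotypes: Sequence[str] | None = None,
    require_complete_replicates: bool = False,
) -> GenotypeTable:
    """Read a tab-separated variant fitness table.

    Expected columns: ``variant`` (aa sequence or comma-separated substitution
    codes), then per phenotype ``fitness_<ph>`` and ``sigma_<ph>``, optionally
    ``rep1_<ph>`` .. ``repR_<ph>``. Rows missing fitness or sigma (or with
    sigma <= 0) for any declared phenotype are dropped with a logged count;
    ``require_complete_replicates`` additionally drops rows with any missing
    replicate value (the modelling set).
    """
    df = pd.read_csv(path, sep="\t")
    if "variant" not in df.columns:
        raise ValueError("variant table must have a 'variant' column")
    df["variant"] = df["variant"].fillna("")  # empty field = wild type
    if phenotypes is None:
        phenotypes = [c[len("fitness_"):] for c in df.columns if c.startswith("fitness_")]
        if not phenotypes:
            raise ValueError("no fitness_<phenotype> columns found")
    for ph in phenotypes:
        for col in (f"fitness_{ph}", f"sigma_{ph}"):
            if col not in df.columns:
                raise ValueError(f"missing mandatory column {col}")

    keep = np.ones(len(df), dtype=bool)
    for ph in phenotypes:
        ok = df[f"fitness_{ph}"].notna() & (df[f"sigma_{ph}"].fillna(0) > 0)
        keep &= ok.to_numpy()
        rep_cols = sorted(c for c in df.columns if re.match(rf"rep\d+_{ph}$", c))
        if require_complete_replicates and rep_cols:
            keep &= df[rep_cols].notna().all(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d rows lacking valid fitness/sigma", n_dropped)
    df = df[keep].reset_index(drop=True)

    variants = [_parse_variant_field(v, lib) for v in df["variant"]]
    table = encode_genotypes(variants, lib)
    for ph in phenotypes:
        table.fitness[ph] = df[f"fitness_{ph}"].to_numpy(float)
        table.sigma[ph] = df[f"sigma_{ph}"].to_numpy(float)
        rep_cols = sorted(c for c in df.columns if re.match(rf"rep\d+_{ph}$", c))
        if rep_cols:
            table.replicates[ph] = df[rep_cols].to_numpy(float)
    return table


def write_variant_table(table: GenotypeTable, path) -> None:
    """Write a GenotypeTable in the tab-separated variant-table layout."""
    if table.library is None:
        raise ValueError("table has no library definition")
    rows = {"variant": [",".join(table.decode(i)) or "WT" for i in range(table.n)],
            "order": table.order}
    for ph in table.phenotypes:
        rows[f"fitness_{ph}"] = table.fitness[ph]
        rows[f"sigma_{ph}"] = table.sigma[ph]
        if ph in table.replicates:
            reps = table.replicates[ph]
            for r in range(reps.shape[1]):
                rows[f"rep{r + 1}_{ph}"] = reps[:, r]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_substitution_table(path) -> list[SubstitutionEffect]:
    """Read a tab-separated single-substitution free-energy table."""
    df = pd.read_csv(path, sep="\t")

    def _opt(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return float(row[col])

    effects = []
    for _, row in df.iterrows():
        effects.append(SubstitutionEffect(
            position=int(row["position"]),
            wt_aa=str(row["wt_aa"]),
            mut_aa=str(row["mut_aa"]),
            ddg_f=_opt(row, "ddg_f"),
            ddg_b=_opt(row, "ddg_b"),
            ci95_f=_opt(row, "ci95_f"),
            ci95_b=_opt(row, "ci95_b"),
            n_backgrounds=int(row["n_backgrounds"]) if "n_backgrounds" in df.columns else 0,
        ))
    return effects


def write_substitution_table(effects: Sequence[SubstitutionEffect], path) -> None:
    df = pd.DataFrame([{
        "id": e.code, "position": e.position, "wt_aa": e.wt_aa, "mut_aa": e.mut_aa,
        "ddg_f": e.ddg_f, "ci95_f": e.ci95_f, "n_backgrounds": e.n_backgrounds,
        "ddg_b": e.ddg_b, "ci95_b": e.ci95_b,
    } for e in effects])
    df.to_csv(path, sep="\t", index=False)


def library_to_dict(lib: LibraryDefinition) -> dict:
    return {
        "wt_aa_seq": lib.wt_aa_seq,
        "wt_nt_seq": lib.wt_nt_seq,
        "phenotypes": list(lib.phenotypes),
        "substitutions": [s.code for s in lib.substitutions],
    }


def library_from_dict(d: dict) -> LibraryDefinition:
    return LibraryDefinition(
        wt_aa_seq=d["wt_aa_seq"],
        wt_nt_seq=d.get("wt_nt_seq"),
        phenotypes=tuple(d.get("phenotypes", ("abundance",))),
        substitutions=[parse_substitution(c) for c in d["substitutions"]],
    )


def translate(nt_seq: str, code: dict[str, str] | None = None) -> str:
    """Translate a nucleotide sequence (standard code by default)."""
    if code is None:
        return str(Seq(nt_seq).translate())
    return "".join(code[nt_seq[i:i + 3].upper()] for i in range(0, len(nt_seq), 3))
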