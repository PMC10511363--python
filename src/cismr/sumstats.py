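"""Canonical data model and I/O for association summary statistics.

The whole package works on GWAS- and eQTL-style per-variant association
summaries: one row per variant carrying effect/other allele, effect-allele
frequency, effect size, standard error, p-value and sample size.  This
module defines the in-memory containers (:class:`SummaryStats`,
:class:`LDMatrix`, :class:`GeneAnnot`) plus readers/writers for plain
tab-delimited tables and dense text LD matrices.

Conventions
-----------
* Coordinates are 1-based, inclusive (GRCh38-style); all window arithmetic
  downstream uses closed intervals.
* Chromosome labels are strings with any leading ``"chr"`` stripped.
* Alleles are upper-cased single bases; only biallelic SNPs are kept
  (indels are dropped at load and counted in the load report).
* Effect sizes are per effect-allele: log-odds for case/control traits,
  per unit of trait for quantitative traits.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for summary-statistic tables
CANONICAL_COLUMNS = (
    "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n", "n_case",
)
#: fields that must be mapped for a load to proceed
REQUIRED_FIELDS = ("chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue")

TRAIT_TYPES = ("quantitative", "case_control")


def normalize_chrom(label) -> str:
    """Strip a leading ``chr`` prefix; X/Y/MT stay as strings."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def _chrom_rank(c: str):
    """Sort key putting numeric chromosomes first in numeric order."""
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def complement_allele(a: str) -> str:
    return COMPLEMENT[a]


def is_palindromic(a: str, b: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be resolved from labels."""
    return COMPLEMENT.get(a) == b


class VariantKey(NamedTuple):
    """Identity of one SNP: chromosome, 1-based position, effect/other allele."""

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def validate(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for a in (self.effect_allele, self.other_allele):
            if a not in VALID_ALLELES:
                raise ValueError(f"allele {a!r} outside SNP alphabet")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")


@dataclass(frozen=True)
class StudyMeta:
    """Study-level description of one trait's summary statistics.

    ``trait_type`` drives downstream behaviour: the Steiger variance-explained
    formula and the colocalization prior-variance rule both branch on it.
    The label fields (cell type, stimulation, timepoint, cohort) are free
    strings carried through to result tables.
    """

    trait_id: str
    trait_type: str = "quantitative"
    cell_type: Optional[str] = None
    stimulation: Optional[str] = None
    timepoint: Optional[str] = None
    cohort: Optional[str] = None
    default_n: Optional[int] = None
    case_fraction: Optional[float] = None

    def __post_init__(self):
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"trait_type must be one of {TRAIT_TYPES}")
        if self.case_fraction is not None and not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must lie in (0, 1)")

    @property
    def state_label(self) -> str:
        parts = [p for p in (self.cell_type, self.stimulation, self.timepoint, self.cohort) if p]
        return ":".join(parts) if parts else self.trait_id


@dataclass
class LoadReport:
    """Row accounting for one table load: input count and per-reason drops."""

    n_input: int = 0
    dropped: Counter = field(default_factory=Counter)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    @property
    def n_loaded(self) -> int:
        return self.n_input - self.n_dropped


@dataclass
class SummaryStats:
    """One study's association records, sorted by (chrom, pos), unique keys."""

    meta: StudyMeta
    df: pd.DataFrame
    load_report: Optional[LoadReport] = None

    def __post_init__(self):
        df = self.df.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[list(CANONICAL_COLUMNS)]
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["pos"] = df["pos"].astype(np.int64)
        order = sorted(range(len(df)), key=lambda i: (_chrom_rank(df["chrom"].iat[i]), df["pos"].iat[i]))
        self.df = df.iloc[order].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(c, int(p), ea, oa)
            for c, p, ea, oa in zip(
                self.df["chrom"], self.df["pos"],
                self.df["effect_allele"], self.df["other_allele"],
            )
        ]

    def subset(self, mask) -> "SummaryStats":
        """New SummaryStats restricted to rows where ``mask`` holds."""
        return SummaryStats(meta=self.meta, df=self.df.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass
class GeneAnnot:
    """Gene annotation: identifier, chromosome and transcription start site."""

    gene_id: str
    chrom: str
    tss: int

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        self.tss = int(self.tss)
        if self.tss < 1:
            raise ValueError("tss must be >= 1")


@dataclass
class LDMatrix:
    """Signed correlation matrix over an ordered variant list.

    Asymmetry below 1e-8 is repaired as (M + Mᵀ)/2; anything larger, an
    off-unit diagonal, or |r| > 1 raises.  Variants are looked up by
    (chrom, pos) — allele orientation does not matter for r².
    """

    variants: list
    r: np.ndarray
    _pos_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("LD matrix must be square")
        if r.shape[0] != len(self.variants):
            raise ValueError(
                f"dimension mismatch: {r.shape[0]} matrix rows vs {len(self.variants)} variants"
            )
        asym = np.max(np.abs(r - r.T)) if r.size else 0.0
        if asym >= 1e-8:
            raise ValueError(f"LD matrix asymmetry {asym:.3g} exceeds tolerance 1e-8")
        r = (r + r.T) / 2.0
        if r.size:
            if np.max(np.abs(np.diag(r) - 1.0)) > 1e-8:
                raise ValueError("LD matrix diagonal must be 1")
            if np.max(np.abs(r)) > 1.0 + 1e-12:
                raise ValueError("LD correlations must satisfy |r| <= 1")
            np.fill_diagonal(r, 1.0)
        self.r = r
        self._pos_index = {
            (normalize_chrom(v.chrom), int(v.pos)): i for i, v in enumerate(self.variants)
        }

    def __len__(self) -> int:
        return len(self.variants)

    def index_of(self, chrom, pos) -> Optional[int]:
        return self._pos_index.get((normalize_chrom(chrom), int(pos)))

    def r2(self, i: int, j: int) -> float:
        return float(self.r[i, j] ** 2)


def _read_delimited(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise ValueError(f"{path}: empty file")
    sep = "\t" if "\t" in first else r"\s+"
    return pd.read_csv(path, sep=sep, dtype=str, na_values=["NA", "nan", ""])


def read_sumstats(path, column_map: Optional[Mapping[str, str]] = None,
                  meta: Optional[StudyMeta] = None) -> SummaryStats:
    """Load a tab/whitespace-delimited summary-statistics table.

    ``column_map`` maps canonical field names (see :data:`CANONICAL_COLUMNS`)
    to source column names; omitted entries default to the canonical name
    itself.  Rows violating record invariants (non-SNP alleles, se <= 0,
    p outside (0, 1], frequency outside [0, 1], duplicate keys, ...) are
    dropped and tallied in the attached :class:`LoadReport`.  Missing
    per-row N falls back to ``meta.default_n``.
    """
    if meta is None:
        meta = StudyMeta(trait_id=str(path))
    raw = _read_delimited(path)
    cmap = dict(column_map or {})
    resolved = {}
    for fieldname in CANONICAL_COLUMNS:
        src = cmap.get(fieldname, fieldname)
        if src in raw.columns:
            resolved[fieldname] = raw[src]
        elif fieldname in REQUIRED_FIELDS:
            raise ValueError(f"{path}: required column {src!r} (for {fieldname!r}) not found")
    df = pd.DataFrame(resolved)
    report = LoadReport(n_input=len(df))

    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper().str.strip()
    df["other_allele"] = df["other_allele"].astype(str).str.upper().str.strip()
    for col in ("pos", "eaf", "beta", "se", "pvalue", "n", "n_case"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("eaf", "n", "n_case"):
        if col not in df.columns:
            df[col] = np.nan
    if meta.default_n is not None:
        df["n"] = df["n"].fillna(float(meta.default_n))

    keep = np.ones(len(df), dtype=bool)

    def drop(mask, reason):
        mask = np.asarray(mask, dtype=bool) & keep
        if mask.any():
            report.dropped[reason] += int(mask.sum())
            keep[mask] = False

    drop(df["pos"].isna() | df["beta"].isna() | df["se"].isna() | df["pvalue"].isna(), "unparseable")
    drop(~df["effect_allele"].isin(VALID_ALLELES) | ~df["other_allele"].isin(VALID_ALLELES), "non_snp")
    drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    drop(df["pos"] < 1, "bad_position")
    drop(df["se"] <= 0, "nonpositive_se")
    drop((df["pvalue"] <= 0) | (df["pvalue"] > 1), "bad_pvalue")
    drop(df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1)), "bad_eaf")
    drop(
        df["n_case"].notna() & (df["n"].notna())
        & ((df["n_case"] <= 0) | (df["n_case"] >= df["n"])),
        "bad_n_case",
    )
    dup = df.duplicated(subset=["chrom", "pos", "effect_allele", "other_allele"], keep="first")
    drop(dup, "duplicate_key")

    df = df.loc[keep]
    if len(df) == 0:
        raise ValueError(f"{path}: no valid rows after filtering ({dict(report.dropped)})")
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64)
    stats = SummaryStats(meta=meta, df=df.reset_index(drop=True))
    stats.load_report = report
    log.info("%s: loaded %d records, dropped %d", path, len(stats), report.n_dropped)
    return stats


def read_ld(matrix_path, index_path) -> LDMatrix:
    """Read a dense text LD matrix plus its one-variant-per-line index.

    The index file is tab/whitespace-delimited with four columns
    (chrom, pos, effect_allele, other_allele), no header.
    """
    r = np.loadtxt(matrix_path, dtype=float, ndmin=2)
    idx = pd.read_csv(
        index_path, sep=r"\s+", header=None,
        names=["chrom", "pos", "effect_allele", "other_allele"], dtype=str,
    )
    variants = [
        VariantKey(normalize_chrom(c), int(p), str(ea).upper(), str(oa).upper())
        for c, p, ea, oa in idx.itertuples(index=False)
    ]
    return LDMatrix(variants=variants, r=r)


def write_ld(ld: LDMatrix, matrix_path, index_path) -> None:
    np.savetxt(matrix_path, ld.r, fmt="%.10g", delimiter="\t")
    with open(index_path, "w") as fh:
        for v in ld.variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.effect_allele}\t{v.other_allele}\n")


def write_table(rows, path) -> None:
    """Write flat records as a deterministic tab-delimited table.

    Floats are rendered with 6 significant digits; rows are sorted by all
    non-float columns (in column order) so output is independent of input
    order.  An empty row set yields a header-only file when ``rows`` is a
    DataFrame.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df = df.copy()
    key_cols = [c for c in df.columns if not pd.api.types.is_float_dtype(df[c])]
    if key_cols and len(df):
        df = df.sort_values(by=key_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def read_gene_annotations(path) -> list[GeneAnnot]:
    """Read a gene annotation table with columns gene_id, chrom, tss."""
    df = _read_delimited(path)
    for col in ("gene_id", "chrom", "tss"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [GeneAnnot(g, c, int(float(t))) for g, c, t in zip(df["gene_id"], df["chrom"], df["tss"])]
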