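"""Instrument selection: cis filters, LD clumping, and allele harmonization.

Candidate instruments for a gene are cis-eQTLs passing two closed +/-500 kb
windows simultaneously — one around the gene's transcription start site and
one around the outcome locus lead — that reach exposure significance.  They
are then greedily clumped to mutual near-independence (r² < 0.001 within
10 Mb by default) and harmonized so that exposure and outcome effects refer
to the same effect allele on the same strand.

Harmonization handles, per shared (chrom, pos):

* identical alleles → kept unchanged;
* swapped effect/other alleles → outcome beta sign-flipped, EAF mirrored;
* reverse-complement alleles (with or without swap) → strand-flipped first;
* palindromic pairs (A/T, C/G) → orientation inferred from allele
  frequencies only when both EAFs are outside the ambiguity zone
  [limit, 1-limit] (default limit 0.42); otherwise dropped;
* anything else → dropped as incompatible.

Every action and drop is tallied in the audit counter.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .loci import Locus
from .sumstats import (
    COMPLEMENT, GeneAnnot, LDMatrix, SummaryStats, VariantKey, is_palindromic,
)

log = logging.getLogger(__name__)

DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW = 10_000_000
DEFAULT_PALINDROMIC_EAF_LIMIT = 0.42

HARMONIZATION_ACTIONS = (
    "unchanged", "sign_flipped", "strand_flipped",
    "strand_flipped_and_sign_flipped", "palindromic_inferred",
)


@dataclass
class InstrumentPair:
    """One harmonized exposure/outcome effect pair."""

    key: VariantKey
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: float
    p_exp: float
    p_out: float
    n_exp: Optional[float]
    n_out: Optional[float]
    action: str

    def __post_init__(self):
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError("standard errors must be positive")


@dataclass
class InstrumentSet:
    """Harmonized pairs for one gene:state:outcome test, with audit trail."""

    pairs: list = field(default_factory=list)
    audit: Counter = field(default_factory=Counter)
    gene_id: Optional[str] = None
    state_label: Optional[str] = None
    outcome_id: Optional[str] = None
    lead: Optional[VariantKey] = None

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            rows.append({
                "gene_id": self.gene_id, "state_label": self.state_label,
                "outcome_id": self.outcome_id,
                "chrom": p.key.chrom, "pos": p.key.pos,
                "effect_allele": p.key.effect_allele, "other_allele": p.key.other_allele,
                "beta_exp": p.beta_exp, "se_exp": p.se_exp,
                "beta_out": p.beta_out, "se_out": p.se_out,
                "eaf": p.eaf, "p_exp": p.p_exp, "p_out": p.p_out,
                "n_exp": p.n_exp, "n_out": p.n_out, "action": p.action,
            })
        return pd.DataFrame(rows)


def instrument_set_from_frame(df: pd.DataFrame) -> InstrumentSet:
    """Rebuild an :class:`InstrumentSet` from its ``to_frame`` layout."""
    iset = InstrumentSet()
    if len(df):
        first = df.iloc[0]
        iset.gene_id = first.get("gene_id")
        iset.state_label = first.get("state_label")
        iset.outcome_id = first.get("outcome_id")
    for _, r in df.iterrows():
        iset.pairs.append(InstrumentPair(
            key=VariantKey(str(r["chrom"]), int(r["pos"]),
                           str(r["effect_allele"]), str(r["other_allele"])),
            beta_exp=float(r["beta_exp"]), se_exp=float(r["se_exp"]),
            beta_out=float(r["beta_out"]), se_out=float(r["se_out"]),
            eaf=float(r["eaf"]) if pd.notna(r["eaf"]) else np.nan,
            p_exp=float(r["p_exp"]), p_out=float(r["p_out"]),
            n_exp=float(r["n_exp"]) if pd.notna(r["n_exp"]) else None,
            n_out=float(r["n_out"]) if pd.notna(r["n_out"]) else None,
            action=str(r["action"]),
        ))
    return iset


def cis_filter(eqtls: SummaryStats, gene: GeneAnnot, half_window: int = 500_000) -> SummaryStats:
    """Keep records on the gene's chromosome with |pos - TSS| <= half_window."""
    df = eqtls.df
    mask = (df["chrom"] == gene.chrom) & (np.abs(df["pos"] - gene.tss) <= half_window)
    return eqtls.subset(mask.to_numpy())


def lead_proximity_filter(eqtls: SummaryStats, locus: Locus, half_window: int = 500_000) -> SummaryStats:
    """Keep records within half_window of the outcome locus lead variant."""
    df = eqtls.df
    mask = (df["chrom"] == locus.lead.chrom) & (np.abs(df["pos"] - locus.lead.pos) <= half_window)
    return eqtls.subset(mask.to_numpy())


def select_instruments(candidates: SummaryStats, p_threshold: float = 5e-8) -> SummaryStats:
    """Keep exposure-significant records (p <= threshold)."""
    return candidates.subset((candidates.df["pvalue"] <= p_threshold).to_numpy())


def clump(candidates: SummaryStats, ld: LDMatrix,
          r2_threshold: float = DEFAULT_CLUMP_R2,
          window: int = DEFAULT_CLUMP_WINDOW,
          audit: Optional[Counter] = None) -> SummaryStats:
    """Greedy LD clumping.

    Candidates are visited in ascending p (ties by ascending position); one
    is accepted iff its r² with every already-accepted variant within
    ``window`` bases on the same chromosome stays below ``r2_threshold``.
    Candidates absent from the LD matrix are dropped (conservative) and
    tallied under ``clump_missing_ld``.  The result is returned in genomic
    order and depends only on (p-values, LD, positions), not input order.
    """
    df = candidates.df
    ld_idx = np.array([
        -1 if (i := ld.index_of(c, p)) is None else i
        for c, p in zip(df["chrom"], df["pos"])
    ])
    missing = ld_idx < 0
    if missing.any():
        if audit is not None:
            audit["clump_missing_ld"] += int(missing.sum())
        log.info("clump: dropped %d candidates absent from LD matrix", int(missing.sum()))
    order = sorted(
        np.flatnonzero(~missing),
        key=lambda i: (df["pvalue"].iat[i], df["pos"].iat[i]),
    )
    accepted: list[int] = []
    for i in order:
        ok = True
        for j in accepted:
            same_chrom = df["chrom"].iat[i] == df["chrom"].iat[j]
            if same_chrom and abs(int(df["pos"].iat[i]) - int(df["pos"].iat[j])) <= window:
                if ld.r[ld_idx[i], ld_idx[j]] ** 2 >= r2_threshold:
                    ok = False
                    break
        if ok:
            accepted.append(i)
    mask = np.zeros(len(df), dtype=bool)
    mask[accepted] = True
    return candidates.subset(mask)


def _orientation(exp_ea, exp_oa, out_ea, out_oa):
    """Classify outcome allele labels relative to the exposure's.

    Returns one of ``unchanged | sign_flipped | strand_flipped |
    strand_flipped_and_sign_flipped | None`` (incompatible).
    """
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return "unchanged"
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return "sign_flipped"
    cea, coa = COMPLEMENT[exp_ea], COMPLEMENT[exp_oa]
    if (out_ea, out_oa) == (cea, coa):
        return "strand_flipped"
    if (out_ea, out_oa) == (coa, cea):
        return "strand_flipped_and_sign_flipped"
    return None


def harmonize(exposure: SummaryStats, outcome: SummaryStats,
              palindromic_eaf_limit: float = DEFAULT_PALINDROMIC_EAF_LIMIT) -> InstrumentSet:
    """Match exposure and outcome records by (chrom, pos) and align alleles.

    The returned pairs carry exposure-orientation effect alleles; the
    harmonized EAF is the exposure's.  Variants without a counterpart, with
    incompatible alleles, or palindromic with ambiguous frequency are
    dropped and audited.
    """
    lo, hi = palindromic_eaf_limit, 1.0 - palindromic_eaf_limit
    merged = pd.merge(
        exposure.df, outcome.df, on=["chrom", "pos"], suffixes=("_exp", "_out"), how="outer",
        indicator=True,
    )
    iset = InstrumentSet()
    unmatched = merged["_merge"] != "both"
    if unmatched.any():
        iset.audit["dropped_unmatched"] += int(unmatched.sum())
    for row in merged.loc[~unmatched].itertuples(index=False):
        exp_ea, exp_oa = row.effect_allele_exp, row.other_allele_exp
        out_ea, out_oa = row.effect_allele_out, row.other_allele_out
        beta_out, eaf_out = float(row.beta_out), row.eaf_out
        palindromic = is_palindromic(exp_ea, exp_oa)

        if not palindromic:
            action = _orientation(exp_ea, exp_oa, out_ea, out_oa)
            if action is None:
                iset.audit["dropped_incompatible"] += 1
                continue
            if action in ("sign_flipped", "strand_flipped_and_sign_flipped"):
                beta_out = -beta_out
                if pd.notna(eaf_out):
                    eaf_out = 1.0 - eaf_out
        else:
            # A/T or C/G: labels cannot resolve strand; use frequencies.
            if {out_ea, out_oa} != {exp_ea, exp_oa}:
                iset.audit["dropped_incompatible"] += 1
                continue
            eaf_exp = row.eaf_exp
            if pd.isna(eaf_exp) or pd.isna(eaf_out):
                iset.audit["dropped_palindromic_no_eaf"] += 1
                continue
            if (lo <= eaf_exp <= hi) or (lo <= eaf_out <= hi):
                iset.audit["dropped_palindromic_ambiguous"] += 1
                continue
            # nominal label alignment first, then frequency concordance
            if out_ea == exp_oa:
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
            if (eaf_exp < 0.5) != (eaf_out < 0.5):
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
            action = "palindromic_inferred"

        iset.audit[action] += 1
        iset.pairs.append(InstrumentPair(
            key=VariantKey(row.chrom, int(row.pos), exp_ea, exp_oa),
            beta_exp=float(row.beta_exp), se_exp=float(row.se_exp),
            beta_out=beta_out, se_out=float(row.se_out),
            eaf=float(row.eaf_exp) if pd.notna(row.eaf_exp) else np.nan,
            p_exp=float(row.pvalue_exp), p_out=float(row.pvalue_out),
            n_exp=float(row.n_exp) if pd.notna(row.n_exp) else None,
            n_out=float(row.n_out) if pd.notna(row.n_out) else None,
            action=action,
        ))
    return iset
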