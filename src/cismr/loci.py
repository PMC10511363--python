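"""Outcome-GWAS locus definition and region exclusion.

Loci are defined greedily from genome-wide-significant variants: the
globally smallest-p remaining variant becomes a lead, a closed +/- half
window around it becomes the locus, and all significant variants inside
that window on the same chromosome are absorbed.  Loci led from within
an exclusion region (by default the MHC, chr6:28,510,120-33,480,577 on
GRCh38, whose extreme LD confounds downstream inference) are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .sumstats import SummaryStats, VariantKey, normalize_chrom, _chrom_rank

log = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DEFAULT_HALF_WINDOW = 500_000


@dataclass(frozen=True)
class GenomicRegion:
    """1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end:
            raise ValueError("region start must be <= end")

    def contains(self, chrom, pos) -> bool:
        return normalize_chrom(chrom) == self.chrom and self.start <= int(pos) <= self.end


#: MHC region (GRCh38), excluded by default when selecting loci
MHC_REGION = GenomicRegion("6", 28_510_120, 33_480_577)


@dataclass(frozen=True)
class Locus:
    """A GWAS locus: lead variant plus its closed analysis window."""

    lead: VariantKey
    lead_p: float
    window_start: int
    window_end: int
    outcome_id: str

    def contains(self, chrom, pos) -> bool:
        return (
            normalize_chrom(chrom) == self.lead.chrom
            and self.window_start <= int(pos) <= self.window_end
        )


def define_loci(gwas: SummaryStats, p_threshold: float = GENOME_WIDE_P,
                half_window: int = DEFAULT_HALF_WINDOW) -> list[Locus]:
    """Greedy min-p locus selection.

    Repeatedly takes the smallest-p remaining significant variant as a lead
    (ties broken by chromosome then smaller position), emits its locus, and
    removes all significant variants within ``half_window`` of it on the same
    chromosome.  Output is sorted by (chrom, window_start) and is invariant
    to input row order; no two leads on one chromosome lie within
    ``half_window`` of each other.
    """
    df = gwas.df
    sig = df.loc[df["pvalue"] <= p_threshold,
                 ["chrom", "pos", "effect_allele", "other_allele", "pvalue"]].copy()
    if sig.empty:
        return []
    order = sorted(
        range(len(sig)),
        key=lambda i: (sig["pvalue"].iat[i], _chrom_rank(sig["chrom"].iat[i]), sig["pos"].iat[i]),
    )
    sig = sig.iloc[order]
    chroms = sig["chrom"].to_numpy()
    positions = sig["pos"].to_numpy()
    alive = np.ones(len(sig), dtype=bool)
    loci: list[Locus] = []
    for i in range(len(sig)):
        if not alive[i]:
            continue
        row = sig.iloc[i]
        lead = VariantKey(row["chrom"], int(row["pos"]), row["effect_allele"], row["other_allele"])
        loci.append(Locus(
            lead=lead,
            lead_p=float(row["pvalue"]),
            window_start=max(1, lead.pos - half_window),
            window_end=lead.pos + half_window,
            outcome_id=gwas.meta.trait_id,
        ))
        absorbed = (chroms == lead.chrom) & (np.abs(positions - lead.pos) <= half_window)
        alive &= ~absorbed
    loci.sort(key=lambda l: (_chrom_rank(l.lead.chrom), l.window_start))
    return loci


def exclude_region(loci: list[Locus], region: GenomicRegion,
                   mode: str = "lead") -> list[Locus]:
    """Drop loci falling in ``region``.

    ``mode="lead"`` (default) removes loci whose lead variant lies inside the
    region; ``mode="window"`` removes loci whose window overlaps it at all.
    """
    if mode == "lead":
        kept = [l for l in loci if not region.contains(l.lead.chrom, l.lead.pos)]
    elif mode == "window":
        kept = [
            l for l in loci
            if not (l.lead.chrom == region.chrom
                    and l.window_start <= region.end and region.start <= l.window_end)
        ]
    else:
        raise ValueError("mode must be 'lead' or 'window'")
    n_removed = len(loci) - len(kept)
    if n_removed:
        log.info("excluded %d loci inside %s:%d-%d", n_removed, region.chrom, region.start, region.end)
    return kept


def window_variants(stats: SummaryStats, locus: Locus) -> SummaryStats:
    """Subset of ``stats`` inside the locus window (closed interval)."""
    df = stats.df
    mask = (df["chrom"] == locus.lead.chrom) \
        & (df["pos"] >= locus.window_start) & (df["pos"] <= locus.window_end)
    return stats.subset(mask.to_numpy())
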