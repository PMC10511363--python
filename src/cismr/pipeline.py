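"""End-to-end orchestration: loci → instruments → MR → FDR → colocalization.

For each outcome, genome-wide-significant loci are defined and MHC-excluded;
each gene whose cis window intersects a locus is tested: candidate
instruments pass the dual +/-500 kb filters (TSS and locus lead), exposure
significance, LD clumping, and harmonization, then the tiered MR dispatch
runs.  Benjamini-Hochberg adjustment pools all combinations of one exposure
dataset (across states, genes and outcomes).  Combinations passing
FDR <= 0.05 *and* the sensitivity gate proceed to colocalization over the
full shared locus window (all harmonizable variants, not just instruments),
subject to the >= 50 shared-variant requirement; every colocalization is
annotated with a prior-sensitivity scan and the secondary-peak diagnostic.

Each input combination appears exactly once in the output with a verdict:

``not_tested`` (no intersecting locus or no candidate instruments) →
``mr_fail`` (instruments lost in harmonization) → ``fdr_fail`` →
``sensitivity_fail`` → ``coloc_insufficient_variants`` → ``coloc_fail`` →
``colocalized``.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .coloc import (
    ColocResult, ColocStudyInput, coloc_abf, detect_secondary_peaks, prior_sensitivity,
)
from .instruments import (
    InstrumentSet, cis_filter, clump, harmonize, lead_proximity_filter, select_instruments,
)
from .loci import GenomicRegion, Locus, MHC_REGION, define_loci, exclude_region, window_variants
from .mr import MRResult, SensitivityReport, bh_adjust, run_mr
from .sumstats import GeneAnnot, LDMatrix, StudyMeta, SummaryStats, write_table

log = logging.getLogger(__name__)

VERDICTS = (
    "not_tested", "mr_fail", "fdr_fail", "sensitivity_fail",
    "coloc_insufficient_variants", "coloc_fail", "colocalized",
)


@dataclass
class RunConfig:
    """Thresholds and knobs for one pipeline run (echoed into the run report)."""

    p_sig: float = 5e-8
    exposure_p_sig: float = 5e-8
    half_window: int = 500_000
    clump_r2: float = 0.001
    clump_window: int = 10_000_000
    palindromic_eaf_limit: float = 0.42
    fdr: float = 0.05
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    pp_h4_threshold: float = 0.8
    min_coloc_variants: int = 50
    exclude_regions: tuple = (MHC_REGION,)
    exclude_mode: str = "lead"
    n_boot: int = 5000
    seed: int = 0

    def __post_init__(self):
        for name in ("p_sig", "exposure_p_sig", "half_window", "clump_r2",
                     "clump_window", "fdr", "p1", "p2", "p12",
                     "pp_h4_threshold", "min_coloc_variants"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "exclude_regions"}
        d["exclude_regions"] = [
            [r.chrom, r.start, r.end] for r in self.exclude_regions
        ]
        return d


@dataclass
class ExposureDataset:
    """One exposure source: per-gene summary stats under one state label."""

    dataset_id: str
    state_label: str
    meta: StudyMeta
    stats_by_gene: Mapping[str, SummaryStats]


@dataclass
class CombinationResult:
    """Verdict and all populated stage outputs for one dataset:state:gene:outcome."""

    dataset: str
    state_label: str
    gene_id: str
    outcome_id: str
    verdict: str = "not_tested"
    nsnp: int = 0
    locus: Optional[Locus] = None
    mr: Optional[MRResult] = None
    sensitivity: Optional[SensitivityReport] = None
    coloc: Optional[ColocResult] = None
    n_shared_coloc: Optional[int] = None
    audit: Counter = field(default_factory=Counter)


def _pick_locus(loci: Sequence[Locus], gene: GeneAnnot, half_window: int) -> Optional[Locus]:
    """Nearest-lead locus whose window intersects the gene's cis window."""
    best, best_dist = None, None
    for locus in loci:
        if locus.lead.chrom != gene.chrom:
            continue
        if locus.window_start <= gene.tss + half_window and gene.tss - half_window <= locus.window_end:
            dist = abs(locus.lead.pos - gene.tss)
            if best is None or dist < best_dist:
                best, best_dist = locus, dist
    return best


def _coloc_stage(result: CombinationResult, exposure: SummaryStats, outcome: SummaryStats,
                 locus: Locus, ld: Optional[LDMatrix], meta_exp: StudyMeta,
                 meta_out: StudyMeta, config: RunConfig) -> None:
    """Window-level colocalization with sensitivity scan and peak diagnostic."""
    exp_win = window_variants(exposure, locus)
    out_win = window_variants(outcome, locus)
    shared = harmonize(exp_win, out_win, config.palindromic_eaf_limit)
    result.n_shared_coloc = len(shared)
    if len(shared) < config.min_coloc_variants:
        result.verdict = "coloc_insufficient_variants"
        return
    df = shared.to_frame()
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"]).to_numpy()
    s1 = ColocStudyInput(
        beta=df["beta_exp"].to_numpy(), se=df["se_exp"].to_numpy(),
        trait_type=meta_exp.trait_type, maf=maf, n=df["n_exp"].to_numpy(dtype=float),
    )
    s2 = ColocStudyInput(
        beta=df["beta_out"].to_numpy(), se=df["se_out"].to_numpy(),
        trait_type=meta_out.trait_type, maf=maf, n=df["n_out"].to_numpy(dtype=float),
    )
    res = coloc_abf(s1, s2, p1=config.p1, p2=config.p2, p12=config.p12)
    curve, min_pass, robust = prior_sensitivity(
        s1, s2, p1=config.p1, p2=config.p2, threshold=config.pp_h4_threshold, base=res,
    )
    res.sensitivity_curve = curve
    res.min_p12_pass = min_pass
    res.robust = robust
    viol_out, _ = detect_secondary_peaks(out_win, ld=ld)
    viol_exp, _ = detect_secondary_peaks(exp_win, ld=ld)
    res.violation = bool(viol_out or viol_exp)
    result.coloc = res
    result.verdict = "colocalized" if res.pp_h4 >= config.pp_h4_threshold else "coloc_fail"


def run_pipeline(datasets: Sequence[ExposureDataset], outcomes: Sequence[SummaryStats],
                 genes: Mapping[str, GeneAnnot],
                 ld_lookup: Optional[Callable[[str], Optional[LDMatrix]]] = None,
                 config: Optional[RunConfig] = None):
    """Run the four-stage analysis and return (results, report).

    ``ld_lookup`` maps a gene id to its LD matrix (or None: clumping then
    drops all candidates but the top, conservatively keeping the smallest-p
    variant — without LD no independence claim is possible, so only one
    instrument survives).  Deterministic given config.seed.
    """
    config = config or RunConfig()
    ld_lookup = ld_lookup or (lambda gene_id: None)
    report: dict = {"config": config.to_dict(), "outcomes": {}, "stage_counts": Counter()}
    results: list[CombinationResult] = []

    loci_by_outcome = {}
    for outcome in outcomes:
        loci = define_loci(outcome, config.p_sig, config.half_window)
        n_raw = len(loci)
        for region in config.exclude_regions:
            loci = exclude_region(loci, region, mode=config.exclude_mode)
        loci_by_outcome[outcome.meta.trait_id] = loci
        report["outcomes"][outcome.meta.trait_id] = {
            "loci_significant": n_raw, "loci_after_exclusion": len(loci),
        }

    for ds in datasets:
        combo_results: list[CombinationResult] = []
        for outcome in outcomes:
            loci = loci_by_outcome[outcome.meta.trait_id]
            for gene_id in sorted(ds.stats_by_gene):
                result = CombinationResult(
                    dataset=ds.dataset_id, state_label=ds.state_label,
                    gene_id=gene_id, outcome_id=outcome.meta.trait_id,
                )
                combo_results.append(result)
                gene = genes[gene_id]
                locus = _pick_locus(loci, gene, config.half_window)
                if locus is None:
                    result.audit["no_locus"] += 1
                    continue
                result.locus = locus
                eqtls = ds.stats_by_gene[gene_id]
                pool = lead_proximity_filter(
                    cis_filter(eqtls, gene, config.half_window), locus, config.half_window)
                candidates = select_instruments(pool, config.exposure_p_sig)
                if len(candidates) == 0:
                    result.audit["no_significant_eqtl"] += 1
                    continue
                ld = ld_lookup(gene_id)
                if ld is not None:
                    clumped = clump(candidates, ld, config.clump_r2,
                                    config.clump_window, audit=result.audit)
                else:
                    top = candidates.df["pvalue"].idxmin()
                    clumped = candidates.subset(candidates.df.index == top)
                    result.audit["clump_no_ld_top_only"] += 1
                iset = harmonize(clumped, window_variants(outcome, locus),
                                 config.palindromic_eaf_limit)
                iset.gene_id, iset.state_label = gene_id, ds.state_label
                iset.outcome_id, iset.lead = outcome.meta.trait_id, locus.lead
                result.audit.update(iset.audit)
                if len(iset) == 0:
                    result.verdict = "mr_fail"
                    continue
                result.nsnp = len(iset)
                primary, sens = run_mr(
                    iset, ds.meta, outcome.meta,
                    n_boot=config.n_boot, seed=config.seed,
                )
                result.mr, result.sensitivity = primary, sens

        # BH family: all tested combinations of this dataset, pooled
        tested = [r for r in combo_results if r.mr is not None]
        if tested:
            adj = bh_adjust([r.mr.pvalue for r in tested])
            for r, a in zip(tested, adj):
                r.mr.adj_pvalue = float(a)
        for r in tested:
            if r.mr.adj_pvalue > config.fdr:
                r.verdict = "fdr_fail"
            elif not r.sensitivity.overall_pass:
                r.verdict = "sensitivity_fail"
            else:
                outcome = next(o for o in outcomes if o.meta.trait_id == r.outcome_id)
                _coloc_stage(
                    r, ds.stats_by_gene[r.gene_id], outcome, r.locus,
                    ld_lookup(r.gene_id), ds.meta, outcome.meta, config,
                )
        for r in combo_results:
            report["stage_counts"][r.verdict] += 1
        results.extend(combo_results)

    report["stage_counts"] = dict(report["stage_counts"])
    return results, report


MR_SIGNIFICANT_VERDICTS = ("coloc_insufficient_variants", "coloc_fail", "colocalized")


def results_table(results: Sequence[CombinationResult]) -> pd.DataFrame:
    """Flatten combination results into one row per state:gene:outcome."""
    rows = []
    for r in results:
        row = {
            "dataset": r.dataset, "state_label": r.state_label,
            "gene_id": r.gene_id, "outcome_id": r.outcome_id,
            "verdict": r.verdict, "nsnp": r.nsnp,
        }
        if r.mr is not None:
            row.update({
                "method": r.mr.method, "estimate": r.mr.estimate, "se": r.mr.se,
                "pvalue": r.mr.pvalue, "adj_pvalue": r.mr.adj_pvalue,
                "or_point": r.mr.or_point, "or_low95": r.mr.or_low95,
                "or_high95": r.mr.or_high95,
            })
            s = r.sensitivity
            row.update({
                "steiger_direction": s.steiger_direction, "steiger_p": s.steiger_p,
                "egger_intercept": s.egger.intercept if s.egger else np.nan,
                "egger_intercept_p": s.egger.intercept_p if s.egger else np.nan,
                "sensitivity_pass": s.overall_pass,
            })
        if r.coloc is not None:
            row.update({f"pp_h{i}": r.coloc.pp[f"pp_h{i}"] for i in range(5)})
            row.update({
                "coloc_nsnps": r.coloc.nsnps, "coloc_robust": r.coloc.robust,
                "coloc_violation": r.coloc.violation,
                "min_p12_pass": r.coloc.min_p12_pass,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_proportions(results: Sequence[CombinationResult]) -> pd.DataFrame:
    """Per-dataset accounting of MR hits, colocalizations, and violations.

    ``prop_colocalized`` is colocalized / MR-significant (NA when there are
    no MR-significant combinations, not 0); ``pct_violation`` is the share
    of colocalized combinations flagged by the secondary-peak diagnostic.
    """
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    for dataset in sorted({r.dataset for r in results}):
        sub = [r for r in results if r.dataset == dataset]
        mr_sig = [r for r in sub if r.verdict in MR_SIGNIFICANT_VERDICTS]
        colocalized = [r for r in sub if r.verdict == "colocalized"]
        violators = [r for r in colocalized if r.coloc is not None and r.coloc.violation]
        rows.append({
            "dataset": dataset,
            "n_combinations": len(sub),
            "n_mr_significant": len(mr_sig),
            "n_colocalized": len(colocalized),
            "prop_colocalized": (len(colocalized) / len(mr_sig)) if mr_sig else np.nan,
            "pct_violation": (100.0 * len(violators) / len(colocalized)) if colocalized else np.nan,
        })
    return pd.DataFrame(rows)


def write_run_outputs(results, report, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    write_table(results_table(results), os.path.join(outdir, "results.tsv"))
    write_table(summarize_proportions(results), os.path.join(outdir, "proportions.tsv"))
    with open(os.path.join(outdir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
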