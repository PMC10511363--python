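"""Synthetic paired exposure/outcome summary statistics over LD blocks.

The generator draws GWAS/eQTL-style summary statistics directly from their
asymptotic sampling distribution rather than simulating individual-level
genotypes: with LD matrix R, sparse per-allele causal vector b, and
per-variant standard errors S = diag(se_i), the true marginal effects are
mu = R b and the observed effects are

    beta_obs ~ MVN(mu, S R S).

Standard errors follow the usual large-sample forms: for a quantitative
trait se_i = sdY / sqrt(2 n maf_i (1 - maf_i)); for a case/control trait on
the log-odds scale se_i = 1 / sqrt(2 n phi (1 - phi) maf_i (1 - maf_i))
with case fraction phi.  Exposure and outcome noise are independent (the
two-sample design); a shared-noise correlation knob is available for
sample-overlap experiments.

Each simulated gene window carries a truth record (causal architecture,
true effects, hypothesis label) so pipeline verdicts can be scored.  The
outcome copy can be stressed with allele-label swaps, strand flips, and
palindromic allele pairs: these are label-only transformations that
harmonization must undo exactly for non-palindromic variants.

Causal architectures follow the colocalization hypothesis vocabulary:
H0 (no causal variant), H1/H2 (one study only), H3 (distinct causal
variants in LD), H4 (one shared causal variant).  MR scenarios set the
outcome causal vector to mr_effect x the exposure vector (plus an optional
pleiotropy vector); reverse-causal scenarios swap the roles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import (
    COMPLEMENT, GeneAnnot, LDMatrix, StudyMeta, SummaryStats, VariantKey,
)

P_FLOOR = 1e-300

_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimScenario:
    """One gene window's generating conditions.

    Effect-size conventions: ``exposure_r2`` is the variance in the exposure
    explained by each causal variant (converted internally to a per-allele
    effect at the variant's drawn MAF); ``outcome_effect`` is a per-allele
    effect on the outcome scale (log-odds for case/control).  ``mr_effect``
    is the causal effect of one unit of exposure on the outcome; when
    nonzero the outcome causal vector is mr_effect x exposure vector plus
    any pleiotropy.
    """

    m: int = 100
    rho: float = 0.9
    spacing: int = 5_000
    start_pos: int = 1_000_000
    chrom: str = "1"
    maf_range: tuple = (0.1, 0.5)
    hypothesis: str = "H4"
    n_causal: int = 1
    causal_indices: Optional[tuple] = None
    exposure_effect: Optional[float] = None  # per-allele; overrides exposure_r2
    exposure_r2: float = 0.01
    exposure_r2_range: Optional[tuple] = None  # per-variant U(lo, hi) overrides exposure_r2
    outcome_effect: float = 0.15
    mr_effect: float = 0.0
    pleiotropy: str = "none"            # none | balanced | directional
    pleiotropy_scale: float = 0.08
    reverse_causal: bool = False
    h3_ld_r: float = 0.5
    n_exp: int = 10_000
    n_out: int = 50_000
    exposure_type: str = "quantitative"
    outcome_type: str = "case_control"
    case_fraction: float = 0.5
    sdY: float = 1.0
    noise_scale: float = 1.0
    overlap_correlation: float = 0.0
    palindromic_fraction: float = 0.15
    strand_flip_fraction: float = 0.25
    allele_swap_fraction: float = 0.25
    seed: Optional[int] = None

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("|rho| must be < 1")
        if self.hypothesis not in ("H0", "H1", "H2", "H3", "H4"):
            raise ValueError("hypothesis must be one of H0..H4")
        for frac in (self.palindromic_fraction, self.strand_flip_fraction,
                     self.allele_swap_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_exp, self.n_out) < 4:
            raise ValueError("sample sizes must be >= 4")


@dataclass
class TruthRecord:
    """Ground truth for one simulated gene window."""

    gene_id: str
    hypothesis: str
    exposure_causal: list
    outcome_causal: list
    b_exp: np.ndarray
    b_out: np.ndarray
    mr_effect: float
    reverse_causal: bool
    expected_mr_hit: bool
    expected_coloc: bool
    outcome_unstressed: Optional[pd.DataFrame] = None


def _ar1(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_ld(m: int, rho: float, spacing: int = 5_000, chrom: str = "1",
                start_pos: int = 1_000_000, seed: Optional[int] = None) -> LDMatrix:
    """AR(1) LD block: r[i][j] = rho^|i-j|, positive definite for |rho| < 1."""
    variants = [
        VariantKey(chrom, start_pos + i * spacing, "A", "G") for i in range(m)
    ]
    return LDMatrix(variants=variants, r=_ar1(m, rho))


def _causal_vectors(sc: SimScenario, maf: np.ndarray, rng: np.random.Generator):
    """Per-allele causal effect vectors (b_exp, b_out) for the scenario."""
    m = sc.m
    b_exp = np.zeros(m)
    b_out = np.zeros(m)
    if sc.causal_indices is not None:
        idx = list(sc.causal_indices)
    elif sc.n_causal == 1:
        idx = [m // 2]
    else:
        idx = list(np.linspace(0, m - 1, sc.n_causal).round().astype(int))
    sd_g = np.sqrt(2.0 * maf * (1.0 - maf))

    def exposure_effect_at(i):
        # per-allele effect explaining exposure_r2 of the exposure variance
        if sc.exposure_effect is not None:
            return sc.exposure_effect
        if sc.exposure_r2_range is not None:
            r2 = rng.uniform(*sc.exposure_r2_range)
        else:
            r2 = sc.exposure_r2
        return math.sqrt(r2) * sc.sdY / sd_g[i]

    exp_idx: list = []
    out_idx: list = []
    if sc.hypothesis == "H0":
        pass
    elif sc.hypothesis == "H1":
        exp_idx = idx
        for i in idx:
            b_exp[i] = exposure_effect_at(i)
    elif sc.hypothesis == "H2":
        out_idx = idx
        for i in idx:
            b_out[i] = sc.outcome_effect
    elif sc.hypothesis == "H3":
        # distinct causal variants separated so that their AR(1) correlation
        # is close to h3_ld_r
        offset = max(1, round(math.log(sc.h3_ld_r) / math.log(sc.rho))) if sc.rho > 0 else 1
        for i in idx:
            j = i + offset if i + offset < m else i - offset
            exp_idx.append(i)
            out_idx.append(j)
            b_exp[i] = exposure_effect_at(i)
            b_out[j] = sc.outcome_effect
    else:  # H4: shared causal variant(s)
        exp_idx = idx
        out_idx = idx
        for i in idx:
            b_exp[i] = exposure_effect_at(i)
            b_out[i] = sc.mr_effect * b_exp[i] if sc.mr_effect != 0 else sc.outcome_effect

    if sc.reverse_causal:
        # the variants act on the outcome; the exposure inherits a scaled copy
        out_idx = idx
        exp_idx = idx
        b_out = np.zeros(m)
        for i in idx:
            b_out[i] = sc.outcome_effect
        b_exp = sc.mr_effect * b_out

    if sc.pleiotropy != "none" and exp_idx:
        alpha = rng.uniform(0.0, sc.pleiotropy_scale, size=len(exp_idx))
        if sc.pleiotropy == "balanced":
            alpha *= rng.choice([-1.0, 1.0], size=len(exp_idx))
        for i, a in zip(exp_idx, alpha):
            b_out[i] += a

    return b_exp, b_out, sorted(set(exp_idx)), sorted(set(out_idx))


def _draw_alleles(sc: SimScenario, rng: np.random.Generator):
    pal = rng.random(sc.m) < sc.palindromic_fraction
    ea = np.empty(sc.m, dtype=object)
    oa = np.empty(sc.m, dtype=object)
    for i in range(sc.m):
        pool = _PALINDROMIC_PAIRS if pal[i] else _NONPALINDROMIC_PAIRS
        ea[i], oa[i] = pool[rng.integers(len(pool))]
    return ea, oa


def _se_vector(maf: np.ndarray, n: int, trait_type: str, sdY: float,
               case_fraction: float) -> np.ndarray:
    het = 2.0 * maf * (1.0 - maf)
    if trait_type == "quantitative":
        return sdY / np.sqrt(het * n)
    phi = case_fraction
    return 1.0 / np.sqrt(het * n * phi * (1.0 - phi))


def _study_frame(sc: SimScenario, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    z = beta / se
    p = np.maximum(2.0 * sps.norm.sf(np.abs(z)), P_FLOOR)
    return pd.DataFrame({
        "chrom": sc.chrom, "pos": pos, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se, "pvalue": p, "n": float(n),
        "n_case": np.nan,
    })


def _apply_stressors(df: pd.DataFrame, sc: SimScenario, rng: np.random.Generator) -> pd.DataFrame:
    """Label-only allele swaps and strand flips on the outcome copy."""
    df = df.copy()
    swap = rng.random(len(df)) < sc.allele_swap_fraction
    flip = rng.random(len(df)) < sc.strand_flip_fraction
    ea = df["effect_allele"].to_numpy(dtype=object)
    oa = df["other_allele"].to_numpy(dtype=object)
    beta = df["beta"].to_numpy(dtype=float)
    eaf = df["eaf"].to_numpy(dtype=float)
    for i in range(len(df)):
        if swap[i]:
            ea[i], oa[i] = oa[i], ea[i]
            beta[i] = -beta[i]
            eaf[i] = 1.0 - eaf[i]
        if flip[i]:
            ea[i] = COMPLEMENT[ea[i]]
            oa[i] = COMPLEMENT[oa[i]]
    df["effect_allele"], df["other_allele"] = ea, oa
    df["beta"], df["eaf"] = beta, eaf
    z = df["beta"] / df["se"]
    df["pvalue"] = np.maximum(2.0 * sps.norm.sf(np.abs(z)), P_FLOOR)
    return df


def simulate_pair(scenario: SimScenario, gene_id: str = "G000",
                  rng: Optional[np.random.Generator] = None,
                  apply_stressors: bool = True):
    """Generate one gene window's exposure/outcome summary statistics.

    Returns ``(exposure, outcome, ld, truth)``; the outcome carries the
    harmonization stressors (when enabled) and the truth record keeps the
    unstressed outcome table for round-trip checks.  Fully reproducible
    from ``scenario.seed`` (or a supplied generator).
    """
    sc = scenario
    rng = rng if rng is not None else np.random.default_rng(sc.seed)
    m = sc.m
    pos = sc.start_pos + sc.spacing * np.arange(m)
    eaf = rng.uniform(sc.maf_range[0], sc.maf_range[1], size=m)
    flip_to_major = rng.random(m) < 0.5
    eaf = np.where(flip_to_major, 1.0 - eaf, eaf)
    maf = np.minimum(eaf, 1.0 - eaf)
    ea, oa = _draw_alleles(sc, rng)

    R = _ar1(m, sc.rho)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(m))
    b_exp, b_out, exp_idx, out_idx = _causal_vectors(sc, maf, rng)

    se_exp = _se_vector(maf, sc.n_exp, sc.exposure_type, sc.sdY, sc.case_fraction)
    se_out = _se_vector(maf, sc.n_out, sc.outcome_type, sc.sdY, sc.case_fraction)
    mu_exp = R @ b_exp
    mu_out = R @ b_out

    eps_exp = L @ rng.standard_normal(m)
    eps_out = L @ rng.standard_normal(m)
    if sc.overlap_correlation:
        shared = L @ rng.standard_normal(m)
        c = sc.overlap_correlation
        eps_exp = math.sqrt(1 - c) * eps_exp + math.sqrt(c) * shared
        eps_out = math.sqrt(1 - c) * eps_out + math.sqrt(c) * shared
    beta_exp = mu_exp + sc.noise_scale * se_exp * eps_exp
    beta_out = mu_out + sc.noise_scale * se_out * eps_out

    exp_df = _study_frame(sc, pos, ea, oa, eaf, beta_exp, se_exp, sc.n_exp)
    out_df = _study_frame(sc, pos, ea, oa, eaf, beta_out, se_out, sc.n_out)
    truth = TruthRecord(
        gene_id=gene_id, hypothesis=sc.hypothesis,
        exposure_causal=exp_idx, outcome_causal=out_idx,
        b_exp=b_exp, b_out=b_out, mr_effect=sc.mr_effect,
        reverse_causal=sc.reverse_causal,
        expected_mr_hit=(sc.hypothesis in ("H3", "H4") and not sc.reverse_causal),
        expected_coloc=(sc.hypothesis == "H4"),
        outcome_unstressed=out_df.copy(),
    )
    if apply_stressors:
        out_df = _apply_stressors(out_df, sc, rng)

    meta_exp = StudyMeta(trait_id=f"{gene_id}_expr", trait_type=sc.exposure_type,
                         default_n=sc.n_exp)
    meta_out = StudyMeta(trait_id="outcome", trait_type=sc.outcome_type,
                         default_n=sc.n_out, case_fraction=sc.case_fraction
                         if sc.outcome_type == "case_control" else None)
    exposure = SummaryStats(meta=meta_exp, df=exp_df)
    outcome = SummaryStats(meta=meta_out, df=out_df)
    ld = LDMatrix(variants=[VariantKey(sc.chrom, int(p), e, o)
                            for p, e, o in zip(pos, ea, oa)], r=R)
    return exposure, outcome, ld, truth


@dataclass
class SimulatedDataset:
    """A multi-gene fixture: per-gene exposures plus one pooled outcome GWAS."""

    dataset_id: str
    exposures: dict                  # gene_id -> SummaryStats
    outcome: SummaryStats
    genes: dict                      # gene_id -> GeneAnnot
    ld: dict                         # gene_id -> LDMatrix
    truth: dict                      # gene_id -> TruthRecord
    meta_exp: StudyMeta
    scenario: SimScenario

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for g, t in self.truth.items():
            rows.append({
                "gene_id": g, "hypothesis": t.hypothesis,
                "exposure_causal": ",".join(map(str, t.exposure_causal)),
                "outcome_causal": ",".join(map(str, t.outcome_causal)),
                "mr_effect": t.mr_effect, "reverse_causal": t.reverse_causal,
                "expected_mr_hit": t.expected_mr_hit,
                "expected_coloc": t.expected_coloc,
            })
        return pd.DataFrame(rows)


def simulate_dataset(n_genes: int, scenario_weights: dict,
                     base_scenario: Optional[SimScenario] = None,
                     seed: Optional[int] = None,
                     dataset_id: str = "sim") -> SimulatedDataset:
    """Generate a multi-gene dataset from a mixture of causal architectures.

    ``scenario_weights`` maps hypothesis labels (H0..H4) to mixture weights
    summing to 1.  Genes are laid out on rotating chromosomes with 50 Mb
    offsets so windows never interact.  Deterministic given ``seed``.
    """
    weights = dict(scenario_weights)
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("scenario weights must sum to 1")
    base = base_scenario if base_scenario is not None else SimScenario()
    rng = np.random.default_rng(seed)
    labels = sorted(weights)
    probs = np.array([weights[l] for l in labels])

    exposures, genes, ld_map, truth = {}, {}, {}, {}
    outcome_frames = []
    meta_out = None
    for i in range(n_genes):
        gene_id = f"G{i:04d}"
        hyp = labels[int(rng.choice(len(labels), p=probs))]
        chrom = str((i % 22) + 1)
        start = 1_000_000 + (i // 22) * 50_000_000
        sc = replace(base, hypothesis=hyp, chrom=chrom, start_pos=start, seed=None)
        exposure, outcome, ld, tr = simulate_pair(sc, gene_id=gene_id, rng=rng)
        exposures[gene_id] = exposure
        ld_map[gene_id] = ld
        truth[gene_id] = tr
        tss = int(start + sc.spacing * (sc.m // 2))
        genes[gene_id] = GeneAnnot(gene_id=gene_id, chrom=chrom, tss=tss)
        outcome_frames.append(outcome.df)
        meta_out = outcome.meta

    outcome_all = SummaryStats(meta=meta_out, df=pd.concat(outcome_frames, ignore_index=True))
    meta_exp = StudyMeta(trait_id=dataset_id, trait_type=base.exposure_type,
                         default_n=base.n_exp, cohort=dataset_id)
    return SimulatedDataset(
        dataset_id=dataset_id, exposures=exposures, outcome=outcome_all,
        genes=genes, ld=ld_map, truth=truth, meta_exp=meta_exp, scenario=base,
    )


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write the fixture tree (TSV summary stats, LD files, annotations, truth)."""
    import os

    from .sumstats import write_ld, write_table

    os.makedirs(outdir, exist_ok=True)
    write_table(ds.outcome.df, os.path.join(outdir, "outcome.tsv"))
    gene_rows = []
    for gene_id, stats in ds.exposures.items():
        path = os.path.join(outdir, f"{gene_id}.eqtl.tsv")
        write_table(stats.df, path)
        mpath = os.path.join(outdir, f"{gene_id}.ld.tsv")
        ipath = os.path.join(outdir, f"{gene_id}.ld.index.tsv")
        write_ld(ds.ld[gene_id], mpath, ipath)
        g = ds.genes[gene_id]
        gene_rows.append({
            "gene_id": gene_id, "chrom": g.chrom, "tss": g.tss,
            "sumstats": os.path.basename(path),
            "ld_matrix": os.path.basename(mpath),
            "ld_index": os.path.basename(ipath),
        })
    write_table(pd.DataFrame(gene_rows), os.path.join(outdir, "genes.tsv"))
    write_table(ds.truth_table(), os.path.join(outdir, "truth.tsv"))
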