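"""Bayesian colocalization under the single-causal-variant model.

Given two studies' effect estimates over an identical, identically ordered
variant list, each variant gets a Wakefield log approximate Bayes factor
(ABF) per study, and the five hypothesis posteriors are assembled by
enumerating causal configurations:

* H0 — no association in either study;
* H1/H2 — association in study 1 / study 2 only;
* H3 — both associated, distinct causal variants;
* H4 — both associated, one shared causal variant.

Per-variant priors are p1, p2 (causal for one study only) and p12 (causal
for both); defaults p1 = p2 = 1e-4, p12 = 1e-5.  PP_H4 >= 0.8 is the
conventional colocalization call.  All mass accumulation is in log space,
so |log ABF| up to ~700 is safe.

The prior-variance (``W``) rule follows the standard approximate-Bayes-factor
colocalization method: prior effect SD 0.2 on the log-odds scale for
case/control traits and 0.15 x sdY per phenotype SD for quantitative traits,
with sdY estimated from (se², MAF, N) when not supplied.  Both SDs are
overridable per study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import LDMatrix, SummaryStats

log = logging.getLogger(__name__)

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
PP_H4_THRESHOLD = 0.8
MIN_COLOC_VARIANTS = 50

PRIOR_SD_CASE_CONTROL = 0.2
PRIOR_SD_QUANTITATIVE = 0.15  # multiplied by sdY

HYPOTHESES = ("pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4")


def estimate_sdY(vbeta, maf, n) -> float:
    """Estimate the phenotype SD from per-variant beta variances.

    Under a standard quantitative-trait model, var(beta_i) is approximately
    sdY² / (2 n_i maf_i (1 - maf_i)); regressing d_i = 2 n_i maf_i (1-maf_i)
    on x_i = 1/var(beta_i) through the origin gives slope sdY².
    """
    vbeta = np.asarray(vbeta, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    if vbeta.size < 2:
        raise ValueError("sdY estimation needs at least 2 variants")
    if np.any(np.isnan(maf)) or np.any(np.isnan(n)):
        raise ValueError("sdY estimation needs MAF and N for every variant")
    x = 1.0 / vbeta
    d = 2.0 * n * maf * (1.0 - maf)
    slope = np.sum(d * x) / np.sum(x * x)
    if slope <= 0:
        raise ValueError("nonpositive sdY² estimate; supply sdY directly")
    return float(np.sqrt(slope))


@dataclass
class ColocStudyInput:
    """Aligned per-variant summaries for one side of a colocalization call."""

    beta: np.ndarray
    se: np.ndarray
    trait_type: str = "quantitative"
    maf: Optional[np.ndarray] = None
    n: Optional[np.ndarray] = None
    sdY: Optional[float] = None
    prior_sd: Optional[float] = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.beta.shape != self.se.shape:
            raise ValueError("beta and se must be aligned")
        if np.any(self.se <= 0):
            raise ValueError("all standard errors must be positive")
        if self.maf is not None:
            self.maf = np.asarray(self.maf, dtype=float)
        if self.n is not None:
            self.n = np.asarray(self.n, dtype=float)

    def effective_prior_sd(self) -> float:
        if self.prior_sd is not None:
            return float(self.prior_sd)
        if self.trait_type == "case_control":
            return PRIOR_SD_CASE_CONTROL
        sdY = self.sdY
        if sdY is None:
            if self.maf is None or self.n is None:
                raise ValueError("quantitative study needs sdY, or MAF and N to estimate it")
            sdY = estimate_sdY(self.se ** 2, self.maf, self.n)
        return PRIOR_SD_QUANTITATIVE * float(sdY)


def wakefield_labf(beta, se, prior_sd) -> np.ndarray:
    """Wakefield log approximate Bayes factor for association.

    With V = se², W = prior_sd², z = beta/se:
    labf = 0.5 log(V/(V+W)) + 0.5 z² W/(V+W).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    V = se ** 2
    W = float(prior_sd) ** 2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(V / (V + W)) + 0.5 * z2 * W / (V + W)


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities plus diagnostics for one region."""

    nsnps: int
    pp: dict
    per_variant_h4: np.ndarray
    p1: float
    p2: float
    p12: float
    min_p12_pass: Optional[float] = None
    robust: Optional[bool] = None
    violation: Optional[bool] = None
    sensitivity_curve: Optional[pd.DataFrame] = None

    @property
    def pp_h4(self) -> float:
        return self.pp["pp_h4"]


def _hypothesis_logmasses(labf1: np.ndarray, labf2: np.ndarray,
                          p1: float, p2: float, p12: float) -> np.ndarray:
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    m = l1.size
    lH0 = 0.0
    lH1 = np.log(p1) + logsumexp(l1)
    lH2 = np.log(p2) + logsumexp(l2)
    lH4 = np.log(p12) + logsumexp(l1 + l2)
    if m >= 2:
        # sum over ordered pairs i != j of exp(l1_i + l2_j)
        pairwise = l1[:, None] + l2[None, :]
        np.fill_diagonal(pairwise, -np.inf)
        lH3 = np.log(p1) + np.log(p2) + logsumexp(pairwise)
    else:
        lH3 = -np.inf
    return np.array([lH0, lH1, lH2, lH3, lH4])


def coloc_abf(study1: ColocStudyInput, study2: ColocStudyInput,
              p1: float = DEFAULT_P1, p2: float = DEFAULT_P2,
              p12: float = DEFAULT_P12) -> ColocResult:
    """Colocalization posteriors from two aligned studies.

    The variant lists must be identical and identically ordered; the
    pipeline layer is responsible for harmonization and for the >= 50
    variant requirement, so the engine itself works on any m >= 1.
    """
    if study1.beta.shape != study2.beta.shape:
        raise ValueError("studies must cover the same ordered variant list")
    m = study1.beta.size
    labf1 = wakefield_labf(study1.beta, study1.se, study1.effective_prior_sd())
    labf2 = wakefield_labf(study2.beta, study2.se, study2.effective_prior_sd())
    lmass = _hypothesis_logmasses(labf1, labf2, p1, p2, p12)
    pp = np.exp(lmass - logsumexp(lmass))
    joint = labf1 + labf2
    per_variant = np.exp(joint - logsumexp(joint))
    res = ColocResult(
        nsnps=m,
        pp=dict(zip(HYPOTHESES, pp.tolist())),
        per_variant_h4=per_variant,
        p1=p1, p2=p2, p12=p12,
    )
    res._labf1 = labf1  # cached for the prior-sensitivity scan
    res._labf2 = labf2
    return res


def prior_sensitivity(study1: ColocStudyInput, study2: ColocStudyInput,
                      p1: float = DEFAULT_P1, p2: float = DEFAULT_P2,
                      p12_grid: Optional[np.ndarray] = None,
                      threshold: float = PP_H4_THRESHOLD,
                      robust_p12: float = 1e-6,
                      base: Optional[ColocResult] = None):
    """Scan PP_H4 over a grid of shared-causal priors p12.

    ABFs are computed once and reweighted per grid point.  ``min_p12_pass``
    is the smallest grid p12 at which PP_H4 clears ``threshold`` (None if
    never); the result is flagged robust when that happens by
    p12 <= ``robust_p12``, i.e. colocalization survives a prior an order of
    magnitude more skeptical than the default.

    Returns ``(curve, min_p12_pass, robust)`` where curve is a DataFrame
    with columns p12 and pp_h4.
    """
    if p12_grid is None:
        p12_grid = np.logspace(-8, -4, 50)
    if base is None:
        base = coloc_abf(study1, study2, p1=p1, p2=p2, p12=p12_grid[-1])
    labf1, labf2 = base._labf1, base._labf2
    pph4 = np.empty(len(p12_grid))
    for i, p12 in enumerate(p12_grid):
        lmass = _hypothesis_logmasses(labf1, labf2, p1, p2, p12)
        pph4[i] = np.exp(lmass[4] - logsumexp(lmass))
    curve = pd.DataFrame({"p12": p12_grid, "pp_h4": pph4})
    passing = np.flatnonzero(pph4 >= threshold)
    min_p12_pass = float(p12_grid[passing[0]]) if passing.size else None
    robust = min_p12_pass is not None and min_p12_pass <= robust_p12
    return curve, min_p12_pass, robust


def detect_secondary_peaks(assoc: SummaryStats, ld: Optional[LDMatrix] = None,
                           lead_mask_bases: int = 250_000,
                           lead_mask_r2: float = 0.01,
                           secondary_p: float = 1e-6,
                           primary_p: float = 5e-8):
    """Diagnose multiple association peaks in a window.

    Iteratively takes the smallest-p unmasked variant as a peak (the first
    peak must reach ``primary_p``, later ones ``secondary_p``), then masks
    variants within ``lead_mask_bases`` of it — and, when an LD matrix is
    supplied, variants with r² >= ``lead_mask_r2`` with it.  Two or more
    peaks indicate the single-causal-variant assumption may be violated by
    LD structure.

    Returns ``(violation, peaks)`` with peaks as (chrom, pos, pvalue) tuples.
    """
    df = assoc.df
    if len(df) == 0:
        return False, []
    pos = df["pos"].to_numpy()
    chrom = df["chrom"].to_numpy()
    pval = df["pvalue"].to_numpy(dtype=float)
    ld_idx = None
    if ld is not None:
        ld_idx = np.array([
            -1 if (i := ld.index_of(c, p)) is None else i for c, p in zip(chrom, pos)
        ])
    unmasked = np.ones(len(df), dtype=bool)
    peaks = []
    while unmasked.any():
        i = int(np.flatnonzero(unmasked)[np.argmin(pval[unmasked])])
        threshold = primary_p if not peaks else secondary_p
        if pval[i] > threshold:
            break
        peaks.append((chrom[i], int(pos[i]), float(pval[i])))
        near = (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= lead_mask_bases)
        if ld_idx is not None and ld_idx[i] >= 0:
            in_ld = np.zeros(len(df), dtype=bool)
            has_ld = ld_idx >= 0
            in_ld[has_ld] = ld.r[ld_idx[i], ld_idx[has_ld]] ** 2 >= lead_mask_r2
            near |= in_ld
        unmasked &= ~near
    return len(peaks) >= 2, peaks
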