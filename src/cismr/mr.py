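"""Two-sample MR estimators, Steiger directionality, and the sensitivity battery.

The primary estimator is dispatched on the number of harmonized instruments:
a single instrument gets the Wald ratio, two get inverse-variance-weighted
(IVW) regression through the origin, and three or more additionally trigger
the full sensitivity battery (weighted median, penalized weighted median,
weighted mode, Egger regression with its intercept test).  The Steiger
directionality test runs for every tier.

Conventions
-----------
* IVW uses outcome-variance weights 1/se_out² and a multiplicative
  random-effects standard-error scaling floored at 1, i.e. the reported SE
  is never smaller than the fixed-effect SE.
* Egger pre-orients every pair so beta_exp >= 0, fits a two-parameter
  weighted regression, and reports t-based p-values on k-2 degrees of
  freedom.
* Weighted median and mode standard errors come from a parametric
  bootstrap over the sampling distributions of (beta_exp, beta_out);
  results are reproducible given the seed.
* Ratio-estimate standard errors use the first-order delta method
  se_out/|beta_exp|; a second-order correction (adding the
  beta_out²·se_exp²/beta_exp⁴ term) is available via ``second_order=True``
  on :func:`wald_ratio`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .instruments import InstrumentPair, InstrumentSet
from .sumstats import StudyMeta

log = logging.getLogger(__name__)

Z95 = sps.norm.ppf(0.975)
P_FLOOR = 1e-300  # keep p-values inside (0, 1] even for extreme z


def _norm_p(z: float) -> float:
    return max(float(2.0 * sps.norm.sf(abs(z))), P_FLOOR)


def _t_p(t: float, df: int) -> float:
    return max(float(2.0 * sps.t.sf(abs(t), df)), P_FLOOR)


@dataclass
class MRResult:
    """Primary MR estimate on the outcome scale (log-odds for case/control)."""

    method: str  # "wald_ratio" | "ivw"
    nsnp: int
    estimate: float
    se: float
    pvalue: float
    or_point: float = field(init=False)
    or_low95: float = field(init=False)
    or_high95: float = field(init=False)
    adj_pvalue: Optional[float] = None

    def __post_init__(self):
        self.or_point = float(np.exp(self.estimate))
        self.or_low95 = float(np.exp(self.estimate - Z95 * self.se))
        self.or_high95 = float(np.exp(self.estimate + Z95 * self.se))


@dataclass
class EstimateTriple:
    estimate: float
    se: float
    pvalue: float


@dataclass
class EggerFit:
    slope: EstimateTriple
    intercept: float
    intercept_se: float
    intercept_p: float


@dataclass
class SensitivityReport:
    """Sensitivity-battery output and pass/fail flags for one MR test.

    Battery estimates are populated only for the tiers where they apply
    (nsnp >= 3); ``overall_pass`` is the conjunction of the applicable
    flags, each of which is also reported so users can re-gate.
    """

    weighted_median: Optional[EstimateTriple] = None
    penalized_weighted_median: Optional[EstimateTriple] = None
    weighted_mode: Optional[EstimateTriple] = None
    egger: Optional[EggerFit] = None
    steiger_direction: Optional[bool] = None
    steiger_p: Optional[float] = None
    pass_egger_intercept: bool = True
    pass_sign_consistency: bool = True
    pass_steiger: bool = True
    overall_pass: bool = True


def _as_arrays(pairs: Sequence[InstrumentPair]):
    bx = np.array([p.beta_exp for p in pairs], dtype=float)
    sx = np.array([p.se_exp for p in pairs], dtype=float)
    by = np.array([p.beta_out for p in pairs], dtype=float)
    sy = np.array([p.se_out for p in pairs], dtype=float)
    return bx, sx, by, sy


def wald_ratio(pair: InstrumentPair, second_order: bool = False) -> MRResult:
    """Single-instrument ratio estimate beta_out / beta_exp."""
    if pair.beta_exp == 0:
        raise ValueError("undefined instrument: beta_exp is zero")
    est = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    if second_order:
        se = float(np.sqrt(se ** 2 + pair.beta_out ** 2 * pair.se_exp ** 2 / pair.beta_exp ** 4))
    return MRResult("wald_ratio", 1, float(est), float(se), _norm_p(est / se))


def ivw(pairs: Sequence[InstrumentPair]) -> MRResult:
    """Inverse-variance-weighted regression of beta_out on beta_exp through the origin.

    Multiplicative random-effects scaling: the fixed-effect SE is inflated by
    sqrt(Q/(k-1)) when Cochran's Q exceeds its degrees of freedom.
    """
    k = len(pairs)
    if k < 2:
        raise ValueError("IVW requires at least 2 instruments")
    bx, _, by, sy = _as_arrays(pairs)
    w = 1.0 / sy ** 2
    swx2 = np.sum(w * bx ** 2)
    est = np.sum(w * bx * by) / swx2
    se_fixed = swx2 ** -0.5
    q = np.sum(w * (by - est * bx) ** 2)
    se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
    return MRResult("ivw", k, float(est), float(se), _norm_p(est / se))


def egger(pairs: Sequence[InstrumentPair]) -> EggerFit:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Pairs are first oriented so beta_exp >= 0; the intercept p-value is the
    directional-pleiotropy test.  SEs carry the multiplicative
    random-effects scaling on k-2 degrees of freedom.
    """
    k = len(pairs)
    if k < 3:
        raise ValueError("Egger regression requires at least 3 instruments")
    bx, _, by, sy = _as_arrays(pairs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    q = np.sum(w * resid ** 2)
    scale = max(1.0, np.sqrt(q / (k - 2)))
    cov = np.linalg.inv(xtwx) * scale ** 2
    se = np.sqrt(np.diag(cov))
    return EggerFit(
        slope=EstimateTriple(float(coef[1]), float(se[1]), _t_p(coef[1] / se[1], k - 2)),
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_p=_t_p(coef[0] / se[0], k - 2),
    )


def _ratios_and_weights(pairs: Sequence[InstrumentPair]):
    bx, _, by, sy = _as_arrays(pairs)
    r = by / bx
    se_r = sy / np.abs(bx)
    return r, 1.0 / se_r ** 2


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    s = (np.cumsum(w) - w / 2.0) / np.sum(w)
    return float(np.interp(0.5, s, v))


def _bootstrap_se(pairs, point_fn, n_boot, rng) -> float:
    bx, sx, by, sy = _as_arrays(pairs)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        ests[b] = point_fn(bxs, bys, sy)
    return float(np.std(ests, ddof=1))


def weighted_median(pairs: Sequence[InstrumentPair], n_boot: int = 5000,
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None) -> EstimateTriple:
    """Weighted median of per-instrument ratio estimates.

    The estimate interpolates the sorted ratios at cumulative standardized
    weight 0.5; the SE is a parametric bootstrap over the instruments'
    sampling distributions.
    """
    if len(pairs) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    rng = rng if rng is not None else np.random.default_rng(seed)

    def point(bx, by, sy):
        r = by / bx
        w = (np.abs(bx) / sy) ** 2
        return _weighted_median(r, w)

    r, w = _ratios_and_weights(pairs)
    est = _weighted_median(r, w)
    se = _bootstrap_se(pairs, point, n_boot, rng)
    return EstimateTriple(est, se, _norm_p(est / se))


def penalized_weighted_median(pairs: Sequence[InstrumentPair], penalty: float = 20.0,
                              n_boot: int = 5000, seed: Optional[int] = None,
                              rng: Optional[np.random.Generator] = None) -> EstimateTriple:
    """Weighted median with outlier-penalized weights.

    Each instrument's heterogeneity contribution Q_i = w_i (r_i - r_IVW)² is
    referred to a chi-square(1); weights are multiplied by
    min(1, penalty * P(X² > Q_i)), shrinking instruments whose ratio sits
    far from the IVW consensus.
    """
    if len(pairs) < 3:
        raise ValueError("penalized weighted median requires at least 3 instruments")
    rng = rng if rng is not None else np.random.default_rng(seed)
    ivw_est = ivw(pairs).estimate

    def point(bx, by, sy):
        r = by / bx
        w = (np.abs(bx) / sy) ** 2
        q = sps.chi2.sf(w * (r - ivw_est) ** 2, df=1)
        return _weighted_median(r, w * np.minimum(1.0, penalty * q))

    r, w = _ratios_and_weights(pairs)
    q = sps.chi2.sf(w * (r - ivw_est) ** 2, df=1)
    est = _weighted_median(r, w * np.minimum(1.0, penalty * q))
    se = _bootstrap_se(pairs, point, n_boot, rng)
    return EstimateTriple(est, se, _norm_p(est / se))


def _mode_point(r: np.ndarray, w: np.ndarray, phi: float) -> float:
    k = len(r)
    iqr = np.subtract(*np.percentile(r, [75, 25]))
    spread = min(np.std(r, ddof=1), iqr / 1.34)
    h = phi * 0.9 * spread * k ** (-1 / 5)
    if h <= 0:
        return float(r[0])
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)
    dens = np.sum(w[:, None] * np.exp(-0.5 * ((grid[None, :] - r[:, None]) / h) ** 2), axis=0)
    return float(grid[np.argmax(dens)])


def weighted_mode(pairs: Sequence[InstrumentPair], phi: float = 1.0,
                  n_boot: int = 5000, seed: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None) -> EstimateTriple:
    """Mode of the weighted kernel density over ratio estimates.

    Normal kernel, Silverman-style bandwidth h = phi * 0.9 * min(sd, IQR/1.34)
    * k^(-1/5), argmax on a 512-point grid spanning the ratio range +/- 3h.
    Degenerate inputs (all ratios identical) return that common ratio.
    """
    if len(pairs) < 3:
        raise ValueError("weighted mode requires at least 3 instruments")
    rng = rng if rng is not None else np.random.default_rng(seed)

    def point(bx, by, sy):
        r = by / bx
        w = (np.abs(bx) / sy) ** 2
        return _mode_point(r, w / np.sum(w), phi)

    r, w = _ratios_and_weights(pairs)
    est = _mode_point(r, w / np.sum(w), phi)
    se = _bootstrap_se(pairs, point, n_boot, rng)
    return EstimateTriple(est, se, _norm_p(est / se))


def _variance_explained(beta, se, n, trait_type: str) -> np.ndarray:
    """Per-variant variance explained from a z-statistic and sample size."""
    t = np.asarray(beta) / np.asarray(se)
    n = np.asarray(n, dtype=float)
    if trait_type == "quantitative":
        return t ** 2 / (t ** 2 + n - 2)
    return t ** 2 / (t ** 2 + n)


def steiger(pairs: Sequence[InstrumentPair], meta_exp: StudyMeta,
            meta_out: StudyMeta) -> tuple[bool, float]:
    """Directionality test: do the instruments explain more variance in the
    exposure than in the outcome?

    Per-SNP variance explained is summed over instruments on each side;
    ``direction`` is True when the exposure sum is strictly larger (a tie is
    False).  The p-value compares Fisher-transformed sqrt(sum r²) values
    with SE sqrt(1/(n_exp-3) + 1/(n_out-3)).
    """
    if any(p.n_exp is None or p.n_out is None for p in pairs):
        raise ValueError("Steiger test needs per-record sample sizes on both sides")
    bx, sx, by, sy = _as_arrays(pairs)
    n_exp = np.array([p.n_exp for p in pairs], dtype=float)
    n_out = np.array([p.n_out for p in pairs], dtype=float)
    r2_exp = float(np.sum(_variance_explained(bx, sx, n_exp, meta_exp.trait_type)))
    r2_out = float(np.sum(_variance_explained(by, sy, n_out, meta_out.trait_type)))
    direction = r2_exp > r2_out
    cap = 1.0 - 1e-12
    z_exp = np.arctanh(min(np.sqrt(r2_exp), cap))
    z_out = np.arctanh(min(np.sqrt(r2_out), cap))
    se_diff = np.sqrt(1.0 / (np.mean(n_exp) - 3) + 1.0 / (np.mean(n_out) - 3))
    p = _norm_p((z_exp - z_out) / se_diff)
    return direction, p


def sensitivity_gate(report: SensitivityReport, primary: MRResult) -> bool:
    """Pass/fail rule combining the battery into one flag.

    Pass requires: Egger intercept p >= 0.05 (when computed), every computed
    battery estimate sharing the primary estimate's sign (zero matches
    either sign), and Steiger direction True.  Each component flag is set on
    the report, and ``overall_pass`` is their conjunction.
    """
    def same_sign(a, b):
        return a == 0 or b == 0 or (a > 0) == (b > 0)

    report.pass_egger_intercept = (
        report.egger is None or report.egger.intercept_p >= 0.05
    )
    battery = [
        t.estimate for t in (
            report.weighted_median, report.penalized_weighted_median, report.weighted_mode,
        ) if t is not None
    ]
    if report.egger is not None:
        battery.append(report.egger.slope.estimate)
    report.pass_sign_consistency = all(same_sign(b, primary.estimate) for b in battery)
    report.pass_steiger = bool(report.steiger_direction)
    report.overall_pass = (
        report.pass_egger_intercept and report.pass_sign_consistency and report.pass_steiger
    )
    return report.overall_pass


def run_mr(instruments: InstrumentSet, meta_exp: StudyMeta, meta_out: StudyMeta,
           n_boot: int = 5000, seed: Optional[int] = None) -> tuple[MRResult, SensitivityReport]:
    """Dispatch the estimator tier on instrument count and run the battery.

    nsnp = 1 → Wald ratio, sensitivity limited to Steiger; nsnp = 2 → IVW +
    Steiger; nsnp >= 3 → IVW as primary plus the full battery.
    """
    pairs = instruments.pairs
    if not pairs:
        raise ValueError("empty instrument set")
    rng = np.random.default_rng(seed)
    report = SensitivityReport()
    if len(pairs) == 1:
        primary = wald_ratio(pairs[0])
    else:
        primary = ivw(pairs)
    if len(pairs) >= 3:
        report.weighted_median = weighted_median(pairs, n_boot=n_boot, rng=rng)
        report.penalized_weighted_median = penalized_weighted_median(pairs, n_boot=n_boot, rng=rng)
        report.weighted_mode = weighted_mode(pairs, n_boot=n_boot, rng=rng)
        report.egger = egger(pairs)
    report.steiger_direction, report.steiger_p = steiger(pairs, meta_exp, meta_out)
    sensitivity_gate(report, primary)
    return primary, report


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
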