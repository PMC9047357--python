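"""Two-sample MR estimators on a harmonized exposure/outcome dataset.

All estimators operate on per-SNP effect pairs (beta_exp, beta_out) with
outcome standard errors as precision weights.  Causal effects are on the
log-odds-ratio scale for binary outcomes; every estimate carries the
exponentiated odds ratio with a 95% Wald interval and a two-sided normal
p-value.  Inverse-variance weighting uses first-order Wald-ratio standard
errors (se_out/|beta_exp|), and regression-based estimators apply
multiplicative random-effects scaling with the residual standard deviation
floored at 1 -- under-dispersion never shrinks a standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
from scipy import stats

from .instruments import HarmonizedDataset

__all__ = [
    "MREstimate",
    "InsufficientInstrumentsError",
    "DegenerateInstrumentError",
    "ratio_estimates",
    "ivw",
    "weighted_median",
    "mr_egger",
    "leave_one_out",
    "to_odds_ratio",
]

Z95 = 1.96  # normal quantile used for all 95% intervals


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


class DegenerateInstrumentError(ValueError):
    """An instrument has a zero exposure effect, so its Wald ratio is undefined."""


@dataclass
class MREstimate:
    """One estimator's causal-effect result.

    ``beta`` is the causal log odds ratio, ``or_`` its exponential with a
    95% Wald CI; ``q_stat``/``q_pval`` hold Cochran heterogeneity where the
    estimator defines it and ``intercept*`` fields are Egger-only.
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    q_stat: float | None = None
    q_pval: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    def __post_init__(self) -> None:
        self.or_ = float(np.exp(self.beta))
        self.ci_low = float(np.exp(self.beta - Z95 * self.se))
        self.ci_high = float(np.exp(self.beta + Z95 * self.se))

    def to_dict(self) -> dict:
        return asdict(self)


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float, float]:
    """(OR, CI low, CI high, two-sided normal p) for a log-OR and its SE."""
    if not se > 0:
        raise ValueError("se must be positive")
    p = 2 * stats.norm.sf(abs(beta) / se)
    return float(np.exp(beta)), float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se)), float(p)


def _estimate(method: str, beta: float, se: float, n_snp: int, **kw) -> MREstimate:
    pval = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else float("nan")
    return MREstimate(method=method, beta=float(beta), se=float(se), pval=pval, n_snp=n_snp, **kw)


# ---------------------------------------------------------------------------
# Wald ratios


def ratio_estimates(h: HarmonizedDataset) -> list[tuple[str, float, float]]:
    """Per-SNP Wald ratios ``theta_j = beta_out/beta_exp`` with first-order
    standard errors ``sigma_j = se_out/|beta_exp|``."""
    out = []
    for r in h.records:
        if r.beta_exp == 0:
            raise DegenerateInstrumentError(f"{r.snp}: exposure effect is zero")
        out.append((r.snp, r.beta_out / r.beta_exp, r.se_out / abs(r.beta_exp)))
    return out


# ---------------------------------------------------------------------------
# IVW


def ivw(h: HarmonizedDataset, re_policy: str = "multiplicative") -> MREstimate:
    """Inverse-variance-weighted estimate: weighted regression of outcome on
    exposure effects through the origin, weights 1/se_out².

    ``re_policy="multiplicative"`` (default) scales the coefficient SE by
    the residual standard deviation floored at 1; ``"fixed"`` keeps the
    fixed-effects SE.  Cochran's Q and its chi-square p-value (df n−1) are
    attached.
    """
    if re_policy not in ("fixed", "multiplicative"):
        raise ValueError("re_policy must be 'fixed' or 'multiplicative'")
    if len(h) < 2:
        raise InsufficientInstrumentsError("IVW needs at least 2 instruments")
    bx, _, by, sy = h.arrays()
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = 1.0 / np.sqrt(sxx)
    resid = by - beta * bx
    q = float(np.sum(w * resid**2))
    df = len(h) - 1
    q_pval = float(stats.chi2.sf(q, df)) if df > 0 else None
    if re_policy == "multiplicative":
        scale = max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
        se = se_fixed * scale
    else:
        se = se_fixed
    return _estimate("ivw", beta, se, len(h), q_stat=q, q_pval=q_pval)


# ---------------------------------------------------------------------------
# Weighted median


def _weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weight-ordered median with linear interpolation at the 50% point.

    Thetas are sorted ascending; with normalized weights w_j the cumulative
    midpoint positions are s_j = sum_{k<=j} w_k − w_j/2, and the estimate
    interpolates between the thetas bracketing s = 0.5.
    """
    order = np.argsort(theta)
    th = theta[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2
    return float(np.interp(0.5, s, th))


def _penalized_weights(
    theta: np.ndarray, sigma: np.ndarray, penalty_mult: float
) -> np.ndarray:
    """Down-weight heterogeneous SNPs about the unpenalized estimate.

    Each SNP's one-df chi-square heterogeneity contribution about the
    unpenalized weighted median gives an upper-tail probability q_j; the
    inverse-variance weight is multiplied by min(1, penalty_mult · q_j).
    """
    w = 1.0 / sigma**2
    b0 = _weighted_median(theta, w)
    q = stats.chi2.sf(w * (theta - b0) ** 2, df=1)
    return w * np.minimum(1.0, penalty_mult * q)


def weighted_median(
    h: HarmonizedDataset,
    penalized: bool = False,
    n_boot: int = 1000,
    seed: int | None = None,
    penalty_mult: float = 20.0,
) -> MREstimate:
    """(Penalized) weighted-median causal estimate with bootstrap SE.

    Consistent when at least half of the inverse-variance weight comes from
    valid instruments.  The SE comes from a parametric bootstrap: exposure
    and outcome betas are redrawn from normal distributions with their
    reported SEs and the median recomputed ``n_boot`` times (penalty
    weights are recomputed inside every replicate for the penalized
    variant).
    """
    if len(h) < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 instruments")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    bx, sx, by, sy = h.arrays()
    theta = by / bx
    sigma = sy / np.abs(bx)

    def point(th: np.ndarray, sg: np.ndarray) -> float:
        if penalized:
            return _weighted_median(th, _penalized_weights(th, sg, penalty_mult))
        return _weighted_median(th, 1.0 / sg**2)

    beta = point(theta, sigma)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        th_b = by_b / bx_b
        sg_b = sy / np.abs(bx_b)
        boots[b] = point(th_b, sg_b)
    se = float(np.std(boots, ddof=1))
    method = "penalized_weighted_median" if penalized else "weighted_median"
    return _estimate(method, beta, se, len(h))


# ---------------------------------------------------------------------------
# MR-Egger


def mr_egger(h: HarmonizedDataset) -> MREstimate:
    """MR-Egger regression: weighted least squares of outcome on exposure
    effects with an intercept, after orienting every pair so beta_exp >= 0.

    The slope is the pleiotropy-adjusted causal estimate; a nonzero
    intercept indicates directional pleiotropy.  SEs use the same
    multiplicative residual scaling (floored at 1) as IVW.
    """
    if len(h) < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    bx, _, by, sy = h.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(x), x])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ y)
    resid = y - X @ coef
    df = len(h) - 2
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss_w / df)) if df > 0 else 1.0
    cov = np.linalg.inv(xtx) * scale**2
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    q_pval = float(stats.chi2.sf(rss_w, df)) if df > 0 else None
    est = _estimate(
        "mr_egger",
        slope,
        se_slope,
        len(h),
        q_stat=rss_w,
        q_pval=q_pval,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_pval=float(2 * stats.norm.sf(abs(intercept) / se_int)),
    )
    return est


# ---------------------------------------------------------------------------
# Leave-one-out


def leave_one_out(
    h: HarmonizedDataset, estimator: Callable[[HarmonizedDataset], MREstimate] = ivw
) -> list[tuple[str, MREstimate]]:
    """Re-estimate omitting each instrument in turn (IVW by default)."""
    if len(h) < 3:
        raise InsufficientInstrumentsError("leave-one-out needs at least 3 instruments")
    out = []
    for i, rec in enumerate(h.records):
        sub = HarmonizedDataset(
            exposure_id=h.exposure_id,
            outcome_id=h.outcome_id,
            records=h.records[:i] + h.records[i + 1 :],
        )
        out.append((rec.snp, estimator(sub)))
    return out
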