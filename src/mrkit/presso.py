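"""MR-PRESSO: pleiotropy residual sum and outlier test.

A simulation-based check for horizontal pleiotropy.  The observed residual
sum of squares about leave-one-out IVW fits is compared with its null
distribution, obtained by redrawing the per-SNP effects from normal
distributions centered on the fitted values with the reported standard
errors.  SNPs whose individual residuals are extreme against their
simulated distribution are flagged as outliers (Bonferroni-corrected), and
a distortion test asks whether removing them shifts the IVW estimate more
than removing equally many random SNPs would.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .estimators import MREstimate, ivw, _estimate
from .instruments import HarmonizedDataset

__all__ = ["PressoResult", "run_presso", "AllOutliersError"]


class AllOutliersError(RuntimeError):
    """Every instrument was flagged; no corrected estimate is possible."""


@dataclass
class PressoResult:
    """Global, outlier and distortion test outputs.

    ``per_snp_pvals`` holds ``(rsID, outlier p, Bonferroni-adjusted p)``;
    ``corrected_estimate`` and ``distortion_pval`` are None when no outlier
    was flagged.
    """

    rss_obs: float
    global_pval: float
    per_snp_pvals: list[tuple[str, float, float]]
    outliers: list[str]
    raw_estimate: MREstimate
    corrected_estimate: MREstimate | None = None
    distortion_pval: float | None = None
    n_sim: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["raw_estimate"] = self.raw_estimate.to_dict()
        d["corrected_estimate"] = (
            None if self.corrected_estimate is None else self.corrected_estimate.to_dict()
        )
        return d


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out origin-regression slopes, one per column.

    ``x``/``y`` may be 1-D (one dataset) or 2-D ``(n_sim, n_snp)``; the
    totals trick makes each leave-one-out fit O(1).
    """
    sxy = np.sum(w * x * y, axis=-1, keepdims=True)
    sxx = np.sum(w * x * x, axis=-1, keepdims=True)
    return (sxy - w * x * y) / (sxx - w * x * x)


def _weighted_residuals(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-SNP weighted squared residuals about the leave-one-out fits."""
    theta = _loo_slopes(x, y, w)
    return w * (y - theta * x) ** 2


def run_presso(
    h: HarmonizedDataset,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
    n_distortion: int = 1000,
) -> PressoResult:
    """Run the global, outlier and distortion tests on a harmonized dataset.

    Parameters
    ----------
    h : HarmonizedDataset
        At least 4 instruments.
    n_sim : int
        Simulation replicates for the global/outlier null (>= 100).  The
        reported p-values use add-one smoothing, so the smallest achievable
        p is 1/(n_sim+1).
    outlier_alpha : float
        Significance level applied to the Bonferroni-adjusted per-SNP p.
    seed : int, optional
        Seed for the simulation RNG; fix it for reproducible reports.
    n_distortion : int
        Random same-size SNP removals used by the distortion test.
    """
    if len(h) < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = h.arrays()
    n = len(h)
    w = 1.0 / sy**2

    # Observed statistics: residuals about leave-one-out IVW fits.
    obs_resid = _weighted_residuals(bx, by, w)
    rss_obs = float(obs_resid.sum())

    # Null simulation: redraw effects around the leave-one-out fitted values
    # with the observed SEs, then recompute the same statistics.
    theta_loo = _loo_slopes(bx, by, w)
    x_sim = rng.normal(bx, sx, size=(n_sim, n))
    y_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, n))
    sim_resid = _weighted_residuals(x_sim, y_sim, w)
    rss_sim = sim_resid.sum(axis=1)
    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    # Per-SNP outlier test with Bonferroni adjustment over the panel.
    p_raw = (1 + np.sum(sim_resid >= obs_resid, axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * n)
    snps = h.snps
    per_snp = [(snps[j], float(p_raw[j]), float(p_adj[j])) for j in range(n)]
    outliers = [snps[j] for j in range(n) if p_adj[j] < outlier_alpha]

    raw = ivw(h)
    corrected = None
    distortion_pval = None
    if outliers:
        if len(outliers) == n:
            raise AllOutliersError("every instrument flagged as a pleiotropic outlier")
        kept = HarmonizedDataset(
            exposure_id=h.exposure_id,
            outcome_id=h.outcome_id,
            records=[r for r in h.records if r.snp not in set(outliers)],
        )
        corrected = ivw(kept)
        # Distortion: is the shift larger than removing random subsets of
        # the same size?
        d_obs = (corrected.beta - raw.beta) / abs(raw.beta)
        n_out = len(outliers)
        shifts = np.empty(n_distortion)
        idx = np.arange(n)
        for b in range(n_distortion):
            drop = rng.choice(idx, size=n_out, replace=False)
            keep = np.setdiff1d(idx, drop)
            xb, yb, wb = bx[keep], by[keep], w[keep]
            beta_b = np.sum(wb * xb * yb) / np.sum(wb * xb * xb)
            shifts[b] = (beta_b - raw.beta) / abs(raw.beta)
        distortion_pval = float((1 + np.sum(np.abs(shifts) >= abs(d_obs))) / (n_distortion + 1))

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        per_snp_pvals=per_snp,
        outliers=outliers,
        raw_estimate=raw,
        corrected_estimate=corrected,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
    )
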