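"""Multivariable MR: joint instrument panels across exposures and direct
(conditional) effect estimation by weighted regression without intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimators import MREstimate, _estimate
from .instruments import clump, select_instruments
from .sumstats import LDTable, SummaryStatsTable

__all__ = ["MVMRDataset", "MVMRResult", "assemble_mvmr", "mvmr_estimate", "CollinearExposuresError"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class CollinearExposuresError(ValueError):
    """The exposure effect matrix is rank deficient."""


@dataclass
class MVMRDataset:
    """Joint panel for multivariable MR.

    ``df`` has one row per SNP with columns ``beta_<exposure>``,
    ``se_<exposure>`` for every exposure plus ``beta_out``/``se_out``, all
    expressed on one effect-allele orientation.  ``provenance`` records
    which exposure's instrument list contributed each SNP, and ``audit``
    lists ``(rsID, reason)`` for SNPs dropped during assembly.
    """

    exposure_ids: list[str]
    outcome_id: str
    df: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)
    audit: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def write_wide_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class MVMRResult:
    """Per-exposure direct-effect estimates from one joint fit."""

    estimates: dict[str, MREstimate]
    n_snp: int


def _lookup_aligned(table: SummaryStatsTable, snp: str, ea: str, oa: str):
    """(beta, se) for ``snp`` expressed for effect allele ``ea``; None if the
    SNP is absent or its alleles are incompatible."""
    sub = table.df[table.df["snp"] == snp]
    if sub.empty:
        return None
    r = sub.iloc[0]
    pair = (r["effect_allele"], r["other_allele"])
    flipped = (_COMPLEMENT[pair[0]], _COMPLEMENT[pair[1]])
    if pair == (ea, oa) or flipped == (ea, oa):
        return float(r["beta"]), float(r["se"])
    if pair == (oa, ea) or flipped == (oa, ea):
        return -float(r["beta"]), float(r["se"])
    return None


def assemble_mvmr(
    exposures: list[SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LDTable | None = None,
    p_threshold: float = 5e-8,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> MVMRDataset:
    """Build the joint instrument panel for multivariable MR.

    Each exposure contributes its clumped genome-wide-significant SNPs; the
    union is clumped again across exposures (keeping, within a linked
    group, the SNP with the smallest minimum p across exposures), and every
    surviving SNP is looked up in all exposure tables and the outcome and
    aligned to the orientation of the table that contributed it.  SNPs
    missing from any table, or with incompatible alleles, are dropped with
    an audit reason.
    """
    if len(exposures) < 2:
        raise ValueError("multivariable MR needs at least 2 exposures")

    provenance: dict[str, str] = {}
    pool_rows = []
    for tab in exposures:
        chosen = clump(select_instruments(tab, p_threshold), ld, r2_max, window_kb)
        for _, r in chosen.df.iterrows():
            if r["snp"] not in provenance:
                provenance[r["snp"]] = tab.trait_id
                pool_rows.append(r)

    # Cross-exposure clumping on the pooled panel, ranked by each SNP's
    # smallest p-value across the exposures.
    def min_p(snp: str) -> float:
        ps = []
        for tab in exposures:
            sub = tab.df[tab.df["snp"] == snp]
            if not sub.empty:
                ps.append(float(sub.iloc[0]["pval"]))
        return min(ps) if ps else 1.0

    pool = pd.DataFrame(pool_rows).reset_index(drop=True)
    pool = pool.assign(pval=[min_p(s) for s in pool["snp"]])
    joint = clump(
        SummaryStatsTable(trait_id="mvmr_pool", df=pool, trait_type=exposures[0].trait_type),
        ld,
        r2_max,
        window_kb,
    )

    rows = []
    audit: list[tuple[str, str]] = []
    for _, r in joint.df.iterrows():
        snp, ea, oa = r["snp"], r["effect_allele"], r["other_allele"]
        row = {"snp": snp, "effect_allele": ea, "other_allele": oa}
        ok = True
        for tab in exposures:
            got = _lookup_aligned(tab, snp, ea, oa)
            if got is None:
                audit.append((snp, f"missing_or_mismatched_in_{tab.trait_id}"))
                ok = False
                break
            row[f"beta_{tab.trait_id}"], row[f"se_{tab.trait_id}"] = got
        if not ok:
            continue
        got = _lookup_aligned(outcome, snp, ea, oa)
        if got is None:
            audit.append((snp, f"missing_or_mismatched_in_{outcome.trait_id}"))
            continue
        row["beta_out"], row["se_out"] = got
        rows.append(row)

    if not rows:
        raise ValueError("empty joint panel after assembly")
    df = pd.DataFrame(rows)
    return MVMRDataset(
        exposure_ids=[t.trait_id for t in exposures],
        outcome_id=outcome.trait_id,
        df=df,
        provenance={s: provenance[s] for s in df["snp"] if s in provenance},
        audit=audit,
    )


def mvmr_estimate(d: MVMRDataset, intercept: bool = False) -> MVMRResult:
    """Direct effects: weighted least squares of the outcome effects on the
    exposure-effect matrix, weights 1/se_out², no intercept by default.

    Per-coefficient SEs use multiplicative residual scaling floored at 1,
    mirroring the univariable IVW convention.
    """
    k = len(d.exposure_ids)
    if len(d) <= k:
        raise ValueError("need more SNPs than exposures")
    X = d.df[[f"beta_{e}" for e in d.exposure_ids]].to_numpy(float)
    y = d.df["beta_out"].to_numpy(float)
    w = 1.0 / d.df["se_out"].to_numpy(float) ** 2
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearExposuresError("exposure effect matrix is rank deficient")
    design = sm.add_constant(X) if intercept else X
    fit = sm.WLS(y, design, weights=w).fit()
    # floor the residual scale at 1 (multiplicative random effects)
    infl = np.sqrt(max(1.0, fit.scale) / fit.scale) if fit.scale > 0 else 1.0
    bse = fit.bse * infl
    offset = 1 if intercept else 0
    estimates = {
        e: _estimate(f"mvmr[{e}]", fit.params[offset + i], bse[offset + i], len(d))
        for i, e in enumerate(d.exposure_ids)
    }
    return MVMRResult(estimates=estimates, n_snp=len(d))
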