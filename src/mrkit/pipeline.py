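"""Full-study orchestration: basic MR on every outcome, FDR across
outcomes, and — for outcomes with evidence of causality — the downstream
cascade (confounder-excluded rerun, validation cohort, multivariable MR,
two-step mediation, reverse MR).

The report is a plain JSON-serializable dictionary wrapped in
:class:`StudyReport`, so it round-trips losslessly and can be diffed
between runs.  All randomness is controlled by one config seed from which
per-stage seeds are derived deterministically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .estimators import ivw, leave_one_out, mr_egger, weighted_median
from .instruments import (
    HarmonizationPolicy,
    HarmonizedDataset,
    clump,
    harmonize,
    instrument_strength,
    select_instruments,
)
from .mediation import two_step
from .mvmr import assemble_mvmr, mvmr_estimate
from .presso import run_presso
from .sumstats import LDTable, SummaryStatsTable

__all__ = ["bh_fdr", "StudyConfig", "StudyReport", "StageError", "run_study", "basic_mr"]

log = logging.getLogger(__name__)

BASIC_METHODS = ("ivw", "weighted_median", "penalized_weighted_median", "mr_egger")


class StageError(RuntimeError):
    """A pipeline stage failed; ``partial_report`` carries what completed."""

    def __init__(self, stage: str, cause: Exception, partial_report: "StudyReport"):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.partial_report = partial_report


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving.

    Adjusted values are monotone over the sorted p-values and returned in
    the input order.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    return list(multipletests(p, method="fdr_bh")[1].astype(float))


@dataclass
class StudyConfig:
    """One full study run: inputs, thresholds, and seeds.

    Every threshold of the analysis is a named, defaulted field: the
    genome-wide significance level, clumping r² and window, proxy r²,
    palindrome policy, and the significance level α.  ``fdr_family``
    selects how adjusted p-values are grouped: ``"per_method"`` adjusts
    each method across the outcomes (family size = number of outcomes) or
    ``"all"`` pools every basic-MR test.
    """

    exposure: SummaryStatsTable
    outcomes: dict[str, SummaryStatsTable]
    ld: LDTable | None = None
    confounder_snps: Sequence[str] | None = None
    validation_exposure: SummaryStatsTable | None = None
    mvmr_exposures: list[SummaryStatsTable] | None = None
    mediation_upstream: list[SummaryStatsTable] | None = None
    cause_pvals: dict[str, float] | None = None  # externally computed, reported as-is
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    proxy_r2: float = 0.9
    palindromic_policy: str = "exclude"
    alpha: float = 0.05
    fdr_family: str = "per_method"
    select_and_clump: bool = True
    reverse_mr: bool = False
    exposure_n: float | None = None
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0

    def policy(self) -> HarmonizationPolicy:
        return HarmonizationPolicy(palindromic=self.palindromic_policy, proxy_r2_min=self.proxy_r2)


@dataclass
class StudyReport:
    """A machine-readable study report (plain JSON-serializable dict)."""

    data: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.data, indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StudyReport":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(data=json.loads(text))

    def __eq__(self, other) -> bool:
        return isinstance(other, StudyReport) and self.data == other.data


def basic_mr(h: HarmonizedDataset, n_boot: int = 1000, seed: int = 0) -> dict[str, dict]:
    """All four basic estimators on one harmonized dataset, as dicts."""
    return {
        "ivw": ivw(h).to_dict(),
        "weighted_median": weighted_median(h, n_boot=n_boot, seed=seed).to_dict(),
        "penalized_weighted_median": weighted_median(
            h, penalized=True, n_boot=n_boot, seed=seed + 1
        ).to_dict(),
        "mr_egger": mr_egger(h).to_dict(),
    }


def _harmonization_block(h: HarmonizedDataset) -> dict:
    return {
        "n_snps": len(h),
        "snps": h.snps,
        "exclusions": [list(e) for e in h.exclusions],
        "proxies": [
            {"snp": r.snp, "proxy": r.used_snp, "r2": r.proxy_r2}
            for r in h.records
            if r.proxy_r2 is not None
        ],
        "notes": list(h.notes),
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full cascade and return the study report.

    Per outcome: harmonize, instrument strength, the four basic
    estimators, MR-PRESSO; then FDR across outcomes per method.  Only
    outcomes whose IVW survives FDR at α proceed to the downstream stages
    (confounder-excluded rerun, validation-cohort rerun, multivariable MR,
    two-step mediation, reverse MR), matching the study-flow rule that
    only causality suggested by basic MR undergoes further tests.
    """
    report = StudyReport(
        data={
            "config": {
                "exposure": config.exposure.trait_id,
                "outcomes": list(config.outcomes),
                "p_threshold": config.p_threshold,
                "clump_r2": config.clump_r2,
                "clump_kb": config.clump_kb,
                "proxy_r2": config.proxy_r2,
                "palindromic_policy": config.palindromic_policy,
                "alpha": config.alpha,
                "fdr_family": config.fdr_family,
                "seed": config.seed,
                "n_boot": config.n_boot,
                "n_sim": config.n_sim,
            },
            "outcomes": {},
            "log": [],
        }
    )
    logbook = report.data["log"]
    stage = "instrument_selection"
    try:
        instruments = config.exposure
        if config.select_and_clump:
            instruments = clump(
                select_instruments(instruments, config.p_threshold),
                config.ld,
                config.clump_r2,
                config.clump_kb,
            )
            logbook.append(f"selected {len(instruments)} instruments at p<{config.p_threshold}")

        stage = "basic_mr"
        harmonized: dict[str, HarmonizedDataset] = {}
        for i, (oid, outcome) in enumerate(config.outcomes.items()):
            h = harmonize(instruments, outcome, config.ld, config.policy())
            harmonized[oid] = h
            for snp, reason in h.exclusions:
                logbook.append(f"{oid}: excluded {snp} ({reason})")
            strength = instrument_strength(instruments.subset(h.snps), n=config.exposure_n)
            seed_o = config.seed + 100 * (i + 1)
            block = {
                "harmonization": _harmonization_block(h),
                "instrument_stats": {
                    "total_r2": strength.total_r2,
                    "k": strength.k,
                    "mean_f": strength.mean_f,
                    "total_f": strength.total_f,
                },
                "basic_mr": basic_mr(h, n_boot=config.n_boot, seed=seed_o),
                "presso": run_presso(h, n_sim=config.n_sim, seed=seed_o + 7).to_dict(),
                "leave_one_out": [
                    {"omitted": snp, "beta": est.beta, "se": est.se, "pval": est.pval}
                    for snp, est in leave_one_out(h)
                ],
                "seed": seed_o,
            }
            if config.cause_pvals and oid in config.cause_pvals:
                block["cause_pval_external"] = config.cause_pvals[oid]
            report.data["outcomes"][oid] = block

        stage = "fdr"
        oids = list(config.outcomes)
        if config.fdr_family == "per_method":
            for method in BASIC_METHODS:
                adj = bh_fdr([report.data["outcomes"][o]["basic_mr"][method]["pval"] for o in oids])
                for o, a in zip(oids, adj):
                    report.data["outcomes"][o]["basic_mr"][method]["fdr"] = a
            adj = bh_fdr(
                [report.data["outcomes"][o]["presso"]["raw_estimate"]["pval"] for o in oids]
            )
            for o, a in zip(oids, adj):
                report.data["outcomes"][o]["presso"]["fdr"] = a
        else:
            flat = [(o, m) for o in oids for m in BASIC_METHODS]
            adj = bh_fdr([report.data["outcomes"][o]["basic_mr"][m]["pval"] for o, m in flat])
            for (o, m), a in zip(flat, adj):
                report.data["outcomes"][o]["basic_mr"][m]["fdr"] = a

        significant = [
            o
            for o in oids
            if report.data["outcomes"][o]["basic_mr"]["ivw"].get(
                "fdr", report.data["outcomes"][o]["basic_mr"]["ivw"]["pval"]
            )
            < config.alpha
        ]
        for o in oids:
            report.data["outcomes"][o]["significant"] = o in significant
        logbook.append(f"outcomes significant in basic MR: {significant or 'none'}")

        # Downstream cascade for significant outcomes only.
        for i, oid in enumerate(significant):
            outcome = config.outcomes[oid]
            h = harmonized[oid]
            block = report.data["outcomes"][oid]
            seed_o = block["seed"]

            stage = f"confounder_rerun[{oid}]"
            if config.confounder_snps:
                h2 = h.drop(config.confounder_snps, reason="user_excluded_confounder")
                block["confounder_excluded"] = {
                    "removed": [s for s in config.confounder_snps if s in h.snps],
                    "basic_mr": basic_mr(h2, n_boot=config.n_boot, seed=seed_o + 11),
                    "presso": run_presso(h2, n_sim=config.n_sim, seed=seed_o + 13).to_dict(),
                }
            else:
                block["confounder_excluded"] = None
                logbook.append(f"{oid}: no confounder list supplied; rerun skipped")

            stage = f"validation[{oid}]"
            if config.validation_exposure is not None:
                val_instruments = clump(
                    select_instruments(config.validation_exposure, config.p_threshold),
                    config.ld,
                    config.clump_r2,
                    config.clump_kb,
                )
                hv = harmonize(val_instruments, outcome, config.ld, config.policy())
                block["validation"] = {
                    "exposure": config.validation_exposure.trait_id,
                    "harmonization": _harmonization_block(hv),
                    "basic_mr": basic_mr(hv, n_boot=config.n_boot, seed=seed_o + 17),
                }

            stage = f"mvmr[{oid}]"
            if config.mvmr_exposures:
                panel = assemble_mvmr(
                    [config.exposure] + list(config.mvmr_exposures),
                    outcome,
                    config.ld,
                    config.p_threshold,
                    config.clump_r2,
                    config.clump_kb,
                )
                res = mvmr_estimate(panel)
                block["mvmr"] = {
                    "n_snp": res.n_snp,
                    "estimates": {e: est.to_dict() for e, est in res.estimates.items()},
                    "audit": [list(a) for a in panel.audit],
                }

            stage = f"mediation[{oid}]"
            if config.mediation_upstream:
                med_out = ivw(h)
                block["mediation"] = {}
                for up in config.mediation_upstream:
                    res = two_step(
                        up,
                        config.exposure,
                        outcome,
                        config.ld,
                        alpha=config.alpha,
                        p_threshold=config.p_threshold,
                        r2_max=config.clump_r2,
                        window_kb=config.clump_kb,
                        policy=config.policy(),
                        mediator_on_outcome=med_out,
                    )
                    block["mediation"][up.trait_id] = {
                        "step1": res.step1.to_dict(),
                        "step2": res.step2.to_dict(),
                        "mediation_suggested": res.mediation_suggested,
                        "indirect_beta_descriptive": res.indirect_beta,
                    }

            stage = f"reverse_mr[{oid}]"
            if config.reverse_mr:
                rev_instruments = clump(
                    select_instruments(outcome, config.p_threshold),
                    config.ld,
                    config.clump_r2,
                    config.clump_kb,
                )
                hr = harmonize(rev_instruments, config.exposure, config.ld, config.policy())
                block["reverse_mr"] = {"ivw": ivw(hr).to_dict(), "n_snp": len(hr)}

    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        report.data["failed_stage"] = stage
        report.data["error"] = str(exc)
        report.data = json.loads(json.dumps(report.data))
        raise StageError(stage, exc, report) from exc

    # normalize to pure JSON types so the report round-trips losslessly
    report.data = json.loads(report.to_json(indent=0))
    return report
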