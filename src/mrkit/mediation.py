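"""Two-step MR for mediation: does an upstream trait act on the outcome
through a candidate mediator?

Step 1 estimates the upstream trait's effect on the mediator with IVW using
the trait's own instruments; step 2 estimates the same trait's effect on
the outcome.  Mediation is *suggested* (not quantified) when both steps are
significant -- a qualitative screen, with an optional descriptive
product-of-coefficients as supplementary output.
"""

from __future__ import annotations

from dataclasses import dataclass

from .estimators import MREstimate, ivw
from .instruments import HarmonizationPolicy, clump, harmonize, select_instruments
from .sumstats import LDTable, SummaryStatsTable

__all__ = ["MediationResult", "two_step"]


@dataclass
class MediationResult:
    """Both steps of a two-step MR for one upstream trait.

    ``mediation_suggested`` is true iff both step p-values fall below the
    significance level used.  ``indirect_beta`` is a descriptive
    product-of-coefficients (step-1 effect x mediator-on-outcome effect);
    it is supplementary and carries no formal interval.
    """

    trait: str
    step1: MREstimate
    step2: MREstimate
    alpha: float
    mediation_suggested: bool
    indirect_beta: float | None = None


def _prepare(
    upstream: SummaryStatsTable,
    target: SummaryStatsTable,
    ld: LDTable | None,
    p_threshold: float,
    r2_max: float,
    window_kb: float,
    policy: HarmonizationPolicy | None,
):
    chosen = clump(select_instruments(upstream, p_threshold), ld, r2_max, window_kb)
    if len(chosen) < 2:
        raise ValueError(f"{upstream.trait_id}: fewer than 2 instruments after selection/clumping")
    return harmonize(chosen, target, ld, policy)


def two_step(
    upstream: SummaryStatsTable,
    mediator: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDTable | None = None,
    alpha: float = 0.05,
    p_threshold: float = 5e-8,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
    policy: HarmonizationPolicy | None = None,
    mediator_on_outcome: MREstimate | None = None,
) -> MediationResult:
    """Run both steps of a two-step MR for one upstream trait.

    Step 1: IVW of the upstream trait's instruments against the mediator.
    Step 2: IVW of the same instruments against the outcome.  When
    ``mediator_on_outcome`` (an already-computed mediator-to-outcome IVW
    estimate) is supplied, a descriptive indirect effect
    ``step1.beta * mediator_on_outcome.beta`` is attached.
    """
    step1 = ivw(_prepare(upstream, mediator, ld, p_threshold, r2_max, window_kb, policy))
    step2 = ivw(_prepare(upstream, outcome, ld, p_threshold, r2_max, window_kb, policy))
    suggested = bool(step1.pval < alpha and step2.pval < alpha)
    indirect = None
    if mediator_on_outcome is not None:
        indirect = float(step1.beta * mediator_on_outcome.beta)
    return MediationResult(
        trait=upstream.trait_id,
        step1=step1,
        step2=step2,
        alpha=alpha,
        mediation_suggested=suggested,
        indirect_beta=indirect,
    )
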