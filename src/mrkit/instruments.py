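"""Instrument selection, LD clumping, proxy substitution, harmonization,
and instrument-strength statistics (R² and F).

Harmonization aligns outcome effects to the exposure effect allele: swapped
alleles negate the outcome beta and flip its frequency; palindromic SNPs
(A/T or C/G) are strand-ambiguous and are excluded by default, with an
optional frequency-inference policy for validation runs.  A missing outcome
SNP may be replaced by a proxy in strong LD.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .sumstats import (
    VALID_ALLELES,
    LDTable,
    SummaryStatsTable,
    SumstatsValidationError,
)

__all__ = [
    "HarmonizedRecord",
    "HarmonizedDataset",
    "InstrumentStats",
    "HarmonizationPolicy",
    "select_instruments",
    "clump",
    "is_palindromic",
    "find_proxy",
    "harmonize",
    "instrument_strength",
    "NoInstrumentsError",
]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Reasons an instrument can be dropped during harmonization.
EXCLUSION_REASONS = (
    "missing_in_outcome_no_proxy",
    "palindromic",
    "ambiguous_frequency",
    "allele_mismatch",
    "user_excluded_confounder",
)


class NoInstrumentsError(RuntimeError):
    """Harmonization left no usable instruments."""


@dataclass(frozen=True)
class HarmonizedRecord:
    """One instrument's exposure/outcome effect pair on a shared effect allele.

    ``used_snp`` is the rsID whose outcome association was read -- the
    instrument itself, or an LD proxy (then ``proxy_r2`` records the LD).
    """

    snp: str
    used_snp: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    proxy_r2: float | None = None

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise SumstatsValidationError(f"{self.snp}: non-positive SE in harmonized record")


@dataclass
class HarmonizedDataset:
    """Exposure/outcome pairs plus a complete exclusion audit.

    ``records`` and ``exclusions`` partition the input instrument set;
    ``exclusions`` is a list of ``(rsID, reason)`` with reasons from
    :data:`EXCLUSION_REASONS`.
    """

    exposure_id: str
    outcome_id: str
    records: list[HarmonizedRecord]
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.snp for r in self.records] + [s for s, _ in self.exclusions]
        if len(ids) != len(set(ids)):
            raise SumstatsValidationError("rsID appears twice across records/exclusions")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snps(self) -> list[str]:
        return [r.snp for r in self.records]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        bx = np.array([r.beta_exp for r in self.records], dtype=float)
        sx = np.array([r.se_exp for r in self.records], dtype=float)
        by = np.array([r.beta_out for r in self.records], dtype=float)
        sy = np.array([r.se_out for r in self.records], dtype=float)
        return bx, sx, by, sy

    def drop(self, snps: Iterable[str], reason: str = "user_excluded_confounder") -> "HarmonizedDataset":
        """A copy with the named instruments moved to the exclusion audit."""
        dropset = set(snps)
        kept = [r for r in self.records if r.snp not in dropset]
        newly = [(r.snp, reason) for r in self.records if r.snp in dropset]
        return HarmonizedDataset(
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            records=kept,
            exclusions=self.exclusions + newly,
            notes=list(self.notes),
        )

    def write_audit(self, path: str | Path) -> None:
        """Exclusion audit as JSON lines (rsID, reason, proxy info)."""
        with open(path, "w") as fh:
            for snp, reason in self.exclusions:
                fh.write(json.dumps({"snp": snp, "reason": reason}) + "\n")
            for r in self.records:
                if r.proxy_r2 is not None:
                    fh.write(
                        json.dumps({"snp": r.snp, "proxy": r.used_snp, "r2": r.proxy_r2}) + "\n"
                    )


@dataclass
class HarmonizationPolicy:
    """Options governing allele alignment.

    ``palindromic``: ``"exclude"`` drops strand-ambiguous SNPs outright
    (the default); ``"infer"`` orients them from allele frequency and drops
    only those whose frequency falls inside ``ambiguity_band``.
    ``proxy_r2_min`` is the strict lower bound for proxy LD;
    ``proxy_eaf_tol`` is the frequency-similarity margin used to orient a
    proxy when the LD table carries no allele correspondence.
    """

    palindromic: str = "exclude"
    ambiguity_band: tuple[float, float] = (0.42, 0.58)
    proxy_r2_min: float = 0.9
    use_proxies: bool = True
    proxy_eaf_tol: float = 0.1

    def __post_init__(self) -> None:
        if self.palindromic not in ("exclude", "infer"):
            raise ValueError("palindromic policy must be 'exclude' or 'infer'")


# ---------------------------------------------------------------------------
# Selection and clumping


def select_instruments(table: SummaryStatsTable, p_threshold: float = 5e-8) -> SummaryStatsTable:
    """Rows with ``pval`` strictly below ``p_threshold``."""
    keep = table.df[table.df["pval"] < p_threshold]
    return SummaryStatsTable(
        trait_id=table.trait_id,
        df=keep,
        trait_type=table.trait_type,
        ancestry=table.ancestry,
        n_total=table.n_total,
    )


def clump(
    table: SummaryStatsTable,
    ld: LDTable | None = None,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> SummaryStatsTable:
    """Greedy p-value-ordered LD clumping.

    SNPs are visited by ascending p; a SNP is accepted iff no previously
    accepted SNP both lies within ``window_kb`` on the same chromosome and
    has r² >= ``r2_max`` with it.  Pairs absent from the LD table count as
    r² = 0 (a warning is logged once), and rows without chrom/pos are
    treated as within-window of everything, so LD alone decides.
    """
    if not (0.0 <= r2_max <= 1.0):
        raise ValueError("r2_max must lie in [0,1]")
    df = table.df.sort_values(["pval", "snp"], kind="mergesort")
    accepted: list[pd.Series] = []
    missing_pairs = 0
    for _, row in df.iterrows():
        ok = True
        for acc in accepted:
            same_chrom = (
                pd.isna(row["chrom"]) or pd.isna(acc["chrom"]) or row["chrom"] == acc["chrom"]
            )
            if not same_chrom:
                continue
            if not (pd.isna(row["pos"]) or pd.isna(acc["pos"])):
                if abs(float(row["pos"]) - float(acc["pos"])) > window_kb * 1000:
                    continue
            r2 = ld.r2(row["snp"], acc["snp"]) if ld is not None else None
            if r2 is None:
                missing_pairs += 1
                r2 = 0.0
            if r2 >= r2_max:
                ok = False
                break
        if ok:
            accepted.append(row)
    if missing_pairs:
        log.warning(
            "clump: %d SNP pairs absent from the LD table were treated as unlinked (r2=0)",
            missing_pairs,
        )
    kept = {r["snp"] for r in accepted}
    return table.subset(kept)


# ---------------------------------------------------------------------------
# Alleles, proxies, harmonization


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {C,G} (strand-ambiguous)."""
    ea, oa = effect_allele.upper(), other_allele.upper()
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        raise SumstatsValidationError(f"invalid allele pair {effect_allele}/{other_allele}")
    return _COMPLEMENT[ea] == oa


def find_proxy(
    snp: str,
    ld: LDTable | None,
    outcome: SummaryStatsTable,
    r2_min: float = 0.9,
) -> tuple[str, float] | None:
    """Best outcome-present LD proxy with r² strictly above ``r2_min``.

    Returns ``(proxy rsID, r²)``; ties in r² are broken by rsID order.
    """
    if ld is None:
        return None
    present = set(outcome.snps)
    candidates = [
        (b, r2) for b, r2 in ld.partners(snp) if b in present and b != snp and r2 > r2_min
    ]
    if not candidates:
        return None
    best = min(candidates, key=lambda t: (-t[1], t[0]))
    return best


def _orient(
    ea_x: str, oa_x: str, ea_y: str, oa_y: str
) -> str:
    """How outcome alleles relate to exposure alleles.

    Returns 'same', 'swap', or 'mismatch'.  Strand-flipped representations
    (complement on both alleles) of non-palindromic SNPs are recognized.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "swap"
    cy = (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y])
    if cy == (ea_x, oa_x):
        return "same"
    if cy == (oa_x, ea_x):
        return "swap"
    return "mismatch"


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDTable | None = None,
    policy: HarmonizationPolicy | None = None,
) -> HarmonizedDataset:
    """Pair every exposure instrument with an outcome effect on the same allele.

    For each instrument: match by rsID in the outcome table, else try an LD
    proxy above the policy threshold.  Outcome effects reported for swapped
    alleles are negated and their frequency replaced by its complement.
    Palindromic instruments follow the policy (default: excluded).  Every
    dropped instrument lands in the exclusion audit with its reason.
    """
    policy = policy or HarmonizationPolicy()
    out_by_snp = {r["snp"]: r for _, r in outcome.df.iterrows()}
    records: list[HarmonizedRecord] = []
    exclusions: list[tuple[str, str]] = []
    notes: list[str] = []

    for _, exp in exposure.df.iterrows():
        snp = exp["snp"]
        ea_x, oa_x = exp["effect_allele"], exp["other_allele"]
        eaf_x = None if pd.isna(exp["eaf"]) else float(exp["eaf"])

        palin = is_palindromic(ea_x, oa_x)
        if palin and policy.palindromic == "exclude":
            exclusions.append((snp, "palindromic"))
            continue

        used_snp, proxy_r2 = snp, None
        if snp in out_by_snp:
            out = out_by_snp[snp]
        else:
            proxy = find_proxy(snp, ld, outcome, policy.proxy_r2_min) if policy.use_proxies else None
            if proxy is None:
                exclusions.append((snp, "missing_in_outcome_no_proxy"))
                continue
            used_snp, proxy_r2 = proxy
            out = out_by_snp[used_snp]

        beta_y = float(out["beta"])
        se_y = float(out["se"])
        eaf_y = None if pd.isna(out["eaf"]) else float(out["eaf"])
        ea_y, oa_y = out["effect_allele"], out["other_allele"]

        if used_snp != snp:
            # Map the proxy's outcome effect onto the instrument's alleles:
            # use the LD table's allele correspondence when available, else
            # fall back to frequency similarity.
            amap = ld.allele_map(snp, used_snp) if ld is not None else None
            if amap is not None:
                a_inst, a_proxy_linked = amap
                if a_proxy_linked == ea_y:
                    pass  # proxy effect allele tags a_inst
                elif a_proxy_linked == oa_y:
                    beta_y, eaf_y = -beta_y, (None if eaf_y is None else 1 - eaf_y)
                    a_proxy_linked = ea_y
                else:
                    exclusions.append((snp, "allele_mismatch"))
                    continue
                # now the (possibly flipped) proxy effect allele tags a_inst
                if a_inst == oa_x:
                    beta_y, eaf_y = -beta_y, (None if eaf_y is None else 1 - eaf_y)
                elif a_inst != ea_x:
                    exclusions.append((snp, "allele_mismatch"))
                    continue
            else:
                if eaf_x is None or eaf_y is None:
                    exclusions.append((snp, "ambiguous_frequency"))
                    continue
                d_keep = abs(eaf_y - eaf_x)
                d_flip = abs((1 - eaf_y) - eaf_x)
                if d_keep < policy.proxy_eaf_tol and d_flip >= policy.proxy_eaf_tol:
                    pass
                elif d_flip < policy.proxy_eaf_tol and d_keep >= policy.proxy_eaf_tol:
                    beta_y, eaf_y = -beta_y, 1 - eaf_y
                else:
                    exclusions.append((snp, "ambiguous_frequency"))
                    continue
            records.append(
                HarmonizedRecord(
                    snp=snp,
                    used_snp=used_snp,
                    beta_exp=float(exp["beta"]),
                    se_exp=float(exp["se"]),
                    beta_out=beta_y,
                    se_out=se_y,
                    eaf_exp=eaf_x,
                    eaf_out=eaf_y,
                    proxy_r2=proxy_r2,
                )
            )
            continue

        # direct rsID match
        if palin:
            # policy == "infer": orient from allele frequency; for a
            # palindromic SNP 'same' and 'swap' are indistinguishable from
            # the letters, so the frequencies must agree in direction.
            lo, hi = policy.ambiguity_band
            if eaf_x is None or eaf_y is None or lo <= eaf_x <= hi or lo <= eaf_y <= hi:
                exclusions.append((snp, "ambiguous_frequency"))
                continue
            # outcome may report the pair as (ea, oa) or swapped; put the
            # outcome effect on the exposure letters first
            if (ea_y, oa_y) in ((oa_x, ea_x),):
                beta_y, eaf_y = -beta_y, 1 - eaf_y
            elif (ea_y, oa_y) != (ea_x, oa_x) and (
                _COMPLEMENT[ea_y],
                _COMPLEMENT[oa_y],
            ) != (ea_x, oa_x):
                exclusions.append((snp, "allele_mismatch"))
                continue
            if (eaf_x < 0.5) != (eaf_y < 0.5):
                beta_y, eaf_y = -beta_y, 1 - eaf_y
                notes.append(f"{snp}: palindromic orientation inferred by frequency flip")
        else:
            rel = _orient(ea_x, oa_x, ea_y, oa_y)
            if rel == "mismatch":
                exclusions.append((snp, "allele_mismatch"))
                continue
            if rel == "swap":
                beta_y, eaf_y = -beta_y, (None if eaf_y is None else 1 - eaf_y)

        records.append(
            HarmonizedRecord(
                snp=snp,
                used_snp=used_snp,
                beta_exp=float(exp["beta"]),
                se_exp=float(exp["se"]),
                beta_out=beta_y,
                se_out=se_y,
                eaf_exp=eaf_x,
                eaf_out=eaf_y,
                proxy_r2=proxy_r2,
            )
        )

    if not records:
        raise NoInstrumentsError(
            f"no instruments survive harmonization of {exposure.trait_id} vs {outcome.trait_id}"
        )
    return HarmonizedDataset(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        records=records,
        exclusions=exclusions,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Instrument strength


@dataclass
class InstrumentStats:
    """Per-instrument and aggregate variance explained and F statistics.

    R² per SNP is ``2·MAF·(1−MAF)·β²``; the aggregate F uses
    ``F = (N−K−1)/K · R²/(1−R²)`` with K the instrument count, and the
    per-SNP F uses the same formula with K = 1 and that SNP's R².
    F fields are None when the GWAS sample size is unknown.
    """

    per_snp_r2: list[tuple[str, float]]
    total_r2: float
    k: int
    n: float | None = None
    per_snp_f: list[tuple[str, float]] | None = None
    mean_f: float | None = None
    total_f: float | None = None

    def strong(self, threshold: float = 10.0) -> bool | None:
        """Conventional strong-instrument check (total F > threshold)."""
        return None if self.total_f is None else bool(self.total_f > threshold)


def instrument_strength(table: SummaryStatsTable, n: float | None = None) -> InstrumentStats:
    """Variance explained (R²) and F statistics for an instrument set.

    EAF must be present for every row (MAF = min(eaf, 1−eaf)); when the
    sample size ``n`` is unknown the F statistics are omitted with a logged
    warning.  The R² formula is applied to the betas exactly as reported
    (log-odds scale for binary traits).
    """
    df = table.df
    if df["eaf"].isna().any():
        missing = ", ".join(df.loc[df["eaf"].isna(), "snp"])
        raise SumstatsValidationError(f"EAF required for instrument strength; missing for {missing}")
    maf = np.minimum(df["eaf"].to_numpy(float), 1 - df["eaf"].to_numpy(float))
    r2 = 2 * maf * (1 - maf) * df["beta"].to_numpy(float) ** 2
    per_snp = list(zip(df["snp"], r2.astype(float)))
    total = float(r2.sum())
    k = len(df)
    if n is None:
        n = table.n_total
    if n is None:
        log.warning("instrument_strength: sample size unknown; F statistics omitted")
        return InstrumentStats(per_snp_r2=per_snp, total_r2=total, k=k)
    per_f = [(s, (n - 2) / 1 * r / (1 - r)) for s, r in per_snp]
    mean_f = float(np.mean([f for _, f in per_f]))
    total_f = float((n - k - 1) / k * total / (1 - total))
    return InstrumentStats(
        per_snp_r2=per_snp,
        total_r2=total,
        k=k,
        n=n,
        per_snp_f=per_f,
        mean_f=mean_f,
        total_f=total_f,
    )
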