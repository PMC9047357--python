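"""GWAS summary-statistics containers and delimited-text I/O.

The pipeline consumes per-variant association tables (rsID, alleles, beta,
SE, p, effect-allele frequency, optional chrom/pos/N) from heterogeneous
exports -- Pan-UKBB, FinnGen and IEU Open GWAS all use different headers --
so reading is driven by a user-supplied column map while the in-memory
canonical column names are fixed.  Only biallelic SNPs (single-letter
A/C/G/T alleles) are accepted; binary-trait effect sizes are log odds
ratios.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "SummaryStatsTable",
    "LDTable",
    "SumstatsFormatError",
    "SumstatsValidationError",
    "CANONICAL_COLUMNS",
    "read_sumstats",
    "write_sumstats",
    "read_ld_table",
    "write_ld_table",
    "varicose_instruments",
]

VALID_ALLELES = frozenset("ACGT")

#: Canonical on-disk / in-memory column order for summary statistics.
CANONICAL_COLUMNS = (
    "snp",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
    "eaf",
    "chrom",
    "pos",
    "n",
)

_MANDATORY = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")


class SumstatsFormatError(ValueError):
    """A file is structurally unusable (missing mandatory columns, etc.)."""


class SumstatsValidationError(ValueError):
    """Table content violates an invariant (duplicate rsIDs, bad values)."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association with one trait.

    ``beta`` is on the trait's analysis scale (log odds for binary traits),
    ``se`` its standard error, ``eaf`` the effect-allele frequency.
    """

    snp: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    chrom: str | None = None
    pos: int | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        problems = self.problems()
        if problems:
            raise SumstatsValidationError(f"{self.snp}: " + "; ".join(problems))

    def problems(self) -> list[str]:
        """Invariant violations as human-readable reasons (empty if valid)."""
        out: list[str] = []
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            out.append("allele not a single base A/C/G/T")
        elif self.effect_allele == self.other_allele:
            out.append("effect and other allele identical")
        if not np.isfinite(self.beta):
            out.append("beta not finite")
        if not (np.isfinite(self.se) and self.se > 0):
            out.append("se not positive")
        if not (0.0 <= self.pval <= 1.0):
            out.append("pval out of [0,1]")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            out.append("eaf out of range")
        return out


def _row_problems(row: pd.Series) -> list[str]:
    """Validate one canonical-column row without constructing an object."""
    out: list[str] = []
    ea, oa = row["effect_allele"], row["other_allele"]
    if not (isinstance(ea, str) and isinstance(oa, str)) or ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        out.append("allele not a single base A/C/G/T")
    elif ea == oa:
        out.append("effect and other allele identical")
    if not np.isfinite(row["beta"]):
        out.append("beta not finite")
    if not (np.isfinite(row["se"]) and row["se"] > 0):
        out.append("se not positive")
    if not (0.0 <= row["pval"] <= 1.0):
        out.append("pval out of [0,1]")
    eaf = row.get("eaf")
    if eaf is not None and not pd.isna(eaf) and not (0.0 < eaf < 1.0):
        out.append("eaf out of range")
    return out


@dataclass
class SummaryStatsTable:
    """A validated per-trait table of variant associations.

    ``df`` holds one row per rsID with the canonical columns
    (:data:`CANONICAL_COLUMNS`); rsIDs are unique.  ``trait_type`` is
    ``"binary"`` or ``"continuous"``.
    """

    trait_id: str
    df: pd.DataFrame
    trait_type: str = "binary"
    ancestry: str = "EUR"
    n_total: float | None = None

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[list(CANONICAL_COLUMNS)]
        df["snp"] = df["snp"].astype(str)
        if df["snp"].duplicated().any():
            dups = sorted(df.loc[df["snp"].duplicated(), "snp"].unique())
            raise SumstatsValidationError(f"duplicate rsIDs: {', '.join(dups)}")
        self.df = df.reset_index(drop=True)
        if self.trait_type not in ("binary", "continuous"):
            raise SumstatsValidationError(f"unknown trait_type {self.trait_type!r}")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, snp: str) -> bool:
        return snp in set(self.df["snp"])

    @property
    def snps(self) -> list[str]:
        return list(self.df["snp"])

    def record(self, snp: str) -> VariantAssociation:
        """The association for one rsID as a typed record."""
        sub = self.df[self.df["snp"] == snp]
        if sub.empty:
            raise KeyError(snp)
        r = sub.iloc[0]
        return VariantAssociation(
            snp=r["snp"],
            effect_allele=r["effect_allele"],
            other_allele=r["other_allele"],
            beta=float(r["beta"]),
            se=float(r["se"]),
            pval=float(r["pval"]),
            eaf=None if pd.isna(r["eaf"]) else float(r["eaf"]),
            chrom=None if pd.isna(r["chrom"]) else str(r["chrom"]),
            pos=None if pd.isna(r["pos"]) else int(r["pos"]),
            n=None if pd.isna(r["n"]) else float(r["n"]),
        )

    def records(self) -> list[VariantAssociation]:
        return [self.record(s) for s in self.snps]

    def subset(self, snps: Iterable[str]) -> "SummaryStatsTable":
        keep = set(snps)
        return replace(self, df=self.df[self.df["snp"].isin(keep)].reset_index(drop=True))

    @classmethod
    def from_records(
        cls,
        trait_id: str,
        records: Sequence[VariantAssociation],
        **meta,
    ) -> "SummaryStatsTable":
        df = pd.DataFrame(
            [
                {
                    "snp": r.snp,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "beta": r.beta,
                    "se": r.se,
                    "pval": r.pval,
                    "eaf": np.nan if r.eaf is None else r.eaf,
                    "chrom": r.chrom,
                    "pos": np.nan if r.pos is None else r.pos,
                    "n": np.nan if r.n is None else r.n,
                }
                for r in records
            ],
            columns=list(CANONICAL_COLUMNS),
        )
        return cls(trait_id=trait_id, df=df, **meta)


# ---------------------------------------------------------------------------
# Reading / writing


def read_sumstats(
    path: str | Path | io.TextIOBase,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "trait",
    trait_type: str = "binary",
    ancestry: str = "EUR",
    n_total: float | None = None,
    sep: str = "\t",
) -> tuple[SummaryStatsTable, list[tuple[str, str]]]:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical names to the file's header names, e.g.
    ``{"snp": "rsid", "beta": "beta_EUR"}``; canonical names absent from the
    map are looked up verbatim.  Rows violating per-variant invariants are
    dropped, and returned as ``(rsID_or_row_label, reason)`` pairs so the
    caller can audit them.  Alleles are upper-cased; indel / multi-allelic
    rows are rejected.

    Returns
    -------
    (table, rejected)
        The validated table and the list of per-row rejection reasons.

    Raises
    ------
    SumstatsFormatError
        If a mandatory column is missing.
    SumstatsValidationError
        If surviving rows contain duplicate rsIDs.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, sep=sep, dtype={"chrom": str}, float_precision="round_trip")
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
    missing = [c for c in _MANDATORY if c not in rename.values()]
    if missing:
        raise SumstatsFormatError(
            f"missing mandatory column(s): {', '.join(missing)} "
            f"(file columns: {', '.join(raw.columns)})"
        )
    df = raw.rename(columns=rename)
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]].copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    for col in ("beta", "se", "pval", "eaf", "pos", "n"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    rejected: list[tuple[str, str]] = []
    keep_idx = []
    for idx, row in df.iterrows():
        problems = _row_problems(row)
        if problems:
            rejected.append((str(row.get("snp", f"row{idx}")), "; ".join(problems)))
        else:
            keep_idx.append(idx)
    table = SummaryStatsTable(
        trait_id=trait_id,
        df=df.loc[keep_idx],
        trait_type=trait_type,
        ancestry=ancestry,
        n_total=n_total,
    )
    return table, rejected


def write_sumstats(table: SummaryStatsTable, path: str | Path | io.TextIOBase) -> None:
    """Write a table as tab-delimited text with the canonical fixed header.

    ``read_sumstats`` inverts this exactly: all numeric fields are written
    with ``repr`` round-trip precision.
    """
    df = table.df.copy()
    # pandas' default float formatting is the shortest exact representation,
    # so numeric fields survive the round trip bit-for-bit
    df.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# LD tables


@dataclass
class LDTable:
    """Pairwise LD (r-squared) lookups, symmetric in the two rsIDs.

    ``df`` columns: ``snp_a, snp_b, r2`` and optionally
    ``allele_a, allele_b_linked`` recording which allele of ``snp_b`` is
    co-inherited with which allele of ``snp_a`` (needed to orient proxies).
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["snp_a", "snp_b", "r2"]))

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ("allele_a", "allele_b_linked"):
            if col not in df.columns:
                df[col] = None
        bad = df[(df["r2"] < 0) | (df["r2"] > 1)] if len(df) else df.iloc[:0]
        if len(bad):
            raise SumstatsValidationError("r2 out of [0,1] in LD table")
        self.df = df.reset_index(drop=True)
        # symmetric index for O(1) lookup either way round
        self._index: dict[tuple[str, str], int] = {}
        for i, row in self.df.iterrows():
            self._index[(row["snp_a"], row["snp_b"])] = i
            self._index.setdefault((row["snp_b"], row["snp_a"]), i)

    def r2(self, a: str, b: str) -> float | None:
        """r² between two rsIDs, or None when the pair is absent."""
        if a == b:
            return 1.0
        i = self._index.get((a, b))
        return None if i is None else float(self.df.at[i, "r2"])

    def partners(self, snp: str) -> list[tuple[str, float]]:
        """All (other rsID, r²) pairs recorded for ``snp``."""
        out = []
        for (a, b), i in self._index.items():
            if a == snp:
                out.append((b, float(self.df.at[i, "r2"])))
        return out

    def allele_map(self, a: str, b: str) -> tuple[str, str] | None:
        """(allele of a, co-inherited allele of b) if recorded, else None."""
        i = self._index.get((a, b))
        if i is None:
            return None
        aa = self.df.at[i, "allele_a"]
        bb = self.df.at[i, "allele_b_linked"]
        if aa is None or bb is None or pd.isna(aa) or pd.isna(bb):
            return None
        if self.df.at[i, "snp_a"] != a:
            aa, bb = bb, aa
        return str(aa), str(bb)


def read_ld_table(path: str | Path | io.TextIOBase, sep: str = "\t") -> LDTable:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    need = {"snp_a", "snp_b", "r2"}
    if not need <= set(df.columns):
        raise SumstatsFormatError(f"LD table needs columns {sorted(need)}")
    return LDTable(df=df)


def write_ld_table(ld: LDTable, path: str | Path | io.TextIOBase) -> None:
    cols = ["snp_a", "snp_b", "r2", "allele_a", "allele_b_linked"]
    ld.df[cols].to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="")


# ---------------------------------------------------------------------------
# Varicose-veins instrument fixture

# The 23 independent genome-wide-significant varicose-veins instruments
# (Pan-ancestry UK Biobank, European subset), as published:
# rsID, effect allele, other allele, beta (log-OR), SE, p, EAF, nearest gene.
_VARICOSE_INSTRUMENTS = [
    ("rs11121615", "T", "C", -0.284, 0.015, 6.55e-81, 0.690, "CASZ1"),
    ("rs72787716", "T", "C", -0.098, 0.017, 4.72e-09, 0.209, "LBH"),
    ("rs6546368", "C", "T", 0.155, 0.014, 3.59e-27, 0.657, "AC017083.3"),
    ("rs2734045", "A", "G", 0.100, 0.014, 2.21e-13, 0.482, "LINC01565"),
    ("rs28558138", "C", "G", -0.131, 0.014, 2.52e-21, 0.420, "snoU13"),
    ("rs2250127", "A", "G", 0.144, 0.016, 5.74e-20, 0.247, "LINC01184"),
    ("rs11135046", "T", "G", -0.121, 0.014, 4.97e-19, 0.543, "EBF1"),
    ("rs1155207", "G", "A", -0.106, 0.014, 7.46e-15, 0.487, "HIST1H3PS1"),
    ("rs62401797", "G", "C", -0.146, 0.026, 1.09e-08, 0.079, "RP11-228O6.2"),
    ("rs2800709", "G", "T", -0.078, 0.014, 7.91e-09, 0.519, "RSPO3"),
    ("rs75731123", "G", "A", -0.108, 0.019, 1.28e-08, 0.149, "RP1L1"),
    ("rs10817784", "G", "A", 0.094, 0.016, 1.49e-09, 0.738, "DEC1"),
    ("rs2083714", "G", "A", 0.081, 0.014, 1.92e-09, 0.499, "SBF2"),
    ("rs55726902", "A", "G", 0.100, 0.016, 2.08e-10, 0.242, "HDAC7"),
    ("rs41286076", "T", "C", 0.092, 0.015, 3.03e-09, 0.256, "KLF5"),
    ("rs4772697", "G", "A", 0.083, 0.014, 3.59e-09, 0.361, "RP11-252M24.1"),
    ("rs437564", "T", "C", 0.085, 0.014, 2.60e-09, 0.377, "RP11-1348G14.4"),
    ("rs34457921", "G", "A", -0.088, 0.015, 4.88e-09, 0.298, "ZFPM1"),
    ("rs2911463", "A", "G", -0.190, 0.015, 1.07e-37, 0.687, "PIEZO1"),
    ("rs236548", "A", "G", -0.119, 0.016, 3.16e-14, 0.745, "CALM2P1"),
    ("rs2241173", "G", "A", -0.091, 0.014, 3.15e-11, 0.575, "LINC01152"),
    ("rs6021277", "T", "C", 0.102, 0.014, 8.16e-14, 0.460, "NFATC2"),
    ("rs6062619", "G", "A", -0.113, 0.016, 3.84e-13, 0.268, "SOX18"),
]

#: rsIDs whose secondary genome-wide associations (height) make them
#: candidate confounder instruments; used as the default exclusion list.
CONFOUNDER_ASSOCIATED_SNPS = ("rs41286076", "rs1155207")


def varicose_instruments() -> SummaryStatsTable:
    """The 23 published varicose-veins instruments as a summary table.

    Effect sizes are log odds ratios against varicose veins (binary);
    the exposure GWAS sample size is not published, so ``n_total`` is None.
    """
    records = [
        VariantAssociation(snp=s, effect_allele=ea, other_allele=oa, beta=b, se=se, pval=p, eaf=eaf)
        for s, ea, oa, b, se, p, eaf, _gene in _VARICOSE_INSTRUMENTS
    ]
    return SummaryStatsTable.from_records(
        "varicose_veins", records, trait_type="binary", ancestry="EUR", n_total=None
    )
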