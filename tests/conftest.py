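import numpy as np
import pytest

from mrkit.instruments import HarmonizedDataset, HarmonizedRecord
from mrkit.sumstats import SummaryStatsTable, VariantAssociation, varicose_instruments


def make_harmonized(beta_exp, beta_out, se_out, se_exp=None, exposure="exp", outcome="out"):
    """Build a HarmonizedDataset directly from effect arrays."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.broadcast_to(np.asarray(se_out, dtype=float), beta_exp.shape)
    se_exp = (
        np.full_like(beta_exp, 1e-6)
        if se_exp is None
        else np.broadcast_to(np.asarray(se_exp, dtype=float), beta_exp.shape)
    )
    records = [
        HarmonizedRecord(
            snp=f"rs{i:04d}",
            used_snp=f"rs{i:04d}",
            beta_exp=float(bx),
            se_exp=float(sx),
            beta_out=float(by),
            se_out=float(sy),
        )
        for i, (bx, sx, by, sy) in enumerate(zip(beta_exp, se_exp, beta_out, se_out))
    ]
    return HarmonizedDataset(exposure_id=exposure, outcome_id=outcome, records=records)


def plant_outlier(h: HarmonizedDataset, k: int, n_sigma: float = 10.0) -> HarmonizedDataset:
    """Shift one instrument's outcome effect by n_sigma standard errors."""
    recs = list(h.records)
    r = recs[k]
    recs[k] = HarmonizedRecord(
        snp=r.snp,
        used_snp=r.used_snp,
        beta_exp=r.beta_exp,
        se_exp=r.se_exp,
        beta_out=r.beta_out + n_sigma * r.se_out,
        se_out=r.se_out,
        eaf_exp=r.eaf_exp,
        eaf_out=r.eaf_out,
    )
    return HarmonizedDataset(h.exposure_id, h.outcome_id, recs)


def random_table(rng: np.random.Generator, n: int = 12, trait_id: str = "toy") -> SummaryStatsTable:
    """A small random but valid summary table (non-palindromic alleles)."""
    pairs = [("A", "G"), ("T", "C"), ("G", "A"), ("C", "T")]
    recs = []
    for i in range(n):
        ea, oa = pairs[rng.integers(0, len(pairs))]
        recs.append(
            VariantAssociation(
                snp=f"rs{1000 + i}",
                effect_allele=ea,
                other_allele=oa,
                beta=float(rng.normal(0, 0.15)),
                se=float(rng.uniform(0.01, 0.03)),
                pval=float(rng.uniform(0, 1) ** 4),
                eaf=float(rng.uniform(0.05, 0.95)),
                chrom=str(int(rng.integers(1, 5))),
                pos=int(rng.integers(1, 2_000_000)),
            )
        )
    return SummaryStatsTable.from_records(trait_id, recs)


@pytest.fixture(scope="session")
def instrument_table():
    """The 23 published varicose-veins instruments."""
    return varicose_instruments()
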