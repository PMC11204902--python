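import numpy as np
import pandas as pd
import pytest

from prscad.data_io import GenotypePanel, PhenotypeTable

ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]


def make_panel(dosage, missing=None, chrom="1", pos_start=10_000, pos_step=2_000,
               pairs=None, sample_prefix="S"):
    """Build a GenotypePanel from a dosage matrix with synthetic metadata."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if missing is None:
        missing = np.zeros((n, m), dtype=bool)
    if pairs is None:
        pairs = [ALLELE_PAIRS[j % len(ALLELE_PAIRS)] for j in range(m)]
    meta = pd.DataFrame({
        "id": [f"rs{j+1}" for j in range(m)],
        "chrom": chrom,
        "pos": [pos_start + pos_step * j for j in range(m)],
        "ref": [p[0] for p in pairs],
        "alt": [p[1] for p in pairs],
    })
    return GenotypePanel(
        sample_ids=[f"{sample_prefix}{i+1:04d}" for i in range(n)],
        variant_meta=meta, dosage=dosage,
        missing_mask=np.asarray(missing, dtype=bool),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel(rng):
    """30 samples x 50 variants, HWE binomial dosages, no missingness."""
    p = rng.uniform(0.1, 0.5, 50)
    return make_panel(rng.binomial(2, p, (30, 50)).astype(float))


@pytest.fixture
def small_phenotypes(rng):
    n = 30
    df = pd.DataFrame({
        "sample_id": [f"S{i+1:04d}" for i in range(n)],
        "case_status": rng.integers(0, 2, n),
        "sex": rng.integers(0, 2, n),
        "age": rng.normal(57.7, 12.4, n).clip(20),
        "weight": rng.normal(78, 14, n).clip(40),
        "t2dm": rng.integers(0, 2, n),
        "smoking": rng.integers(0, 2, n),
        "sbp": rng.normal(132.6, 19.7, n).clip(80),
        "total_chol": rng.normal(200.7, 44.6, n).clip(90),
    })
    return PhenotypeTable(df=df)
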