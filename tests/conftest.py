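import numpy as np
import pandas as pd
import pytest

from akit import genio


def make_snp_table(n, n_chrom=1, span=0.5):
    """Evenly spaced SNP metadata over ``n_chrom`` chromosomes."""
    per = -(-n // n_chrom)
    rows = []
    i = 0
    for c in range(n_chrom):
        for j in range(min(per, n - c * per)):
            rows.append((f"rs{i}", str(c + 1), j * span / per, (j + 1) * 1000, "A", "G"))
            i += 1
    return pd.DataFrame(rows, columns=genio.SNP_COLUMNS)


def make_freq_table(freqs: dict[str, np.ndarray], totals: int | dict = 10**9,
                    n_chrom: int = 1) -> genio.FreqTable:
    """FreqTable from exact per-population frequencies.

    The default huge total makes sampling corrections negligible, so
    statistics computed from it match per-SNP arithmetic on the
    frequencies themselves.
    """
    pops = list(freqs)
    P = np.stack([np.asarray(freqs[p], dtype=float) for p in pops])
    n = P.shape[1]
    if isinstance(totals, int):
        tot = np.full(P.shape, totals, dtype=np.int64)
    else:
        tot = np.stack([np.full(n, totals[p], dtype=np.int64) for p in pops])
    count1 = np.rint(P * tot).astype(np.int64)
    return genio.FreqTable(pops, make_snp_table(n, n_chrom), count1, tot)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_matrix():
    """2 samples x 3 SNPs with one missing call."""
    samples = pd.DataFrame({"sample_id": ["i1", "i2"], "population": ["P1", "P2"]})
    snps = make_snp_table(3)
    calls = np.array([[0, 1, 2], [2, genio.MISSING, 0]], dtype=np.int8)
    return genio.GenotypeMatrix(samples, snps, calls)


def random_matrix(rng, n_samples=5, n_snps=50, missing=0.1, n_pops=2, n_chrom=1):
    pops = [f"P{i % n_pops}" for i in range(n_samples)]
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n_samples)],
                            "population": pops})
    calls = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    calls[rng.random(calls.shape) < missing] = genio.MISSING
    return genio.GenotypeMatrix(samples, make_snp_table(n_snps, n_chrom), calls)
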