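import numpy as np
import pytest

from scdnax import Amplicon, ScdnaDataset, SimConfig, Variant, simulate_dataset


def make_dataset(af, dp, gq, ngt, read_counts=None, metadata=None) -> ScdnaDataset:
    """Build a small dataset by hand from call-layer matrices."""
    af = np.asarray(af, dtype=float)
    n, v = af.shape
    if read_counts is None:
        read_counts = np.full((n, 2), 10, dtype=np.int64)
    read_counts = np.asarray(read_counts, dtype=np.int64)
    a = read_counts.shape[1]
    return ScdnaDataset(
        cell_barcodes=[f"BC{i:03d}" for i in range(n)],
        amplicons=[
            Amplicon(f"AMP{j}", "chr1", 1000 * (j + 1), 1000 * (j + 1) + 200)
            for j in range(a)
        ],
        variants=[Variant("chr1", 500 + j, "A", "T") for j in range(v)],
        read_counts=read_counts,
        af=af,
        dp=np.asarray(dp, dtype=np.int64),
        gq=np.asarray(gq, dtype=np.int64),
        ngt=np.asarray(ngt, dtype=np.int64),
        run_metadata=metadata or {"sample_name": "test", "panel_name": "p",
                                  "genome_build": "GRCh38"},
    )


def random_dataset(rng: np.random.Generator, max_cells=20, max_variants=10):
    """A small random-but-valid dataset for oracle/round-trip checks."""
    n = int(rng.integers(2, max_cells + 1))
    v = int(rng.integers(1, max_variants + 1))
    a = int(rng.integers(1, 6))
    dp = rng.integers(0, 60, size=(n, v))
    alt = rng.binomial(dp, rng.uniform(0, 1, size=(n, v)))
    af = np.where(dp > 0, 100.0 * alt / np.maximum(dp, 1), 0.0)
    ngt = rng.integers(0, 4, size=(n, v))
    ngt[dp == 0] = 3
    gq = rng.integers(0, 100, size=(n, v))
    rc = rng.integers(0, 100, size=(n, a))
    return make_dataset(af, dp, gq, ngt, read_counts=rc)


@pytest.fixture
def four_clone_sim():
    """Default four-clone mixture with ground truth (seeded)."""
    return simulate_dataset(SimConfig(n_cells=600, seed=11))


@pytest.fixture
def tiny_dataset():
    """5 cells x 3 amplicons x 2 variants, fully valid."""
    rng = np.random.default_rng(3)
    dp = rng.integers(1, 50, size=(5, 2))
    af = np.round(rng.uniform(0, 100, size=(5, 2)), 3)
    gq = rng.integers(0, 100, size=(5, 2))
    ngt = rng.integers(0, 3, size=(5, 2))
    rc = rng.integers(0, 80, size=(5, 3))
    return make_dataset(af, dp, gq, ngt, read_counts=rc)
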