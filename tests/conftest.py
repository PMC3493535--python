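import numpy as np
import pandas as pd
import pytest

from drgepi import (
    SimConfig,
    build_feature_profiles,
    map_reads_to_genic,
    map_reads_to_promoters,
    promoter_windows,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def bundle_truth():
    """One default synthetic bundle shared across tests."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def bundle(bundle_truth):
    return bundle_truth[0]


@pytest.fixture(scope="session")
def truth(bundle_truth):
    return bundle_truth[1]


@pytest.fixture(scope="session")
def profiles(bundle):
    genes, reads = bundle["genes"], bundle["reads"]
    genic = map_reads_to_genic(genes, reads)
    prom = map_reads_to_promoters(promoter_windows(genes), reads)
    return build_feature_profiles(genes, genic, prom, bundle["mirna"], bundle["chromdb"], reads=reads)


def random_genes(rng, n, chrom_span=100_000, n_chroms=2) -> pd.DataFrame:
    """Random (possibly overlapping) gene models for oracle comparisons."""
    starts = rng.integers(1, chrom_span, n)
    lengths = rng.integers(1, 5000, n)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": [f"chr{c}" for c in rng.integers(1, n_chroms + 1, n)],
            "start": starts,
            "end": starts + lengths - 1,
            "strand": rng.choice(["+", "-"], n),
            "is_te": np.zeros(n, dtype=bool),
            "is_pseudogene": np.zeros(n, dtype=bool),
        }
    )


def random_reads(rng, n, chrom_span=100_000, n_chroms=2, max_len=300) -> pd.DataFrame:
    starts = rng.integers(1, chrom_span, n)
    lengths = rng.integers(1, max_len, n)
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(n)],
            "chrom": [f"chr{c}" for c in rng.integers(1, n_chroms + 1, n)],
            "start": starts,
            "end": starts + lengths - 1,
        }
    )


def brute_force_assign(regions: pd.DataFrame, reads: pd.DataFrame, min_overlap: int) -> set:
    """All-pairs interval-overlap oracle (1-based inclusive)."""
    out = set()
    for g in regions.itertuples(index=False):
        for r in reads.itertuples(index=False):
            if g.chrom != r.chrom:
                continue
            overlap = min(g.end, r.end) - max(g.start, r.start) + 1
            if overlap >= min_overlap:
                out.add((g.gene_id, r.read_id))
    return out
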