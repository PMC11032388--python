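import numpy as np
import pytest

from triomix.io_formats import GenomicInterval
from triomix.synthetic import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: 120 genes, 30 genes per regulatory class."""
    return SimConfig(n_genes=120, n_mirnas=30, n_islands=80, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    return generate_cohort(small_config, outdir)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=20_000, max_len=400, prefix="iv"):
    """Random half-open intervals for overlap-oracle tests."""
    out = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len + 1))
        chrom = chroms[int(rng.integers(len(chroms)))]
        out.append(GenomicInterval(chrom, start, start + length, ".", f"{prefix}_{i:04d}"))
    return out


def brute_force_overlaps(queries, subjects, min_overlap=1):
    """O(n^2) pairwise overlap oracle on half-open intervals."""
    pairs = []
    for q in queries:
        for s in subjects:
            if q.chrom != s.chrom:
                continue
            if min(q.end, s.end) - max(q.start, s.start) >= min_overlap:
                pairs.append((q.id, s.id))
    return sorted(pairs)
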