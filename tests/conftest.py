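import numpy as np
import pytest

import chromaprof as cp


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort used by generator and pipeline tests."""
    return cp.default_sim_config(101, n_genes=400, n_fragments=40_000)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return cp.sample_gene_cohort(small_config)


@pytest.fixture(scope="session")
def rpm_track_factory(small_cohort, small_config):
    """Simulate a library for the shared small cohort and reduce it to rpm."""

    def make(factor, condition, placement="default", size_class=None, mode="span"):
        lib = cp.simulate_library(
            factor, condition, small_cohort, config=small_config, placement=placement
        )
        if size_class is not None:
            lib = cp.select_size_class(lib, size_class)
        reduce = cp.span_coverage if mode == "span" else cp.midpoint_coverage
        return cp.normalize_rpm(
            reduce(lib, small_cohort.chrom_sizes), lib.library_size
        )

    return make


def random_fragments(rng, n, chroms=("chr1", "chr2"), span=5000, min_len=20, max_len=200):
    """Small random FragmentSet for oracle comparisons."""
    c = rng.choice(chroms, size=n)
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(min_len, max_len + 1, size=n)
    return cp.FragmentSet(np.array(c, dtype=object), starts, starts + lengths)
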