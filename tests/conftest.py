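import pytest

from conjoinscan.filters import FilterConfig, run_cascade
from conjoinscan.simulate import SimParams, generate_bundle


def small_params(seed: int = 11, **overrides) -> SimParams:
    """Desk-scale generator settings for fast unit tests."""
    defaults = dict(
        seed=seed,
        n_chromosomes=2,
        chrom_length=60_000,
        n_genes=30,
        n_cg_events=3,
        n_transloc=1,
        n_intra_distant=1,
        artifact_counts={
            "blacklisted": 1,
            "shared_breakpoint": 2,
            "genomic_match": 1,
            "low_coverage": 1,
            "low_incidence": 1,
            "no_junction_support": 1,
        },
        depth=20.0,
    )
    defaults.update(overrides)
    return SimParams(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(small_params())


@pytest.fixture(scope="session")
def full_bundle():
    """Default-scale bundle: 22 true events, 5 artifacts per class."""
    return generate_bundle(SimParams(seed=20205))


@pytest.fixture(scope="session")
def full_cascade(full_bundle):
    b = full_bundle
    config = FilterConfig(blacklist=b.blacklist)
    survivors, report = run_cascade(
        b.calls, b.genome, b.reads.alignments, config,
        reads=b.reads.sequences(), gene_model=b.gene_model,
    )
    return b, config, survivors, report
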