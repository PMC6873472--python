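import pytest

from ichneukit import simulate_genome, simulate_reads
from ichneukit.read_qc import FilterProfile


@pytest.fixture(scope="session")
def small_genome():
    """A 4 kb random genome: 50x coverage gives ~1,000 read pairs."""
    return simulate_genome(4000, 0.35, seed=101)


@pytest.fixture(scope="session", params=["cvestalis", "dcollaris"])
def profile(request):
    return FilterProfile.preset(request.param)


@pytest.fixture(scope="session")
def defect_library(small_genome):
    """~1,000 pairs, one planted defect class per read, verified against preset B.

    Preset B is the strictest profile; labels verified against it are also
    first-fail-consistent under preset A for every rule preset A applies.
    """
    return simulate_reads(
        small_genome, depth=50, seed=7,
        n_rate=0.02, lowq_frac=0.02, adapter_frac=0.02,
        overlap_frac=0.02, err_kmer_frac=0.02, dup_frac=0.02,
        verify_profile=FilterProfile.preset("dcollaris"),
    )
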