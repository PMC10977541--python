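import pytest

from rcnvseq.annotate import CytobandTable
from rcnvseq.genome import build_bin_grid, hg19, toy_genome


@pytest.fixture(scope="session")
def toy_grid():
    """Scaled 24-chromosome genome, ~3100 bins at 20 kb; fast unit-test substrate."""
    return build_bin_grid(toy_genome()).with_synthetic_gc(seed=0)


@pytest.fixture(scope="session")
def hg19_grid():
    """Full-size hg19 bin grid (154,794 bins at 20 kb)."""
    return build_bin_grid(hg19())


@pytest.fixture(scope="session")
def cytobands():
    return CytobandTable.load()


@pytest.fixture(scope="session")
def study():
    from rcnvseq.cohort import study_cohort

    return study_cohort()
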