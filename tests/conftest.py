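import pytest
from hypothesis import settings

from rbliquid.genome import ChromSpec, GenomeBins, make_bin_grid

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def tiny_grid() -> GenomeBins:
    """Two small chromosomes, 10 equal 1-kb bins each."""
    chroms = [ChromSpec("chr1", 10_000, 5_000), ChromSpec("chr2", 10_000, 4_000)]
    return make_bin_grid(chroms, 1_000, gc_seed=0)


@pytest.fixture
def single_chrom_grid():
    """One chromosome tiled by `n` 1-kb bins; returns a factory."""

    def build(n: int, centromere_fraction: float = 0.5) -> GenomeBins:
        length = n * 1_000
        cen = max(1, int(length * centromere_fraction))
        return make_bin_grid([ChromSpec("chr1", length, cen)], 1_000, gc_seed=0)

    return build
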