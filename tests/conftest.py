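import numpy as np
import pytest

from psorakit import BinnedTrack, GenomeConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_config():
    """200-kb circular genome at 1-kb bins; oriC and dif roughly opposed."""
    return GenomeConfig(
        genome_length_bp=200_000,
        bin_size_bp=1000,
        oric_bp=150_000,
        dif_bp=50_000,
    )


@pytest.fixture
def masked_config():
    """10-bin genome with one masked bin flanked by 3 bins each side."""
    return GenomeConfig(
        genome_length_bp=10_000,
        bin_size_bp=1000,
        masked_intervals=((4000, 5000, "rep"),),
    )


def make_track(config, values, kind="count", mask=None):
    return BinnedTrack(config=config, values=np.asarray(values, dtype=float),
                       kind=kind, mask=mask)
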