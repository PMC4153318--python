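import numpy as np
import pytest

from tcss import DischargeEvent, ExperimentConfig


def make_event(onset, offset, area="cortex", source="ephys", **kw):
    return DischargeEvent(onset_s=onset, offset_s=offset, source=source, area=area, **kw)


@pytest.fixture
def small_config():
    """A small, quiet experiment for fast rendering tests."""
    return ExperimentConfig(
        duration_s=60.0,
        n_cells_cortex=40,
        n_cells_thalamus=30,
        noise_sd=0.0,
        bleach_fraction=0.0,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
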