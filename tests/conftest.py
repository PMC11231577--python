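import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240708)


@pytest.fixture
def small_synth_cfg():
    """A reduced generator configuration for fast unit tests."""
    from zinchrom.synth import FretSimParams, QpcrSimParams, SynthConfig
    from dataclasses import replace

    return SynthConfig(
        seed=11,
        genome_length=400_000,
        n_regions=60,
        region_length=200,
        n_motifs=3,
        fret=FretSimParams(n_cells=5, frames_per_phase=12),
        qpcr=replace(QpcrSimParams(), n_bio_replicates=2),
    )
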