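import numpy as np
import pytest

from pndeeg.eegsignal import EEGRecording
from pndeeg.synth import SyntheticConfig, gen_cohort


def sinusoid(freq: float, duration: float, amplitude: float = 1.0,
             fs: float = 1000.0, phase: float = 0.0) -> EEGRecording:
    t = np.arange(int(round(duration * fs))) / fs
    return EEGRecording(samples=amplitude * np.sin(2 * np.pi * freq * t + phase),
                        sample_rate=fs)


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """Small, fast cohort: 11 surgical animals, short recordings."""
    return SyntheticConfig(
        n_per_group={"young-sham": 2, "aged-sham": 2, "young-surgery": 3,
                     "aged-surgery": 8},
        vulnerable_fraction=0.5,
        baseline_duration_s=10.0,
        maintenance_duration_s=60.0,
        emergence_duration_s={"preserved": 150.0, "vulnerable": 160.0},
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return gen_cohort(tiny_config)
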