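import numpy as np
import pytest

from eegdep.montage import CHANNELS_19
from eegdep.recording import Recording
from eegdep.synth import GeneratorConfig, SubjectRecord, generate_recording


def clean_config(**kw) -> GeneratorConfig:
    """Generator config with every nuisance component switched off."""
    base = dict(
        n_healthy=1, n_nonmajor=0, n_major=1,
        duration_s=60.0, blink_rate=0.0, line_noise_amp=0.0,
        artifact_epoch_frac=0.0, bad_channel_prob=0.0, seed=7,
    )
    base.update(kw)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def clean_recording() -> Recording:
    """80 s artifact-free synthetic recording of a healthy subject."""
    cfg = clean_config(duration_s=80.0)
    profile = SubjectRecord(
        subject_id="h001", group="healthy", latent_severity=0.1,
        sds=40.0, sas=45.0,
    )
    return generate_recording(profile, cfg)


@pytest.fixture()
def zeros_recording() -> Recording:
    return Recording(
        subject_id="z", fs=500.0, channels=CHANNELS_19,
        data=np.zeros((19, 300_000)),
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
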