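import numpy as np
import pytest

from p300bci import (
    EpochSet,
    ErpTemplate,
    NoiseModel,
    ParadigmConfig,
    Recording,
    StimulusSchedule,
    generate_flash_schedule,
    synthesize_recording,
)


@pytest.fixture(scope="session")
def paradigm() -> ParadigmConfig:
    return ParadigmConfig()


@pytest.fixture(scope="session")
def template() -> ErpTemplate:
    return ErpTemplate(peak_amplitude_uv=10.0, peak_latency_ms=400.0)


@pytest.fixture(scope="session")
def silent_noise() -> NoiseModel:
    return NoiseModel.silent(seed=0)


@pytest.fixture
def online_schedule(paradigm) -> StimulusSchedule:
    return generate_flash_schedule(paradigm, n_blinks=20, target_button=3, seed=11)


@pytest.fixture
def clean_recording(paradigm, template, silent_noise, online_schedule) -> Recording:
    """Noise-free online selection with a 10 uV P300 at 400 ms."""
    return synthesize_recording(online_schedule, template, silent_noise, paradigm)


def build_epochset(
    data: np.ndarray,
    *,
    buttons=None,
    targets=None,
    selection_ids=None,
    environments=None,
    fs: float = 300.0,
    channels=None,
) -> EpochSet:
    """EpochSet straight from an (n, ch, samples) array with default labels."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(data.shape[1]))
    return EpochSet(
        epochs=data,
        button=np.zeros(n, dtype=int) if buttons is None else np.asarray(buttons),
        is_target=(
            np.zeros(n, dtype=bool) if targets is None else np.asarray(targets, dtype=bool)
        ),
        selection_id=(
            np.zeros(n, dtype=int) if selection_ids is None else np.asarray(selection_ids)
        ),
        environment=(
            np.full(n, "NA", dtype=object)
            if environments is None
            else np.asarray(environments, dtype=object)
        ),
        onset_s=np.arange(n, dtype=float),
        sampling_rate_hz=fs,
        channel_labels=channels,
    )
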