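"""Oddball flash paradigm: stimulus schedules and synthetic EEG recordings.

This module emulates a seven-button P300 selection paradigm recorded from a
seven-channel dry-electrode montage (Fz, Pz, Oz, P3, P4, PO7, PO8) at 300 Hz
with a left-ear reference. Buttons highlight one at a time (100 ms on /
100 ms off, i.e. a 200 ms stimulus-onset asynchrony); attending the target
button elicits a P300-like positive deflection a few hundred milliseconds
after each target flash. The simulator adds the deflection as a Gaussian bump
on top of a configurable background (1/f "pink" noise, white noise, a 10 Hz
alpha rhythm, slow random-walk drift) plus optional high-amplitude artifact
transients, so that every downstream stage — filtering, epoching, averaging,
classification, artifact rejection — can be exercised without hardware.

All randomness flows from explicit integer seeds; there is no global random
state, and identical seeds yield bit-identical schedules and recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DEFAULT_CHANNELS",
    "ParadigmConfig",
    "StimulusSchedule",
    "ErpTemplate",
    "NoiseModel",
    "Recording",
    "generate_flash_schedule",
    "synthesize_recording",
    "inject_artifacts",
    "add_transient",
]

DEFAULT_CHANNELS = ("Fz", "Pz", "Oz", "P3", "P4", "PO7", "PO8")

#: Posterior-dominant scalp projection of the P300 source, largest at Pz.
DEFAULT_CHANNEL_WEIGHTS = {
    "Fz": 0.5,
    "Pz": 1.0,
    "Oz": 0.6,
    "P3": 0.8,
    "P4": 0.8,
    "PO7": 0.7,
    "PO8": 0.7,
}


@dataclass(frozen=True)
class ParadigmConfig:
    """Constants of the selection paradigm and the acquisition montage."""

    n_buttons: int = 7
    flash_on_ms: float = 100.0
    flash_off_ms: float = 100.0
    blinks_training: int = 30
    blinks_online: int = 20
    selections_per_env: int = 15
    sampling_rate_hz: float = 300.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    reference_label: str = "A1"  # left-ear reference electrode

    def __post_init__(self) -> None:
        if self.n_buttons < 2:
            raise ValueError("n_buttons must be at least 2")
        if self.flash_on_ms + self.flash_off_ms <= 0:
            raise ValueError("flash on+off duration must be positive")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def soa_s(self) -> float:
        """Stimulus-onset asynchrony in seconds (flash on + off)."""
        return (self.flash_on_ms + self.flash_off_ms) / 1000.0


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered flash events for one selection.

    ``onsets_s`` are the instants each button toggles to its highlight
    colour; consecutive onsets are separated by exactly one SOA.
    """

    onsets_s: np.ndarray
    buttons: np.ndarray
    target_button: int
    selection_id: int = 0
    environment: str = "NA"

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_s, dtype=float)
        buttons = np.asarray(self.buttons, dtype=int)
        object.__setattr__(self, "onsets_s", onsets)
        object.__setattr__(self, "buttons", buttons)
        if onsets.shape != buttons.shape or onsets.ndim != 1:
            raise ValueError("onsets and buttons must be 1-D and equal length")
        if len(onsets) and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if len(buttons):
            counts = np.bincount(buttons)
            if counts[counts > 0].min() != counts.max():
                raise ValueError("every button must occur equally often")
        if self.environment not in ("VR", "AR", "NA"):
            raise ValueError(f"unknown environment {self.environment!r}")

    @property
    def is_target(self) -> np.ndarray:
        return self.buttons == self.target_button

    @property
    def n_events(self) -> int:
        return len(self.onsets_s)

    def events(self):
        """Iterate (onset_s, button, is_target) tuples."""
        for onset, button in zip(self.onsets_s, self.buttons):
            yield float(onset), int(button), bool(button == self.target_button)


@dataclass(frozen=True)
class ErpTemplate:
    """Gaussian P300-like deflection added to every target flash.

    ``width_ms`` is the full width at half maximum of the bump. Default
    amplitude and latency follow the grand-average values of the study
    population the simulator emulates (5.09 uV at 415.88 ms).
    """

    peak_amplitude_uv: float = 5.09
    peak_latency_ms: float = 415.88
    width_ms: float = 100.0
    channel_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_WEIGHTS)
    )

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        if not (0 < self.peak_latency_ms < 1000):
            raise ValueError("peak latency must lie inside the 1 s epoch")
        if self.channel_weights and max(self.channel_weights.values()) <= 0:
            raise ValueError("at least one channel weight must be positive")

    @property
    def sigma_s(self) -> float:
        # FWHM -> Gaussian sigma
        return self.width_ms / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def waveform(self, t_s: np.ndarray) -> np.ndarray:
        """Evaluate the bump at times ``t_s`` (seconds post-stimulus)."""
        mu = self.peak_latency_ms / 1000.0
        return self.peak_amplitude_uv * np.exp(-0.5 * ((t_s - mu) / self.sigma_s) ** 2)


@dataclass(frozen=True)
class NoiseModel:
    """Additive background activity and artifact process.

    Defaults are the moderate-noise condition used throughout this package's
    simulations: enough background power that single-trial epochs are
    dominated by noise, while 20-blink averaging restores reliable decoding.
    ``drift_sd_uv`` scales a random walk so the drift standard deviation
    grows as drift_sd_uv * sqrt(t seconds).
    """

    pink_sd_uv: float = 6.0
    white_sd_uv: float = 3.0
    alpha_amplitude_uv: float = 3.0
    drift_sd_uv: float = 2.0
    artifact_rate_per_min: float = 0.0
    artifact_amplitude_uv: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pink_sd_uv", "white_sd_uv", "alpha_amplitude_uv",
                     "drift_sd_uv", "artifact_rate_per_min",
                     "artifact_amplitude_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def silent(cls, seed: int = 0) -> "NoiseModel":
        """A noise-free model (all amplitudes zero)."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, seed)


@dataclass
class Recording:
    """Multi-channel continuous EEG with its stimulus schedule.

    ``data`` is channels x samples in microvolts; ``reference_data`` holds
    the (noise-only) reference electrode series until re-referencing removes
    it.
    """

    data: np.ndarray
    sampling_rate_hz: float
    channel_labels: tuple[str, ...]
    schedule: StimulusSchedule
    reference_data: np.ndarray | None = None
    reference_label: str = "A1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be (n_channels, n_samples) matching labels")
        if self.reference_data is not None:
            self.reference_data = np.asarray(self.reference_data, dtype=float)
            if self.reference_data.shape != (self.data.shape[1],):
                raise ValueError("reference series must match data length")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            sampling_rate_hz=self.sampling_rate_hz,
            channel_labels=tuple(self.channel_labels),
            schedule=self.schedule,
            reference_data=None if self.reference_data is None else self.reference_data.copy(),
            reference_label=self.reference_label,
        )


def generate_flash_schedule(
    config: ParadigmConfig,
    n_blinks: int,
    target_button: int,
    seed: int,
    *,
    selection_id: int = 0,
    environment: str = "NA",
    start_offset_s: float = 1.0,
) -> StimulusSchedule:
    """Blockwise-random flash order: each round of ``n_buttons`` flashes is a
    fresh permutation of all buttons, so every button occurs exactly
    ``n_blinks`` times and targets cannot bunch arbitrarily.

    Onsets start at ``start_offset_s`` and advance by one SOA per flash.
    """
    if not 0 <= target_button < config.n_buttons:
        raise ValueError(
            f"target_button {target_button} outside 0..{config.n_buttons - 1}"
        )
    if n_blinks < 1:
        raise ValueError("n_blinks must be at least 1")
    rng = np.random.default_rng(seed)
    blocks = [rng.permutation(config.n_buttons) for _ in range(n_blinks)]
    buttons = np.concatenate(blocks)
    onsets = start_offset_s + np.arange(len(buttons)) * config.soa_s
    return StimulusSchedule(
        onsets_s=onsets,
        buttons=buttons,
        target_button=target_button,
        selection_id=selection_id,
        environment=environment,
    )


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec /= np.sqrt(freqs)
    pink = np.fft.irfft(spec, n=n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def _alpha_band_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance narrowband (8-12 Hz) noise: an alpha-like rhythm whose
    phase wanders, so it is not locked to the flash train and averages out
    across epochs (a strictly periodic 10 Hz tone would be phase-locked to
    the 200 ms SOA and survive averaging)."""
    from scipy import signal as sps

    white = rng.standard_normal(n)
    sos = sps.butter(2, [8.0, 12.0], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfilt(sos, white)
    sd = band.std()
    return band / sd if sd > 0 else band


def _background(noise: NoiseModel, rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """One channel of background activity (no ERP, no artifacts)."""
    out = np.zeros(n)
    # rng streams are always consumed so that setting one amplitude to zero
    # does not change the realization of the other components
    pink = _pink_noise(rng, n)
    if noise.pink_sd_uv > 0:
        out += noise.pink_sd_uv * pink
    white = rng.standard_normal(n)
    if noise.white_sd_uv > 0:
        out += noise.white_sd_uv * white
    alpha = _alpha_band_noise(rng, n, fs)
    if noise.alpha_amplitude_uv > 0:
        out += noise.alpha_amplitude_uv * alpha
    steps = rng.standard_normal(n)
    if noise.drift_sd_uv > 0:
        out += noise.drift_sd_uv / np.sqrt(fs) * np.cumsum(steps)
    return out


def synthesize_recording(
    schedule: StimulusSchedule,
    template: ErpTemplate,
    noise: NoiseModel,
    config: ParadigmConfig,
    *,
    tail_s: float = 1.5,
    max_duration_s: float = 900.0,
) -> Recording:
    """Render a continuous recording for one selection.

    The ERP template is added at every *target* flash onset, scaled per
    channel by ``template.channel_weights``; non-target flashes add nothing.
    Background noise is generated independently per channel (and for the
    reference electrode) from ``noise.seed``, so the noise component does not
    depend on the template: a noisy recording equals the noise-free recording
    plus the zero-amplitude-template recording under the same seed.
    """
    if template.peak_latency_ms / 1000.0 + template.sigma_s * 3 > 1.0 + 1e-9:
        raise ValueError("template latency + width must fit inside the 1 s epoch")
    fs = config.sampling_rate_hz
    if schedule.n_events:
        duration = float(schedule.onsets_s[-1]) + tail_s
    else:
        duration = tail_s
    if duration > max_duration_s:
        raise ValueError(
            f"schedule spans {duration:.1f} s, above the {max_duration_s:.1f} s limit"
        )
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # Deterministic signal part: template at each target onset.
    signal = np.zeros((len(config.channels), n))
    if template.peak_amplitude_uv != 0.0:
        bump_len = int(round(1.0 * fs))  # support limited to the 1 s epoch
        bump = template.waveform(np.arange(bump_len) / fs)
        weights = np.array(
            [template.channel_weights.get(ch, 0.0) for ch in config.channels]
        )
        for onset in schedule.onsets_s[schedule.is_target]:
            i0 = int(round(onset * fs))
            i1 = min(i0 + bump_len, n)
            signal[:, i0:i1] += weights[:, None] * bump[: i1 - i0]

    # Stochastic part: independent background per channel + reference.
    rng = np.random.default_rng(noise.seed)
    channel_rngs = rng.spawn(len(config.channels) + 1)
    data = signal.copy()
    for row, crng in zip(data, channel_rngs[:-1]):
        row += _background(noise, crng, n, fs)
    reference = _background(noise, channel_rngs[-1], n, fs)

    return Recording(
        data=data,
        sampling_rate_hz=fs,
        channel_labels=tuple(config.channels),
        schedule=schedule,
        reference_data=reference,
        reference_label=config.reference_label,
    )


def add_transient(
    recording: Recording,
    time_s: float,
    amplitude_uv: float,
    *,
    channel: int = 0,
    width_s: float = 0.1,
) -> Recording:
    """Add one single-cycle sine artifact pulse at ``time_s`` on one channel.

    The pulse is bipolar with zero mean, peaking at +/- ``amplitude_uv``, so
    its peak amplitude survives baseline correction, and its fundamental
    (1/width_s, 10 Hz at the default width) lies inside the analysis band.
    """
    out = recording.copy()
    fs = out.sampling_rate_hz
    i0 = int(round(time_s * fs))
    n_pulse = max(int(round(width_s * fs)), 2)
    i1 = min(i0 + n_pulse, out.n_samples)
    if i0 >= out.n_samples or i0 < 0:
        raise ValueError("transient time outside the recording")
    pulse = amplitude_uv * np.sin(2 * np.pi * (np.arange(n_pulse) + 0.5) / n_pulse)
    out.data[channel, i0:i1] += pulse[: i1 - i0]
    return out


def inject_artifacts(recording: Recording, noise: NoiseModel) -> Recording:
    """Add seeded high-amplitude transients at ~``artifact_rate_per_min``.

    Each artifact is a 100 ms single-cycle sine pulse peaking at
    ``artifact_amplitude_uv`` on one randomly chosen channel. A zero rate
    returns an unchanged copy of the recording.
    """
    if noise.artifact_rate_per_min == 0:
        return recording.copy()
    rng = np.random.default_rng((noise.seed, 0xA57))
    duration_min = recording.duration_s / 60.0
    n_artifacts = rng.poisson(noise.artifact_rate_per_min * duration_min)
    out = recording.copy()
    for _ in range(n_artifacts):
        time_s = rng.uniform(0, recording.duration_s - 0.1)
        channel = int(rng.integers(len(recording.channel_labels)))
        out = add_transient(
            out, time_s, noise.artifact_amplitude_uv, channel=channel
        )
    return out
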