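"""Six-stage ERP preprocessing pipeline.

Raw recording -> re-reference (left ear) -> 0.1-30 Hz Butterworth bandpass
-> 0-1000 ms epochs at each flash onset -> per-epoch mean subtraction
(baseline correction) -> consecutive trial averaging (sliding or block)
-> decimation to 100 Hz. Every stage is linear, so the pipeline commutes
with scaling and addition of recordings sharing a schedule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .paradigm import Recording

__all__ = [
    "PipelineConfig",
    "EpochSet",
    "rereference",
    "bandpass",
    "extract_epochs",
    "baseline_correct",
    "consecutive_average",
    "resample_epochs",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the signal-processing chain.

    ``causal_filtering`` selects forward-only filtering (what an online
    decoder could compute) over zero-phase forward-backward filtering.
    ``avg_mode`` controls consecutive trial averaging: "sliding" emits one
    average per window step of 1 (m epochs -> m - window + 1 outputs),
    "block" emits one average per disjoint window.
    """

    band_low_hz: float = 0.1
    band_high_hz: float = 30.0
    filter_order: int = 5
    epoch_start_ms: float = 0.0
    epoch_end_ms: float = 1000.0
    avg_window: int = 20
    avg_mode: str = "sliding"
    resample_to_hz: float = 100.0
    causal_filtering: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("require 0 < band_low_hz < band_high_hz")
        if self.epoch_end_ms <= self.epoch_start_ms:
            raise ValueError("epoch_end_ms must exceed epoch_start_ms")
        if self.avg_window < 1:
            raise ValueError("avg_window must be >= 1")
        if self.avg_mode not in ("sliding", "block"):
            raise ValueError("avg_mode must be 'sliding' or 'block'")


@dataclass
class EpochSet:
    """Stimulus-locked EEG segments with per-epoch labels.

    ``epochs`` is (n_epochs, n_channels, n_samples) in microvolts. The label
    arrays (button, is_target, selection_id, environment, onset_s) all have
    length n_epochs and travel with the data through every stage.
    """

    epochs: np.ndarray
    button: np.ndarray
    is_target: np.ndarray
    selection_id: np.ndarray
    environment: np.ndarray
    onset_s: np.ndarray
    sampling_rate_hz: float
    channel_labels: tuple[str, ...]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        n = self.epochs.shape[0]
        self.button = np.asarray(self.button, dtype=int)
        self.is_target = np.asarray(self.is_target, dtype=bool)
        self.selection_id = np.asarray(self.selection_id, dtype=int)
        self.environment = np.asarray(self.environment, dtype=object)
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        for name in ("button", "is_target", "selection_id", "environment", "onset_s"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"label array {name!r} length mismatch")
        if self.epochs.ndim != 3 or self.epochs.shape[1] != len(self.channel_labels):
            raise ValueError("epochs must be (n, n_channels, n_samples)")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            epochs=self.epochs[mask],
            button=self.button[mask],
            is_target=self.is_target[mask],
            selection_id=self.selection_id[mask],
            environment=self.environment[mask],
            onset_s=self.onset_s[mask],
            sampling_rate_hz=self.sampling_rate_hz,
            channel_labels=self.channel_labels,
            n_skipped=self.n_skipped,
        )

    @staticmethod
    def concatenate(sets: list["EpochSet"]) -> "EpochSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        first = sets[0]
        for s in sets[1:]:
            if s.channel_labels != first.channel_labels:
                raise ValueError("channel labels differ")
            if s.sampling_rate_hz != first.sampling_rate_hz:
                raise ValueError("sampling rates differ")
        return EpochSet(
            epochs=np.concatenate([s.epochs for s in sets]),
            button=np.concatenate([s.button for s in sets]),
            is_target=np.concatenate([s.is_target for s in sets]),
            selection_id=np.concatenate([s.selection_id for s in sets]),
            environment=np.concatenate([s.environment for s in sets]),
            onset_s=np.concatenate([s.onset_s for s in sets]),
            sampling_rate_hz=first.sampling_rate_hz,
            channel_labels=first.channel_labels,
            n_skipped=sum(s.n_skipped for s in sets),
        )


def rereference(recording: Recording) -> Recording:
    """Subtract the reference electrode series from every channel."""
    if recording.reference_data is None:
        raise ValueError("recording carries no reference series")
    return Recording(
        data=recording.data - recording.reference_data[None, :],
        sampling_rate_hz=recording.sampling_rate_hz,
        channel_labels=tuple(recording.channel_labels),
        schedule=recording.schedule,
        reference_data=None,
        reference_label=recording.reference_label,
    )


def design_bandpass(config: PipelineConfig, fs: float) -> np.ndarray:
    """Second-order sections of the Butterworth bandpass (shared with tests)."""
    if config.band_high_hz >= fs / 2:
        raise ValueError(
            f"band edge {config.band_high_hz} Hz not below Nyquist {fs / 2} Hz"
        )
    return sps.butter(
        config.filter_order,
        [config.band_low_hz, config.band_high_hz],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def bandpass(recording: Recording, config: PipelineConfig) -> Recording:
    """Butterworth bandpass along time; causal by default, zero-phase on
    request. Applied to the reference series too, if still present."""
    fs = recording.sampling_rate_hz
    if fs <= 60:
        raise ValueError("recording must be sampled above 60 Hz")
    sos = design_bandpass(config, fs)
    filt = sps.sosfilt if config.causal_filtering else sps.sosfiltfilt
    data = np.asarray(filt(sos, recording.data, axis=1))
    ref = recording.reference_data
    if ref is not None:
        ref = np.asarray(filt(sos, ref))
    return Recording(
        data=data,
        sampling_rate_hz=fs,
        channel_labels=tuple(recording.channel_labels),
        schedule=recording.schedule,
        reference_data=ref,
        reference_label=recording.reference_label,
    )


def extract_epochs(recording: Recording, config: PipelineConfig) -> EpochSet:
    """Cut one fixed-length epoch per flash onset.

    The first sample of each epoch is the sample at the onset (plus
    ``epoch_start_ms`` if nonzero). Events whose epoch would run past the end
    of the recording are skipped with a warning and counted in
    ``n_skipped``.
    """
    fs = recording.sampling_rate_hz
    sched = recording.schedule
    n_samp = int(round((config.epoch_end_ms - config.epoch_start_ms) / 1000.0 * fs))
    start_off = int(round(config.epoch_start_ms / 1000.0 * fs))

    slabs, buttons, targets, onsets = [], [], [], []
    skipped = 0
    for onset, button, is_tgt in sched.events():
        i0 = int(round(onset * fs)) + start_off
        i1 = i0 + n_samp
        if i0 < 0 or i1 > recording.n_samples:
            skipped += 1
            continue
        slabs.append(recording.data[:, i0:i1])
        buttons.append(button)
        targets.append(is_tgt)
        onsets.append(onset)
    if skipped:
        logger.warning("extract_epochs: skipped %d truncated event(s)", skipped)

    n = len(slabs)
    epochs = (
        np.stack(slabs)
        if n
        else np.empty((0, len(recording.channel_labels), n_samp))
    )
    return EpochSet(
        epochs=epochs,
        button=np.array(buttons, dtype=int),
        is_target=np.array(targets, dtype=bool),
        selection_id=np.full(n, sched.selection_id, dtype=int),
        environment=np.full(n, sched.environment, dtype=object),
        onset_s=np.array(onsets, dtype=float),
        sampling_rate_hz=fs,
        channel_labels=tuple(recording.channel_labels),
        n_skipped=skipped,
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each epoch's per-channel temporal mean (whole-window
    baseline: the epoch starts at the stimulus, so no pre-stimulus interval
    exists). Idempotent."""
    corrected = epochs.epochs - epochs.epochs.mean(axis=2, keepdims=True)
    return replace_epochs(epochs, corrected)


def replace_epochs(epochs: EpochSet, data: np.ndarray, **kw) -> EpochSet:
    """New EpochSet with the same labels but different epoch data."""
    return EpochSet(
        epochs=data,
        button=epochs.button,
        is_target=epochs.is_target,
        selection_id=epochs.selection_id,
        environment=epochs.environment,
        onset_s=epochs.onset_s,
        sampling_rate_hz=kw.get("sampling_rate_hz", epochs.sampling_rate_hz),
        channel_labels=epochs.channel_labels,
        n_skipped=epochs.n_skipped,
    )


def consecutive_average(epochs: EpochSet, config: PipelineConfig) -> EpochSet:
    """Average runs of consecutive same-button epochs to raise SNR.

    Epochs are grouped by (selection_id, button) and ordered by onset within
    each group; windows never cross selection boundaries. Sliding mode emits
    m - window + 1 overlapping averages per group of m epochs, block mode
    emits floor(m / window) disjoint ones. Groups smaller than the window
    produce no output (logged).
    """
    w = config.avg_window
    out_sets = []
    keys = sorted(
        {(int(s), int(b)) for s, b in zip(epochs.selection_id, epochs.button)}
    )
    for sel, btn in keys:
        mask = (epochs.selection_id == sel) & (epochs.button == btn)
        group = epochs.subset(mask)
        order = np.argsort(group.onset_s, kind="stable")
        group = group.subset(order)
        m = len(group)
        if m < w:
            logger.warning(
                "consecutive_average: group (selection=%d, button=%d) has %d < %d epochs",
                sel, btn, m, w,
            )
            continue
        if config.avg_mode == "sliding":
            starts = range(m - w + 1)
        else:
            starts = range(0, m - w + 1, w)
        idx = [range(s, s + w) for s in starts]
        averaged = np.stack([group.epochs[list(i)].mean(axis=0) for i in idx])
        first = [i[0] for i in idx]
        out_sets.append(replace_epochs(group.subset(np.array(first)), averaged))
    if not out_sets:
        empty = epochs.subset(np.zeros(len(epochs), dtype=bool))
        return empty
    return EpochSet.concatenate(out_sets)


def resample_epochs(epochs: EpochSet, config: PipelineConfig) -> EpochSet:
    """Decimate to ``resample_to_hz`` by keeping every k-th sample from index
    0. No extra anti-alias filter is applied: the 30 Hz lowpass earlier in
    the chain already bounds content well below the new Nyquist."""
    factor = epochs.sampling_rate_hz / config.resample_to_hz
    k = int(round(factor))
    if abs(factor - k) > 1e-9 or k < 1:
        raise ValueError(
            f"sampling rate {epochs.sampling_rate_hz} Hz is not an integer "
            f"multiple of {config.resample_to_hz} Hz"
        )
    return replace_epochs(
        epochs, epochs.epochs[:, :, ::k], sampling_rate_hz=config.resample_to_hz
    )


def run_pipeline(recording: Recording, config: PipelineConfig) -> EpochSet:
    """Full chain: rereference -> bandpass -> epochs -> baseline ->
    consecutive average -> decimate."""
    rec = rereference(recording)
    rec = bandpass(rec, config)
    ep = extract_epochs(rec, config)
    ep = baseline_correct(ep)
    ep = consecutive_average(ep, config)
    return resample_epochs(ep, config)


def single_trial_epochs(
    recording: Recording, config: PipelineConfig, *, resample: bool = True
) -> EpochSet:
    """Pipeline without the averaging stage.

    Used for ERP waveform analysis (grand averages over single blinks,
    decimated) and for artifact QC (``resample=False``: amplitude screening
    happens at the native rate so brief transients keep their peaks), both
    of which operate on un-averaged epochs.
    """
    rec = rereference(recording)
    rec = bandpass(rec, config)
    ep = extract_epochs(rec, config)
    ep = baseline_correct(ep)
    return resample_epochs(ep, config) if resample else ep
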