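"""Three-level amplitude-based noise rejection.

An epoch is poorly measured when its maximum absolute amplitude strictly
exceeds 80 uV (beyond the physiological P300 range); a selection is
noise-contaminated when bad epochs strictly exceed half its epochs; a
subject is excluded when at least 10 of the 15 selections in either
environment are contaminated. Screening runs on baseline-corrected,
un-averaged epochs: averaging would dilute exactly the transients this is
meant to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochSet

__all__ = [
    "QcConfig",
    "QcReport",
    "flag_bad_epochs",
    "flag_contaminated_selection",
    "should_exclude_subject",
    "qc_report",
]


@dataclass(frozen=True)
class QcConfig:
    epoch_amp_threshold_uv: float = 80.0
    selection_bad_fraction: float = 0.5  # strict: contaminated iff bad > fraction
    subject_bad_selections: int = 10     # inclusive: excluded iff count >= this
    selections_per_env: int = 15

    def __post_init__(self) -> None:
        if self.epoch_amp_threshold_uv <= 0:
            raise ValueError("threshold must be positive")
        if not 0 < self.selection_bad_fraction < 1:
            raise ValueError("selection_bad_fraction must be in (0, 1)")
        if not 0 < self.subject_bad_selections <= self.selections_per_env:
            raise ValueError("subject_bad_selections must be in 1..selections_per_env")


@dataclass
class QcReport:
    """Counts and flags at every rejection level, grouped by environment."""

    epoch_bad: np.ndarray
    selection_contaminated: dict[str, np.ndarray]
    subject_excluded: bool
    n_epochs: int = 0
    n_bad_epochs: int = 0

    def to_dict(self) -> dict:
        return {
            "n_epochs": self.n_epochs,
            "n_bad_epochs": self.n_bad_epochs,
            "selections_contaminated": {
                env: [bool(x) for x in flags]
                for env, flags in self.selection_contaminated.items()
            },
            "n_contaminated": {
                env: int(np.sum(flags))
                for env, flags in self.selection_contaminated.items()
            },
            "subject_excluded": self.subject_excluded,
        }


def flag_bad_epochs(epochs: EpochSet, qc: QcConfig = QcConfig()) -> np.ndarray:
    """True where max |amplitude| over channels and samples strictly exceeds
    the threshold (an 80 uV epoch is still good)."""
    if len(epochs) == 0:
        raise ValueError("no epochs to screen")
    peaks = np.abs(epochs.epochs).max(axis=(1, 2))
    return peaks > qc.epoch_amp_threshold_uv


def flag_contaminated_selection(flags: np.ndarray, qc: QcConfig = QcConfig()) -> bool:
    """A selection is contaminated iff bad epochs strictly exceed the bad
    fraction (70 of 140 is exactly half: not contaminated)."""
    flags = np.asarray(flags, dtype=bool)
    return bool(flags.sum() > qc.selection_bad_fraction * flags.size)


def should_exclude_subject(
    contaminated_by_env: dict[str, np.ndarray], qc: QcConfig = QcConfig()
) -> bool:
    """Excluded iff any single environment reaches the contaminated-selection
    count (inclusive: exactly 10 of 15 already excludes)."""
    return any(
        int(np.sum(np.asarray(flags, dtype=bool))) >= qc.subject_bad_selections
        for flags in contaminated_by_env.values()
    )


def qc_report(epochs: EpochSet, qc: QcConfig = QcConfig()) -> QcReport:
    """Apply all three levels to one subject's un-averaged epochs."""
    bad = flag_bad_epochs(epochs, qc)
    contaminated: dict[str, np.ndarray] = {}
    for env in sorted(set(epochs.environment.tolist())):
        env_mask = epochs.environment == env
        sel_ids = sorted(set(epochs.selection_id[env_mask].tolist()))
        flags = [
            flag_contaminated_selection(
                bad[env_mask & (epochs.selection_id == sid)], qc
            )
            for sid in sel_ids
        ]
        contaminated[str(env)] = np.asarray(flags, dtype=bool)
    return QcReport(
        epoch_bad=bad,
        selection_contaminated=contaminated,
        subject_excluded=should_exclude_subject(contaminated, qc),
        n_epochs=len(epochs),
        n_bad_epochs=int(bad.sum()),
    )
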