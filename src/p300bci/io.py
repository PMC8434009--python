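"""File formats: event schedules, recordings, epoch sets, models, fixtures,
and the flat YAML run configuration.

Events travel as a tab-separated text file (onset_s, button, is_target,
selection_id, environment) with 6-decimal onsets. Recordings and epoch sets
are stored as a compressed .npz container plus a JSON metadata sidecar (and a
labels CSV for epochs). The packaged per-subject outcome tables load into
SubjectRecord lists.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .erp_stats import ErpConfig, SubjectRecord
from .paradigm import ErpTemplate, NoiseModel, ParadigmConfig, Recording, StimulusSchedule
from .preprocess import EpochSet, PipelineConfig
from .qc import QcConfig
from .classify import ClassifierModel

__all__ = [
    "ParseError",
    "write_events",
    "read_events",
    "save_recording",
    "load_recording",
    "export_recording_csv",
    "save_epochs",
    "load_epochs",
    "save_model",
    "load_model",
    "read_fixture_tables",
    "RunConfig",
]

EVENT_COLUMNS = ("onset_s", "button", "is_target", "selection_id", "environment")


class ParseError(ValueError):
    """Malformed events file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


def write_events(schedule: StimulusSchedule, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for onset, button, is_tgt in schedule.events():
            fh.write(
                f"{onset:.6f}\t{button}\t{int(is_tgt)}\t"
                f"{schedule.selection_id}\t{schedule.environment}\n"
            )


def read_events(path) -> StimulusSchedule:
    """Parse one selection's events; enforces the schedule invariants
    (monotone onsets, coherent target flags) with line-numbered errors."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("empty file (missing header)", 1)
    header = lines[0].split("\t")
    if tuple(header) != EVENT_COLUMNS:
        raise ParseError(f"bad header {header!r}", 1)
    onsets, buttons, targets, sel_ids, envs = [], [], [], [], []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != len(EVENT_COLUMNS):
            raise ParseError(f"expected {len(EVENT_COLUMNS)} fields, got {len(parts)}", lineno)
        try:
            onsets.append(float(parts[0]))
            buttons.append(int(parts[1]))
            targets.append(bool(int(parts[2])))
            sel_ids.append(int(parts[3]))
            envs.append(parts[4])
        except ValueError as err:
            raise ParseError(str(err), lineno) from err
        if len(onsets) > 1 and onsets[-1] <= onsets[-2]:
            raise ParseError("onsets must be strictly increasing", lineno)
    if len(set(sel_ids)) > 1 or len(set(envs)) > 1:
        raise ParseError("file mixes multiple selections or environments")
    if not onsets:
        return StimulusSchedule(
            onsets_s=np.array([]), buttons=np.array([], dtype=int), target_button=0
        )
    target_buttons = {b for b, t in zip(buttons, targets) if t}
    nontarget_buttons = {b for b, t in zip(buttons, targets) if not t}
    if len(target_buttons) > 1 or target_buttons & nontarget_buttons:
        raise ParseError("inconsistent is_target flags")
    target = target_buttons.pop() if target_buttons else -1
    if target == -1:
        # no target rows: pick an id outside the button set so is_target stays all-false
        target = max(buttons) + 1
    return StimulusSchedule(
        onsets_s=np.array(onsets),
        buttons=np.array(buttons, dtype=int),
        target_button=int(target),
        selection_id=sel_ids[0],
        environment=envs[0],
    )


# ---------------------------------------------------------------------------
# Recordings and epoch sets


def save_recording(recording: Recording, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {"data": recording.data}
    if recording.reference_data is not None:
        arrays["reference"] = recording.reference_data
    np.savez_compressed(out_dir / "recording.npz", **arrays)
    meta = {
        "sampling_rate_hz": recording.sampling_rate_hz,
        "channel_labels": list(recording.channel_labels),
        "reference_label": recording.reference_label,
        "has_reference": recording.reference_data is not None,
        "target_button": int(recording.schedule.target_button),
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))
    write_events(recording.schedule, out_dir / "events.tsv")
    return out_dir


def load_recording(in_dir) -> Recording:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    arrays = np.load(in_dir / "recording.npz")
    schedule = read_events(in_dir / "events.tsv")
    if meta["target_button"] != schedule.target_button:
        # reconstruct a target that never flashed (all-nontarget schedules)
        schedule = dataclasses.replace(schedule, target_button=meta["target_button"])
    return Recording(
        data=arrays["data"],
        sampling_rate_hz=meta["sampling_rate_hz"],
        channel_labels=tuple(meta["channel_labels"]),
        schedule=schedule,
        reference_data=arrays["reference"] if meta["has_reference"] else None,
        reference_label=meta["reference_label"],
    )


def export_recording_csv(recording: Recording, path) -> None:
    """Plain-text export, samples x channels."""
    df = pd.DataFrame(recording.data.T, columns=list(recording.channel_labels))
    if recording.reference_data is not None:
        df[recording.reference_label] = recording.reference_data
    df.to_csv(path, index=False)


def save_epochs(epochs: EpochSet, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out_dir / "epochs.npz", epochs=epochs.epochs)
    labels = pd.DataFrame(
        {
            "button": epochs.button,
            "is_target": epochs.is_target.astype(int),
            "selection_id": epochs.selection_id,
            "environment": epochs.environment,
            "onset_s": epochs.onset_s,
        }
    )
    labels.to_csv(out_dir / "labels.csv", index=False)
    meta = {
        "sampling_rate_hz": epochs.sampling_rate_hz,
        "channel_labels": list(epochs.channel_labels),
        "n_skipped": epochs.n_skipped,
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def load_epochs(in_dir) -> EpochSet:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    data = np.load(in_dir / "epochs.npz")["epochs"]
    # keep_default_na: the "NA" environment label is a real value, not NaN
    labels = pd.read_csv(in_dir / "labels.csv", keep_default_na=False)
    return EpochSet(
        epochs=data,
        button=labels["button"].to_numpy(),
        is_target=labels["is_target"].to_numpy().astype(bool),
        selection_id=labels["selection_id"].to_numpy(),
        environment=labels["environment"].to_numpy(dtype=object),
        onset_s=labels["onset_s"].to_numpy(),
        sampling_rate_hz=meta["sampling_rate_hz"],
        channel_labels=tuple(meta["channel_labels"]),
        n_skipped=meta["n_skipped"],
    )


def save_model(model: ClassifierModel, path) -> None:
    np.savez_compressed(
        path,
        weights=model.weights,
        bias=np.array([model.bias]),
        feature_shape=np.array(model.feature_shape),
        regularization=np.array(model.regularization),
    )


def load_model(path) -> ClassifierModel:
    data = np.load(path, allow_pickle=False)
    return ClassifierModel(
        weights=data["weights"],
        bias=float(data["bias"][0]),
        feature_shape=tuple(int(x) for x in data["feature_shape"]),
        regularization=str(data["regularization"]),
    )


# ---------------------------------------------------------------------------
# Fixture tables


def read_fixture_tables(fixtures_dir=None) -> list[SubjectRecord]:
    """Join the per-subject outcome table (accuracy/sickness/preference) with
    the per-subject ERP table (peak latency/amplitude), keyed by subject id.

    With no directory given, the tables packaged with the library are used.
    """
    if fixtures_dir is None:
        base = resources.files("p300bci").joinpath("data")
        t3 = pd.read_csv(base.joinpath("table3.csv").open())
        t4 = pd.read_csv(base.joinpath("table4.csv").open())
    else:
        fixtures_dir = Path(fixtures_dir)
        t3 = pd.read_csv(fixtures_dir / "table3.csv")
        t4 = pd.read_csv(fixtures_dir / "table4.csv")
    for name, df in (("table3", t3), ("table4", t4)):
        if df["subject"].duplicated().any():
            raise ValueError(f"duplicated subject id in {name}")
    if set(t3["subject"]) != set(t4["subject"]):
        missing = set(t3["subject"]) ^ set(t4["subject"])
        raise ValueError(f"subject(s) present in only one table: {sorted(missing)}")
    merged = t3.merge(t4, on="subject", validate="one_to_one")
    records = [
        SubjectRecord(
            subject_id=row["subject"],
            accuracy_vr=float(row["acc_vr"]),
            accuracy_ar=float(row["acc_ar"]),
            sickness_vr=row["sickness_vr"] == "Y",
            sickness_ar=row["sickness_ar"] == "Y",
            preference=row["preference"],
            latency_vr=float(row["lat_vr"]),
            latency_ar=float(row["lat_ar"]),
            amplitude_vr=float(row["amp_vr"]),
            amplitude_ar=float(row["amp_ar"]),
        )
        for _, row in merged.iterrows()
    ]
    return records


# ---------------------------------------------------------------------------
# Run configuration


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end simulated experiment needs.

    Round-trips losslessly through YAML; unknown keys are rejected so typos
    cannot silently fall back to defaults.
    """

    paradigm: ParadigmConfig = ParadigmConfig()
    pipeline: PipelineConfig = PipelineConfig()
    qc: QcConfig = QcConfig()
    erp: ErpConfig = ErpConfig()
    template: ErpTemplate = ErpTemplate()
    noise: NoiseModel = NoiseModel()
    seed: int = 0
    n_training_selections: int = 5

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists for plain YAML/JSON

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sections = {
            "paradigm": ParadigmConfig,
            "pipeline": PipelineConfig,
            "qc": QcConfig,
            "erp": ErpConfig,
            "template": ErpTemplate,
            "noise": NoiseModel,
        }
        known = set(sections) | {"seed", "n_training_selections"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs: dict = {}
        for key, typ in sections.items():
            if key not in raw:
                continue
            section = dict(raw[key])
            field_names = {f.name for f in dataclasses.fields(typ)}
            bad = set(section) - field_names
            if bad:
                raise ValueError(f"unknown key(s) in {key!r}: {sorted(bad)}")
            if key == "paradigm" and "channels" in section:
                section["channels"] = tuple(section["channels"])
            if key == "erp":
                for wkey in ("peak_window_ms", "mean_window_ms"):
                    if wkey in section:
                        section[wkey] = tuple(section[wkey])
            kwargs[key] = typ(**section)
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "n_training_selections" in raw:
            kwargs["n_training_selections"] = int(raw["n_training_selections"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)
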