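"""File formats: recording CSV (+ JSON sidecar), calibration CSV, pairs CSV,
model and report JSON."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .bpmodel import CalibrationModel, CalibrationRecord
from .preprocess import PttEstimate, RawRecording
from .valstats import MeasurementPair, ValidationReport


def _sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_recording_csv(
    recording: RawRecording, path: str | Path, metadata: dict[str, Any] | None = None
) -> None:
    """Write `t,scg,ppg` rows plus a JSON sidecar with fs and any metadata."""
    df = pd.DataFrame({"t": recording.t, "scg": recording.scg, "ppg": recording.ppg})
    df.to_csv(path, index=False, float_format="%.9g")
    side = {"fs_hz": recording.fs_hz}
    if metadata:
        side.update(metadata)
    _sidecar_path(path).write_text(json.dumps(side, indent=2))


def read_recording_csv(path: str | Path) -> RawRecording:
    df = pd.read_csv(path)
    for col in ("t", "scg", "ppg"):
        if col not in df.columns:
            raise ValueError(f"recording CSV missing column {col!r}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        fs = float(json.loads(sidecar.read_text())["fs_hz"])
    else:
        dt = np.diff(df["t"].to_numpy())
        fs = 1.0 / float(np.median(dt))
    # regenerate the grid from fs to absorb CSV round-off in t
    t = np.arange(len(df)) / fs + float(df["t"].iloc[0])
    return RawRecording(
        t=t, scg=df["scg"].to_numpy(float), ppg=df["ppg"].to_numpy(float), fs_hz=fs
    )


def read_calibration_csv(path: str | Path) -> list[CalibrationRecord]:
    """Read `ptt_ms,sbp_ref,dbp_ref` rows (three for the full protocol)."""
    df = pd.read_csv(path)
    for col in ("ptt_ms", "sbp_ref", "dbp_ref"):
        if col not in df.columns:
            raise ValueError(f"calibration CSV missing column {col!r}")
    return [
        CalibrationRecord(ptt_ms=float(r.ptt_ms), sbp_ref=float(r.sbp_ref), dbp_ref=float(r.dbp_ref))
        for r in df.itertuples()
    ]


def write_model_json(model: CalibrationModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(model), indent=2))


def read_model_json(path: str | Path) -> CalibrationModel:
    return CalibrationModel(**json.loads(Path(path).read_text()))


def write_ptt_json(estimate: PttEstimate, path: str | Path) -> None:
    d = dataclasses.asdict(estimate)
    d["quality"] = estimate.quality.value
    d["per_beat_ptt_ms"] = list(estimate.per_beat_ptt_ms)
    Path(path).write_text(json.dumps(d, indent=2))


def read_pairs_csv(path: str | Path) -> list[MeasurementPair]:
    """Read `participant_id,test_sbp,test_dbp,ref_sbp,ref_dbp[,test_hr,ref_hr]`."""
    df = pd.read_csv(path)
    required = ("participant_id", "test_sbp", "test_dbp", "ref_sbp", "ref_dbp")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"pairs CSV missing column {col!r}")
    has_hr = "test_hr" in df.columns and "ref_hr" in df.columns
    pairs = []
    for r in df.itertuples():
        pairs.append(
            MeasurementPair(
                participant_id=str(r.participant_id),
                test_sbp=float(r.test_sbp),
                test_dbp=float(r.test_dbp),
                ref_sbp=float(r.ref_sbp),
                ref_dbp=float(r.ref_dbp),
                test_hr=float(r.test_hr) if has_hr and not pd.isna(r.test_hr) else None,
                ref_hr=float(r.ref_hr) if has_hr and not pd.isna(r.ref_hr) else None,
            )
        )
    return pairs


def write_pairs_csv(pairs: Sequence[MeasurementPair], path: str | Path) -> None:
    from .valstats import pairs_to_frame

    pairs_to_frame(pairs).to_csv(path, index=False)


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (obj != obj):  # NaN
        return None
    return obj


def report_to_dict(
    report: ValidationReport, extra: dict[str, Any] | None = None
) -> dict[str, Any]:
    d = _jsonify(report)
    # drop the bulky Bland-Altman point clouds from the serialized report
    for q in ("sbp", "dbp", "hr"):
        if d.get(q):
            d[q]["bland_altman"].pop("averages", None)
            d[q]["bland_altman"].pop("differences", None)
    if extra:
        d.update(extra)
    return d


def write_report_json(
    report: ValidationReport, path: str | Path, extra: dict[str, Any] | None = None
) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report, extra), indent=2, sort_keys=True))
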