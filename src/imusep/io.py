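"""File formats: IMU and marker CSV dialects, trial manifest, dataset layout.

CSV is the canonical interchange format.  IMU files carry the header
``time_s,gyro_x,gyro_y,gyro_z,accel_x,accel_y,accel_z,mag_x,mag_y,mag_z``
(SI units, 500 Hz nominal); marker files carry ``time_s`` followed by
``<NAME>_x_mm,<NAME>_y_mm,<NAME>_z_mm`` triplets at 250 Hz, empty cells
marking gaps.  All numeric output is serialized with 9 significant digits
and a stable column order.

A dataset directory contains ``manifest.yaml`` (subjects, trial roles,
analysis windows, file paths), one subdirectory per subject with the trial
CSVs, ``geometry.json`` and, for synthetic data, ``ground_truth.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .frames import MarkerSet
from .orientation import ImuRecord
from .synthetic import (
    SkeletonGeometry,
    SubjectData,
    SubjectTruth,
    SyntheticConfig,
    SyntheticDataset,
    TrialData,
)

__all__ = [
    "read_imu_csv",
    "write_imu_csv",
    "read_marker_csv",
    "write_marker_csv",
    "write_dataset",
    "load_dataset",
    "write_results",
]

IMU_HEADER = [
    "time_s",
    "gyro_x", "gyro_y", "gyro_z",
    "accel_x", "accel_y", "accel_z",
    "mag_x", "mag_y", "mag_z",
]

_FLOAT_FMT = "%.9g"


def _check_uniform(ts: np.ndarray, path, what: str) -> None:
    if len(ts) < 2:
        return
    dts = np.diff(ts)
    dt = float(np.median(dts))
    bad = np.where(np.abs(dts - dt) > max(1e-6 * dt, 1e-9))[0]
    if bad.size:
        raise ParseError(
            f"{path}: non-uniform {what} timestamps at sample {int(bad[0]) + 1} "
            f"(dt {dts[bad[0]]:.6g} s vs {dt:.6g} s)"
        )


def read_imu_csv(path) -> ImuRecord:
    """Read one sensor stream; rejects malformed headers and jittery clocks."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != IMU_HEADER:
        raise ParseError(f"{path}: header {list(df.columns)} != {IMU_HEADER}")
    ts = df["time_s"].to_numpy(float)
    _check_uniform(ts, path, "IMU")
    return ImuRecord(
        timestamps=ts,
        gyro=df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(float),
        accel=df[["accel_x", "accel_y", "accel_z"]].to_numpy(float),
        mag=df[["mag_x", "mag_y", "mag_z"]].to_numpy(float),
        sensor_id=path.stem,
    )


def write_imu_csv(rec: ImuRecord, path) -> None:
    data = np.column_stack([rec.timestamps, rec.gyro, rec.accel, rec.mag])
    pd.DataFrame(data, columns=IMU_HEADER).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_marker_csv(path, expected_names=None) -> MarkerSet:
    """Read marker trajectories; empty cells become NaN gaps."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if not cols or cols[0] != "time_s":
        raise ParseError(f"{path}: first column must be 'time_s'")
    names = []
    for c in cols[1:]:
        if not c.endswith(("_x_mm", "_y_mm", "_z_mm")):
            raise ParseError(f"{path}: unexpected column {c!r}")
        name = c[:-5]
        if name not in names:
            names.append(name)
    positions = {}
    for name in names:
        triplet = [f"{name}_{ax}_mm" for ax in "xyz"]
        missing = [c for c in triplet if c not in cols]
        if missing:
            raise ParseError(f"{path}: marker {name!r} missing columns {missing}")
        positions[name] = df[triplet].to_numpy(float)
    if expected_names is not None:
        unknown = sorted(set(names) - set(expected_names))
        if unknown:
            raise ParseError(f"{path}: unknown marker names {unknown}")
    ts = df["time_s"].to_numpy(float)
    _check_uniform(ts, path, "marker")
    return MarkerSet(ts, positions)


def write_marker_csv(ms: MarkerSet, path) -> None:
    cols = {"time_s": ms.timestamps}
    for name in ms.positions:  # insertion order is the stable column order
        for i, ax in enumerate("xyz"):
            cols[f"{name}_{ax}_mm"] = ms.positions[name][:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _qdump(q) -> list[float]:
    return [float(x) for x in np.asarray(q).ravel()]


def write_dataset(dataset: SyntheticDataset, out_dir) -> Path:
    """Serialize a synthetic dataset (manifest, CSVs, geometry, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = dataset.geometry
    (out / "geometry.json").write_text(
        json.dumps(
            {
                "rmc_local": geometry.rmc_local.tolist(),
                "inter_asis": geometry.inter_asis,
                "thigh_length": geometry.thigh_length,
                "shank_length": geometry.shank_length,
            },
            indent=1,
        )
    )
    manifest = {"subjects": []}
    truth_all = {}
    for subject in dataset.subjects:
        sdir = out / subject.subject_id
        sdir.mkdir(exist_ok=True)
        strials = []
        for trial in subject.trials:
            tdir = sdir / trial.name
            tdir.mkdir(exist_ok=True)
            entry = {
                "name": trial.name,
                "role": trial.role,
                "movement": trial.movement,
                "repetition": trial.repetition,
                "static_window": list(trial.static_window),
                "movement_windows": {k: list(v) for k, v in trial.movement_windows.items()},
                "analysis_window": list(trial.analysis_window)
                if trial.analysis_window
                else None,
                "imu": {},
            }
            for seg, rec in trial.imu.items():
                rel = f"{subject.subject_id}/{trial.name}/imu_{seg}.csv"
                write_imu_csv(rec, out / rel)
                entry["imu"][seg] = rel
            if trial.markers is not None:
                rel = f"{subject.subject_id}/{trial.name}/markers.csv"
                write_marker_csv(trial.markers, out / rel)
                entry["markers"] = rel
            strials.append(entry)
        manifest["subjects"].append(
            {
                "id": subject.subject_id,
                "inter_asis_mm": subject.inter_asis,
                "leg_length_mm": subject.leg_length,
                "trials": strials,
            }
        )
        tr = subject.truth
        truth_all[subject.subject_id] = {
            "q_mount": {s: _qdump(q) for s, q in tr.q_mount.items()},
            "q_frame_error": {s: _qdump(q) for s, q in tr.q_frame_error.items()},
            "frame_error_deg": tr.frame_error_deg,
            "gyro_bias": {s: _qdump(b) for s, b in tr.gyro_bias.items()},
            "sta_axis": {s: _qdump(a) for s, a in tr.sta_axis.items()},
            "hand_eye": _qdump(tr.hand_eye),
        }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    (out / "ground_truth.json").write_text(json.dumps(truth_all, indent=1))
    return out


def load_dataset(root) -> SyntheticDataset:
    """Load a dataset directory back into memory (ground truth optional)."""
    root = Path(root)
    manifest = yaml.safe_load((root / "manifest.yaml").read_text())
    geo_raw = json.loads((root / "geometry.json").read_text())
    from .synthetic import default_geometry  # local default for landmark maps

    geometry = default_geometry()
    geometry = SkeletonGeometry(
        landmarks=geometry.landmarks,
        rmc_local=np.asarray(geo_raw["rmc_local"], float),
        mounts=geometry.mounts,
        inter_asis=float(geo_raw["inter_asis"]),
        thigh_length=float(geo_raw["thigh_length"]),
        shank_length=float(geo_raw["shank_length"]),
        hjc_local=geometry.hjc_local,
    )
    truth_path = root / "ground_truth.json"
    truth_all = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    subjects = []
    for sub in manifest["subjects"]:
        trials = []
        for entry in sub["trials"]:
            imu = {seg: read_imu_csv(root / rel) for seg, rel in entry.get("imu", {}).items()}
            markers = (
                read_marker_csv(root / entry["markers"]) if "markers" in entry else None
            )
            trials.append(
                TrialData(
                    name=entry["name"],
                    role=entry["role"],
                    movement=entry.get("movement", ""),
                    repetition=int(entry.get("repetition", 0)),
                    imu=imu,
                    markers=markers,
                    static_window=tuple(entry.get("static_window", (0.5, 5.0))),
                    movement_windows={
                        k: tuple(v) for k, v in entry.get("movement_windows", {}).items()
                    },
                    analysis_window=tuple(entry["analysis_window"])
                    if entry.get("analysis_window")
                    else None,
                )
            )
        raw = truth_all.get(sub["id"])
        truth = (
            SubjectTruth(
                q_mount={s: np.array(q) for s, q in raw["q_mount"].items()},
                q_frame_error={s: np.array(q) for s, q in raw["q_frame_error"].items()},
                frame_error_deg=float(raw["frame_error_deg"]),
                gyro_bias={s: np.array(b) for s, b in raw["gyro_bias"].items()},
                sta_axis={s: np.array(a) for s, a in raw["sta_axis"].items()},
                hand_eye=np.array(raw["hand_eye"]),
            )
            if raw
            else SubjectTruth({}, {}, 0.0, {}, {}, np.array([1.0, 0, 0, 0]))
        )
        subjects.append(
            SubjectData(
                subject_id=sub["id"],
                trials=trials,
                truth=truth,
                inter_asis=float(sub["inter_asis_mm"]),
                leg_length=float(sub["leg_length_mm"]),
            )
        )
    return SyntheticDataset(config=SyntheticConfig(), geometry=geometry, subjects=subjects)


def write_results(df: pd.DataFrame, summary, out_dir) -> None:
    """Tidy results CSV plus a JSON mirror of the aggregate summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = ["subject", "trial", "repetition", "segment", "comparison", "rmsd_deg", "max_deg"]
    df[cols].to_csv(out / "results.csv", index=False, float_format=_FLOAT_FMT)
    payload = {
        "single_subject": bool(summary.single_subject),
        "per_subject": summary.per_subject.to_dict(orient="records"),
        "group": summary.group.to_dict(orient="records"),
    }
    (out / "summary.json").write_text(json.dumps(payload, indent=1))
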