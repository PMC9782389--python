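"""End-to-end processing: raw recordings to the nine-comparison decomposition.

Per subject the pipeline runs, in order: sensor offset calibration (neutral
trial) -> orientation filter -> hand-eye calibration (compass trial) ->
sensor-body calibrations A-C -> static-trial marker alignments -> per
movement trial: marker frames, synchronization/down-sampling, frame
composition and the nine comparisons -> aggregation over repetitions and
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decompose
from .calibrate import (
    build_sensor_body_cal,
    downsample_series,
    estimate_sync_offset,
    flexion_axis_functional,
    hand_eye_from_compass,
    longitudinal_axis_static,
    static_frame_alignment,
)
from .decompose import (
    AggregateSummary,
    ComparisonResult,
    aggregate,
    apply_mcbf,
    compose_scbf,
    express_in_grf,
    run_table1,
)
from .errors import InsufficientExcitationError, MissingFrameError
from .frames import (
    MarkerSet,
    SubjectAnthropometry,
    cluster_frame,
    hip_joint_center,
    lowpass_markers,
    pelvis_frame,
    shank_frame,
    thigh_frame,
)
from .orientation import FilterConfig, ImuRecord, apply_imu_calibration, estimate_static_cal
from .orientation import run_orientation_filter
from .quat import QuaternionSeries
from .synthetic import (
    CALIBRATION_SIGNS,
    SubjectData,
    SyntheticDataset,
    TrialData,
    default_geometry,
)

__all__ = ["PipelineConfig", "SubjectCalibrations", "process_subject", "run_study"]


@dataclass
class PipelineConfig:
    """Tunables of the processing chain (defaults as used in the study)."""

    beta: float = 0.043  # orientation-filter gain
    warmup: float = 5.0  # s excluded before any analysis window
    use_mag: bool = True
    lowpass_fc: float = 8.0  # marker low-pass cut-off, Hz
    lowpass_order: int = 4
    sync: bool = True  # estimate and apply the IMU/marker lag

    def filter_config(self) -> FilterConfig:
        return FilterConfig(beta=self.beta, warmup=self.warmup, use_mag=self.use_mag)


@dataclass
class SubjectCalibrations:
    """All constants estimated for one subject."""

    imu_cal: dict = field(default_factory=dict)  # segment -> ImuCalParams
    hand_eye: np.ndarray | None = None  # q_GRF^IRF
    scbf: dict = field(default_factory=dict)  # (method, segment) -> BodyCal
    mcbf_imu: dict = field(default_factory=dict)  # segment -> BodyCal (q_AL^IMU-sf)
    mcbf_rmc: dict = field(default_factory=dict)  # segment -> BodyCal (q_AL^RMC-sf)


def _segment_al_frames(
    markers: MarkerSet, segments, anthro: SubjectAnthropometry | None
) -> dict[str, QuaternionSeries]:
    """Anatomical body-frame series for the requested segments."""
    out = {}
    hjc = {}
    if any(s.startswith("thigh") for s in segments) or "pelvis" in segments:
        for side in ("L", "R"):
            hjc[side] = hip_joint_center(markers, side, anthro)
    for seg in segments:
        if seg == "pelvis":
            out[seg] = pelvis_frame(markers)
        elif seg.startswith("thigh"):
            side = seg[-1].upper()
            out[seg] = thigh_frame(markers, side, hjc[side])
        elif seg.startswith("shank"):
            out[seg] = shank_frame(markers, seg[-1].upper())
        else:
            raise MissingFrameError(f"unknown segment {seg!r}")
    return out


def _rmc_frames(markers: MarkerSet, segments, rmc_local) -> dict[str, QuaternionSeries]:
    return {
        seg: cluster_frame(markers, tuple(f"{seg}_RMC{i}" for i in (1, 2, 3, 4)), rmc_local)
        for seg in segments
    }


def _grf_imu_series(
    trial: TrialData, seg: str, cals: SubjectCalibrations, cfg: PipelineConfig
) -> QuaternionSeries:
    """Calibrated, filtered, GRF-expressed sensor series for one segment."""
    rec = apply_imu_calibration(trial.imu[seg], cals.imu_cal[seg])
    irf_series = run_orientation_filter(rec, cfg.filter_config())
    return express_in_grf(cals.hand_eye, irf_series)


def _sync_and_downsample(
    imu_series: QuaternionSeries,
    raw_imu: ImuRecord,
    rmc: QuaternionSeries,
    cfg: PipelineConfig,
) -> QuaternionSeries:
    """Down-sample the 500 Hz filter output onto the marker clock."""
    factor = max(1, int(round(imu_series.rate / rmc.rate)))
    lag = 0
    if cfg.sync:
        try:
            lag = estimate_sync_offset(raw_imu, rmc).lag
        except InsufficientExcitationError:
            lag = 0  # static trial: streams already share the start trigger
    ds = downsample_series(imu_series, factor=factor)
    if lag > 0:
        q = ds.q[lag:]
    elif lag < 0:
        q = np.concatenate([np.repeat(ds.q[:1], -lag, axis=0), ds.q[: len(ds.q) + lag]])
    else:
        q = ds.q
    n = min(len(q), len(rmc.timestamps))
    return QuaternionSeries(
        rmc.timestamps[:n], q[:n], source_frame=imu_series.source_frame,
        target_frame=imu_series.target_frame,
    )


def calibrate_subject(subject: SubjectData, cfg: PipelineConfig | None = None,
                      rmc_local=None, anthro: SubjectAnthropometry | None = None
                      ) -> SubjectCalibrations:
    """Estimate every constant alignment from the calibration recordings."""
    cfg = cfg or PipelineConfig()
    if rmc_local is None:
        rmc_local = default_geometry().rmc_local
    cals = SubjectCalibrations()
    neutral = subject.trial("neutral")
    segments = list(neutral.imu.keys())
    for seg in segments:
        cals.imu_cal[seg] = estimate_static_cal(neutral.imu[seg].window(*neutral.static_window))

    compass = subject.trial("compass")
    cals.hand_eye = hand_eye_from_compass(
        compass.markers["COMPASS_TAIL"], compass.markers["COMPASS_TIP"]
    )

    for method in ("A", "B", "C"):
        trial = subject.trial(f"calib{method}")
        for seg in segments:
            rec = apply_imu_calibration(trial.imu[seg], cals.imu_cal[seg])
            long_axis = longitudinal_axis_static(rec, trial.static_window)
            flex_axis = flexion_axis_functional(
                rec,
                trial.movement_windows[seg],
                long_axis,
                expected_sign=CALIBRATION_SIGNS[method][seg],
            )
            cals.scbf[(method, seg)] = build_sensor_body_cal(
                long_axis, flex_axis, method, segment=seg
            )

    static = subject.trial("static")
    markers = lowpass_markers(static.markers, cfg.lowpass_order, cfg.lowpass_fc)
    al = _segment_al_frames(markers, segments, anthro)
    rmc = _rmc_frames(markers, segments, rmc_local)
    t0 = cfg.warmup + 0.5
    t1 = float(static.markers.timestamps[-1]) - 0.2
    for seg in segments:
        imu_grf = _grf_imu_series(static, seg, cals, cfg)
        imu_ds = _sync_and_downsample(imu_grf, static.imu[seg], rmc[seg], cfg)
        w = (t0, min(t1, float(imu_ds.timestamps[-1])))
        cals.mcbf_imu[seg] = static_frame_alignment(
            al[seg].window(*w), imu_ds.window(*w), segment=seg
        )
        cals.mcbf_rmc[seg] = static_frame_alignment(
            al[seg].window(*w), rmc[seg].window(*w), segment=seg
        )
    return cals


def movement_frames(
    subject: SubjectData,
    trial: TrialData,
    cals: SubjectCalibrations,
    cfg: PipelineConfig | None = None,
    rmc_local=None,
    anthro: SubjectAnthropometry | None = None,
    segments=None,
) -> dict[str, dict[str, QuaternionSeries]]:
    """The six GRF-referenced frame series per segment for one trial,
    cropped to the trial's analysis window."""
    cfg = cfg or PipelineConfig()
    if rmc_local is None:
        rmc_local = default_geometry().rmc_local
    segments = segments or list(trial.imu.keys())
    markers = lowpass_markers(trial.markers, cfg.lowpass_order, cfg.lowpass_fc)
    al = _segment_al_frames(markers, segments, anthro)
    rmc = _rmc_frames(markers, segments, rmc_local)
    w = trial.analysis_window or (cfg.warmup + 0.5, float(markers.timestamps[-1]))
    out: dict[str, dict[str, QuaternionSeries]] = {}
    for seg in segments:
        imu_grf = _grf_imu_series(trial, seg, cals, cfg)
        imu_ds = _sync_and_downsample(imu_grf, trial.imu[seg], rmc[seg], cfg)
        wseg = (w[0], min(w[1], float(imu_ds.timestamps[-1])))
        frames = {
            "AL-mcbf": al[seg].window(*wseg),
            "RMC-mcbf": apply_mcbf(rmc[seg].window(*wseg), cals.mcbf_rmc[seg], "RMC-mcbf"),
            "IMU-mcbf": apply_mcbf(imu_ds.window(*wseg), cals.mcbf_imu[seg], "IMU-mcbf"),
        }
        for method in ("A", "B", "C"):
            frames[f"IMU-scbf{method}"] = compose_scbf(
                imu_ds.window(*wseg), cals.scbf[(method, seg)]
            )
        out[seg] = frames
    return out


def process_subject(
    subject: SubjectData,
    cfg: PipelineConfig | None = None,
    rmc_local=None,
    anthro: SubjectAnthropometry | None = None,
) -> list[ComparisonResult]:
    """Full decomposition for one subject: all movement trials, nine
    comparisons per segment."""
    cfg = cfg or PipelineConfig()
    cals = calibrate_subject(subject, cfg, rmc_local=rmc_local, anthro=anthro)
    results: list[ComparisonResult] = []
    for trial in subject.trials:
        if trial.role != "movement":
            continue
        frames = movement_frames(subject, trial, cals, cfg, rmc_local=rmc_local, anthro=anthro)
        for seg, fr in frames.items():
            results.extend(
                run_table1(
                    fr,
                    segment=seg,
                    trial=trial.movement or trial.name,
                    subject=subject.subject_id,
                    repetition=trial.repetition,
                )
            )
    return results


def run_study(
    dataset: SyntheticDataset, cfg: PipelineConfig | None = None
) -> tuple[pd.DataFrame, AggregateSummary, list[ComparisonResult]]:
    """Process every subject of a dataset and aggregate.

    Returns the tidy per-repetition results table, the aggregate summary
    (repetition means per subject, cross-subject mean and STD) and the raw
    comparison results.
    """
    cfg = cfg or PipelineConfig()
    results: list[ComparisonResult] = []
    for subject in dataset.subjects:
        anthro = SubjectAnthropometry(subject.leg_length, subject.inter_asis)
        results.extend(
            process_subject(
                subject, cfg, rmc_local=dataset.geometry.rmc_local, anthro=anthro
            )
        )
    df = decompose.results_frame(results)
    return df, aggregate(df), results
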