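"""Frame comparisons and RMSD aggregation: the error-source decomposition.

Once six body-frame series per segment are expressed in the camera global
frame (the three sensor-calibrated body frames IMU-scbfA/B/C, the two
marker-calibrated sensor body frames IMU-mcbf and RMC-mcbf, and the
anatomical frame AL-mcbf), nine pairwise comparisons isolate the error
sources:

=====  ==========  =========  ======================================
 id    frame 1     frame 2    error isolated
=====  ==========  =========  ======================================
 #1-3  IMU-scbfX   IMU-mcbf   body-frame definition (calibration X)
 #4    RMC-mcbf    AL-mcbf    soft tissue artefact
 #5    IMU-mcbf    RMC-mcbf   orientation filter
 #6    IMU-mcbf    AL-mcbf    filter + soft tissue artefact
 #7-9  IMU-scbfX   AL-mcbf    total (calibration X)
=====  ==========  =========  ======================================

Each comparison is the per-sample smallest rotation angle between the two
frames, summarized as its root-mean-square over the analysis window (RMSD)
and its maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import BodyCal
from .errors import EmptyInputError, FrameMismatchError, MissingFrameError
from .quat import QuaternionSeries, qangle, qinv, qmul, qrel

__all__ = [
    "TABLE1_PAIRS",
    "ComparisonResult",
    "AggregateSummary",
    "compose_scbf",
    "express_in_grf",
    "apply_mcbf",
    "compare_frames",
    "run_table1",
    "aggregate",
    "independence_check",
]

#: The nine comparisons: id -> (frame 1, frame 2, error description).
TABLE1_PAIRS = {
    1: ("IMU-scbfA", "IMU-mcbf", "Error definition body frames A"),
    2: ("IMU-scbfB", "IMU-mcbf", "Error definition body frames B"),
    3: ("IMU-scbfC", "IMU-mcbf", "Error definition body frames C"),
    4: ("RMC-mcbf", "AL-mcbf", "Soft Tissue Artefact"),
    5: ("IMU-mcbf", "RMC-mcbf", "Error orientation filter"),
    6: ("IMU-mcbf", "AL-mcbf", "Error orientation filter + Soft Tissue Artefact"),
    7: ("IMU-scbfA", "AL-mcbf", "Total error with calibration A"),
    8: ("IMU-scbfB", "AL-mcbf", "Total error with calibration B"),
    9: ("IMU-scbfC", "AL-mcbf", "Total error with calibration C"),
}


@dataclass
class ComparisonResult:
    """Angle series and RMSD for one comparison on one segment/trial."""

    comparison_id: int
    segment: str
    trial: str
    angle_series: np.ndarray  # degrees per sample
    rmsd: float  # degrees
    max_error: float  # degrees
    subject: str = ""
    repetition: int = 0

    @property
    def description(self) -> str:
        return TABLE1_PAIRS[self.comparison_id][2]


@dataclass
class AggregateSummary:
    """Per-subject repetition means plus cross-subject mean and STD.

    ``per_subject`` has one row per subject x trial x segment x comparison
    (mean RMSD over repetitions); ``group`` reduces it over subjects with
    mean and sample (n-1) standard deviation.  ``single_subject`` flags
    groups whose STD is reported as 0 because only one subject contributed.
    """

    per_subject: pd.DataFrame
    group: pd.DataFrame
    single_subject: bool = False


def compose_scbf(sensor_series: QuaternionSeries, cal: BodyCal) -> QuaternionSeries:
    """Right-multiply a sensor series by a sensor-body calibration:
    ``q_t(.. -> IMU-scbf) = q_t(.. -> IMU-sf) (x) q(IMU-sf -> IMU-scbf)``."""
    if cal.method not in ("A", "B", "C"):
        raise FrameMismatchError(f"expected a sensor-body calibration, got {cal.method!r}")
    q = qmul(sensor_series.q, cal.q_sensor_to_body)
    return QuaternionSeries(
        sensor_series.timestamps.copy(),
        q,
        source_frame=sensor_series.source_frame,
        target_frame=f"IMU-scbf{cal.method}",
    )


def express_in_grf(hand_eye: np.ndarray, series: QuaternionSeries) -> QuaternionSeries:
    """Left-multiply an IRF-referenced series by ``q_GRF^IRF``."""
    if series.source_frame and series.source_frame != "IRF":
        raise FrameMismatchError(
            f"series reference is {series.source_frame!r}, expected 'IRF'"
        )
    q = qmul(np.broadcast_to(np.asarray(hand_eye, float), series.q.shape), series.q)
    return QuaternionSeries(
        series.timestamps.copy(), q, source_frame="GRF", target_frame=series.target_frame
    )


def apply_mcbf(sensor_series: QuaternionSeries, cal: BodyCal, target_frame: str) -> QuaternionSeries:
    """Right-multiply by the inverse static-trial alignment:
    ``q_t(GRF -> X-mcbf) = q_t(GRF -> X-sf) (x) (q_AL-mcbf^X-sf)^-1``.

    During the static trial the result coincides with the anatomical frame.
    """
    if cal.method != "mcbf":
        raise FrameMismatchError(f"expected an mcbf alignment, got {cal.method!r}")
    q = qmul(sensor_series.q, qinv(cal.q_sensor_to_body))
    return QuaternionSeries(
        sensor_series.timestamps.copy(),
        q,
        source_frame=sensor_series.source_frame,
        target_frame=target_frame,
    )


def compare_frames(
    a: QuaternionSeries,
    b: QuaternionSeries,
    comparison_id: int,
    segment: str = "",
    trial: str = "",
    subject: str = "",
    repetition: int = 0,
) -> ComparisonResult:
    """Smallest-angle series between two co-referenced frame series."""
    if len(a) != len(b):
        raise FrameMismatchError(f"series lengths differ: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise EmptyInputError("cannot compare empty series")
    if a.source_frame and b.source_frame and a.source_frame != b.source_frame:
        raise FrameMismatchError(
            f"reference frames differ: {a.source_frame!r} vs {b.source_frame!r}"
        )
    angles = qangle(qrel(a.q, b.q))
    return ComparisonResult(
        comparison_id=comparison_id,
        segment=segment,
        trial=trial,
        subject=subject,
        repetition=repetition,
        angle_series=angles,
        rmsd=float(np.sqrt(np.mean(angles**2))),
        max_error=float(angles.max()),
    )


def run_table1(
    frames: dict[str, QuaternionSeries],
    segment: str = "",
    trial: str = "",
    subject: str = "",
    repetition: int = 0,
) -> list[ComparisonResult]:
    """All nine comparisons for one segment and trial.

    ``frames`` maps the six frame labels (IMU-scbfA/B/C, IMU-mcbf,
    RMC-mcbf, AL-mcbf) to GRF-referenced series.
    """
    needed = {f for pair in TABLE1_PAIRS.values() for f in pair[:2]}
    missing = sorted(needed - frames.keys())
    if missing:
        skipped = [
            i for i, (f1, f2, _) in TABLE1_PAIRS.items() if f1 in missing or f2 in missing
        ]
        raise MissingFrameError(
            f"missing frames {missing}; comparisons {skipped} cannot be computed"
        )
    return [
        compare_frames(
            frames[f1], frames[f2], cid,
            segment=segment, trial=trial, subject=subject, repetition=repetition,
        )
        for cid, (f1, f2, _) in TABLE1_PAIRS.items()
    ]


def results_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy table: one row per subject x trial x repetition x segment x comparison."""
    return pd.DataFrame(
        {
            "subject": r.subject,
            "trial": r.trial,
            "repetition": r.repetition,
            "segment": r.segment,
            "comparison": r.comparison_id,
            "rmsd_deg": r.rmsd,
            "max_deg": r.max_error,
        }
        for r in results
    )


def aggregate(results: list[ComparisonResult] | pd.DataFrame) -> AggregateSummary:
    """Repetition mean per subject, then cross-subject mean and STD.

    The standard deviation is over subjects (sample STD, n-1 denominator);
    with a single subject it is reported as 0 and flagged.
    """
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    if len(df) == 0:
        raise EmptyInputError("no comparison results to aggregate")
    keys = ["trial", "segment", "comparison"]
    per_subject = (
        df.groupby(["subject", *keys], as_index=False)
        .agg(rmsd_deg=("rmsd_deg", "mean"), max_deg=("max_deg", "mean"))
    )
    n_subjects = per_subject["subject"].nunique()
    group = (
        per_subject.groupby(keys, as_index=False)
        .agg(
            mean_rmsd_deg=("rmsd_deg", "mean"),
            std_rmsd_deg=("rmsd_deg", lambda x: x.std(ddof=1)),
            mean_max_deg=("max_deg", "mean"),
            n_subjects=("rmsd_deg", "size"),
        )
    )
    single = n_subjects < 2
    if single:
        group["std_rmsd_deg"] = 0.0
    return AggregateSummary(per_subject=per_subject, group=group, single_subject=single)


def independence_check(
    sta_rmsd: float, filter_rmsd: float, combined_rmsd: float
) -> float:
    """Diagnostic ratio ``combined / sqrt(sta^2 + filter^2)``.

    Near 1 when the two error sources are independent, so their combined
    effect composes as a root sum of squares.  Returns NaN when the
    denominator is zero.
    """
    if min(sta_rmsd, filter_rmsd, combined_rmsd) < 0:
        raise EmptyInputError("RMSD values must be non-negative")
    denom = float(np.hypot(sta_rmsd, filter_rmsd))
    if denom == 0.0:
        return float("nan")
    return float(combined_rmsd / denom)
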