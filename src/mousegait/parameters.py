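"""Scalar gait parameters: joint min/max/ROM, stride length, step width.

Kinematic summaries come from the sagittal plane (per-joint minimum, maximum
and range of motion over a normalized gait cycle, ROM = max - min); spatial
summaries come from the transverse plane (stride length = distance of the
hindpaw shift between successive strikes; step width = lateral distance
between the two hindpaws during stance).  Per-trial values average the two
steady-state (middle) cycles, treated as replicate strides of one walk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    GaitError,
    MissingDataError,
    PipelineStageError,
)
from .events import (
    EventDetectionParams,
    GaitCycle,
    detect_gait_events,
    segment_cycles,
    select_steady_state,
)
from .io_markers import TrialRecording
from .kinematics import (
    JOINTS,
    NormalizedCurve,
    compute_angle_series,
    normalize_cycle,
    smooth_series,
)


@dataclass
class KinematicSummary:
    """Min, max and range of motion (degrees) of one joint over a cycle."""

    joint: str
    min_angle: float
    max_angle: float

    def __post_init__(self) -> None:
        if np.isfinite(self.min_angle) and np.isfinite(self.max_angle):
            if self.min_angle > self.max_angle:
                raise ValueError(
                    f"{self.joint}: min {self.min_angle} exceeds max {self.max_angle}"
                )

    @property
    def rom(self) -> float:
        return self.max_angle - self.min_angle


@dataclass
class SpatialSummary:
    """Transverse-plane parameters of one trial (mm)."""

    stride_length: float
    step_width: float
    n_cycles_used: int

    def __post_init__(self) -> None:
        if self.stride_length < 0 or self.step_width < 0:
            raise ValueError("spatial parameters must be non-negative")
        if self.n_cycles_used < 1:
            raise ValueError("n_cycles_used must be >= 1")


@dataclass
class ParameterSet:
    """All scalar gait parameters of one subject at one timepoint."""

    subject_id: str
    group_label: str
    age_weeks: int
    kinematics: dict[str, KinematicSummary]
    spatial: SpatialSummary

    def __post_init__(self) -> None:
        if set(self.kinematics) != set(JOINTS):
            raise ValueError(
                f"kinematics must cover exactly {JOINTS}, got "
                f"{sorted(self.kinematics)}"
            )

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "group": self.group_label,
            "age_weeks": self.age_weeks,
        }
        for joint in JOINTS:
            ks = self.kinematics[joint]
            row[f"{joint}_min"] = ks.min_angle
            row[f"{joint}_max"] = ks.max_angle
            row[f"{joint}_rom"] = ks.rom
        row["stride_length"] = self.spatial.stride_length
        row["step_width"] = self.spatial.step_width
        row["n_cycles_used"] = self.spatial.n_cycles_used
        return row


#: scalar parameter columns of a tidy parameter table
PARAMETER_COLUMNS = tuple(
    f"{j}_{s}" for j in JOINTS for s in ("min", "max", "rom")
) + ("stride_length", "step_width")


def parameter_table(param_sets: Iterable[ParameterSet]) -> pd.DataFrame:
    """Tidy table: one row per subject x timepoint, one column per parameter."""
    return pd.DataFrame([p.to_row() for p in param_sets])


def kinematic_summary(curve: NormalizedCurve) -> KinematicSummary:
    """Min/max/ROM of one normalized joint-angle curve."""
    if not np.isfinite(curve.angle).all():
        bad = int(np.argwhere(~np.isfinite(curve.angle))[0][0])
        raise MissingDataError(
            f"{curve.joint}: non-finite angle at {curve.percent[bad]:.0f}% of cycle"
        )
    return KinematicSummary(
        joint=curve.joint,
        min_angle=float(curve.angle.min()),
        max_angle=float(curve.angle.max()),
    )


def stride_length(paw_positions: np.ndarray, cycle: GaitCycle) -> float:
    """Distance (mm) of the hindpaw shift across one gait cycle.

    Euclidean distance between the paw position at the cycle's opening
    footstrike and at the closing footstrike; reduces to the forward shift
    when there is no lateral drift.
    """
    pos = np.asarray(paw_positions, dtype=float)
    if cycle.end_frame > len(pos) - 1:
        raise MissingDataError(
            f"cycle end frame {cycle.end_frame} outside trajectory of length {len(pos)}"
        )
    a, b = pos[cycle.start_frame], pos[cycle.end_frame]
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        missing = cycle.start_frame if not np.isfinite(a).all() else cycle.end_frame
        raise MissingDataError(f"paw position missing at footstrike frame {missing}")
    return float(np.linalg.norm(b - a))


def _stance_interval(obj) -> tuple[int, int]:
    """(start, stop) stance frames from a GaitCycle or a plain tuple."""
    if isinstance(obj, GaitCycle):
        return obj.start_frame, obj.toe_off_frame
    start, stop = obj
    return int(start), int(stop)


def step_width(
    right_paw: np.ndarray,
    left_paw: np.ndarray,
    right_cycles: Sequence[GaitCycle],
    left_stances: Sequence,
) -> float:
    """Mean lateral distance (mm) between the hindpaws during stance.

    For each analyzed right-paw cycle, the lateral (y) centroid of its stance
    phase is paired with the nearest-in-time left-paw stance centroid; the
    result is the mean absolute separation over the cycles.
    """
    right = np.asarray(right_paw, dtype=float)
    left = np.asarray(left_paw, dtype=float)
    if not left_stances:
        raise MissingDataError("no left-paw stance available for step width")
    left_iv = [_stance_interval(s) for s in left_stances]
    left_mid = np.array([(a + b) / 2.0 for a, b in left_iv])

    widths = []
    for cyc in right_cycles:
        r_y = right[cyc.start_frame : cyc.toe_off_frame, 1]
        if not np.isfinite(r_y).any():
            raise MissingDataError(
                f"right-paw stance at frame {cyc.start_frame} has no finite samples"
            )
        r_mid = (cyc.start_frame + cyc.toe_off_frame) / 2.0
        j = int(np.argmin(np.abs(left_mid - r_mid)))
        a, b = left_iv[j]
        l_y = left[a:b, 1]
        if not np.isfinite(l_y).any():
            raise MissingDataError(
                f"left-paw stance at frame {a} has no finite samples"
            )
        widths.append(abs(np.nanmean(r_y) - np.nanmean(l_y)))
    if not widths:
        raise MissingDataError("no right-paw cycles available for step width")
    return float(np.mean(widths))


def summarize_trial(
    trial: TrialRecording,
    curves: dict[str, Sequence[NormalizedCurve]],
    cycles: Sequence[GaitCycle],
    left_stances: Sequence,
) -> ParameterSet:
    """Assemble a per-trial :class:`ParameterSet` from pipeline outputs.

    ``curves`` maps each joint to its per-cycle normalized curves (one per
    analyzed cycle); kinematic scalars average the per-cycle min/max; spatial
    scalars follow :func:`stride_length` / :func:`step_width` over the same
    cycles.
    """
    kin = {}
    for joint in JOINTS:
        per_cycle = [kinematic_summary(c) for c in curves[joint]]
        kin[joint] = KinematicSummary(
            joint=joint,
            min_angle=float(np.mean([k.min_angle for k in per_cycle])),
            max_angle=float(np.mean([k.max_angle for k in per_cycle])),
        )
    right_t = trial.transverse_paws["right_hind"]
    left_t = trial.transverse_paws["left_hind"]
    strides = [stride_length(right_t, c) for c in cycles]
    width = step_width(right_t, left_t, cycles, left_stances)
    spatial = SpatialSummary(
        stride_length=float(np.mean(strides)),
        step_width=width,
        n_cycles_used=len(cycles),
    )
    return ParameterSet(
        subject_id=trial.subject_id,
        group_label=trial.group_label,
        age_weeks=trial.age_weeks,
        kinematics=kin,
        spatial=spatial,
    )


def analyze_trial(
    trial: TrialRecording,
    event_params: EventDetectionParams | None = None,
    smooth_window: int | None = None,
) -> ParameterSet:
    """Full per-trial pipeline: angles -> events -> steady state -> parameters.

    ``smooth_window`` (odd, frames) optionally moving-average-filters the
    angle series before normalization; it is off by default and, when used,
    is an explicit, logged analysis choice.  Failures are re-raised as
    :class:`PipelineStageError` naming the stage that failed.

    Returns the trial's :class:`ParameterSet` averaged over the middle two
    gait cycles.
    """
    try:
        series = compute_angle_series(trial)
        if smooth_window:
            series = {j: smooth_series(s, smooth_window) for j, s in series.items()}
    except GaitError as exc:
        raise PipelineStageError("kinematics", str(exc)) from exc

    try:
        toe_sagittal = trial.sagittal_markers["metatarsal"]
        events = detect_gait_events(toe_sagittal, trial.frame_rate, event_params)
        cycles = segment_cycles(events)
        steady = select_steady_state(cycles)
        left_x = trial.transverse_paws["left_hind"][:, 0]
        left_events = detect_gait_events(left_x, trial.frame_rate, event_params)
        left_stances = list(zip(left_events.footstrikes, left_events.toe_offs))
    except GaitError as exc:
        raise PipelineStageError("events", str(exc)) from exc

    try:
        curves = {
            j: [normalize_cycle(series[j], c) for c in steady] for j in JOINTS
        }
        return summarize_trial(trial, curves, steady, left_stances)
    except GaitError as exc:
        raise PipelineStageError("parameters", str(exc)) from exc
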