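"""Joint angles from marker triplets, and percent-of-cycle normalization.

The interior angle at each joint is computed with the law of cosines from the
Euclidean distances between three markers:

    cos(theta) = (a^2 + b^2 - c^2) / (2 a b)

where ``a`` and ``b`` are the vertex-to-proximal and vertex-to-distal segment
lengths and ``c`` the proximal-to-distal distance.  The result is the 0-180
degree interior angle; by our documented convention ankle dorsiflexion
decreases this angle and plantarflexion increases it.

Joint triplets (proximal, vertex, distal):

* hip   : iliac_crest, hip, knee
* knee  : hip, knee, ankle
* ankle : knee, ankle, metatarsal

Angle traces are time-normalized onto a 101-point 0..100% grid per gait
cycle (the standard convention in gait analysis) by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, MissingDataError, SegmentationError
from .io_markers import TrialRecording

if TYPE_CHECKING:  # pragma: no cover
    from .events import GaitCycle

JOINTS = ("hip", "knee", "ankle")

#: (proximal, vertex, distal) marker names per joint
TRIPLETS: dict[str, tuple[str, str, str]] = {
    "hip": ("iliac_crest", "hip", "knee"),
    "knee": ("hip", "knee", "ankle"),
    "ankle": ("knee", "ankle", "metatarsal"),
}

_EPS_MM = 1e-9  # minimum segment length


def joint_angle(proximal, vertex, distal):
    """Interior angle (degrees) at ``vertex``, by the law of cosines.

    Accepts single points of shape (2,) or stacked frames of shape (n, 2);
    returns a float or an (n,) array.  The cosine argument is clamped to
    [-1, 1] to absorb floating-point overshoot on collinear triples.  Frames
    with any NaN coordinate yield NaN.  A genuinely zero-length segment
    raises :class:`GeometryError` naming the frame.
    """
    p = np.asarray(proximal, dtype=float)
    v = np.asarray(vertex, dtype=float)
    d = np.asarray(distal, dtype=float)
    scalar = p.ndim == 1
    p, v, d = np.atleast_2d(p), np.atleast_2d(v), np.atleast_2d(d)

    a = np.linalg.norm(p - v, axis=1)
    b = np.linalg.norm(d - v, axis=1)
    c = np.linalg.norm(p - d, axis=1)

    valid = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    degenerate = valid & ((a < _EPS_MM) | (b < _EPS_MM))
    if degenerate.any():
        frame = int(np.argwhere(degenerate)[0][0])
        side = "vertex-proximal" if a[frame] < _EPS_MM else "vertex-distal"
        raise GeometryError(
            f"zero-length {side} segment at frame {frame}: "
            "cannot form an interior angle"
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (a**2 + b**2 - c**2) / (2.0 * a * b)
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    angle[~valid] = np.nan
    return float(angle[0]) if scalar else angle


@dataclass
class JointAngleSeries:
    """Per-frame interior angle (degrees) of one joint."""

    joint: str
    angle: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        finite = self.angle[np.isfinite(self.angle)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 180 + 1e-9):
            raise ValueError(
                f"{self.joint}: interior angles must lie in [0, 180] degrees"
            )

    def __len__(self) -> int:
        return len(self.angle)


def compute_angle_series(trial: TrialRecording) -> dict[str, JointAngleSeries]:
    """Hip, knee and ankle angle series for every frame of a trial.

    Frames where any marker of a triplet is missing yield a missing (NaN)
    angle for that joint only; the other joints keep their values if their
    own markers are present.
    """
    out = {}
    for joint, (prox, vert, dist) in TRIPLETS.items():
        try:
            ang = joint_angle(
                trial.sagittal_markers[prox],
                trial.sagittal_markers[vert],
                trial.sagittal_markers[dist],
            )
        except GeometryError as exc:
            raise GeometryError(f"{joint} ({prox}-{vert}-{dist}): {exc}") from exc
        out[joint] = JointAngleSeries(joint=joint, angle=np.atleast_1d(ang),
                                      frame_rate=trial.frame_rate)
    return out


def smooth_series(series: JointAngleSeries, window: int) -> JointAngleSeries:
    """Moving-average smoothing with an odd window (reflected edges).

    Smoothing is never applied implicitly; analyses that use it must pass the
    window explicitly so the choice is visible and logged.
    """
    if window is None or window <= 1:
        return series
    if window % 2 == 0:
        raise ValueError(f"smoothing window must be odd, got {window}")
    n = len(series.angle)
    if n < window:
        return series
    half = window // 2
    padded = np.pad(series.angle, half, mode="reflect")
    kernel = np.ones(window) / window
    smoothed = np.convolve(padded, kernel, mode="valid")
    return replace(series, angle=smoothed)


@dataclass
class NormalizedCurve:
    """One joint-angle trace resampled onto the 0..100% gait-cycle grid."""

    joint: str
    percent: np.ndarray  # 101 points, 0..100
    angle: np.ndarray  # degrees at each grid point

    def __post_init__(self) -> None:
        self.percent = np.asarray(self.percent, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.percent.shape != (101,) or self.angle.shape != (101,):
            raise ValueError("a normalized curve has exactly 101 grid points")


GRID = np.linspace(0.0, 100.0, 101)


def normalize_cycle(series: JointAngleSeries, cycle: "GaitCycle") -> NormalizedCurve:
    """Resample one cycle of an angle series onto the 101-point grid.

    0% is the cycle's opening footstrike frame and 100% the closing
    footstrike; interpolation is linear in frame time.
    """
    start, end = cycle.start_frame, cycle.end_frame
    if end - start < 1:
        raise SegmentationError(
            f"cycle [{start}, {end}] has fewer than 2 frames; cannot normalize"
        )
    if start < 0 or end > len(series.angle) - 1:
        raise SegmentationError(
            f"cycle [{start}, {end}] lies outside the series of length "
            f"{len(series.angle)}"
        )
    positions = start + (end - start) * GRID / 100.0
    frames = np.arange(start, end + 1)
    values = np.interp(positions, frames, series.angle[start : end + 1])
    return NormalizedCurve(joint=series.joint, percent=GRID.copy(), angle=values)


@dataclass
class CurveEnsembleStats:
    """Pointwise mean, SD and SEM over a set of normalized curves."""

    joint: str
    percent: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    sem: np.ndarray
    n: int
    single_curve: bool  # SD/SEM are 0 by convention when n == 1


def mean_sd_curve(curves: Sequence[NormalizedCurve]) -> CurveEnsembleStats:
    """Pointwise mean, sample SD, and SEM of same-joint curves."""
    curves = list(curves)
    if not curves:
        raise ValueError("mean_sd_curve needs at least one curve")
    joints = {c.joint for c in curves}
    if len(joints) != 1:
        raise ValueError(f"cannot mix joints in one ensemble: {sorted(joints)}")
    stack = np.vstack([c.angle for c in curves])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if n > 1 else np.zeros(101)
    sem = sd / np.sqrt(n)
    return CurveEnsembleStats(
        joint=curves[0].joint,
        percent=curves[0].percent.copy(),
        mean=mean,
        sd=sd,
        sem=sem,
        n=n,
        single_curve=(n == 1),
    )


def series_to_frame(series: Iterable[JointAngleSeries]) -> pd.DataFrame:
    """Tidy export: one row per (frame, joint)."""
    rows = []
    for s in series:
        rows.append(
            pd.DataFrame(
                {"frame": np.arange(len(s)), "joint": s.joint, "angle_deg": s.angle}
            )
        )
    return pd.concat(rows, ignore_index=True)


def curves_to_frame(curves: Iterable[NormalizedCurve]) -> pd.DataFrame:
    """Tidy export: one row per (percent, joint)."""
    rows = []
    for c in curves:
        rows.append(
            pd.DataFrame({"percent": c.percent, "joint": c.joint, "angle_deg": c.angle})
        )
    return pd.concat(rows, ignore_index=True)
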