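"""Footstrike / toe-off detection, cycle segmentation, steady-state selection.

A gait cycle runs from one ground strike of a paw to the next strike of the
same paw; toe-off splits it into stance and swing.  Marker-based recordings
carry no force signal, so ground contact is inferred from the paw trajectory:

1.  Coarse stance mask: a frame is stance when the paw's smoothed forward
    speed is below ``speed_threshold`` AND (if a height coordinate is
    available) the paw sits below ``height_threshold`` above the per-trial
    ground line (a low percentile of paw height).  Gaps of up to
    ``merge_gap`` frames inside a stance run are closed, and runs shorter
    than ``min_stance_frames`` are discarded.
2.  Boundary refinement: each run entry/exit is sharpened by a raw per-frame
    displacement test (threshold ``refine_step`` mm per frame) inside a small
    window, because a smoothed speed estimate blurs contact boundaries by
    roughly half the smoothing window.

Events are integer frame indices; sub-frame timing is deliberately not
estimated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    InsufficientCyclesError,
    MalformedEventError,
    MissingDataError,
    NoContactError,
    NoSwingError,
    SegmentationError,
)


@dataclass(frozen=True)
class GaitCycle:
    """One strike-to-strike interval with its interior toe-off.

    Stance is ``[start_frame, toe_off_frame)``; swing is
    ``[toe_off_frame, end_frame)``.
    """

    start_frame: int
    toe_off_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if not (self.start_frame < self.toe_off_frame < self.end_frame):
            raise MalformedEventError(
                f"cycle frames must satisfy start < toe_off < end, got "
                f"{self.start_frame} / {self.toe_off_frame} / {self.end_frame}"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    @property
    def stance_frames(self) -> np.ndarray:
        return np.arange(self.start_frame, self.toe_off_frame)

    @property
    def swing_frames(self) -> np.ndarray:
        return np.arange(self.toe_off_frame, self.end_frame)

    @property
    def duty_factor(self) -> float:
        return (self.toe_off_frame - self.start_frame) / self.n_frames


@dataclass
class EventList:
    """Ordered footstrike and toe-off frame indices for one paw.

    Footstrikes and toe-offs alternate strictly:
    ``strike[i] < toe_off[i] < strike[i+1]``.  A trailing toe-off after the
    final strike is allowed (trial ending in swing); a trial ending in stance
    simply lacks the final toe-off.
    """

    footstrikes: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self) -> None:
        self.footstrikes = np.asarray(self.footstrikes, dtype=int)
        self.toe_offs = np.asarray(self.toe_offs, dtype=int)
        for name, arr in (("footstrikes", self.footstrikes), ("toe_offs", self.toe_offs)):
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                bad = int(np.argwhere(np.diff(arr) <= 0)[0][0])
                raise MalformedEventError(
                    f"{name} must be strictly increasing (violation after "
                    f"frame {arr[bad]})"
                )
        nfs, nto = len(self.footstrikes), len(self.toe_offs)
        if nfs and not (nfs - 1 <= nto <= nfs):
            raise MalformedEventError(
                f"{nto} toe-offs cannot interleave {nfs} footstrikes"
            )
        for i, to in enumerate(self.toe_offs):
            lo = self.footstrikes[i] if i < nfs else -1
            hi = self.footstrikes[i + 1] if i + 1 < nfs else np.inf
            if not (lo < to < hi):
                raise MalformedEventError(
                    f"toe-off at frame {to} does not fall between footstrikes "
                    f"({lo}, {hi})"
                )


@dataclass
class EventDetectionParams:
    """Thresholds for marker-based contact detection (all configurable).

    ``speed_threshold`` (mm/s) and ``height_threshold`` (mm above the ground
    line) gate the coarse stance mask; ``ground_percentile`` estimates the
    ground line from paw height.  ``refine_step`` is the raw per-frame
    displacement (mm) that counts as motion during boundary refinement.
    """

    speed_threshold: float = 15.0
    height_threshold: float = 3.0
    min_stance_frames: int = 3
    ground_percentile: float = 5.0
    smooth_time: float = 0.11  # s; speed-estimate window, scales with fps
    smooth_window: int | None = None  # odd frame count; overrides smooth_time
    merge_gap: int = 2
    refine: bool = True
    refine_window: int | None = None  # default: half the smoothing window + 2
    refine_step: float = 0.3
    refine_noise_mult: float = 3.0


def _fill_nan(x: np.ndarray, what: str) -> np.ndarray:
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    if bad.all():
        raise MissingDataError(f"{what}: all samples missing")
    x = x.copy()
    idx = np.arange(len(x))
    x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


def _close_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill False runs of length <= max_gap that are flanked by True."""
    if max_gap <= 0 or not mask.any():
        return mask
    mask = mask.copy()
    n = len(mask)
    i = 0
    while i < n:
        if not mask[i]:
            j = i
            while j < n and not mask[j]:
                j += 1
            if i > 0 and j < n and (j - i) <= max_gap:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[(start, stop_exclusive)] of maximal True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def detect_gait_events(
    paw_xy: np.ndarray,
    frame_rate: float,
    params: EventDetectionParams | None = None,
) -> EventList:
    """Detect alternating footstrike / toe-off frames from a paw trajectory.

    Parameters
    ----------
    paw_xy : array
        (n, 2) sagittal trajectory with columns (forward x mm, height y mm),
        or a 1-D forward-position array when no height coordinate exists
        (e.g. a transverse-plane paw track); the height gate is then skipped.
    frame_rate : float
        Frames per second.
    params : EventDetectionParams, optional

    Raises
    ------
    NoContactError
        No stance run of the required minimum length was found.
    NoSwingError
        The paw never leaves stance (e.g. a constant-position trace).
    """
    params = params or EventDetectionParams()
    arr = np.asarray(paw_xy, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        x, y = arr[:, 0], arr[:, 1]
    elif arr.ndim == 1:
        x, y = arr, None
    else:
        raise ValueError("paw_xy must be (n, 2) or (n,)")
    n = len(x)
    if n < 2:
        raise SegmentationError("need at least 2 frames to detect events")
    if frame_rate <= 0:
        raise ValueError(f"frame_rate must be > 0, got {frame_rate}")

    x = _fill_nan(x, "paw forward position")
    if y is not None:
        y = _fill_nan(y, "paw height")

    if params.smooth_window is not None:
        w = params.smooth_window
    else:
        w = max(5, int(round(params.smooth_time * frame_rate)))
    if w % 2 == 0:
        w += 1
    w = min(w, n if n % 2 == 1 else n - 1)
    if w >= 3:
        speed = np.abs(
            savgol_filter(x, w, polyorder=1, deriv=1, delta=1.0 / frame_rate)
        )
    else:
        speed = np.abs(np.gradient(x)) * frame_rate

    mask = speed < params.speed_threshold
    height = None
    if y is not None:
        ground = np.percentile(y, params.ground_percentile)
        height = y - ground
        mask &= height < params.height_threshold

    if mask.all():
        raise NoSwingError(
            "paw never leaves stance: trajectory is stationary throughout"
        )
    mask = _close_gaps(mask, params.merge_gap)
    runs = [r for r in _true_runs(mask) if r[1] - r[0] >= params.min_stance_frames]
    if not runs:
        raise NoContactError(
            f"no stance run of >= {params.min_stance_frames} frames found"
        )

    step = np.abs(np.diff(x))  # raw per-frame displacement, mm

    # noise-adaptive refinement threshold: the per-frame displacement that
    # counts as motion must clear the measurement jitter, estimated robustly
    # (MAD) from the displacement of coarse-stance frames
    stance_idx = np.flatnonzero(mask[:-1] & mask[1:])
    noise_est = 1.4826 * np.median(step[stance_idx]) if stance_idx.size else 0.0
    thr = max(params.refine_step, params.refine_noise_mult * noise_est)
    r_win = params.refine_window if params.refine_window is not None else max(5, w // 2 + 2)

    def _refine_strike(e: int) -> int:
        if not params.refine:
            return e
        lo = max(e - r_win, 0)
        hi = min(e + r_win, n - 3)
        for f in range(lo, hi + 1):
            still = step[f] < thr and step[f + 1] < thr
            grounded = height is None or height[f] < params.height_threshold
            if still and grounded:
                return f
        return e

    def _refine_toeoff(t: int, strike: int) -> int:
        if not params.refine:
            return t
        lo = max(t - r_win, strike + 1)
        hi = min(t + r_win, n - 3)
        for f in range(lo, hi + 1):
            moving = step[f] >= thr
            sustained = abs(x[f + 2] - x[f]) >= 1.5 * thr
            if moving and sustained:
                return f
        return t

    footstrikes: list[int] = []
    toe_offs: list[int] = []
    for start, stop in runs:
        strike = _refine_strike(start)
        if footstrikes and strike <= (toe_offs[-1] if toe_offs else -1):
            strike = start  # refinement broke ordering; keep coarse frame
        footstrikes.append(strike)
        if stop < n:  # a run touching the end of data has no observed toe-off
            toff = _refine_toeoff(stop, strike)
            if toff <= strike:
                toff = stop
            toe_offs.append(toff)

    # refinement must not push a toe-off onto / past the next footstrike
    for i in range(len(toe_offs)):
        if i + 1 < len(footstrikes) and toe_offs[i] >= footstrikes[i + 1]:
            toe_offs[i] = footstrikes[i + 1] - 1

    return EventList(footstrikes=np.array(footstrikes), toe_offs=np.array(toe_offs))


def segment_cycles(events: EventList) -> list[GaitCycle]:
    """Build strike-to-strike cycles, each carrying its interior toe-off."""
    fs = events.footstrikes
    if len(fs) < 2:
        raise InsufficientCyclesError(
            f"need at least 2 footstrikes to form a cycle, got {len(fs)}"
        )
    cycles = []
    for i in range(len(fs) - 1):
        inside = events.toe_offs[(events.toe_offs > fs[i]) & (events.toe_offs < fs[i + 1])]
        if len(inside) != 1:
            raise MalformedEventError(
                f"cycle [{fs[i]}, {fs[i + 1]}] must contain exactly one "
                f"toe-off, found {len(inside)}"
            )
        cycles.append(GaitCycle(int(fs[i]), int(inside[0]), int(fs[i + 1])))
    return cycles


def select_steady_state(cycles: Sequence[GaitCycle]) -> list[GaitCycle]:
    """The middle two cycles of a walk (steady-state strides).

    Extracting the central pair excludes the accelerating and decelerating
    portions of the run.  For ``n`` cycles the pair is at 0-based indices
    ``floor((n-2)/2)`` and ``floor((n-2)/2)+1``; for an odd count this is the
    earlier of the two center pairs (deterministic tie-break).
    """
    cycles = list(cycles)
    n = len(cycles)
    if n < 2:
        raise InsufficientCyclesError(
            f"steady-state selection needs >= 2 cycles, got {n}"
        )
    i = (n - 2) // 2
    return [cycles[i], cycles[i + 1]]
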