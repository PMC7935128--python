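"""Synthetic quadruped-gait generator with exact ground truth.

Stands in for treadmill/runway marker recordings: it emits a planar right
hindlimb chain (iliac crest, hip, knee, ankle, 5th metatarsal head) in the
sagittal plane plus both hindpaw tracks in the transverse plane, together
with the true joint-angle waveforms, contact events, and spatial parameters,
so every pipeline stage has a sharp recovery oracle.

Construction (trajectory-first, so stride, width and stance timing are exact
by construction rather than emergent):

1. The pelvis (iliac crest / hip) advances at constant speed with a small
   vertical oscillation (two per stride).
2. The toe (metatarsal marker) has an explicit stance segment - stationary
   on the ground line for ``duty_factor`` of each cycle - and a smooth swing
   arc of height ``swing_clearance`` (cosine-eased forward profile, zero
   velocity at lift-off and touch-down).
3. The ankle is placed from the toe through the foot segment with a
   phase-dependent foot pitch waveform (two harmonics).
4. The knee is solved by two-segment inverse kinematics between hip and
   ankle, on the anatomical knee-forward branch.
5. The left hindpaw mirrors the right at lateral offset ``step_width`` with
   a 50% phase shift.
6. I.i.d. Gaussian noise of SD ``noise_sd`` is added to every marker
   coordinate after the truth is captured.

True joint angles are computed from the noise-free markers with an
atan2-based vector formula - an independent code path from the pipeline's
law-of-cosines route, so agreement between the two is a real consistency
check, not a tautology.

Two phenotype presets encode the qualitative disease directions of a
demyelinating peripheral-neuropathy (Trembler-J-like) model versus control:
wider step width, longer stride, larger ankle excursion with a more
dorsiflexed ankle (lower interior-angle minimum) and a less plantarflexed
swing peak, with the ankle deltas growing with age.  The numeric deltas are
invented calibrations reproducing reported directions, not measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np

from .errors import ConfigError, ReachabilityError
from .io_markers import TrialRecording

PRESETS = ("control", "affected")


@dataclass
class SyntheticGaitConfig:
    """Parameters of one generated walking trial (units: mm, s, degrees)."""

    n_cycles: int = 6
    frames_per_cycle: int = 60
    frame_rate: float = 240.0  # fps; 60 frames/cycle -> 4 Hz stride
    stride_length: float = 60.0
    step_width: float = 15.0
    duty_factor: float = 0.6
    thigh: float = 17.0
    shank: float = 18.0
    foot: float = 10.0
    hip_height: float = 26.0
    hip_osc_amp: float = 0.8  # vertical pelvis oscillation, mm
    pelvis_offset: tuple[float, float] = (6.0, 10.0)  # hip -> iliac crest
    swing_clearance: float = 6.0
    # foot pitch alpha(phi) = mean + a1*cos(2pi(phi-p1)) + a2*cos(4pi(phi-p2)),
    # where alpha is the direction angle (deg, CCW from forward x) of the
    # toe->ankle vector.  Defaults tuned for a gait-like ankle curve with
    # peak plantarflexion near push-off (~60-70% of cycle).
    foot_pitch_mean: float = 115.0
    foot_pitch_amp: tuple[float, float] = (22.0, 6.0)
    foot_pitch_phase: tuple[float, float] = (0.15, 0.55)
    noise_sd: float = 0.0
    seed: int = 0
    preset: str = "custom"
    subject_id: str = "sim"
    age_weeks: int = 14

    def __post_init__(self) -> None:
        if not (0.0 < self.duty_factor < 1.0):
            raise ConfigError(f"duty_factor must be in (0,1), got {self.duty_factor}")
        if self.frames_per_cycle < 10:
            raise ConfigError("frames_per_cycle must be >= 10")
        if min(self.thigh, self.shank, self.foot) <= 0:
            raise ConfigError("segment lengths must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        # trailing partial stance so the final footstrike is observable
        tail = int(round(self.duty_factor * self.frames_per_cycle))
        return self.n_cycles * self.frames_per_cycle + tail

    @property
    def cycle_duration(self) -> float:
        return self.frames_per_cycle / self.frame_rate


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated trial."""

    angles: dict[str, np.ndarray]  # per-frame true joint angles, degrees
    footstrikes: np.ndarray  # frame indices, right hindpaw
    toe_offs: np.ndarray
    stride_length: float
    step_width: float
    duty_factor: float
    joint_extrema: dict[str, tuple[float, float, float]]  # (min, max, rom)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "angles": {k: v.tolist() for k, v in self.angles.items()},
            "footstrikes": self.footstrikes.tolist(),
            "toe_offs": self.toe_offs.tolist(),
            "stride_length": self.stride_length,
            "step_width": self.step_width,
            "duty_factor": self.duty_factor,
            "joint_extrema": {k: list(v) for k, v in self.joint_extrema.items()},
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path


def two_link_ik(hip, ankle, thigh: float, shank: float):
    """Knee position from hip and ankle via planar two-segment IK.

    Returns the knee-forward (anatomical) branch.  Accepts (2,) points or
    (n, 2) stacked frames.  The residuals |hip-knee| - thigh and
    |knee-ankle| - shank are < 1e-9 mm for reachable poses.

    Raises
    ------
    ReachabilityError
        If |hip - ankle| exceeds thigh + shank or falls below |thigh - shank|,
        naming the first offending frame.
    """
    hip = np.asarray(hip, dtype=float)
    ankle = np.asarray(ankle, dtype=float)
    scalar = hip.ndim == 1
    hip, ankle = np.atleast_2d(hip), np.atleast_2d(ankle)

    d = ankle - hip
    c = np.linalg.norm(d, axis=1)
    lo, hi = abs(thigh - shank), thigh + shank
    bad = (c > hi * (1 + 1e-12)) | (c < lo * (1 - 1e-12))
    if bad.any():
        f = int(np.argwhere(bad)[0][0])
        raise ReachabilityError(
            f"hip-ankle distance {c[f]:.6g} mm at frame {f} outside the "
            f"reachable range [{lo:.6g}, {hi:.6g}] mm"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cosg = (thigh**2 + c**2 - shank**2) / (2.0 * thigh * c)
    gamma = np.arccos(np.clip(cosg, -1.0, 1.0))
    u = d / c[:, None]
    # rotate u CCW by gamma: with d pointing downward this lands the knee
    # anterior to the hip-ankle line (knee-forward branch)
    rot = np.empty_like(u)
    rot[:, 0] = u[:, 0] * np.cos(gamma) - u[:, 1] * np.sin(gamma)
    rot[:, 1] = u[:, 0] * np.sin(gamma) + u[:, 1] * np.cos(gamma)
    knee = hip + thigh * rot
    return knee[0] if scalar else knee


def _vector_angle_deg(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Interior angle between stacked 2-D vectors via atan2(|cross|, dot).

    Independent of the law-of-cosines route used by the analysis pipeline.
    """
    cross = u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0]
    dot = u[:, 0] * w[:, 0] + u[:, 1] * w[:, 1]
    return np.degrees(np.arctan2(np.abs(cross), dot))


def _swing_profile(s: np.ndarray) -> np.ndarray:
    """Forward progress through swing: cosine-eased, zero end velocities."""
    return 0.5 * (1.0 - np.cos(np.pi * s))


def _swing_height(s: np.ndarray) -> np.ndarray:
    """Swing arc shape: 0 at both ends with zero slope, peak 1 mid-swing."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * s))


def _toe_path(phi_total: np.ndarray, cfg: SyntheticGaitConfig):
    """Right-toe forward position and height at continuous cycle phase."""
    k = np.floor(phi_total)
    phi = phi_total - k
    S, duty = cfg.stride_length, cfg.duty_factor
    swing = phi >= duty
    s = np.where(swing, (phi - duty) / (1.0 - duty), 0.0)
    x = k * S + swing * S * _swing_profile(s)
    yv = swing * cfg.swing_clearance * _swing_height(s)
    return x, yv


def _foot_pitch_rad(phi: np.ndarray, cfg: SyntheticGaitConfig) -> np.ndarray:
    a1, a2 = cfg.foot_pitch_amp
    p1, p2 = cfg.foot_pitch_phase
    deg = (
        cfg.foot_pitch_mean
        + a1 * np.cos(2.0 * np.pi * (phi - p1))
        + a2 * np.cos(4.0 * np.pi * (phi - p2))
    )
    return np.radians(deg)


def _chain_at(phi_total: np.ndarray, cfg: SyntheticGaitConfig):
    """All sagittal marker positions at continuous cycle phase (noise-free)."""
    S, duty = cfg.stride_length, cfg.duty_factor
    toe_x, toe_y = _toe_path(phi_total, cfg)
    # mid-stance the hip stands directly above the planted toe
    hip_x = S * phi_total - duty * S / 2.0
    hip_y = cfg.hip_height + cfg.hip_osc_amp * np.cos(4.0 * np.pi * phi_total)
    hip = np.column_stack([hip_x, hip_y])

    phi = phi_total - np.floor(phi_total)
    alpha = _foot_pitch_rad(phi, cfg)
    toe = np.column_stack([toe_x, toe_y])
    ankle = toe + cfg.foot * np.column_stack([np.cos(alpha), np.sin(alpha)])

    knee = two_link_ik(hip, ankle, cfg.thigh, cfg.shank)
    iliac = hip + np.asarray(cfg.pelvis_offset)
    return {"iliac_crest": iliac, "hip": hip, "knee": knee, "ankle": ankle,
            "metatarsal": toe}


def _true_angles(markers: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {
        "hip": _vector_angle_deg(
            markers["iliac_crest"] - markers["hip"], markers["knee"] - markers["hip"]
        ),
        "knee": _vector_angle_deg(
            markers["hip"] - markers["knee"], markers["ankle"] - markers["knee"]
        ),
        "ankle": _vector_angle_deg(
            markers["knee"] - markers["ankle"],
            markers["metatarsal"] - markers["ankle"],
        ),
    }


def _true_events(cfg: SyntheticGaitConfig):
    """Contact-onset and lift-off frames of the right toe, by construction.

    A frame is in contact when the toe sits at its stance position on the
    ground line; the toe-off is the first frame with any displacement or
    elevation (at integer duty*frames_per_cycle the nominal phase boundary
    frame is still geometrically grounded and counts as stance).
    """
    frames = np.arange(cfg.n_frames)
    phi_total = frames / cfg.frames_per_cycle
    x, y = _toe_path(phi_total, cfg)
    k = np.floor(phi_total)
    displaced = (x - k * cfg.stride_length > 1e-9) | (y > 1e-9)
    contact = ~displaced
    onset = contact & ~np.concatenate(([False], contact[:-1]))
    liftoff = ~contact & np.concatenate(([False], contact[:-1]))
    return frames[onset], frames[liftoff]


def _truth_extrema(cfg: SyntheticGaitConfig, n_dense: int = 2000):
    """Per-joint (min, max, rom) over one cycle on a dense phase grid."""
    phi = np.linspace(1.0, 2.0, n_dense, endpoint=False)  # interior cycle
    markers = _chain_at(phi, cfg)
    angles = _true_angles(markers)
    out = {}
    for joint, ang in angles.items():
        lo, hi = float(ang.min()), float(ang.max())
        out[joint] = (lo, hi, hi - lo)
    return out


def generate_trial(
    config: SyntheticGaitConfig, rng: np.random.Generator | None = None
) -> tuple[TrialRecording, SyntheticTruth]:
    """Generate one trial and its ground truth.

    Deterministic given the config (noise is drawn from ``config.seed``
    unless an explicit generator is supplied).  Raises
    :class:`ReachabilityError` naming the first frame at which the hip-ankle
    distance leaves the two-segment reach.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    frames = np.arange(cfg.n_frames)
    phi_total = frames / cfg.frames_per_cycle
    markers = _chain_at(phi_total, cfg)  # raises ReachabilityError if invalid

    angles = _true_angles(markers)
    footstrikes, toe_offs = _true_events(cfg)
    truth = SyntheticTruth(
        angles=angles,
        footstrikes=footstrikes,
        toe_offs=toe_offs,
        stride_length=cfg.stride_length,
        step_width=cfg.step_width,
        duty_factor=cfg.duty_factor,
        joint_extrema=_truth_extrema(cfg),
    )

    # transverse paw tracks: right at +W/2, left mirrored at 50% phase shift
    left_x, _ = _toe_path(phi_total + 0.5, cfg)
    left_x = left_x - cfg.stride_length / 2.0
    right_t = np.column_stack(
        [markers["metatarsal"][:, 0], np.full(cfg.n_frames, cfg.step_width / 2.0)]
    )
    left_t = np.column_stack([left_x, np.full(cfg.n_frames, -cfg.step_width / 2.0)])

    sagittal = {k: v.copy() for k, v in markers.items()}
    transverse = {"right_hind": right_t, "left_hind": left_t}
    if cfg.noise_sd > 0:
        for d in (sagittal, transverse):
            for k in d:
                d[k] = d[k] + rng.normal(0.0, cfg.noise_sd, size=d[k].shape)

    trial = TrialRecording(
        subject_id=cfg.subject_id,
        group_label=cfg.preset,
        age_weeks=cfg.age_weeks,
        frame_rate=cfg.frame_rate,
        sagittal_markers=sagittal,
        transverse_paws=transverse,
    )
    return trial, truth


# --- phenotype presets -----------------------------------------------------

# Invented calibrations reproducing the reported qualitative directions of
# the affected (Trembler-J-like) phenotype relative to control; the source
# study prints no numeric gait values, so magnitudes are package constants.
AFFECTED_STEP_WIDTH_FACTOR = 1.30  # wider base of support
AFFECTED_STRIDE_FACTOR = 1.15  # longer stride (delayed push-off)
AFFECTED_ANKLE_AMP_FACTOR = 1.6  # larger ankle excursion -> greater ROM
AFFECTED_ANKLE_MEAN_SHIFT = +7.0  # deg of foot pitch: drops the interior-angle
#   maximum (less plantarflexed swing) while the bigger amplitude drops the
#   minimum further (more dorsiflexed terminal stance)
AFFECTED_HIP_OSC_FACTOR = 1.5  # more fluctuating hip


def _age_scale(age_weeks: int) -> float:
    """0.5 at 6 weeks rising to 1.0 at >= 14 weeks (progressive phenotype)."""
    g = min(max((age_weeks - 6.0) / 8.0, 0.0), 1.0)
    return 0.5 + 0.5 * g


def make_preset(name: str, age_weeks: int = 14, **overrides) -> SyntheticGaitConfig:
    """A ready-made control-like or affected-like trial configuration.

    The affected preset differs from control by the documented multiplicative
    and additive deltas above; ankle and hip deltas scale with age to mimic
    a progressive phenotype.  Extra keyword arguments override any config
    field (e.g. ``noise_sd``, ``n_cycles``, ``seed``).
    """
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESETS}")
    if age_weeks <= 0:
        raise ConfigError(f"age_weeks must be positive, got {age_weeks}")
    cfg = SyntheticGaitConfig(preset=name, age_weeks=age_weeks)
    if name == "affected":
        a = _age_scale(age_weeks)
        amp1, amp2 = cfg.foot_pitch_amp
        cfg = replace(
            cfg,
            step_width=cfg.step_width * AFFECTED_STEP_WIDTH_FACTOR,
            stride_length=cfg.stride_length * AFFECTED_STRIDE_FACTOR,
            foot_pitch_amp=(amp1 * (1.0 + (AFFECTED_ANKLE_AMP_FACTOR - 1.0) * a), amp2),
            foot_pitch_mean=cfg.foot_pitch_mean + AFFECTED_ANKLE_MEAN_SHIFT * a,
            hip_osc_amp=cfg.hip_osc_amp * (1.0 + (AFFECTED_HIP_OSC_FACTOR - 1.0) * a),
        )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def sample_subject_config(
    base: SyntheticGaitConfig,
    rng: np.random.Generator,
    cv: float = 0.05,
    anatomy_cv: float = 0.02,
    subject_id: str = "sim",
) -> SyntheticGaitConfig:
    """Perturb a preset into one animal's parameters (between-mouse variation).

    Stride, step width, ankle amplitude and swing clearance get independent
    lognormal multipliers of coefficient of variation ``cv``; the foot-pitch
    mean gets additive N(0, 1.5 deg) jitter.  Hip height uses the smaller
    ``anatomy_cv`` (default 2%): standing posture is tightly conserved in
    age-matched inbred littermates, while gait-style parameters vary more.
    """
    def mult(c: float | None = None) -> float:
        return float(np.exp(rng.normal(0.0, cv if c is None else c)))

    amp1, amp2 = base.foot_pitch_amp
    return replace(
        base,
        subject_id=subject_id,
        stride_length=base.stride_length * mult(),
        step_width=base.step_width * mult(),
        foot_pitch_amp=(amp1 * mult(), amp2),
        foot_pitch_mean=base.foot_pitch_mean + float(rng.normal(0.0, 1.5)),
        swing_clearance=base.swing_clearance * mult(),
        hip_height=base.hip_height * mult(anatomy_cv),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
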