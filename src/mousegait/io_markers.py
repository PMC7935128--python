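"""Trial recordings and their on-disk CSV dialect.

A trial is one walk of one mouse: five sagittal-plane markers of the right
hindlimb (iliac crest, hip, knee, ankle, 5th metatarsal head) plus the
transverse-plane positions of both hindpaws, sampled at a fixed frame rate.

On-disk dialect
---------------
Wide CSV, one row per frame, comma separated, "." decimal, ``NA`` missing
token.  Columns are ``frame`` plus ``<marker>_x`` / ``<marker>_y`` for each
sagittal marker and ``rpaw_x/rpaw_y/lpaw_x/lpaw_y`` for the paws.  Header
comment lines (``# key: value``) carry subject metadata, the frame rate, and
the numeric precision.  Values are written with 12 significant digits so a
write/read round trip reproduces coordinates to better than 1e-9 mm.

Coordinate conventions (the tracker defines none, so we do): sagittal
x = direction of travel (anterior positive), y = vertical up; transverse
x = direction of travel, y = lateral with right positive.  Units are
millimetres internally; ``TrialConfig.unit_scale`` converts on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, EmptyInputError, FormatError

SAGITTAL_MARKERS = ("iliac_crest", "hip", "knee", "ankle", "metatarsal")
TRANSVERSE_PAWS = ("right_hind", "left_hind")

#: default CSV column pair for each marker / paw role
DEFAULT_COLUMNS: dict[str, tuple[str, str]] = {
    **{m: (f"{m}_x", f"{m}_y") for m in SAGITTAL_MARKERS},
    "right_hind": ("rpaw_x", "rpaw_y"),
    "left_hind": ("lpaw_x", "lpaw_y"),
}

_PRECISION = "%.12g"  # 12 significant digits; see round-trip guarantee above


@dataclass
class TrialConfig:
    """How to interpret a trial CSV.

    ``frame_rate`` is required (the recording hardware's fps is not stored in
    generic tracker exports); ``unit_scale`` multiplies raw coordinates into
    millimetres.  ``marker_column_map`` maps each required marker role to its
    (x, y) column pair and must cover every role exactly once.
    """

    frame_rate: float | None = None
    unit_scale: float = 1.0
    marker_column_map: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_COLUMNS)
    )
    subject_id: str | None = None
    group_label: str | None = None
    age_weeks: int | None = None

    def __post_init__(self) -> None:
        required = set(SAGITTAL_MARKERS) | set(TRANSVERSE_PAWS)
        mapped = set(self.marker_column_map)
        missing = required - mapped
        if missing:
            raise ConfigError(
                f"marker_column_map lacks required roles: {sorted(missing)}"
            )
        cols = [c for pair in self.marker_column_map.values() for c in pair]
        if len(cols) != len(set(cols)):
            raise ConfigError("marker_column_map assigns one column to two roles")
        if self.unit_scale <= 0:
            raise ConfigError(f"unit_scale must be > 0, got {self.unit_scale}")
        if self.frame_rate is not None and self.frame_rate <= 0:
            raise ConfigError(f"frame_rate must be > 0, got {self.frame_rate}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("frame_rate", "unit_scale", "subject_id", "group_label", "age_weeks"):
            if key in raw:
                kwargs[key] = raw[key]
        if "marker_column_map" in raw:
            kwargs["marker_column_map"] = {
                role: tuple(pair) for role, pair in raw["marker_column_map"].items()
            }
        return cls(**kwargs)


@dataclass
class TrialRecording:
    """All marker trajectories for one walk of one mouse.

    ``sagittal_markers`` maps the five marker names to (n_frames, 2) arrays of
    (x, y) mm; ``transverse_paws`` maps right_hind/left_hind to (n_frames, 2)
    arrays of (x, y_lateral) mm.  Missing samples are NaN, never silent zeros.
    """

    subject_id: str
    group_label: str
    age_weeks: int
    frame_rate: float
    sagittal_markers: dict[str, np.ndarray]
    transverse_paws: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise FormatError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.age_weeks is not None and self.age_weeks <= 0:
            raise FormatError(f"age_weeks must be positive, got {self.age_weeks}")
        if set(self.sagittal_markers) != set(SAGITTAL_MARKERS):
            raise FormatError(
                "sagittal_markers must contain exactly "
                f"{sorted(SAGITTAL_MARKERS)}, got {sorted(self.sagittal_markers)}"
            )
        if set(self.transverse_paws) != set(TRANSVERSE_PAWS):
            raise FormatError(
                f"transverse_paws must contain exactly {sorted(TRANSVERSE_PAWS)}"
            )
        lengths = set()
        for name, arr in list(self.sagittal_markers.items()) + list(
            self.transverse_paws.items()
        ):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise FormatError(f"trajectory '{name}' must have shape (n, 2)")
            if np.isinf(arr).any():
                bad = int(np.argwhere(np.isinf(arr).any(axis=1))[0][0])
                raise FormatError(
                    f"trajectory '{name}' has a non-finite (inf) value at frame {bad}"
                )
            if name in self.sagittal_markers:
                self.sagittal_markers[name] = arr
            else:
                self.transverse_paws[name] = arr
            lengths.add(len(arr))
        if len(lengths) != 1:
            raise FormatError(
                f"all trajectories must share one length, got lengths {sorted(lengths)}"
            )
        if lengths == {0}:
            raise EmptyInputError("trial has zero frames")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.sagittal_markers.values())))

    def copy(self) -> "TrialRecording":
        return TrialRecording(
            subject_id=self.subject_id,
            group_label=self.group_label,
            age_weeks=self.age_weeks,
            frame_rate=self.frame_rate,
            sagittal_markers={k: v.copy() for k, v in self.sagittal_markers.items()},
            transverse_paws={k: v.copy() for k, v in self.transverse_paws.items()},
        )


def _parse_header_comments(lines: list[str]) -> dict[str, str]:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    return meta


def read_trial(path: str | Path, config: TrialConfig | None = None) -> TrialRecording:
    """Read a trial CSV into a validated :class:`TrialRecording`.

    File header comments supply subject metadata and frame rate; values in
    ``config`` override them.  ``unit_scale`` is applied to all coordinates.

    Raises
    ------
    FormatError
        Missing required column (named), non-monotone or duplicated frame
        index, or malformed values.
    EmptyInputError
        The file has no data rows.
    """
    config = config or TrialConfig()
    path = Path(path)
    text = path.read_text()
    comment_lines = [l for l in text.splitlines() if l.startswith("#")]
    meta = _parse_header_comments(comment_lines)

    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    try:
        df = pd.read_csv(io.StringIO(body), na_values=["NA"], skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data rows") from None
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    if "frame" in df.columns:
        frames = df["frame"].to_numpy()
        if len(np.unique(frames)) != len(frames):
            dup = int(frames[pd.Series(frames).duplicated()].min())
            raise FormatError(f"{path}: duplicated frame index {dup}")
        if np.any(np.diff(frames) <= 0):
            bad = int(np.argwhere(np.diff(frames) <= 0)[0][0])
            raise FormatError(
                f"{path}: non-monotone frame index at row {bad + 1} "
                f"(frame {frames[bad + 1]!r} after {frames[bad]!r})"
            )

    def _columns(role: str) -> np.ndarray:
        xcol, ycol = config.marker_column_map[role]
        for col in (xcol, ycol):
            if col not in df.columns:
                raise FormatError(
                    f"{path}: missing required column '{col}' for marker '{role}'"
                )
        arr = df[[xcol, ycol]].to_numpy(dtype=float)
        return arr * config.unit_scale

    frame_rate = config.frame_rate
    if frame_rate is None and "frame_rate" in meta:
        frame_rate = float(meta["frame_rate"])
    if frame_rate is None:
        raise ConfigError(
            f"{path}: frame_rate not in config and not in file header"
        )

    age = config.age_weeks
    if age is None and "age_weeks" in meta:
        age = int(meta["age_weeks"])

    return TrialRecording(
        subject_id=config.subject_id or meta.get("subject_id", path.stem),
        group_label=config.group_label or meta.get("group_label", "unknown"),
        age_weeks=age if age is not None else 1,
        frame_rate=float(frame_rate),
        sagittal_markers={m: _columns(m) for m in SAGITTAL_MARKERS},
        transverse_paws={p: _columns(p) for p in TRANSVERSE_PAWS},
    )


def write_trial(trial: TrialRecording, path: str | Path) -> Path:
    """Write a trial in the CSV dialect; ``read_trial`` inverts it.

    Values are written with 12 significant digits (stated in the header
    comment), so the round trip reproduces coordinates to <1e-9 mm for
    laboratory-scale magnitudes.  Missing samples are written as ``NA``.
    """
    path = Path(path)
    cols: dict[str, np.ndarray] = {"frame": np.arange(trial.n_frames)}
    for role in SAGITTAL_MARKERS:
        xcol, ycol = DEFAULT_COLUMNS[role]
        cols[xcol] = trial.sagittal_markers[role][:, 0]
        cols[ycol] = trial.sagittal_markers[role][:, 1]
    for role in TRANSVERSE_PAWS:
        xcol, ycol = DEFAULT_COLUMNS[role]
        cols[xcol] = trial.transverse_paws[role][:, 0]
        cols[ycol] = trial.transverse_paws[role][:, 1]
    df = pd.DataFrame(cols)

    header = (
        "# mousegait trial v1\n"
        "# precision: 12 significant digits\n"
        "# units: mm\n"
        f"# subject_id: {trial.subject_id}\n"
        f"# group_label: {trial.group_label}\n"
        f"# age_weeks: {trial.age_weeks}\n"
        f"# frame_rate: {trial.frame_rate!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format=_PRECISION, na_rep="NA")
    return path
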