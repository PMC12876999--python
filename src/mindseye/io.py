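"""Domain types, screen geometry, and fixation-report / raw-sample IO.

Coordinates are screen pixels with the origin at the top-left corner,
x increasing rightward and y downward, 0-based; positions may be
fractional.  Times are milliseconds.  The degree-to-pixel conversion uses
the exact tangent chord formula with the pixel pitch fixed by a
calibration pair (an angle and the on-screen extent it subtends), rather
than a small-angle linear scale, so it stays principled at large
eccentricities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError, FormatError, InputError

PHASES = ("encoding", "imagery", "reinspection")
CONDITIONS = ("FP", "GCW", "AS")
CATEGORIES = ("abstract", "indoor", "outdoor")

#: Canonical fixation-report columns, in writing order.
REPORT_COLUMNS = (
    "participant",
    "trial",
    "phase",
    "condition",
    "category",
    "onset_ms",
    "duration_ms",
    "x_px",
    "y_px",
)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry plus a degree<->pixel calibration.

    Parameters
    ----------
    width_px, height_px
        Screen resolution in pixels.
    viewing_distance_mm
        Eye-to-screen distance in millimetres.
    px_per_deg_calibration
        Pair ``(angle_deg, extent_px)`` fixing the pixel pitch: the chord
        subtended by ``angle_deg`` at the viewing distance measures
        ``extent_px`` pixels.  Default reproduces a 5 degree aperture of
        270 px at 855 mm on a 1920x1080 display.
    """

    width_px: int = 1920
    height_px: int = 1080
    viewing_distance_mm: float = 855.0
    px_per_deg_calibration: tuple[float, float] = (5.0, 270.0)

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise InputError("screen resolution must be positive")
        if self.viewing_distance_mm <= 0:
            raise InputError("viewing distance must be positive")
        angle, extent = self.px_per_deg_calibration
        if angle <= 0 or extent <= 0:
            raise InputError("calibration angle and extent must be positive")

    @property
    def pixel_pitch_mm(self) -> float:
        """Physical size of one pixel, fixed by the calibration pair."""
        angle, extent = self.px_per_deg_calibration
        chord = 2.0 * self.viewing_distance_mm * math.tan(math.radians(angle) / 2.0)
        return chord / extent

    @property
    def diagonal_px(self) -> float:
        return math.hypot(self.width_px, self.height_px)

    def contains(self, x_px: float, y_px: float) -> bool:
        """True if the point lies on the half-open screen [0,w) x [0,h)."""
        return 0 <= x_px < self.width_px and 0 <= y_px < self.height_px


def deg_to_px(angle_deg: float, geometry: ScreenGeometry, *, round_result: bool = True):
    """Convert a visual angle to an on-screen extent in pixels.

    Uses the chord formula ``extent = 2 d tan(angle/2) / pitch``; the result
    is rounded half-up to an integer pixel count unless ``round_result`` is
    False.
    """
    if not math.isfinite(angle_deg) or angle_deg < 0:
        raise InputError(f"angle must be finite and non-negative, got {angle_deg!r}")
    chord_mm = 2.0 * geometry.viewing_distance_mm * math.tan(math.radians(angle_deg) / 2.0)
    px = chord_mm / geometry.pixel_pitch_mm
    return _round_half_up(px) if round_result else px


def px_to_deg(extent_px: float, geometry: ScreenGeometry) -> float:
    """Exact inverse of the unrounded :func:`deg_to_px`."""
    if not math.isfinite(extent_px) or extent_px < 0:
        raise InputError(f"extent must be finite and non-negative, got {extent_px!r}")
    half_chord_mm = extent_px * geometry.pixel_pitch_mm / 2.0
    return math.degrees(2.0 * math.atan(half_chord_mm / geometry.viewing_distance_mm))


@dataclass(frozen=True)
class Fixation:
    """One detected fixation: onset and duration in ms, position in px."""

    onset_ms: float
    duration_ms: float
    x_px: float
    y_px: float

    def __post_init__(self) -> None:
        if self.onset_ms < 0:
            raise InputError(f"onset_ms must be >= 0, got {self.onset_ms}")
        if self.duration_ms <= 0:
            raise InputError(f"duration_ms must be > 0, got {self.duration_ms}")


@dataclass
class Scanpath:
    """Ordered fixation sequence for one participant x trial x phase."""

    participant_id: str
    trial_id: str
    phase: str
    condition: str
    category: str
    fixations: list[Fixation]
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        onsets = [f.onset_ms for f in self.fixations]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise DataError(
                f"fixation onsets must be strictly increasing in "
                f"({self.participant_id}, {self.trial_id}, {self.phase})"
            )

    def __len__(self) -> int:
        return len(self.fixations)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.participant_id, self.trial_id, self.phase)

    def positions(self) -> np.ndarray:
        """(n, 2) array of fixation x/y positions."""
        return np.array([[f.x_px, f.y_px] for f in self.fixations], dtype=float).reshape(-1, 2)

    def durations(self) -> np.ndarray:
        return np.array([f.duration_ms for f in self.fixations], dtype=float)

    def onsets(self) -> np.ndarray:
        return np.array([f.onset_ms for f in self.fixations], dtype=float)

    def with_fixations(self, fixations: list[Fixation]) -> "Scanpath":
        return replace(self, fixations=list(fixations))


@dataclass
class RawSampleTrack:
    """Raw gaze samples: time, position, and a pupil-validity flag."""

    times_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.times_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise InputError("raw track vectors must have equal length")
        if n > 1 and np.any(np.diff(self.times_ms) <= 0):
            raise DataError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_ms)


# ---------------------------------------------------------------------------
# Fixation-report IO
# ---------------------------------------------------------------------------

_DIALECT_SEP = {"tsv": "\t", "csv": ","}


def _format_row(sp: Scanpath, fx: Fixation, extra_cols: list[str], extras: list) -> list[str]:
    row = [
        sp.participant_id,
        sp.trial_id,
        sp.phase,
        sp.condition,
        sp.category,
        f"{int(round(fx.onset_ms))}",
        f"{int(round(fx.duration_ms))}",
        f"{fx.x_px:.2f}",
        f"{fx.y_px:.2f}",
    ]
    row.extend(str(v) for v in extras)
    return row


def write_fixation_report(scanpaths, path, dialect: str = "tsv") -> None:
    """Write scanpaths as a delimited fixation report (one row per fixation).

    Column order is fixed; positions are formatted with 2 decimals and times
    as integers, so writing is deterministic and round-trips with
    :func:`read_fixation_report`.  Unknown columns carried in
    ``Scanpath.annotations['extra_columns']`` are appended verbatim.
    """
    if dialect not in _DIALECT_SEP:
        raise FormatError(f"unknown dialect {dialect!r}")
    sep = _DIALECT_SEP[dialect]
    extra_cols: list[str] = []
    for sp in scanpaths:
        for col in sp.annotations.get("extra_columns", {}):
            if col not in extra_cols:
                extra_cols.append(col)
    lines = [sep.join(list(REPORT_COLUMNS) + extra_cols)]
    for sp in scanpaths:
        extra_map = sp.annotations.get("extra_columns", {})
        for i, fx in enumerate(sp.fixations):
            extras = [extra_map[c][i] if c in extra_map else "" for c in extra_cols]
            lines.append(sep.join(_format_row(sp, fx, extra_cols, extras)))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")


def read_fixation_report(path, dialect: str | None = None,
                         geometry: ScreenGeometry | None = None) -> list[Scanpath]:
    """Read a delimited fixation report into a list of scanpaths.

    Rows are grouped by (participant, trial, phase) in order of first
    appearance; onsets must already be sorted within each group.  The
    canonical dialect is tab-separated; comma-separated files are accepted
    (auto-detected from the header when ``dialect`` is None).
    """
    geometry = geometry or ScreenGeometry()
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file, header row required")
    if dialect is None:
        dialect = "tsv" if "\t" in lines[0] else "csv"
    if dialect not in _DIALECT_SEP:
        raise FormatError(f"unknown dialect {dialect!r}")
    sep = _DIALECT_SEP[dialect]
    header = lines[0].split(sep)
    missing = [c for c in REPORT_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {', '.join(missing)}")
    idx = {c: header.index(c) for c in header}
    extra_cols = [c for c in header if c not in REPORT_COLUMNS]

    groups: dict[tuple[str, str, str], dict] = {}
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(sep)
        if len(cells) != len(header):
            raise FormatError(f"{path}:{ln}: expected {len(header)} cells, got {len(cells)}")
        rec = {c: cells[idx[c]] for c in header}
        key = (rec["participant"], rec["trial"], rec["phase"])
        grp = groups.setdefault(
            key,
            {"condition": rec["condition"], "category": rec["category"],
             "fixations": [], "extras": {c: [] for c in extra_cols}},
        )
        try:
            fx = Fixation(
                onset_ms=float(rec["onset_ms"]),
                duration_ms=float(rec["duration_ms"]),
                x_px=float(rec["x_px"]),
                y_px=float(rec["y_px"]),
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from None
        if grp["fixations"] and fx.onset_ms <= grp["fixations"][-1].onset_ms:
            raise DataError(
                f"{path}: non-monotone onsets in group {key} "
                f"({grp['fixations'][-1].onset_ms} then {fx.onset_ms})"
            )
        grp["fixations"].append(fx)
        for c in extra_cols:
            grp["extras"][c].append(rec[c])

    out = []
    for (pid, trial, phase), grp in groups.items():
        ann = {}
        if extra_cols:
            ann["extra_columns"] = grp["extras"]
        out.append(
            Scanpath(
                participant_id=pid, trial_id=trial, phase=phase,
                condition=grp["condition"], category=grp["category"],
                fixations=grp["fixations"], geometry=geometry, annotations=ann,
            )
        )
    return out


def write_raw_track(track: RawSampleTrack, path) -> None:
    """Write raw samples as TSV ``time_ms  x_px  y_px  valid``."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("time_ms\tx_px\ty_px\tvalid\n")
        for t, x, y, v in zip(track.times_ms, track.x_px, track.y_px, track.valid):
            fh.write(f"{t:g}\t{x:.3f}\t{y:.3f}\t{int(v)}\n")


def read_raw_track(path) -> RawSampleTrack:
    """Read a raw-sample TSV written by :func:`write_raw_track`."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t") != ["time_ms", "x_px", "y_px", "valid"]:
        raise FormatError(f"{path}: expected header 'time_ms\\tx_px\\ty_px\\tvalid'")
    data = [ln.split("\t") for ln in lines[1:] if ln.strip()]
    arr = np.array(data, dtype=float)
    if arr.size == 0:
        arr = arr.reshape(0, 4)
    return RawSampleTrack(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3] != 0)
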