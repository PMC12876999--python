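"""Recurrence quantification analysis (RQA) of fixation sequences.

Two fixations are *recurrent* when the Euclidean distance between their
screen positions is at or below a radius eps (default 2.5 deg of visual
angle, 135 px at the reference geometry).  The boolean recurrence matrix
R[i, j] = (||x_i - x_j|| <= eps) is symmetric with an all-true main
diagonal of self-recurrence.  From it we compute:

recurrence rate
    100 * 2R / (n(n-1)), with R the number of recurrent pairs in the
    strict upper triangle — the proportion of fixation pairs that are
    refixations of the same region.
determinism (DET)
    the percentage of upper-triangle recurrence points lying on diagonal
    runs of length >= l_min: refixations that repeat in the same
    sequential order as the original fixations.
laminarity (LAM)
    100 * (H + V) / (2R), where V counts upper-triangle points on vertical
    runs of length >= l_min and H those on horizontal runs: clustered
    dwells where a region is reinspected with consecutive fixations.

Conventions pinned here (the usual printed formulas leave them open):
runs are scanned along full rows/columns with the self-recurrence cells
acting as run members but never being counted; only strict-upper-triangle
points enter any count; all measures return 0 (with ``degenerate=True``)
when there is no recurrence at all.  The radius comparison is inclusive,
so a pair at exactly eps is recurrent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InputError
from .io import Scanpath, ScreenGeometry, deg_to_px


@dataclass(frozen=True)
class RQAConfig:
    """Radius and line-length settings for RQA.

    ``radius_px`` overrides the degree-based radius when given; otherwise
    the radius is ``deg_to_px(radius_deg, geometry)`` (135 px at the
    default geometry).
    """

    radius_deg: float = 2.5
    radius_px: float | None = None
    l_min: int = 2

    def __post_init__(self) -> None:
        if self.radius_deg <= 0 or (self.radius_px is not None and self.radius_px <= 0):
            raise InputError("recurrence radius must be positive")
        if self.l_min < 2:
            raise InputError("l_min must be >= 2")

    def resolve_radius_px(self, geometry: ScreenGeometry) -> float:
        if self.radius_px is not None:
            return float(self.radius_px)
        return float(deg_to_px(self.radius_deg, geometry))


@dataclass(frozen=True)
class RecurrencePlot:
    matrix: np.ndarray  # (n, n) bool, symmetric, all-true diagonal
    n: int

    @property
    def rec_count(self) -> int:
        """Recurrent pairs in the strict upper triangle."""
        iu = np.triu_indices(self.n, k=1)
        return int(self.matrix[iu].sum())


@dataclass(frozen=True)
class RQAResult:
    n: int
    rec_count: int
    recurrence_rate: float  # %
    determinism: float      # %
    laminarity: float       # %
    fixation_spread: float  # px
    degenerate: bool = False  # True when rec_count == 0 and DET/LAM default to 0


def recurrence_matrix(scanpath: Scanpath, config: RQAConfig | None = None) -> RecurrencePlot:
    """Boolean recurrence matrix of a scanpath (inclusive radius)."""
    config = config or RQAConfig()
    n = len(scanpath)
    if n < 2:
        raise InputError(f"need at least 2 fixations, got {n}")
    eps = config.resolve_radius_px(scanpath.geometry)
    d = squareform(pdist(scanpath.positions()))
    return RecurrencePlot(matrix=d <= eps, n=n)


def recurrence_rate(plot: RecurrencePlot) -> float:
    """Percentage of recurrent fixation pairs: 100 * 2R / (n(n-1))."""
    if plot.n < 2:
        raise InputError("recurrence rate undefined for n < 2")
    return 100.0 * 2.0 * plot.rec_count / (plot.n * (plot.n - 1))


def _run_lengths(line: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of maximal runs of True in a 1-D boolean array."""
    runs = []
    start = None
    for i, v in enumerate(line):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(line) - start))
    return runs


def determinism(plot: RecurrencePlot, config: RQAConfig | None = None) -> float:
    """Percentage of recurrence points on diagonal lines of length >= l_min.

    Computed on the strict upper triangle; returns 0 when there is no
    recurrence.
    """
    config = config or RQAConfig()
    l_min = config.l_min
    if plot.n < l_min:
        raise InputError(f"need n >= l_min = {l_min}")
    rec = plot.rec_count
    if rec == 0:
        return 0.0
    m = plot.matrix
    on_lines = 0
    for k in range(1, plot.n):
        diag = np.diagonal(m, offset=k)
        on_lines += sum(ln for _, ln in _run_lengths(diag) if ln >= l_min)
    return 100.0 * on_lines / rec


def laminarity(plot: RecurrencePlot, config: RQAConfig | None = None) -> float:
    """Percentage of recurrence points on horizontal/vertical lines.

    Vertical runs are scanned down full columns and horizontal runs along
    full rows; the self-recurrence diagonal joins runs but its points are
    never counted, and only strict-upper-triangle points contribute.  The
    denominator 2R represents both triangles' recurrences.
    """
    config = config or RQAConfig()
    l_min = config.l_min
    if plot.n < l_min:
        raise InputError(f"need n >= l_min = {l_min}")
    rec = plot.rec_count
    if rec == 0:
        return 0.0
    m = plot.matrix
    v_points = 0
    h_points = 0
    for j in range(plot.n):
        for start, ln in _run_lengths(m[:, j]):
            if ln >= l_min:
                # count cells strictly above the diagonal (i < j)
                v_points += max(0, min(start + ln, j) - start)
        for start, ln in _run_lengths(m[j, :]):
            if ln >= l_min:
                # count cells strictly right of the diagonal (k > j)
                h_points += max(0, start + ln - max(start, j + 1))
    return 100.0 * (h_points + v_points) / (2.0 * rec)


def fixation_spread(scanpath: Scanpath) -> float:
    """RMS Euclidean distance of fixations from their centroid, in px.

    Used as a dispersion covariate: recurrence measures shrink trivially
    when gaze is concentrated, so contrasts should control for spread.
    """
    n = len(scanpath)
    if n < 2:
        raise InputError(f"need at least 2 fixations, got {n}")
    pos = scanpath.positions()
    centred = pos - pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def analyze(scanpath: Scanpath, config: RQAConfig | None = None) -> RQAResult:
    """All RQA measures for one scanpath."""
    config = config or RQAConfig()
    plot = recurrence_matrix(scanpath, config)
    rec = plot.rec_count
    return RQAResult(
        n=plot.n,
        rec_count=rec,
        recurrence_rate=recurrence_rate(plot),
        determinism=determinism(plot, config),
        laminarity=laminarity(plot, config),
        fixation_spread=fixation_spread(scanpath),
        degenerate=(rec == 0),
    )
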