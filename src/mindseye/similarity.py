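"""Five-dimension scanpath similarity over aligned saccade vectors.

Scanpaths are represented as sequences of saccade vectors (consecutive
fixation-to-fixation displacements).  The two sequences are optionally
simplified (merging small or collinear saccades around brief fixations),
then aligned by the cheapest monotone path through the matrix of
vector-difference magnitudes, and compared per aligned pair on five
normalized dimensions:

========  =====================================================
shape     |u - v| / (2 * screen diagonal)
length    ||u| - |v|| / diagonal
direction angular difference / pi
position  distance between endpoint fixations / diagonal
duration  |d_u - d_v| / max(d_u, d_v)
========  =====================================================

Each dimension's similarity is 1 minus the mean dissimilarity over the
aligned pairs, so identical scanpaths score 1 on every dimension and a
pure translation scores 1 on everything except position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .io import Scanpath

DIMENSIONS = ("shape", "length", "direction", "position", "duration")


@dataclass(frozen=True)
class SaccadeVector:
    """One saccade as a free vector plus its start fixation's metadata."""

    dx: float
    dy: float
    start_x: float
    start_y: float
    duration_ms: float  # duration of the originating fixation

    @property
    def amplitude(self) -> float:
        return math.hypot(self.dx, self.dy)

    @property
    def end_x(self) -> float:
        return self.start_x + self.dx

    @property
    def end_y(self) -> float:
        return self.start_y + self.dy


@dataclass(frozen=True)
class SimilarityProfile:
    shape: float
    length: float
    direction: float
    position: float
    duration: float

    def as_dict(self) -> dict:
        return {d: getattr(self, d) for d in DIMENSIONS}


@dataclass(frozen=True)
class SimilarityConfig:
    """Simplification thresholds (fractions of screen diagonal, degrees, ms)."""

    amp_threshold_frac: float = 0.10
    dir_threshold_deg: float = 45.0
    dur_threshold_ms: float = 300.0
    simplify: bool = True


def scanpath_to_vectors(scanpath: Scanpath) -> list[SaccadeVector]:
    """Saccade vectors between consecutive fixations."""
    if len(scanpath) < 2:
        raise InputError("need at least 2 fixations to form a saccade")
    out = []
    fx = scanpath.fixations
    for a, b in zip(fx, fx[1:]):
        out.append(
            SaccadeVector(
                dx=b.x_px - a.x_px, dy=b.y_px - a.y_px,
                start_x=a.x_px, start_y=a.y_px, duration_ms=a.duration_ms,
            )
        )
    return out


def _angle_between(u: SaccadeVector, v: SaccadeVector) -> float:
    """Angle in radians between two saccade vectors; 0 if either is null."""
    if u.amplitude == 0 or v.amplitude == 0:
        return 0.0
    diff = math.atan2(u.dy, u.dx) - math.atan2(v.dy, v.dx)
    diff = abs((diff + math.pi) % (2.0 * math.pi) - math.pi)
    return diff


def simplify_scanpath(scanpath: Scanpath,
                      config: SimilarityConfig | None = None) -> list[SaccadeVector]:
    """Simplify a scanpath into a reduced saccade-vector sequence.

    Consecutive saccade pairs are merged when (a) both are shorter than
    ``amp_threshold_frac`` of the screen diagonal, or (b) their directions
    differ by less than ``dir_threshold_deg`` — in either case only when
    the intervening fixation is briefer than ``dur_threshold_ms``.  A merge
    sums the two vectors and pools the intervening fixation's duration into
    the originating fixation.  Merging repeats to a fixed point; every pass
    strictly decreases the vector count, so it terminates in < n passes.
    """
    config = config or SimilarityConfig()
    vectors = scanpath_to_vectors(scanpath)
    if not config.simplify:
        return vectors
    amp_cut = config.amp_threshold_frac * scanpath.geometry.diagonal_px
    dir_cut = math.radians(config.dir_threshold_deg)

    changed = True
    while changed and len(vectors) > 1:
        changed = False
        out: list[SaccadeVector] = []
        i = 0
        while i < len(vectors):
            if i + 1 < len(vectors):
                u, v = vectors[i], vectors[i + 1]
                brief_between = v.duration_ms < config.dur_threshold_ms
                small = u.amplitude < amp_cut and v.amplitude < amp_cut
                collinear = _angle_between(u, v) < dir_cut
                if brief_between and (small or collinear):
                    out.append(
                        SaccadeVector(
                            dx=u.dx + v.dx, dy=u.dy + v.dy,
                            start_x=u.start_x, start_y=u.start_y,
                            duration_ms=u.duration_ms + v.duration_ms,
                        )
                    )
                    i += 2
                    changed = True
                    continue
            out.append(vectors[i])
            i += 1
        vectors = out
    return vectors


def _cost_matrix(u: list[SaccadeVector], v: list[SaccadeVector]) -> np.ndarray:
    du = np.array([[a.dx, a.dy] for a in u])
    dv = np.array([[b.dx, b.dy] for b in v])
    diff = du[:, None, :] - dv[None, :, :]
    return np.hypot(diff[..., 0], diff[..., 1])


def align_vectors(u: list[SaccadeVector], v: list[SaccadeVector]) -> list[tuple[int, int]]:
    """Lowest-cost monotone alignment of two saccade-vector sequences.

    Dynamic programming over the |u| x |v| matrix of vector-difference
    magnitudes; steps move right, down, or diagonally, the path cost is the
    sum of visited cells, and ties prefer the diagonal step.
    """
    if not u or not v:
        raise InputError("cannot align empty vector sequences")
    m = _cost_matrix(u, v)
    ni, nj = m.shape
    cost = np.full((ni, nj), np.inf)
    cost[0, 0] = m[0, 0]
    for i in range(ni):
        for j in range(nj):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0 and j > 0:
                best = cost[i - 1, j - 1]
            if i > 0:
                best = min(best, cost[i - 1, j])
            if j > 0:
                best = min(best, cost[i, j - 1])
            cost[i, j] = m[i, j] + best
    # traceback, preferring the diagonal on ties
    path = [(ni - 1, nj - 1)]
    i, j = ni - 1, nj - 1
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((cost[i - 1, j - 1], 0, (i - 1, j - 1)))
        if i > 0:
            candidates.append((cost[i - 1, j], 1, (i - 1, j)))
        if j > 0:
            candidates.append((cost[i, j - 1], 2, (i, j - 1)))
        _, _, (i, j) = min(candidates)
        path.append((i, j))
    path.reverse()
    return path


def _profile_from_alignment(u, v, pairs, diag: float) -> SimilarityProfile:
    dis = dict.fromkeys(DIMENSIONS, 0.0)
    for i, j in pairs:
        a, b = u[i], v[j]
        dis["shape"] += math.hypot(a.dx - b.dx, a.dy - b.dy) / (2.0 * diag)
        dis["length"] += abs(a.amplitude - b.amplitude) / diag
        dis["direction"] += _angle_between(a, b) / math.pi
        dis["position"] += math.hypot(a.end_x - b.end_x, a.end_y - b.end_y) / diag
        dmax = max(a.duration_ms, b.duration_ms)
        dis["duration"] += abs(a.duration_ms - b.duration_ms) / dmax if dmax > 0 else 0.0
    n = len(pairs)
    return SimilarityProfile(**{d: 1.0 - dis[d] / n for d in DIMENSIONS})


def similarity_profile(a: Scanpath, b: Scanpath,
                       config: SimilarityConfig | None = None) -> SimilarityProfile:
    """Five-dimension similarity between two scanpaths (each in [0, 1])."""
    config = config or SimilarityConfig()
    u = simplify_scanpath(a, config)
    v = simplify_scanpath(b, config)
    pairs = align_vectors(u, v)
    return _profile_from_alignment(u, v, pairs, a.geometry.diagonal_px)
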