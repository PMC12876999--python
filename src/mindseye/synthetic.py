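"""Synthetic multi-participant fixation cohorts for the four gaze regimes.

The generative model is anchor-based: each trial owns a set of spatial
*anchors* (stand-ins for informative image regions), and a scanpath is a
walk over anchors controlled by three levers —

``revisit_prob``
    probability that the next anchor visit returns to an already-visited
    anchor rather than exploring a new one (drives recurrence),
``order_fidelity``
    probability that a revisit follows the successor of the current anchor
    in the order anchors were first toured (drives determinism: faithful
    revisits replay earlier subsequences and form diagonal lines),
``cluster_dwell``
    mean number of consecutive fixations emitted per anchor visit (drives
    laminarity: dwells form vertical/horizontal lines).

Four mode presets emulate the study regimes: *free* viewing (moderate
revisits, single-fixation visits), *part_based* encoding through a
gaze-contingent window (sequential tours with dwells), *holistic*
encoding under an artificial scotoma (large dispersed jumps, no revisit
structure), and *imagery* (frequent, order-faithful, clustered revisits).

In a cohort, the imagery phase is coupled to its encoding phase through
``encoding_coupling`` (lambda): each encoding fixation's anchor is
rehearsed with probability lambda and replaced by a uniformly random
screen position otherwise, and the kept tokens are re-ordered into
repeated first-tour-order sweeps with dwell runs.  At lambda = 1 with
zero jitter the imagery fixation positions are exactly the encoding
multiset, so quadrant AOI profiles coincide trial by trial and the
looking-at-nothing regression slope is exactly 1; at lambda = 0 imagery
is spatially unrelated to encoding and the slope vanishes.

Everything is reproducible bit-for-bit from ``(config, seed)``: the master
seed is streamed into per-trial substreams keyed by participant and trial
index, so extending a cohort never reshuffles existing trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .io import Fixation, RawSampleTrack, Scanpath, ScreenGeometry, deg_to_px

MODES = ("free", "part_based", "holistic", "imagery")

#: Lever presets per mode: (revisit_prob, order_fidelity, cluster_dwell).
MODE_PRESETS = {
    "free": (0.30, 0.20, 1.0),
    "part_based": (0.55, 0.90, 3.0),
    "holistic": (0.02, 0.0, 1.0),
    "imagery": (0.75, 0.90, 2.0),
}

#: Encoding regime implied by each display condition.
CONDITION_ENCODING_MODE = {"FP": "free", "GCW": "part_based", "AS": "holistic"}

_CATEGORIES = ("abstract", "indoor", "outdoor")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """All knobs of the generative model.

    ``revisit_prob``, ``order_fidelity`` and ``cluster_dwell`` default to
    None, meaning "use the mode preset"; setting them overrides the preset
    for every mode (useful for lever sweeps).
    """

    n_participants: int = 8
    n_trials: int = 6
    n_fixations: int = 40
    n_anchors: int = 6
    revisit_prob: float | None = None
    order_fidelity: float | None = None
    cluster_dwell: float | None = None
    jitter_sd: float = 15.0
    saccade_scale: float = 500.0
    encoding_coupling: float = 0.7  # lambda: weight of encoding anchors in imagery
    probe_accuracy: float = 0.70
    vividness_mean: float = 4.5
    vividness_sd: float = 1.3
    seed: int = 0
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    anchor_min_sep_px: float = 200.0
    anchor_margin_px: float = 100.0

    def __post_init__(self) -> None:
        for name in ("revisit_prob", "order_fidelity", "encoding_coupling"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_participants", "n_trials", "n_fixations", "n_anchors"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.jitter_sd < 0 or self.saccade_scale <= 0:
            raise ConfigError("jitter_sd must be >= 0 and saccade_scale > 0")

    def levers(self, mode: str) -> tuple[float, float, float]:
        if mode not in MODE_PRESETS:
            raise ConfigError(f"unknown mode {mode!r}")
        preset = MODE_PRESETS[mode]
        return (
            preset[0] if self.revisit_prob is None else self.revisit_prob,
            preset[1] if self.order_fidelity is None else self.order_fidelity,
            preset[2] if self.cluster_dwell is None else self.cluster_dwell,
        )


def _trial_rng(config: SyntheticCohortConfig, p_idx: int, t_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, p_idx, t_idx)))


def sample_anchors(config: SyntheticCohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Anchor locations with a minimum mutual separation, away from edges."""
    geom = config.geometry
    margin = config.anchor_margin_px
    lo = np.array([margin, margin])
    hi = np.array([geom.width_px - margin, geom.height_px - margin])
    if np.any(hi <= lo):
        raise ConfigError("margin leaves no room for anchors")
    anchors: list[np.ndarray] = []
    for _ in range(5000):
        cand = rng.uniform(lo, hi)
        if all(np.hypot(*(cand - a)) > config.anchor_min_sep_px for a in anchors):
            anchors.append(cand)
            if len(anchors) == config.n_anchors:
                return np.array(anchors)
    raise ConfigError(
        f"cannot place {config.n_anchors} anchors {config.anchor_min_sep_px} px "
        "apart on this screen"
    )


def _durations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Log-normal fixation durations clipped to the plausible window."""
    return np.clip(rng.lognormal(mean=np.log(220.0), sigma=0.35, size=n), 100.0, 5000.0)


def _emit(positions: np.ndarray, rng: np.random.Generator,
          config: SyntheticCohortConfig, participant: str, trial: str,
          phase: str, condition: str, category: str) -> Scanpath:
    geom = config.geometry
    pos = np.clip(
        positions,
        [0.0, 0.0],
        [np.nextafter(geom.width_px, 0.0), np.nextafter(geom.height_px, 0.0)],
    )
    durs = _durations(len(pos), rng)
    gaps = rng.uniform(25.0, 45.0, size=len(pos))
    onset = 0.0
    fixations = []
    for (x, y), d, g in zip(pos, durs, gaps):
        fixations.append(Fixation(onset_ms=onset, duration_ms=float(d), x_px=float(x), y_px=float(y)))
        onset += d + g
    return Scanpath(
        participant_id=participant, trial_id=trial, phase=phase,
        condition=condition, category=category, fixations=fixations, geometry=geom,
    )


def _anchor_walk(config: SyntheticCohortConfig, mode: str,
                 anchors: np.ndarray, rng: np.random.Generator) -> list[int]:
    """Sequence of anchor indices (one per fixation) for an anchor-based mode."""
    revisit_prob, order_fidelity, cluster_dwell = config.levers(mode)
    n_fix = config.n_fixations
    k = len(anchors)
    tour: list[int] = []        # anchors in first-visit order
    seq: list[int] = []
    unvisited = list(rng.permutation(k))
    current: int | None = None

    def dwell() -> int:
        return 1 + int(rng.poisson(max(0.0, cluster_dwell - 1.0)))

    while len(seq) < n_fix:
        if current is None:
            nxt = unvisited.pop(0)
        elif (rng.random() < revisit_prob and len(tour) >= 2) or not unvisited:
            if rng.random() < order_fidelity:
                # faithful revisit: successor of current in the first tour
                nxt = tour[(tour.index(current) + 1) % len(tour)]
            else:
                choices = [a for a in tour if a != current] or tour
                nxt = choices[rng.integers(len(choices))]
        else:
            nxt = unvisited.pop(0)
        if nxt not in tour:
            tour.append(nxt)
        seq.extend([nxt] * dwell())
        current = nxt
    return seq[:n_fix]


def _dispersed_positions(config: SyntheticCohortConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Large-amplitude exploratory jumps for the holistic regime."""
    geom = config.geometry
    margin = 20.0
    lo = np.array([margin, margin])
    hi = np.array([geom.width_px - margin, geom.height_px - margin])
    pts = [rng.uniform(lo, hi)]
    while len(pts) < config.n_fixations:
        for _ in range(200):
            cand = rng.uniform(lo, hi)
            if np.hypot(*(cand - pts[-1])) >= config.saccade_scale:
                break
        pts.append(cand)
    return np.array(pts)


def generate_trial(config: SyntheticCohortConfig, mode: str,
                   rng: np.random.Generator | None = None,
                   anchors: np.ndarray | None = None,
                   participant: str = "p00", trial: str = "t00",
                   phase: str = "encoding", condition: str = "FP",
                   category: str = "abstract") -> Scanpath:
    """Generate one synthetic scanpath in the given mode.

    Exactly ``config.n_fixations`` fixations, all on-screen; bit-identical
    for a given (config, rng state).
    """
    if mode not in MODES:
        raise ConfigError(f"unknown mode {mode!r}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if mode == "holistic":
        positions = _dispersed_positions(config, rng)
    else:
        if anchors is None:
            anchors = sample_anchors(config, rng)
        seq = _anchor_walk(config, mode, anchors, rng)
        jitter = rng.normal(0.0, config.jitter_sd, size=(len(seq), 2)) \
            if config.jitter_sd > 0 else np.zeros((len(seq), 2))
        positions = anchors[seq] + jitter
    return _emit(positions, rng, config, participant, trial, phase, condition, category)


def _rehearsal_order(tokens: list[int], cluster_dwell: float,
                     rng: np.random.Generator) -> list[int]:
    """Re-order an anchor-token multiset into repeated tours with dwell runs."""
    first_seen: list[int] = []
    counts: dict[int, int] = {}
    for a in tokens:
        if a not in counts:
            first_seen.append(a)
        counts[a] = counts.get(a, 0) + 1
    out: list[int] = []
    while any(c > 0 for c in counts.values()):
        for a in first_seen:
            if counts[a] > 0:
                take = min(counts[a], 1 + int(rng.poisson(max(0.0, cluster_dwell - 1.0))))
                out.extend([a] * take)
                counts[a] -= take
    return out


def generate_imagery_from_encoding(config: SyntheticCohortConfig,
                                   encoding_seq: list[int], anchors: np.ndarray,
                                   rng: np.random.Generator,
                                   participant: str, trial: str,
                                   condition: str, category: str) -> Scanpath:
    """Imagery scanpath coupled to an encoding anchor sequence via lambda."""
    lam = config.encoding_coupling
    _, _, cluster_dwell = config.levers("imagery")
    keep = rng.random(len(encoding_seq)) < lam if lam < 1.0 \
        else np.ones(len(encoding_seq), dtype=bool)
    kept = [a for a, k in zip(encoding_seq, keep) if k]
    n_noise = len(encoding_seq) - len(kept)
    ordered = _rehearsal_order(kept, cluster_dwell, rng)

    geom = config.geometry
    noise_pts = rng.uniform([0.0, 0.0], [geom.width_px, geom.height_px], size=(n_noise, 2))
    jitter = rng.normal(0.0, config.jitter_sd, size=(len(ordered), 2)) \
        if config.jitter_sd > 0 else np.zeros((len(ordered), 2))
    anchored = anchors[ordered] + jitter if ordered else np.zeros((0, 2))

    positions = list(anchored)
    slots = sorted(rng.choice(len(encoding_seq), size=n_noise, replace=False))
    for slot, pt in zip(slots, noise_pts):
        positions.insert(min(slot, len(positions)), pt)
    return _emit(np.array(positions), rng, config, participant, trial,
                 "imagery", condition, category)


def generate_cohort(config: SyntheticCohortConfig,
                    conditions=("FP", "GCW", "AS")) -> tuple[list[Scanpath], pd.DataFrame]:
    """Generate a full cohort: encoding + imagery scanpaths and a truth table.

    Conditions and picture categories rotate over trials; the encoding
    regime follows the display condition (FP -> free, GCW -> part_based,
    AS -> holistic) and every imagery phase rehearses its own encoding
    through lambda.  The truth table carries the generating parameters and
    simple behavioural outcomes (probe accuracy, vividness rating) per trial.
    """
    scanpaths: list[Scanpath] = []
    truth_rows = []
    for p in range(config.n_participants):
        pid = f"p{p:02d}"
        for t in range(config.n_trials):
            tid = f"t{t:02d}"
            rng = _trial_rng(config, p, t)
            condition = conditions[t % len(conditions)]
            category = _CATEGORIES[(t // len(conditions)) % len(_CATEGORIES)]
            enc_mode = CONDITION_ENCODING_MODE[condition]

            anchors = sample_anchors(config, rng)
            if enc_mode == "holistic":
                positions = _dispersed_positions(config, rng)
                # every encoded location acts as its own rehearsal anchor
                anchors = positions
                enc_seq = list(range(len(positions)))
                enc = _emit(positions, rng, config, pid, tid, "encoding", condition, category)
            else:
                enc_seq = _anchor_walk(config, enc_mode, anchors, rng)
                jitter = rng.normal(0.0, config.jitter_sd, size=(len(enc_seq), 2)) \
                    if config.jitter_sd > 0 else np.zeros((len(enc_seq), 2))
                enc = _emit(anchors[enc_seq] + jitter, rng, config, pid, tid,
                            "encoding", condition, category)
            img = generate_imagery_from_encoding(
                config, enc_seq, anchors, rng, pid, tid, condition, category)
            scanpaths.extend([enc, img])

            revisit, fidelity, dwell = config.levers(enc_mode)
            truth_rows.append({
                "participant": pid, "trial": tid, "condition": condition,
                "category": category, "encoding_mode": enc_mode,
                "revisit_prob": revisit, "order_fidelity": fidelity,
                "cluster_dwell": dwell, "lambda": config.encoding_coupling,
                "n_anchors": config.n_anchors, "jitter_sd": config.jitter_sd,
                "accuracy": int(rng.random() < config.probe_accuracy),
                "vividness": int(np.clip(round(rng.normal(
                    config.vividness_mean, config.vividness_sd)), 1, 7)),
            })
    return scanpaths, pd.DataFrame(truth_rows)


def render_raw_track(scanpath: Scanpath, rate_hz: float = 1000.0,
                     noise_sd_deg: float = 0.02,
                     blink_gaps: list[tuple[float, float]] | None = None,
                     rng: np.random.Generator | None = None) -> RawSampleTrack:
    """Render a scanpath as raw gaze samples.

    Samples sit at the fixation position (plus Gaussian noise of
    ``noise_sd_deg``) for the fixation's duration and ramp linearly to the
    next fixation across the inter-fixation gap, producing saccade
    velocities far above any fixation threshold.  ``blink_gaps`` marks
    time intervals as invalid (pupil lost).
    """
    if len(scanpath) == 0:
        raise InputError("cannot render an empty scanpath")
    rng = rng if rng is not None else np.random.default_rng(0)
    dt = 1000.0 / rate_hz
    fx = scanpath.fixations
    t0 = fx[0].onset_ms
    t_end = fx[-1].onset_ms + fx[-1].duration_ms
    times = np.arange(t0, t_end, dt)

    knots_t, knots_x, knots_y = [], [], []
    for f in fx:
        knots_t.extend([f.onset_ms, f.onset_ms + f.duration_ms - 1e-9])
        knots_x.extend([f.x_px, f.x_px])
        knots_y.extend([f.y_px, f.y_px])
    x = np.interp(times, knots_t, knots_x)
    y = np.interp(times, knots_t, knots_y)

    if noise_sd_deg > 0:
        noise_px = deg_to_px(noise_sd_deg, scanpath.geometry, round_result=False)
        x = x + rng.normal(0.0, noise_px, size=len(x))
        y = y + rng.normal(0.0, noise_px, size=len(y))

    valid = np.ones(len(times), dtype=bool)
    for lo, hi in blink_gaps or []:
        valid &= ~((times >= lo) & (times < hi))
    return RawSampleTrack(times_ms=times, x_px=x, y_px=y, valid=valid)
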