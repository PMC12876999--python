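"""Fixation filtering and participant-level quality control.

Fixations are removed when they fall off the screen or when their duration
is implausibly short (< 100 ms) or long (> 5000 ms).  Duration cut-offs are
strict inequalities — a fixation of exactly 100 or 5000 ms is kept — and
the screen is treated as the half-open rectangle [0, width) x [0, height).
Removal reasons are checked in the order off-screen, too-short, too-long,
so the per-reason counts partition the removed set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Scanpath

#: Default duration window in ms; values at the boundary are kept.
MIN_DURATION_MS = 100.0
MAX_DURATION_MS = 5000.0


@dataclass
class PreprocessReport:
    """Counts of kept/removed fixations for one filtering pass."""

    n_input: int = 0
    n_kept: int = 0
    n_removed_offscreen: int = 0
    n_removed_short: int = 0
    n_removed_long: int = 0
    groups: list = field(default_factory=list)

    def __add__(self, other: "PreprocessReport") -> "PreprocessReport":
        return PreprocessReport(
            n_input=self.n_input + other.n_input,
            n_kept=self.n_kept + other.n_kept,
            n_removed_offscreen=self.n_removed_offscreen + other.n_removed_offscreen,
            n_removed_short=self.n_removed_short + other.n_removed_short,
            n_removed_long=self.n_removed_long + other.n_removed_long,
            groups=self.groups + other.groups,
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_removed_offscreen": self.n_removed_offscreen,
            "n_removed_short": self.n_removed_short,
            "n_removed_long": self.n_removed_long,
        }


def filter_fixations(scanpath: Scanpath, min_ms: float = MIN_DURATION_MS,
                     max_ms: float = MAX_DURATION_MS) -> tuple[Scanpath, PreprocessReport]:
    """Apply the off-screen and duration filters to one scanpath.

    Returns the filtered scanpath (order preserved; may be empty) and a
    report whose counts reconcile: ``n_input = n_kept + removed``.
    """
    geom = scanpath.geometry
    kept = []
    report = PreprocessReport(n_input=len(scanpath.fixations), groups=[scanpath.key])
    for fx in scanpath.fixations:
        if not geom.contains(fx.x_px, fx.y_px):
            report.n_removed_offscreen += 1
        elif fx.duration_ms < min_ms:
            report.n_removed_short += 1
        elif fx.duration_ms > max_ms:
            report.n_removed_long += 1
        else:
            kept.append(fx)
    report.n_kept = len(kept)
    return scanpath.with_fixations(kept), report


def filter_cohort(scanpaths, min_ms: float = MIN_DURATION_MS,
                  max_ms: float = MAX_DURATION_MS):
    """Filter every scanpath; returns (filtered list, pooled report)."""
    out, total = [], PreprocessReport()
    for sp in scanpaths:
        filtered, rep = filter_fixations(sp, min_ms, max_ms)
        out.append(filtered)
        total = total + rep
    return out, total


def qc_summary(scanpaths, z_threshold: float = 3.0) -> pd.DataFrame:
    """Per-participant gaze statistics with across-participant z-scores.

    Computes total fixation time, fixation count, and mean duration per
    participant, z-scores each column across participants, and flags
    |z| > ``z_threshold``.  Flags are advisory only — nothing is excluded.
    With a single participant z-scores are undefined and a ``warning``
    column says so; empty input yields an empty table.
    """
    rows = []
    for sp in scanpaths:
        for fx in sp.fixations:
            rows.append((sp.participant_id, fx.duration_ms))
    if not rows:
        return pd.DataFrame(
            columns=["participant", "total_fixation_ms", "n_fixations", "mean_duration_ms"]
        )
    df = pd.DataFrame(rows, columns=["participant", "duration_ms"])
    summary = df.groupby("participant", sort=True)["duration_ms"].agg(
        total_fixation_ms="sum", n_fixations="count", mean_duration_ms="mean"
    ).reset_index()
    metrics = ["total_fixation_ms", "n_fixations", "mean_duration_ms"]
    if len(summary) < 2:
        summary["warning"] = "single participant: z-scores undefined"
        return summary
    for m in metrics:
        col = summary[m].astype(float)
        sd = col.std(ddof=1)
        summary[f"z_{m}"] = 0.0 if sd == 0 else (col - col.mean()) / sd
    zcols = [f"z_{m}" for m in metrics]
    summary["flagged"] = (summary[zcols].abs() > z_threshold).any(axis=1)
    return summary
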