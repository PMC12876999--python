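"""Condition contrasts with a participant-level cluster bootstrap.

Gaze measures (recurrence, determinism, similarity scores, ...) are
proportion-valued and clustered within participants, so contrasts between
conditions are estimated as differences of participant-level condition
means and their uncertainty by resampling *participants* (the clusters),
never individual trials.  When every participant contributes to both
conditions the design is treated as paired and the participant-wise
difference is resampled.  This descriptive estimator deliberately stands
in for hierarchical proportion models: it preserves the sign-and-interval
decision rule without any MCMC machinery, at the cost of shrinkage-free
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass(frozen=True)
class ContrastResult:
    measure: str
    contrast: str
    point_estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    paired: bool

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0.0 or self.ci_high < 0.0

    def as_dict(self) -> dict:
        return {
            "measure": self.measure, "contrast": self.contrast,
            "estimate": self.point_estimate, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "n_boot": self.n_boot,
            "seed": self.seed, "paired": self.paired,
        }


def condition_contrast(table: pd.DataFrame, measure: str,
                       condition_a: str, condition_b: str,
                       n_boot: int = 2000, seed: int = 0,
                       ci_level: float = 0.95,
                       condition_col: str = "condition",
                       participant_col: str = "participant") -> ContrastResult:
    """Contrast of ``measure`` between two conditions (a minus b).

    Point estimate: mean over participants of the participant's condition
    mean difference (paired) or difference of the two condition means of
    participant means (unpaired).  Percentile bootstrap CI over resampled
    participants; bit-reproducible given ``(seed, n_boot)``.
    """
    for cond in (condition_a, condition_b):
        if not (table[condition_col] == cond).any():
            raise InputError(f"condition {cond!r} not present in table")
    sub = table[table[condition_col].isin([condition_a, condition_b])]
    per = sub.groupby([participant_col, condition_col], sort=True)[measure] \
             .mean().unstack(condition_col)
    if len(per) < 2:
        raise InputError("need at least 2 participants")

    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0
    paired = per[[condition_a, condition_b]].notna().all(axis=1).all()

    if paired:
        diffs = (per[condition_a] - per[condition_b]).to_numpy()
        estimate = float(diffs.mean())
        idx = rng.integers(0, len(diffs), size=(n_boot, len(diffs)))
        boots = diffs[idx].mean(axis=1)
    else:
        a = per[condition_a].dropna().to_numpy()
        b = per[condition_b].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise InputError("need at least 2 participants per condition")
        estimate = float(a.mean() - b.mean())
        ia = rng.integers(0, len(a), size=(n_boot, len(a)))
        ib = rng.integers(0, len(b), size=(n_boot, len(b)))
        boots = a[ia].mean(axis=1) - b[ib].mean(axis=1)

    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return ContrastResult(
        measure=measure, contrast=f"{condition_a}-{condition_b}",
        point_estimate=estimate, ci_low=float(lo), ci_high=float(hi),
        n_boot=n_boot, seed=seed, paired=bool(paired),
    )


def behavioural_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean probe accuracy and vividness by condition and category.

    Expects one row per trial with 0/1 ``accuracy`` and 1-7 ``vividness``;
    returns plain means, no modelling.
    """
    for col in ("accuracy", "vividness"):
        if col not in trials.columns:
            raise InputError(f"trials table lacks column {col!r}")
    out = trials.groupby(["condition", "category"], sort=True).agg(
        n_trials=("accuracy", "count"),
        mean_accuracy=("accuracy", "mean"),
        mean_vividness=("vividness", "mean"),
    ).reset_index()
    return out
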