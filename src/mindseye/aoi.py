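"""Quadrant AOIs and the looking-at-nothing (LAN) association.

The screen is split into four equally sized quadrants.  For each trial the
proportion of fixations falling in each quadrant is computed separately for
the encoding and the imagery phase; regressing the imagery proportions on
the encoding proportions across all (trial x quadrant) points gives a
slope whose positive sign operationalizes gaze reinstatement during
imagery: people look back at the (now empty) regions where the content
was during perception.  The pooled least-squares slope is a deliberately
simple descriptive statistic; it preserves the sign and strength of the
encoding-imagery coupling without any hierarchical model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io import Scanpath, ScreenGeometry

QUADRANTS = ("TL", "TR", "BL", "BR")


@dataclass(frozen=True)
class AOIProfile:
    """Fixation proportions over the four screen quadrants."""

    proportions: tuple  # ordered as QUADRANTS
    n_fixations: int

    @property
    def defined(self) -> bool:
        return self.n_fixations > 0

    def as_dict(self) -> dict:
        return dict(zip(QUADRANTS, self.proportions))


def assign_quadrant(x_px: float, y_px: float, geometry: ScreenGeometry) -> str:
    """Quadrant label for an on-screen point.

    Cells are half-open: a point exactly on the vertical midline belongs to
    the right quadrants, on the horizontal midline to the lower ones.
    """
    if not geometry.contains(x_px, y_px):
        raise InputError(f"point ({x_px}, {y_px}) is off-screen")
    left = x_px < geometry.width_px / 2.0
    top = y_px < geometry.height_px / 2.0
    return ("TL" if left else "TR") if top else ("BL" if left else "BR")


def aoi_profile(scanpath: Scanpath) -> AOIProfile:
    """Quadrant fixation proportions for one scanpath.

    An empty scanpath yields ``n_fixations = 0`` with undefined (NaN)
    proportions; callers should check :attr:`AOIProfile.defined`.
    """
    n = len(scanpath.fixations)
    if n == 0:
        return AOIProfile(proportions=(float("nan"),) * 4, n_fixations=0)
    counts = dict.fromkeys(QUADRANTS, 0)
    for fx in scanpath.fixations:
        counts[assign_quadrant(fx.x_px, fx.y_px, scanpath.geometry)] += 1
    return AOIProfile(
        proportions=tuple(counts[q] / n for q in QUADRANTS), n_fixations=n
    )


def lan_association(pairs) -> tuple[float, float, pd.DataFrame]:
    """Pooled regression of imagery AOI proportions on encoding proportions.

    Parameters
    ----------
    pairs
        Iterable of ``(encoding AOIProfile, imagery AOIProfile)`` per trial.

    Returns
    -------
    slope, intercept, table
        Least-squares fit over all (pair x quadrant) points and the long
        scatter table behind it.  A slope near 1 means imagery replays the
        encoding gaze distribution; near 0 means no spatial coupling.
    """
    rows = []
    for i, (enc, img) in enumerate(pairs):
        if not (enc.defined and img.defined):
            continue
        for q, e, m in zip(QUADRANTS, enc.proportions, img.proportions):
            rows.append((i, q, e, m))
    if len({r[0] for r in rows}) < 2:
        raise InputError("need at least 2 pairs with defined proportions")
    table = pd.DataFrame(rows, columns=["pair", "quadrant", "encoding", "imagery"])
    x = table["encoding"].to_numpy()
    y = table["imagery"].to_numpy()
    vx = np.var(x)
    if vx == 0:
        raise InputError("encoding proportions have zero variance; slope undefined")
    slope = float(np.cov(x, y, bias=True)[0, 1] / vx)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept, table
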