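"""Summary statistics and screening over site tables.

Covers the descriptive side of the survey workflow: coefficients of
variation (spatial heterogeneity proxy), exceedance rates against a
reference background, BCR fraction-proportion profiles, and a correlation
screen between fraction concentrations and soil physicochemical
properties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import FRACTION_NAMES, FractionVector

__all__ = [
    "FractionProfile",
    "coefficient_of_variation",
    "exceedance_rate",
    "fraction_profile",
    "correlation_screen",
]


def coefficient_of_variation(xs) -> float:
    """CV in percent: sample (n−1) standard deviation over the mean × 100."""
    xs = np.asarray(xs, dtype=float)
    if xs.size < 2:
        raise ValueError("need at least two observations")
    mean = xs.mean()
    if mean == 0:
        raise ValueError("mean is zero: CV undefined")
    return float(np.std(xs, ddof=1) / mean * 100.0)


def exceedance_rate(concs, background: float) -> float:
    """Percent of observations strictly above the reference background."""
    concs = np.asarray(concs, dtype=float)
    if concs.size == 0:
        raise ValueError("need at least one observation")
    if not (math.isfinite(background) and background > 0):
        raise ValueError(f"background must be > 0, got {background!r}")
    return float(100.0 * np.count_nonzero(concs > background) / concs.size)


@dataclass(frozen=True)
class FractionProfile:
    """Per-fraction percentages of one metal's fraction sum."""

    metal: str
    percentages: dict[str, float]  # F1..F4 -> % of fraction sum
    dominance_order: tuple[str, ...]  # F-names sorted descending, stable ties


def fraction_profile(fv: FractionVector, metal: str = "") -> FractionProfile:
    """Percent share of each BCR fraction and the dominance order."""
    total = fv.fraction_sum
    if total <= 0:
        raise ValueError("fraction sum must be > 0 to form a profile")
    shares = {
        name: 100.0 * v / total for name, v in zip(FRACTION_NAMES, fv.as_tuple())
    }
    # stable sort keeps F1..F4 input order among ties
    order = tuple(
        sorted(FRACTION_NAMES, key=lambda n: -shares[n])
    )
    return FractionProfile(metal=metal, percentages=shares, dominance_order=order)


def correlation_screen(
    x_block: pd.DataFrame,
    y_block: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Pairwise correlation of every x column with every y column.

    Rows are x columns (e.g. fraction concentrations per site), columns are
    y columns (e.g. physicochemical properties).  Missing values are
    handled pairwise-complete.  Returns a long-format frame with columns
    ``x``, ``y``, ``r``, ``p`` and ``significance`` (``ns``, ``*`` for
    p <= 0.05, ``**`` for p <= 0.01); zero-variance pairs are flagged with
    ``significance = "zero-variance"`` rather than raising.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for xc in x_block.columns:
        for yc in y_block.columns:
            x = pd.to_numeric(x_block[xc], errors="coerce")
            y = pd.to_numeric(y_block[yc], errors="coerce")
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if n < 5:
                raise ValueError(
                    f"pair ({xc}, {yc}): need >= 5 complete observations, got {n}"
                )
            xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
            if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                rows.append(
                    {"x": xc, "y": yc, "n": n, "r": np.nan, "p": np.nan,
                     "significance": "zero-variance"}
                )
                continue
            res = corr(xv, yv)
            r, p = float(res.statistic), float(res.pvalue)
            if p <= 0.01:
                sig = "**"
            elif p <= 0.05:
                sig = "*"
            else:
                sig = "ns"
            rows.append({"x": xc, "y": yc, "n": n, "r": r, "p": p, "significance": sig})
    return pd.DataFrame(rows)
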