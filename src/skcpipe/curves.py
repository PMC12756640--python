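"""Parameter–probability threshold curves.

For each raw tomographic index, the relationship between the index and the
posterior keratoconus probability is smoothed with locally weighted linear
regression (lowess, tricube weights) on an even grid, and the index values
at which the smoothed curve crosses 25% and 75% probability are located by
linear interpolation. These crossings give clinically interpretable
per-parameter flagging ranges: an eye whose value lies beyond the 25%
crossing in the severity direction has entered the ambiguous zone, and
beyond the 75% crossing the likely-disease zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

GRID_POINTS = 200


@dataclass
class ParameterCurve:
    """Smoothed probability curve for one feature, with band crossings.

    ``severity_direction`` is the sign of the Spearman correlation between
    the feature and the posterior (+1: larger values are more diseased).
    ``v25`` / ``v75`` are the feature values at the first crossing of the
    0.25 and 0.75 probability levels along the severity direction, or None
    when the smoothed curve never reaches the level. ``multiple_crossings``
    flags non-monotone curves where a level is crossed more than once.
    """

    feature: str
    grid: np.ndarray
    smoothed: np.ndarray
    v25: float | None
    v75: float | None
    severity_direction: int
    multiple_crossings: bool = False
    clipped: bool = False


def _crossings(grid: np.ndarray, curve: np.ndarray, level: float,
               direction: int) -> list[float]:
    """All level crossings, ordered along the severity direction."""
    g, c = (grid, curve) if direction >= 0 else (grid[::-1], curve[::-1])
    out = []
    for i in range(len(g) - 1):
        lo, hi = c[i], c[i + 1]
        if (lo < level <= hi) or (hi <= level < lo):
            if hi == lo:
                out.append(float(g[i]))
            else:
                frac = (level - lo) / (hi - lo)
                out.append(float(g[i] + frac * (g[i + 1] - g[i])))
    return out


def compute_curve(classified: pd.DataFrame, feature: str,
                  span: float = 0.5, p_col: str = "p_kc") -> ParameterCurve:
    """Smooth posterior probability against one raw feature.

    ``classified`` must hold the raw feature column and the posterior column
    (at least 100 eyes). The curve is evaluated on a 200-point even grid
    spanning the feature's 1st–99th percentiles; smoothed values are clipped
    to [0, 1] (with the clip recorded).
    """
    if len(classified) < 100:
        raise ValueError("need at least 100 eyes with posteriors")
    x = classified[feature].to_numpy(float)
    p = classified[p_col].to_numpy(float)
    lo, hi = np.percentile(x, [1, 99])
    grid = np.linspace(lo, hi, GRID_POINTS)
    smoothed = lowess(p, x, frac=span, xvals=grid)
    clipped = bool((smoothed < 0).any() or (smoothed > 1).any())
    smoothed = np.clip(smoothed, 0.0, 1.0)

    if np.all(p == p[0]) or np.all(x == x[0]):
        rho = np.nan
    else:
        rho = stats.spearmanr(x, p).statistic
    direction = 1 if (np.isnan(rho) or rho >= 0) else -1

    multiple = False
    vals = {}
    for level in (0.25, 0.75):
        cr = _crossings(grid, smoothed, level, direction)
        vals[level] = cr[0] if cr else None
        multiple = multiple or len(cr) > 1
    return ParameterCurve(
        feature=feature, grid=grid, smoothed=smoothed,
        v25=vals[0.25], v75=vals[0.75],
        severity_direction=direction, multiple_crossings=multiple,
        clipped=clipped,
    )


def curve_table(classified: pd.DataFrame, features: list[str],
                span: float = 0.5) -> pd.DataFrame:
    """Per-feature summary of 25%/75% crossings and severity directions."""
    rows = []
    for f in features:
        c = compute_curve(classified, f, span=span)
        rows.append({
            "feature": f, "v25": c.v25, "v75": c.v75,
            "direction": c.severity_direction,
            "multiple_crossings": c.multiple_crossings,
        })
    return pd.DataFrame(rows)


def plot_curve(curve: ParameterCurve, path: str) -> None:
    """Write a single-panel plot of one parameter–probability curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(curve.grid, curve.smoothed, color="black")
    for v, level in ((curve.v25, 0.25), (curve.v75, 0.75)):
        if v is not None:
            ax.axvline(v, color="red", linestyle=":")
            ax.annotate(f"{v:.2f}", (v, level), color="red", fontsize=8)
    ax.set_xlabel(curve.feature)
    ax.set_ylabel("P(KC)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
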