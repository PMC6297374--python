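"""Regression slopes of stability measures against walking speed.

Walking studies report the *increasing rate* of the short-term maximum
Lyapunov exponent as the OLS slope of the measure against speed, fit
separately within a slower band (2.0-5.0 km/h) and a faster band
(5.0-8.0 km/h by the figure convention; a 5.5 km/h lower edge is offered
as a switch because the two conventions coexist).  Hypothesis testing on
the paired slow/fast slope differences is delegated to standard
statistical routines; this module only produces the slopes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["TrendError", "ols_fit", "increasing_rates", "DEFAULT_BANDS"]

# figure convention: the 5.0 km/h point belongs to both bands
DEFAULT_BANDS = {"slow": (2.0, 5.0), "fast": (5.0, 8.0)}
# alternative stated elsewhere in the source conventions
STRICT_BANDS = {"slow": (2.0, 5.0), "fast": (5.5, 8.0)}


class TrendError(ValueError):
    pass


def ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, R^2).

    R^2 is the squared Pearson correlation; a constant y has slope 0 and
    R^2 = 0 by convention, a constant x is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise TrendError("x and y must be 1-D arrays of equal length")
    if len(np.unique(x)) < 2:
        raise TrendError("at least 2 distinct x values are required")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r2 = (sxy * sxy) / (sxx * syy) if syy > 0 else 0.0
    return slope, intercept, r2


def increasing_rates(
    measures_by_speed: pd.DataFrame,
    bands: dict[str, tuple[float, float]] | None = None,
    value_col: str = "lambda_star",
) -> pd.DataFrame:
    """Per (subject, synergy, band) OLS slope of a stability measure vs speed.

    ``measures_by_speed`` needs columns subject, synergy, speed and
    ``value_col``.  A band with < 2 distinct speeds available overall is
    an error; a (subject, synergy) combination that covers fewer than
    half of a band's speeds (e.g. a synergy recruited only near the
    band's edge, like the mid-swing synergy at slow speeds) is returned
    with ``computed=False`` and NaN slope rather than a fabricated or
    edge-extrapolated value.
    """
    bands = bands or DEFAULT_BANDS
    df = measures_by_speed
    required = {"subject", "synergy", "speed", value_col}
    if not required.issubset(df.columns):
        raise TrendError(f"input needs columns {sorted(required)}")
    band_speeds = {}
    for name, (lo, hi) in bands.items():
        n_band = df.loc[df["speed"].between(lo, hi), "speed"].nunique()
        if n_band < 2:
            raise TrendError(
                f"band {name!r} ({lo}-{hi} km/h) covers fewer than 2 speeds"
            )
        band_speeds[name] = n_band
    rows = []
    for (subject, synergy), grp in df.groupby(["subject", "synergy"], sort=True):
        for name, (lo, hi) in bands.items():
            sub = grp[grp["speed"].between(lo, hi)].dropna(subset=[value_col])
            required = max(2, -(-band_speeds[name] // 2))  # ceil(n/2)
            if sub["speed"].nunique() < required:
                rows.append({
                    "subject": subject, "synergy": synergy, "band": name,
                    "band_lo": lo, "band_hi": hi, "slope": np.nan,
                    "intercept": np.nan, "r2": np.nan,
                    "n_speeds": int(sub["speed"].nunique()), "computed": False,
                })
                continue
            slope, intercept, r2 = ols_fit(sub["speed"].to_numpy(),
                                           sub[value_col].to_numpy())
            rows.append({
                "subject": subject, "synergy": synergy, "band": name,
                "band_lo": lo, "band_hi": hi, "slope": slope,
                "intercept": intercept, "r2": r2,
                "n_speeds": int(sub["speed"].nunique()), "computed": True,
            })
    return pd.DataFrame(rows)


def paired_band_differences(trend_table: pd.DataFrame) -> pd.DataFrame:
    """Fast-minus-slow slope differences per (subject, synergy).

    Rows where either band was not computed are dropped; the differences
    feed downstream paired tests, which are not performed here.
    """
    wide = trend_table[trend_table["computed"]].pivot_table(
        index=["subject", "synergy"], columns="band", values="slope"
    )
    if not {"slow", "fast"}.issubset(wide.columns):
        return pd.DataFrame(columns=["subject", "synergy", "slope_diff"])
    wide = wide.dropna(subset=["slow", "fast"])
    out = wide.reset_index()
    out["slope_diff"] = out["fast"] - out["slow"]
    return out[["subject", "synergy", "slope_diff"]]
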