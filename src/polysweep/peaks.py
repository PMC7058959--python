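"""Peak summaries of sweep-signal profiles.

A sweep leaves a dip in diversity (or a peak in a sweep-oriented metric)
around the selected site.  This module smooths per-window profiles (LOESS,
tricube-weighted local quadratic, default span 0.1) and reduces them to the
scalar summaries used to compare ploidies:

* Magnitude — baseline diversity (non-selected population) minus the
  profile minimum;
* Breadth — distance between the half-baseline recovery points either side
  of the selected site, divided by 100 kb;
* Area — Magnitude * Breadth / 2 (triangle approximation of the dip);
* per-metric maxima and the area under the curve over +/-100 kb from the
  selected site, scaled by 100 000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "loess_smooth",
    "PeakSummary",
    "peak_metrics",
    "area_under_peak",
    "persistence_curve",
    "cv_bootstrap",
]


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.1,
    degree: int = 2,
) -> np.ndarray:
    """Locally weighted polynomial regression with tricube weights.

    Each point is fitted from its q = max(5, ceil(span*n)) nearest
    neighbours; no robustness iterations.  Evaluated at the input x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < max(5, int(math.ceil(span * n))):
        raise ValueError(f"need >= {max(5, int(math.ceil(span * n)))} points, got {n}")
    q = min(n, max(5, int(math.ceil(span * n))))
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(n)
    for idx, xi in enumerate(xs):
        d = np.abs(xs - xi)
        nearest = np.argpartition(d, q - 1)[:q]
        dmax = d[nearest].max()
        if dmax == 0:
            out[idx] = ys[nearest].mean()
            continue
        w = (1 - (d[nearest] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        xc = xs[nearest] - xi
        cols = [np.ones_like(xc)]
        for p in range(1, degree + 1):
            cols.append(xc**p)
        A = np.column_stack(cols) * np.sqrt(w)[:, None]
        b = ys[nearest] * np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        out[idx] = coef[0]
    result = np.empty(n)
    result[order] = out
    return result


@dataclass(frozen=True)
class PeakSummary:
    """Magnitude/Breadth/Area of a diversity dip (breadth in units of 100 kb)."""

    magnitude: float
    breadth: float
    area: float
    recovered: bool  # False when the profile never dips below baseline/2
    censored: bool = False  # True when a recovery point fell outside the profile


def peak_metrics(
    positions: np.ndarray,
    profile: np.ndarray,
    baseline: float,
    sel_pos: float,
    half_level: str = "baseline",
) -> PeakSummary:
    """Dip summaries of a smoothed diversity profile.

    Magnitude is baseline minus the profile minimum.  Breadth is the
    distance between the first positions left and right of `sel_pos` where
    the profile recovers to baseline/2 (`half_level="baseline"`, the
    default) or to the dip's half depth (`half_level="depth"`), divided by
    100 kb.  Area = Magnitude * Breadth / 2 exactly.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    positions = np.asarray(positions, dtype=float)
    profile = np.asarray(profile, dtype=float)
    order = np.argsort(positions)
    positions, profile = positions[order], profile[order]
    magnitude = max(baseline - float(np.nanmin(profile)), 0.0)
    if half_level == "baseline":
        level = baseline / 2
    elif half_level == "depth":
        level = baseline - magnitude / 2
    else:
        raise ValueError("half_level must be 'baseline' or 'depth'")

    valid = ~np.isnan(profile)
    if not valid.any() or np.nanmin(profile) >= level:
        # profile never drops below the recovery level: no measurable dip
        return PeakSummary(magnitude=magnitude, breadth=0.0, area=0.0, recovered=False)
    centre_val = np.interp(sel_pos, positions[valid], profile[valid])
    if centre_val >= level:
        return PeakSummary(magnitude=magnitude, breadth=0.0, area=0.0, recovered=False)

    def crossing(direction: int) -> tuple[float, bool]:
        # walk outward from sel_pos until the profile recovers to `level`;
        # a trough still below the level at the profile edge is censored there
        if direction > 0:
            idx = np.where(positions >= sel_pos)[0]
        else:
            idx = np.where(positions <= sel_pos)[0][::-1]
        prev_pos, prev_val = sel_pos, centre_val
        for i in idx:
            v = profile[i]
            if np.isnan(v):
                continue
            if v >= level:
                frac = (level - prev_val) / (v - prev_val)
                return float(prev_pos + frac * (positions[i] - prev_pos)), False
            prev_pos, prev_val = positions[i], v
        return float(prev_pos), True

    right, cens_r = crossing(+1)
    left, cens_l = crossing(-1)
    if right <= left:
        return PeakSummary(magnitude=magnitude, breadth=0.0, area=0.0, recovered=False)
    breadth = (right - left) / 100_000.0
    return PeakSummary(
        magnitude=magnitude,
        breadth=breadth,
        area=magnitude * breadth / 2.0,
        recovered=True,
        censored=cens_r or cens_l,
    )


def area_under_peak(
    positions: np.ndarray,
    profile: np.ndarray,
    sel_pos: float,
    halfwidth: float = 100_000.0,
) -> float:
    """Trapezoidal integral over [sel_pos - halfwidth, sel_pos + halfwidth] / 100 000.

    Endpoint values are linearly interpolated; the profile must cover the
    whole interval.
    """
    positions = np.asarray(positions, dtype=float)
    profile = np.asarray(profile, dtype=float)
    ok = ~np.isnan(profile)
    positions, profile = positions[ok], profile[ok]
    order = np.argsort(positions)
    positions, profile = positions[order], profile[order]
    lo, hi = sel_pos - halfwidth, sel_pos + halfwidth
    if positions.size == 0 or positions[0] > lo or positions[-1] < hi:
        raise ValueError(
            f"profile [{positions[0] if positions.size else None}, "
            f"{positions[-1] if positions.size else None}] does not cover "
            f"[{lo}, {hi}]"
        )
    inside = (positions > lo) & (positions < hi)
    xs = np.concatenate([[lo], positions[inside], [hi]])
    ys = np.concatenate([
        [np.interp(lo, positions, profile)],
        profile[inside],
        [np.interp(hi, positions, profile)],
    ])
    return float(np.trapezoid(ys, xs)) / 100_000.0


def persistence_curve(
    summaries: dict[float, dict[str, np.ndarray]]
) -> pd.DataFrame:
    """Decay of the sweep signal with time since fixation.

    `summaries` maps each tau_post (generations between fixation and
    sampling) to arrays of per-replicate `max` values and peak `area`
    values.  Returns, per tau_post: the median of the per-replicate maxima
    and quartiles of the area distribution.
    """
    if len(summaries) < 1:
        raise ValueError("need at least one tau_post level")
    rows = []
    for tau in sorted(summaries):
        entry = summaries[tau]
        maxima = np.asarray(entry["max"], dtype=float)
        areas = np.asarray(entry.get("area", []), dtype=float)
        row = {
            "tau_post": tau,
            "median_max": float(np.nanmedian(maxima)),
            "n": maxima.size,
        }
        if areas.size:
            q1, q2, q3 = np.nanpercentile(areas, [25, 50, 75])
            row.update(area_q1=q1, area_median=q2, area_q3=q3)
        rows.append(row)
    return pd.DataFrame(rows)


def cv_bootstrap(
    values: np.ndarray,
    rng: np.random.Generator,
    n_resample: int = 1000,
    block: int = 200,
) -> tuple[float, tuple[float, float]]:
    """Coefficient of variation of per-replicate maxima with a bootstrap interval.

    CV = sd/mean (ddof=1).  The interval is the 2.5/97.5 percentile of the
    CV over `n_resample` draws of `block` replicates with replacement.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need >= 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined: mean is zero")
    cv = v.std(ddof=1) / mean
    draws = rng.choice(v, size=(n_resample, block), replace=True)
    means = draws.mean(axis=1)
    sds = draws.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means != 0, sds / means, np.nan)
    lo, hi = np.nanpercentile(cvs, [2.5, 97.5])
    return float(cv), (float(lo), float(hi))
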