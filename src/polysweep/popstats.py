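"""Sweep-detection statistics on haplotype matrices of arbitrary ploidy.

All statistics treat the n*k sampled haplotypes of a population as the
sample — ploidy enters only through the number of sequences.  Windowed
statistics use the overlapping-window scheme width = L/(N/50) with step
width/2, so every interior site falls in exactly two windows.

Sign conventions follow the sweep-scan orientation: Tajima's D is reported
times -1 and F_ST is mean-standardized within a replicate, so all metrics
peak positive at a sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeMatrix

__all__ = [
    "WindowSpec",
    "window_spec",
    "nucleotide_diversity",
    "tajimas_d",
    "hudson_fst",
    "mean_standardize",
    "EHHCurve",
    "ehh",
    "ihh",
    "ihs",
    "standardize_ihs",
    "xpehh",
    "window_table",
]


@dataclass(frozen=True)
class WindowSpec:
    """Half-open windows [start, start+width) stepping by width/2 over [0, L)."""

    width: float
    L: float

    @property
    def step(self) -> float:
        return self.width / 2

    @property
    def bounds(self) -> list[tuple[float, float]]:
        out = []
        start = 0.0
        while start < self.L:
            out.append((start, min(start + self.width, self.L)))
            start += self.step
        return out

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([(s + e) / 2 for s, e in self.bounds])


def window_spec(L: float, N: int) -> WindowSpec:
    """The package's window rule: width = L/(N/50), step = width/2."""
    return WindowSpec(width=L / (N / 50), L=L)


def _pop_matrix(matrix: HaplotypeMatrix, pop: int | slice | np.ndarray) -> np.ndarray:
    if isinstance(pop, int):
        return matrix.pop(pop)
    return matrix.data[pop]


def _site_heterozygosity(sub: np.ndarray) -> np.ndarray:
    """Per-site 2c(m-c)/(m(m-1)) over the haplotype rows of `sub`."""
    m = sub.shape[0]
    if m < 2:
        raise ValueError("need >= 2 haplotypes")
    c = sub.sum(axis=0).astype(float)
    return 2.0 * c * (m - c) / (m * (m - 1))


def nucleotide_diversity(
    matrix: HaplotypeMatrix, pop: int, windows: WindowSpec
) -> np.ndarray:
    """Per-window pairwise nucleotide diversity, per bp."""
    sub = _pop_matrix(matrix, pop)
    if sub.shape[0] == 0:
        raise ValueError("empty population")
    het = _site_heterozygosity(sub)
    pos = matrix.positions
    out = np.zeros(len(windows.bounds))
    for i, (s, e) in enumerate(windows.bounds):
        mask = (pos >= s) & (pos < e)
        out[i] = het[mask].sum() / (e - s)
    return out


def _tajima_constants(m: int) -> tuple[float, float, float]:
    a1 = sum(1.0 / i for i in range(1, m))
    a2 = sum(1.0 / i**2 for i in range(1, m))
    b1 = (m + 1) / (3.0 * (m - 1))
    b2 = 2.0 * (m * m + m + 3) / (9.0 * m * (m - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return a1, e1, e2


def tajimas_d(
    matrix: HaplotypeMatrix, pop: int, windows: WindowSpec
) -> np.ndarray:
    """Per-window -1 x Tajima's D; windows with no segregating sites are NaN."""
    sub = _pop_matrix(matrix, pop)
    m = sub.shape[0]
    if m < 3:
        raise ValueError("Tajima's D needs >= 3 haplotypes")
    a1, e1, e2 = _tajima_constants(m)
    het = _site_heterozygosity(sub)
    c = sub.sum(axis=0)
    seg = (c > 0) & (c < m)
    pos = matrix.positions
    out = np.full(len(windows.bounds), np.nan)
    for i, (s, e) in enumerate(windows.bounds):
        mask = (pos >= s) & (pos < e) & seg
        S = int(mask.sum())
        if S == 0:
            continue
        pi_sum = het[mask].sum()
        denom = math.sqrt(e1 * S + e2 * S * (S - 1))
        out[i] = -(pi_sum - S / a1) / denom
    return out


def hudson_fst(
    matrix: HaplotypeMatrix, popA: int, popB: int, windows: WindowSpec
) -> np.ndarray:
    """Per-window Hudson F_ST = 1 - mean within-population pi / between-pop pi.

    Windows with zero between-population diversity are NaN.
    """
    a = _pop_matrix(matrix, popA)
    b = _pop_matrix(matrix, popB)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("both populations need >= 2 haplotypes")
    ma, mb = a.shape[0], b.shape[0]
    ca = a.sum(axis=0).astype(float)
    cb = b.sum(axis=0).astype(float)
    # plug-in heterozygosity 2pq within (no m/(m-1) correction) so that
    # identical samples give F_ST exactly 0
    het_a = 2.0 * ca * (ma - ca) / (ma * ma)
    het_b = 2.0 * cb * (mb - cb) / (mb * mb)
    dxy = (ca * (mb - cb) + cb * (ma - ca)) / (ma * mb)
    pos = matrix.positions
    out = np.full(len(windows.bounds), np.nan)
    for i, (s, e) in enumerate(windows.bounds):
        mask = (pos >= s) & (pos < e)
        between = dxy[mask].sum()
        if between <= 0:
            continue
        within = 0.5 * (het_a[mask].sum() + het_b[mask].sum())
        out[i] = 1.0 - within / between
    return out


def mean_standardize(values: np.ndarray) -> np.ndarray:
    """Within-replicate standardization: subtract mean, divide by sd (ddof=1).

    NaNs propagate; requires >= 2 defined values.
    """
    v = np.asarray(values, dtype=float)
    defined = v[~np.isnan(v)]
    if defined.size < 2:
        raise ValueError("need >= 2 defined values to standardize")
    sd = defined.std(ddof=1)
    if sd == 0:
        return v - defined.mean()
    return (v - defined.mean()) / sd


# ---------------------------------------------------------------------------
# haplotype homozygosity statistics


@dataclass
class EHHCurve:
    """Extended haplotype homozygosity outward from a focal site.

    Both arrays start at the focal position itself (distance 0).
    """

    focal_pos: float
    pos_right: np.ndarray
    ehh_right: np.ndarray
    pos_left: np.ndarray  # decreasing positions moving leftward
    ehh_left: np.ndarray


def ehh(
    matrix: HaplotypeMatrix | np.ndarray,
    pop: int | None,
    focal: int,
    allele: int | None,
    stop_below: float = 0.0,
    positions: np.ndarray | None = None,
) -> EHHCurve | None:
    """EHH curve around site index `focal` among carriers of `allele`.

    `allele=None` computes the site-EHH over all haplotypes of the
    population (the XP-EHH convention), starting from the focal-site
    partition.  Returns None when fewer than 2 carriers exist.  A bare
    haplotype array requires explicit site `positions` in bp.
    """
    if isinstance(matrix, HaplotypeMatrix):
        sub = matrix.pop(pop) if pop is not None else matrix.data
        pos = matrix.positions
    else:
        sub = matrix
        pos = positions if positions is not None else np.arange(matrix.shape[1], dtype=float)
    if allele is not None:
        sub = sub[sub[:, focal] == allele]
    if sub.shape[0] < 2:
        return None
    m = sub.shape[0]
    denom = m * (m - 1)
    counts = np.bincount(sub[:, focal].astype(np.int64), minlength=2)
    h0 = (counts * (counts - 1)).sum() / denom
    right = _extend_from_focal(sub, focal, +1, stop_below)
    left = _extend_from_focal(sub, focal, -1, stop_below)
    return EHHCurve(
        focal_pos=float(pos[focal]),
        pos_right=np.concatenate([[pos[focal]], pos[focal + 1 : focal + 1 + len(right)]]),
        ehh_right=np.concatenate([[h0], right]),
        pos_left=np.concatenate([[pos[focal]], pos[focal - len(left) : focal][::-1]]),
        ehh_left=np.concatenate([[h0], left]),
    )


def _extend_from_focal(
    sub: np.ndarray, focal: int, direction: int, stop_below: float
) -> np.ndarray:
    m = sub.shape[0]
    denom = m * (m - 1)
    S = sub.shape[1]
    groups = np.unique(sub[:, focal].astype(np.int64), return_inverse=True)[1]
    cols = range(focal + 1, S) if direction > 0 else range(focal - 1, -1, -1)
    out = []
    for col in cols:
        key = groups * 2 + sub[:, col]
        _, groups = np.unique(key, return_inverse=True)
        counts = np.bincount(groups)
        h = (counts * (counts - 1)).sum() / denom
        out.append(h)
        if h < stop_below:
            break
    return np.asarray(out)


def ihh(curve: EHHCurve, cutoff: float = 0.05) -> float:
    """Integrated EHH: trapezoids outward in bp, truncated where EHH < cutoff.

    The trapezoid ending at the first point below the cutoff is included;
    integration otherwise runs to the last available site.  Both directions
    are summed.
    """
    total = 0.0
    for pos, vals in ((curve.pos_right, curve.ehh_right), (curve.pos_left, curve.ehh_left)):
        for i in range(1, len(vals)):
            dx = abs(pos[i] - pos[i - 1])
            total += 0.5 * (vals[i] + vals[i - 1]) * dx
            if vals[i] < cutoff:
                break
    return total


def ihs(
    matrix: HaplotypeMatrix,
    pop: int,
    maf: float = 0.05,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Unstandardized iHS per focal site: ln(iHH_ancestral / iHH_derived).

    Sites below the minor-allele-frequency floor, or with an undefined or
    zero iHH in either allelic class, get NaN.  Standardization across a
    replicate set is a separate step (:func:`standardize_ihs`).
    """
    sub = matrix.pop(pop)
    m = sub.shape[0]
    freqs = sub.sum(axis=0) / m
    rows = []
    for j in range(sub.shape[1]):
        p = freqs[j]
        raw = np.nan
        if min(p, 1 - p) >= maf:
            parts = []
            for allele in (0, 1):
                curve = ehh(sub, None, j, allele, stop_below=cutoff,
                            positions=matrix.positions)
                parts.append(ihh(curve, cutoff) if curve is not None else 0.0)
            if parts[0] > 0 and parts[1] > 0:
                raw = math.log(parts[0] / parts[1])
        rows.append((matrix.positions[j], p, raw))
    return pd.DataFrame(rows, columns=["pos", "daf", "ihs_raw"])


def standardize_ihs(frames: list[pd.DataFrame], n_bins: int = 50) -> pd.DataFrame:
    """Standardize raw iHS within derived-frequency bins pooled over replicates.

    Returns the concatenated table with a `replicate` index column and an
    `ihs` column (NaN where raw was NaN or the bin had < 2 defined scores).
    """
    pooled = pd.concat(
        [f.assign(replicate=i) for i, f in enumerate(frames)], ignore_index=True
    )
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = np.clip(np.digitize(pooled["daf"], edges) - 1, 0, n_bins - 1)
    pooled["ihs"] = np.nan
    for b in np.unique(bins):
        mask = (bins == b) & pooled["ihs_raw"].notna()
        if mask.sum() < 2:
            continue
        v = pooled.loc[mask, "ihs_raw"]
        sd = v.std(ddof=1)
        if sd > 0:
            pooled.loc[mask, "ihs"] = (v - v.mean()) / sd
    return pooled


def xpehh(
    matrix: HaplotypeMatrix,
    popA: int = 0,
    popB: int = 1,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Cross-population EHH per site: ln(iHH_popA / iHH_popB), plus the
    within-replicate standardized score.

    Site-EHH (all haplotypes, partition seeded by the focal site) is
    integrated in both populations out to a common truncation point, the
    distance at which the combined-sample EHH first drops below `cutoff`.
    """
    a = matrix.pop(popA)
    b = matrix.pop(popB)
    both = np.vstack([a, b])
    rows = []
    for j in range(matrix.n_sites):
        comb = ehh(both, None, j, None, stop_below=cutoff, positions=matrix.positions)
        raw = np.nan
        if comb is not None:
            nr = len(comb.ehh_right)
            nl = len(comb.ehh_left)
            vals = []
            for sub in (a, b):
                curve = ehh(sub, None, j, None, stop_below=0.0,
                            positions=matrix.positions)
                if curve is None:
                    vals = []
                    break
                trunc = EHHCurve(
                    curve.focal_pos,
                    curve.pos_right[:nr], curve.ehh_right[:nr],
                    curve.pos_left[:nl], curve.ehh_left[:nl],
                )
                vals.append(ihh(trunc, cutoff=-1.0))
            if len(vals) == 2 and vals[0] > 0 and vals[1] > 0:
                raw = math.log(vals[0] / vals[1])
        rows.append((matrix.positions[j], raw))
    df = pd.DataFrame(rows, columns=["pos", "xpehh_raw"])
    defined = df["xpehh_raw"].dropna()
    if len(defined) >= 2 and defined.std(ddof=1) > 0:
        df["xpehh"] = (df["xpehh_raw"] - defined.mean()) / defined.std(ddof=1)
    else:
        df["xpehh"] = df["xpehh_raw"] - (defined.mean() if len(defined) else 0.0)
    return df


def window_table(
    matrix: HaplotypeMatrix,
    windows: WindowSpec,
    popA: int = 0,
    popB: int | None = 1,
) -> pd.DataFrame:
    """Convenience bundle: per-window pi, -D (and F_ST when two populations)."""
    df = pd.DataFrame({"window_mid": windows.midpoints})
    df["pi_sel"] = nucleotide_diversity(matrix, popA, windows)
    df["tajd_neg_sel"] = tajimas_d(matrix, popA, windows)
    if popB is not None and len(matrix.pop_sizes) > popB and matrix.pop_sizes[popB] >= 2:
        df["pi_neu"] = nucleotide_diversity(matrix, popB, windows)
        df["tajd_neg_neu"] = tajimas_d(matrix, popB, windows)
        fst = hudson_fst(matrix, popA, popB, windows)
        df["fst_raw"] = fst
        try:
            df["fst_std"] = mean_standardize(fst)
        except ValueError:
            df["fst_std"] = np.nan
    return df
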