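"""Preference indices, strong-preference classification, KS/EMD permutation tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.stats import mannwhitneyu

from popcode.io import hierarchical_average_arrays
from popcode.peth import BIN_WIDTH, Peth

PEAK_WINDOW = (-0.2, 0.5)
RESPONSE_HALF_BINS = 2        # peak bin +- 2 bins = 100 ms window

LATERALITY_CELLS = ("ipsi", "none", "contra")
MANUALITY_CELLS = ("uni", "none", "bi")


# ---------------------------------------------------------------------------
# response magnitude and preference index
# ---------------------------------------------------------------------------

def response_magnitude(peth: Peth, peak_window=PEAK_WINDOW,
                       peak_time: float | None = None):
    """Area under the trial-mean PETH in the 100 ms window around its peak.

    The peak is searched on the condition-mean PETH over [-200, +500] ms
    (unless a fixed ``peak_time`` is supplied); the response is the sum of
    rate x bin-width over the peak bin +-2 bins, truncated (and flagged) at
    the PETH edges.  Returns (A in Hz*s, peak_time_s, truncated_flag).
    """
    tm = peth.trial_mean()
    centers = peth.bin_centers
    if peak_time is None:
        sel = (centers >= peak_window[0]) & (centers < peak_window[1])
        idxs = np.flatnonzero(sel & np.isfinite(tm))
        if idxs.size == 0:
            return np.nan, np.nan, False
        peak_idx = idxs[np.argmax(tm[idxs])]
        peak_time = float(centers[peak_idx])
    else:
        peak_idx = int(np.argmin(np.abs(centers - peak_time)))
    lo = peak_idx - RESPONSE_HALF_BINS
    hi = peak_idx + RESPONSE_HALF_BINS + 1
    truncated = lo < 0 or hi > peth.n_bins
    lo, hi = max(lo, 0), min(hi, peth.n_bins)
    bw = float(peth.bin_edges[1] - peth.bin_edges[0])
    window_vals = tm[lo:hi]
    A = float(np.nansum(window_vals) * bw)
    return A, peak_time, truncated


def trial_responses(peth: Peth, peak_time: float) -> np.ndarray:
    """Per-trial response areas using a fixed peak window (Hz*s)."""
    centers = peth.bin_centers
    peak_idx = int(np.argmin(np.abs(centers - peak_time)))
    lo = max(peak_idx - RESPONSE_HALF_BINS, 0)
    hi = min(peak_idx + RESPONSE_HALF_BINS + 1, peth.n_bins)
    bw = float(peth.bin_edges[1] - peth.bin_edges[0])
    with np.errstate(invalid="ignore"):
        return np.nansum(np.where(peth.mask[:, lo:hi], peth.rates[:, lo:hi], 0.0),
                         axis=1) * bw


def preference_index(A: float, B: float) -> float:
    """(A - B) / (A + B); NaN (flagged undefined) when A + B <= 0."""
    if not (np.isfinite(A) and np.isfinite(B)):
        return np.nan
    s = A + B
    if s <= 0:
        return np.nan
    return (A - B) / s


def classify_strong_preference(
    a_trials: np.ndarray,
    b_trials: np.ndarray,
    alpha: float = 0.05,
) -> tuple[str, float]:
    """Mann-Whitney U classification of a condition pair.

    Returns (side, p): side is "a" / "b" (whichever median response is
    larger) when p < alpha, else "none".  Exact U distribution for
    min(n) <= 12, normal approximation with tie correction otherwise;
    p-values deliberately uncorrected for multiple comparisons.
    """
    a = np.asarray(a_trials, float)
    b = np.asarray(b_trials, float)
    if min(a.size, b.size) < 3:
        raise ValueError("need at least 3 trials per side")
    method = "exact" if min(a.size, b.size) <= 12 and not _has_ties(a, b) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if p >= alpha:
        return "none", p
    return ("a" if np.median(a) > np.median(b) else "b"), p


def _has_ties(a, b) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def preference_grid_cell(
    laterality_side: str, manuality_side: str,
    laterality_sides=("ipsi", "contra"), manuality_sides=("uni", "bi"),
) -> tuple[str, str]:
    """Map axis outcomes into the 3x3 {ipsi,none,contra} x {uni,none,bi} grid."""
    lat = {"a": laterality_sides[0], "b": laterality_sides[1],
           "none": "none"}[laterality_side]
    man = {"a": manuality_sides[0], "b": manuality_sides[1],
           "none": "none"}[manuality_side]
    return lat, man


# ---------------------------------------------------------------------------
# earth mover's distance on the 3x3 preference grid
# ---------------------------------------------------------------------------

def grid_ground_metric(shape=(3, 3)) -> np.ndarray:
    """Euclidean distances between grid cells; adjacent cells at distance 1."""
    pos = np.array([(r, c) for r in range(shape[0]) for c in range(shape[1])],
                   dtype=float)
    return np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)


def emd(p: np.ndarray, q: np.ndarray, D: np.ndarray | None = None) -> float:
    """Earth mover's distance between two histograms via the transport LP.

    Histograms are flattened and normalized to unit mass; ``D`` defaults to
    the 3x3 Euclidean grid metric.
    """
    p = np.asarray(p, float).ravel()
    q = np.asarray(q, float).ravel()
    if D is None:
        if p.size != 9:
            raise ValueError("default metric assumes 3x3 histograms")
        D = grid_ground_metric()
    n = p.size
    if q.size != n or D.shape != (n, n):
        raise ValueError("shape mismatch")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("histograms must have positive mass")
    p = p / p.sum()
    q = q / q.sum()
    # flow variables F[i, j]: row sums = p, column sums = q
    A_eq = np.zeros((2 * n, n * n))
    for i in range(n):
        A_eq[i, i * n:(i + 1) * n] = 1.0
        A_eq[n + i, i::n] = 1.0
    b_eq = np.concatenate([p, q])
    res = linprog(D.ravel(), A_eq=A_eq[:-1], b_eq=b_eq[:-1],
                  bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


# ---------------------------------------------------------------------------
# distribution distances with permutation tests
# ---------------------------------------------------------------------------

@dataclass
class DistributionComparison:
    statistic_kind: str
    observed: float
    p_value: float
    n_permutations: int


def ks_distance(cdf_a: np.ndarray, cdf_b: np.ndarray) -> float:
    """Maximum absolute difference between two (averaged) CDF vectors."""
    return float(np.nanmax(np.abs(np.asarray(cdf_a) - np.asarray(cdf_b))))


def _ecdf_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    values = np.sort(values[np.isfinite(values)])
    if values.size == 0:
        return np.full(grid.size, np.nan)
    return np.searchsorted(values, grid, side="right") / values.size


def _recording_groups(df: pd.DataFrame):
    """Precomputed (key, row-index array) pairs per recording."""
    return [
        (key, g.index.to_numpy())
        for key, g in df.groupby(["mouse", "day", "probe"], sort=True)
    ]


def _mean_cdf_by_area_fast(values, labels, groups, grid, areas):
    out = {}
    for area in areas:
        entries = []
        for key, idx in groups:
            v = values[idx][labels[idx] == area]
            if v.size:
                entries.append((key, _ecdf_on_grid(v, grid)))
        out[area] = hierarchical_average_arrays(entries)
    return out


def ks_permutation_test(
    units: pd.DataFrame,
    areas: tuple[str, str],
    n_perm: int = 10000,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> DistributionComparison:
    """Area-label permutation test on the KS distance between mean PI CDFs.

    ``units`` has columns (mouse, day, probe, area, pi), one row per unit.
    Cumulative distributions are computed per recording, hierarchically
    averaged over probes, days and mice per area, then the KS distance between
    the two area-mean CDFs is compared against the distribution obtained by
    randomly reassigning the area label of each unit.  p = fraction of
    permuted statistics >= observed (no +1 smoothing, matching the bootstrap
    counting convention).
    """
    if grid is None:
        grid = np.linspace(-1.0, 1.0, 201)
    df = units.dropna(subset=["pi"]).reset_index(drop=True)
    values = df["pi"].to_numpy()
    labels = df["area"].to_numpy()
    groups = _recording_groups(df)
    cdfs = _mean_cdf_by_area_fast(values, labels, groups, grid, areas)
    if cdfs[areas[0]] is None or cdfs[areas[1]] is None:
        raise ValueError("both areas must contribute at least one recording")
    observed = ks_distance(cdfs[areas[0]], cdfs[areas[1]])
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels)
        c = _mean_cdf_by_area_fast(values, perm, groups, grid, areas)
        if c[areas[0]] is None or c[areas[1]] is None:
            perm_stats[i] = np.nan
            continue
        perm_stats[i] = ks_distance(c[areas[0]], c[areas[1]])
    perm_stats = perm_stats[np.isfinite(perm_stats)]
    p = float(np.sum(perm_stats >= observed) / max(perm_stats.size, 1))
    return DistributionComparison("ks_distance", observed, p, n_perm)


def _mean_hist_by_area_fast(cells, labels, groups, areas):
    out = {}
    for area in areas:
        entries = []
        for key, idx in groups:
            sel = cells[idx][labels[idx] == area]
            if sel.size:
                h = np.bincount(sel, minlength=9).astype(float)
                entries.append((key, h / h.sum()))
        out[area] = hierarchical_average_arrays(entries)
    return out


def emd_permutation_test(
    units: pd.DataFrame,
    areas: tuple[str, str],
    n_perm: int = 10000,
    seed: int = 0,
) -> DistributionComparison:
    """Area-label permutation test on the EMD between mean 3x3 category histograms.

    ``units`` has columns (mouse, day, probe, area, lat_idx, man_idx) with
    grid indices in 0..2.  Histograms are normalized per recording,
    hierarchically averaged per area, and compared under the Euclidean
    ground metric (unity distance between adjacent cells).
    """
    D = grid_ground_metric()
    df = units.reset_index(drop=True)
    cells = (df["lat_idx"].to_numpy() * 3 + df["man_idx"].to_numpy()).astype(int)
    labels = df["area"].to_numpy()
    groups = _recording_groups(df)
    hists = _mean_hist_by_area_fast(cells, labels, groups, areas)
    if hists[areas[0]] is None or hists[areas[1]] is None:
        raise ValueError("both areas must contribute at least one recording")
    h0 = np.nan_to_num(hists[areas[0]])
    h1 = np.nan_to_num(hists[areas[1]])
    observed = emd(h0, h1, D)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels)
        h = _mean_hist_by_area_fast(cells, perm, groups, areas)
        if h[areas[0]] is None or h[areas[1]] is None:
            perm_stats[i] = np.nan
            continue
        perm_stats[i] = emd(np.nan_to_num(h[areas[0]]),
                            np.nan_to_num(h[areas[1]]), D)
    perm_stats = perm_stats[np.isfinite(perm_stats)]
    p = float(np.sum(perm_stats >= observed) / max(perm_stats.size, 1))
    return DistributionComparison("emd", observed, p, n_perm)
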