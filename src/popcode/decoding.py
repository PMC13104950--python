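"""Ridge lagged-window decoding of kinematics from binned spikes.

The lagged design covers 200 ms before to 50 ms after the decoded bin (51
taps per unit at 5 ms); rows whose window crosses an epoch splice are
dropped.  Columns are z-scored on training statistics and the intercept is
unpenalized (implemented by centering).  Data are split into contiguous
tuning / training / testing thirds so temporal autocorrelation does not leak
across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from popcode.correlation import BinnedEpochActivity

LAG_BEFORE_S = 0.200
LAG_AFTER_S = 0.050
DEFAULT_LAMBDA_GRID = np.logspace(-2, 4, 13)
N_FOLDS = 5


@dataclass
class LaggedDesign:
    X: np.ndarray               # (n_rows, n_units * n_taps) lagged counts
    rows: np.ndarray            # indices into the source bin sequence
    n_units: int
    n_taps: int


def build_lagged_design(
    binned: BinnedEpochActivity,
    lag_before_s: float = LAG_BEFORE_S,
    lag_after_s: float = LAG_AFTER_S,
) -> LaggedDesign:
    """Stack lagged spike-count windows; drop rows spanning an epoch splice."""
    bin_s = binned.bin_s
    n_before = int(round(lag_before_s / bin_s))
    n_after = int(round(lag_after_s / bin_s))
    n_taps = n_before + n_after + 1
    counts = binned.counts.astype(float)
    n_bins, n_units = counts.shape
    rows = np.arange(n_before, n_bins - n_after)
    # window stays inside one epoch
    same = binned.epoch_ids[rows - n_before] == binned.epoch_ids[rows + n_after]
    rows = rows[same]
    if rows.size == 0:
        raise ValueError("no decodable rows: epochs shorter than the lag window")
    offsets = np.arange(-n_before, n_after + 1)
    X = np.empty((rows.size, n_units * n_taps))
    for j, off in enumerate(offsets):
        X[:, j::n_taps] = counts[rows + off]
    return LaggedDesign(X=X, rows=rows, n_units=n_units, n_taps=n_taps)


def split_sets(n_rows: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contiguous, disjoint, exhaustive thirds (sizes differ by at most 1)."""
    idx = np.arange(n_rows)
    cuts = [round(n_rows / 3), round(2 * n_rows / 3)]
    return idx[: cuts[0]], idx[cuts[0]: cuts[1]], idx[cuts[1]:]


@dataclass
class DecoderModel:
    coef: np.ndarray            # weights on z-scored columns
    intercept: float
    col_mean: np.ndarray
    col_scale: np.ndarray
    lam: float
    cv_r2: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.col_mean) / self.col_scale
        return Z @ self.coef + self.intercept


def _standardize_stats(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _ridge_solve_multi(X, y, lams):
    """Ridge solutions for every lambda from one eigendecomposition of X^T X."""
    mu, sd = _standardize_stats(X)
    Z = (X - mu) / sd
    ymu = y.mean()
    yc = y - ymu
    G = Z.T @ Z
    b = Z.T @ yc
    evals, evecs = np.linalg.eigh(G)
    vb = evecs.T @ b
    out = []
    for lam in lams:
        coef = evecs @ (vb / (evals + lam))
        out.append(DecoderModel(coef=coef, intercept=ymu, col_mean=mu,
                                col_scale=sd, lam=float(lam)))
    return out


def evaluate_decoder(model: DecoderModel, X: np.ndarray, y: np.ndarray) -> float:
    """Cross-validated R^2 = 1 - SS_res / SS_tot on the given rows."""
    pred = model.predict(X)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _contiguous_folds(n: int, k: int):
    edges = np.linspace(0, n, k + 1).round().astype(int)
    for i in range(k):
        test = np.arange(edges[i], edges[i + 1])
        train = np.concatenate([np.arange(0, edges[i]), np.arange(edges[i + 1], n)])
        yield train, test


def fit_decoder(
    X_tune: np.ndarray,
    y_tune: np.ndarray,
    X_train: np.ndarray,
    y_train: np.ndarray,
    lam_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_folds: int = N_FOLDS,
) -> DecoderModel:
    """Grid-search lambda by contiguous 5-fold CV on the tuning set, then
    refit on the training set at the chosen lambda.

    Rows with non-finite targets are dropped per set.
    """
    def clean(X, y):
        ok = np.isfinite(y)
        return X[ok], y[ok]

    X_tune, y_tune = clean(X_tune, y_tune)
    X_train, y_train = clean(X_train, y_train)
    if y_train.size == 0 or y_tune.size == 0:
        raise ValueError("no finite target samples")

    lam_grid = np.asarray(lam_grid, float)
    scores = np.zeros(lam_grid.size)
    for tr, te in _contiguous_folds(len(y_tune), n_folds):
        models = _ridge_solve_multi(X_tune[tr], y_tune[tr], lam_grid)
        for j, m in enumerate(models):
            scores[j] += evaluate_decoder(m, X_tune[te], y_tune[te])
    scores /= n_folds
    best = int(np.argmax(scores))
    model = _ridge_solve_multi(X_train, y_train, [lam_grid[best]])[0]
    model.cv_r2 = {float(l): float(s) for l, s in zip(lam_grid, scores)}
    return model


@dataclass
class GeneralizationResult:
    r2_within: float
    r2_cross: float
    percent_change: float
    kind: str


def generalize(
    cross_model: DecoderModel,
    X_test: np.ndarray,
    y_test: np.ndarray,
    r2_within: float,
    kind: str = "cross_body",
) -> GeneralizationResult:
    """Percent change in R^2 from the within-condition decoder to ``cross_model``.

    delta = (R2_cross - R2_within) / R2_within * 100; 0% is perfect
    generalization, -100% corresponds to the cross decoder scoring zero.
    Requires R2_within > 0.
    """
    if not r2_within > 0:
        raise ValueError("within-condition R^2 must be positive")
    ok = np.isfinite(y_test)
    r2_cross = evaluate_decoder(cross_model, X_test[ok], y_test[ok])
    pct = (r2_cross - r2_within) / r2_within * 100.0
    return GeneralizationResult(r2_within=r2_within, r2_cross=r2_cross,
                                percent_change=pct, kind=kind)


def bootstrap_generalization_null(
    X_test: np.ndarray,
    y_test: np.ndarray,
    model: DecoderModel,
    mode: str,
    n_boot: int = 1000,
    seed: int = 0,
    n_chunks: int = 20,
) -> np.ndarray:
    """Bootstrap distribution of percent-change under perfect / no generalization.

    The testing set is chunked into ``n_chunks`` contiguous pieces, the
    chunks permuted, and the first/last halves concatenated.  ``perfect``
    decodes each half's kinematics from its own neural data (one half
    arbitrarily designated within-condition); ``none`` decodes the first
    half's kinematics from the second half's neural data.  The same
    (within-condition) decoder is used throughout.
    """
    if mode not in ("perfect", "none"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(y_test)
    if n < 2 * n_chunks:
        raise ValueError("testing set too small to chunk")
    rng = np.random.default_rng(seed)
    edges = np.linspace(0, n, n_chunks + 1).round().astype(int)
    chunks = [np.arange(edges[i], edges[i + 1]) for i in range(n_chunks)]
    pred_all = model.predict(X_test)
    out = np.empty(n_boot)
    for b in range(n_boot):
        order = rng.permutation(n_chunks)
        h1 = np.concatenate([chunks[i] for i in order[: n_chunks // 2]])
        h2 = np.concatenate([chunks[i] for i in order[n_chunks // 2:]])
        ok1, ok2 = np.isfinite(y_test[h1]), np.isfinite(y_test[h2])
        y1, p1 = y_test[h1][ok1], pred_all[h1][ok1]
        y2, p2 = y_test[h2][ok2], pred_all[h2][ok2]
        r2_0 = _r2(y1, p1)
        if mode == "perfect":
            r2_c = _r2(y2, p2)
        else:
            m = min(y1.size, p2.size)
            r2_c = _r2(y1[:m], p2[:m])
        out[b] = (r2_c - r2_0) / r2_0 * 100.0 if r2_0 > 0 else np.nan
    return out


def _r2(y, pred):
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


# the area-level permutation contract is shared with population_geometry
from popcode.geometry import area_permutation_difference_test  # noqa: E402,F401
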