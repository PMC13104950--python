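"""Soft-normalized PCA of event-aligned activity and subspace comparisons.

All statistics operate on T x N matrices (time bins x units) of trial-mean,
soft-normalized PETHs per condition.  Columns (units) are mean-centered over
time before SVD by default so the PCA axes match cov(X, X); centering is
switchable because the upstream convention is not pinned down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import subspace_angles

SOFT_NORM_HZ = 5.0
ALIGNMENT_DIM = 10


def soft_normalize(trial_mean_peths: np.ndarray, c: float = SOFT_NORM_HZ) -> np.ndarray:
    """Divide each unit (column) by its maximum firing rate plus ``c``."""
    X = np.asarray(trial_mean_peths, float)
    denom = np.nanmax(X, axis=0) + c
    denom = np.where(denom > 0, denom, 1.0)
    return X / denom


@dataclass
class PcaDecomposition:
    scores: np.ndarray            # T x P
    loadings: np.ndarray          # P x N, rows orthonormal
    singular_values: np.ndarray
    explained_variance_fractions: np.ndarray
    column_means: np.ndarray


def pca_decompose(X: np.ndarray, center: bool = True) -> PcaDecomposition:
    """Full-rank SVD decomposition X ~= scores @ loadings (after centering)."""
    X = np.asarray(X, float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("X must be at least 2 x 2")
    mu = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    evf = var / total if total > 0 else np.zeros_like(var)
    return PcaDecomposition(
        scores=U * s, loadings=Vt, singular_values=s,
        explained_variance_fractions=evf, column_means=mu,
    )


def condition_covariance(X: np.ndarray) -> np.ndarray:
    """cov(X, X) over time with units as variables."""
    return np.cov(np.asarray(X, float), rowvar=False)


def participation_ratio(C: np.ndarray) -> float:
    """[tr(C)]^2 / tr(C^2) without an eigendecomposition."""
    C = np.asarray(C, float)
    tr = np.trace(C)
    tr2 = np.trace(C @ C)
    if tr2 <= 0:
        raise ValueError("covariance has no variance")
    return float(tr * tr / tr2)


def first_principal_angle(Q_a: np.ndarray, Q_b: np.ndarray) -> float:
    """Smallest principal angle (degrees) between two row-spanned subspaces."""
    Q_a = np.atleast_2d(np.asarray(Q_a, float))
    Q_b = np.atleast_2d(np.asarray(Q_b, float))
    angles = subspace_angles(Q_a.T, Q_b.T)
    return float(np.degrees(angles.min()))


def alignment_index(C_a: np.ndarray, Q_b: np.ndarray,
                    d: int = ALIGNMENT_DIM) -> float:
    """Variance of condition A captured by condition B's top-d PCs,
    normalized by A's own top-d variance.

    ``Q_b`` holds orthonormal rows; only its first ``d`` (or all, if fewer)
    are used.  The denominator is the sum of the top-d eigenvalues of C_a.
    """
    C_a = np.asarray(C_a, float)
    Q_b = np.atleast_2d(np.asarray(Q_b, float))[:d]
    d_eff = Q_b.shape[0]
    num = float(np.sum(Q_b @ C_a * Q_b))
    evals = np.linalg.eigvalsh(C_a)[::-1]
    den = float(np.sum(evals[:d_eff]))
    if den <= 0:
        raise ValueError("condition A carries no variance")
    return num / den


# ---------------------------------------------------------------------------
# bootstrap predictions
# ---------------------------------------------------------------------------

def _half_split(n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    return perm[: n // 2], perm[n // 2:]


def _weighted_average_peth(halves: list[np.ndarray]) -> np.ndarray:
    """Mean of per-condition trial-means (conditions weighted equally)."""
    return np.mean([h.mean(axis=0) for h in halves], axis=0)


def bootstrap_invariant_prediction(
    trial_peths: dict[str, np.ndarray],
    condition_pair: tuple[str, str],
    n_boot: int = 1000,
    seed: int = 0,
    k: int = 1,
    d: int = ALIGNMENT_DIM,
    center: bool = True,
):
    """Finite-data null for perfectly invariant encoding.

    Each iteration splits every condition's trials (arrays of shape
    (n_trials, T, N)) into two halves, averages the two conditions' trial
    means within each half (equal condition weighting), runs PCA per half,
    and records the first principal angle between the halves' top-k
    subspaces and the half-1 -> half-2 alignment index.  Returns
    (angles, alignment_indices) arrays of length n_boot.
    """
    rng = np.random.default_rng(seed)
    a, b = (trial_peths[c] for c in condition_pair)
    if min(a.shape[0], b.shape[0]) < 4:
        raise ValueError("need at least 4 trials per condition")
    angles = np.empty(n_boot)
    aligns = np.empty(n_boot)
    for i in range(n_boot):
        ia1, ia2 = _half_split(a.shape[0], rng)
        ib1, ib2 = _half_split(b.shape[0], rng)
        X1 = _weighted_average_peth([a[ia1], b[ib1]])
        X2 = _weighted_average_peth([a[ia2], b[ib2]])
        p1 = pca_decompose(X1, center=center)
        p2 = pca_decompose(X2, center=center)
        angles[i] = first_principal_angle(p1.loadings[:k], p2.loadings[:k])
        C1 = condition_covariance(X1)
        aligns[i] = alignment_index(C1, p2.loadings, d)
    return angles, aligns


def maximize_joint_projections(
    covariances: list[np.ndarray],
    dims: list[int],
    max_sweeps: int = 200,
    tol: float = 1e-10,
    return_history: bool = False,
):
    """Find jointly orthonormal row-blocks Q_i maximizing sum tr(Q_i C_i Q_i^T).

    Block-coordinate ascent: with the other blocks fixed, the optimal block
    is the top eigenvectors of C_i restricted to the orthogonal complement of
    the other blocks -- each update is exact, so the objective is
    non-decreasing by construction.
    """
    N = covariances[0].shape[0]
    if sum(dims) > N:
        raise ValueError("joint dimensionality exceeds ambient dimension")
    # initialize greedily
    Qs: list[np.ndarray] = []
    for C, d in zip(covariances, dims):
        basis = _complement_basis(Qs, N)
        Qs.append(_top_eigvecs_in(C, basis, d))
    history = [_joint_objective(Qs, covariances)]
    for _ in range(max_sweeps):
        for i, (C, d) in enumerate(zip(covariances, dims)):
            others = [Q for j, Q in enumerate(Qs) if j != i]
            basis = _complement_basis(others, N)
            Qs[i] = _top_eigvecs_in(C, basis, d)
        history.append(_joint_objective(Qs, covariances))
        if history[-1] - history[-2] <= tol * max(abs(history[-1]), 1.0):
            break
    if return_history:
        return Qs, np.array(history)
    return Qs


def _complement_basis(Qs: list[np.ndarray], N: int) -> np.ndarray:
    """Orthonormal basis (columns) of the complement of the stacked rows."""
    if not Qs:
        return np.eye(N)
    stacked = np.vstack(Qs)
    # null space via SVD
    _, s, Vt = np.linalg.svd(stacked, full_matrices=True)
    rank = int(np.sum(s > 1e-12))
    return Vt[rank:].T


def _top_eigvecs_in(C: np.ndarray, basis: np.ndarray, d: int) -> np.ndarray:
    """Top-d eigenvectors of C restricted to span(basis columns), as rows in R^N."""
    M = basis.T @ C @ basis
    evals, evecs = np.linalg.eigh(M)
    top = evecs[:, ::-1][:, :d]
    return (basis @ top).T


def _joint_objective(Qs, covariances) -> float:
    return float(sum(np.sum((Q @ C) * Q) for Q, C in zip(Qs, covariances)))


def bootstrap_orthogonal_prediction(
    trial_peths: dict[str, np.ndarray],
    mode: str,
    n_boot: int = 1000,
    seed: int = 0,
    k: int = 1,
    d: int = ALIGNMENT_DIM,
    subspace_dim: int = ALIGNMENT_DIM,
    center: bool = True,
):
    """Finite-data prediction under fully orthogonal condition subspaces.

    Each iteration splits trials in half and, on half 1, estimates condition
    A's signal subspace, condition B's signal subspace, and the jointly
    orthonormal frame maximizing A's explained variance in the complement of
    B's subspace.  The full condition-A trial mean is then rotated by the
    orthogonal map carrying A's estimated subspace onto that orthogonalized
    frame; condition B is left untouched.  The rotation preserves the noise
    statistics of the estimator exactly while making the signal subspaces
    orthogonal by construction, so the angle/alignment computed between the
    rotated A and raw B data estimate the finite-data expectation under
    maximal dependence.  In the noiseless orthogonal limit the rotation is
    the identity and the prediction collapses to exactly 90 degrees / zero
    alignment.

    ``laterality`` mode orthogonalizes ipsilateral against contralateral;
    ``manuality`` mode orthogonalizes the pooled unimanual (ipsi + contra)
    subspace against the bimanual subspace, evaluating the
    (ipsilateral, bimanual) pair.  Returns (angles, alignment_indices).
    """
    if mode not in ("laterality", "manuality"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    conds = ("ipsilateral", "contralateral", "bimanual")
    have = {c: trial_peths[c] for c in conds if c in trial_peths}
    N = next(iter(have.values())).shape[2]
    d_sub = min(subspace_dim, N // 2)
    full = {c: arr.mean(axis=0) for c, arr in have.items()}
    full = {c: X - X.mean(axis=0) for c, X in full.items()}
    angles = np.empty(n_boot)
    aligns = np.empty(n_boot)
    for i in range(n_boot):
        halves1, halves2 = {}, {}
        for c, arr in have.items():
            i1, i2 = _half_split(arr.shape[0], rng)
            halves1[c] = arr[i1].mean(axis=0)
            halves2[c] = arr[i2].mean(axis=0)
        if mode == "laterality":
            C_a = condition_covariance(halves1["ipsilateral"])
            S_b = pca_decompose(halves1["contralateral"],
                                center=center).loadings[:d_sub]
            targets = ("ipsilateral", "contralateral")
        else:
            C_a = (condition_covariance(halves1["ipsilateral"])
                   + condition_covariance(halves1["contralateral"]))
            S_b = pca_decompose(halves1["bimanual"],
                                center=center).loadings[:d_sub]
            targets = ("ipsilateral", "bimanual")
        evals, evecs = np.linalg.eigh(C_a)
        U = evecs[:, ::-1][:, :d_sub].T                 # A's own subspace
        V = _top_eigvecs_in(C_a, _complement_basis([S_b], N), d_sub)
        R = _rotation_between(U, V)
        # evaluate against the held-out half of B so the constraint estimate
        # and the evaluated estimate carry independent noise, as in the
        # observed statistic; the angle (top-PC noise on both sides) is
        # evaluated half-vs-half, the alignment (variance ratio of A) on the
        # full rotated A - each at the noise scale that calibrates it
        Xa_half = (halves2[targets[0]] - halves2[targets[0]].mean(axis=0)) @ R.T
        Xa_full = full[targets[0]] @ R.T
        Xb = halves2[targets[1]] - halves2[targets[1]].mean(axis=0)
        pb = pca_decompose(Xb, center=center)
        pa = pca_decompose(Xa_half, center=center)
        angles[i] = first_principal_angle(pa.loadings[:k], pb.loadings[:k])
        aligns[i] = alignment_index(condition_covariance(Xa_full),
                                    pb.loadings, d)
    return angles, aligns


def _rotation_between(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Orthogonal map sending the rows of U onto the rows of V.

    U and V hold orthonormal rows of equal count; completions of the two
    bases are paired arbitrarily (isotropic directions are unaffected in
    distribution).
    """
    N = U.shape[1]
    Bu = np.vstack([U, _complement_basis([U], N).T])
    Bv = np.vstack([V, _complement_basis([V], N).T])
    return Bv.T @ Bu


# ---------------------------------------------------------------------------
# area-difference permutation test
# ---------------------------------------------------------------------------

def area_permutation_difference_test(
    deviations: pd.DataFrame,
    areas: tuple[str, str],
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Two-sided permutation test on the between-area difference of mean deviations.

    ``deviations`` has one row per recording (columns mouse, day, probe,
    area, value), where value is the observed statistic minus the median
    bootstrap prediction, already averaged over conditions.  Values are
    averaged over probes, days and mice per area; the statistic is
    mean(area_0) - mean(area_1); area labels are permuted across recordings.
    Returns (observed difference, p, permutation distribution).
    """
    from popcode.io import hierarchical_average_arrays

    def stat(df):
        means = {}
        for area in areas:
            sub = df[df["area"] == area]
            if len(sub) == 0:
                return np.nan
            entries = [
                (key, np.array([g["value"].mean()]))
                for key, g in sub.groupby(["mouse", "day", "probe"])
            ]
            means[area] = hierarchical_average_arrays(entries)[0]
        return means[areas[0]] - means[areas[1]]

    observed = stat(deviations)
    rng = np.random.default_rng(seed)
    labels = deviations["area"].to_numpy()
    work = deviations.copy()
    perm = np.empty(n_perm)
    for i in range(n_perm):
        work["area"] = rng.permutation(labels)
        perm[i] = stat(work)
    perm = perm[np.isfinite(perm)]
    p = float(np.sum(np.abs(perm) >= abs(observed)) / max(perm.size, 1))
    return float(observed), p, perm
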