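"""Moment-to-moment pairwise correlations within food-handling conditions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from popcode.io import Recording

BIN_S = 0.005
MIN_BINS = 1000


@dataclass
class BinnedEpochActivity:
    """Concatenated 5 ms spike counts over one condition's food-handling epochs."""

    counts: np.ndarray          # (n_bins, n_units) integer counts
    epoch_ids: np.ndarray       # (n_bins,) which source epoch each bin came from
    bin_s: float
    unit_ids: list[str]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


def bin_and_slice(
    recording: Recording,
    epochs: np.ndarray,
    bin_s: float = BIN_S,
) -> BinnedEpochActivity:
    """Bin spikes at ``bin_s`` within each (start, end) epoch and concatenate.

    Bin phase is anchored at each epoch's start; partial terminal bins are
    dropped.  Epoch ids are preserved so lagged designs never span a splice.
    """
    epochs = np.asarray(epochs, float).reshape(-1, 2)
    all_edges = []
    ids = []
    for i, (s, t) in enumerate(epochs):
        n = int(np.floor((t - s) / bin_s))
        if n < 1:
            continue
        all_edges.append(s + np.arange(n + 1) * bin_s)
        ids.append(np.full(n, i))
    if not all_edges:
        raise ValueError("no epoch long enough for a single bin")
    counts_cols = []
    for u in recording.units:
        col = np.concatenate([
            np.diff(np.searchsorted(u.spike_times, e)) for e in all_edges
        ])
        counts_cols.append(col)
    return BinnedEpochActivity(
        counts=np.column_stack(counts_cols),
        epoch_ids=np.concatenate(ids),
        bin_s=bin_s,
        unit_ids=[u.unit_id for u in recording.units],
    )


@dataclass
class CorrelationStructure:
    matrix: np.ndarray          # N x N Pearson; NaN for zero-variance pairs
    vector: np.ndarray          # strict upper triangle, NaN-flagged
    n_undefined_pairs: int


def pairwise_correlation_matrix(binned: BinnedEpochActivity) -> CorrelationStructure:
    """Pearson correlation between all units' binned firing vectors.

    Pairs involving a zero-variance vector are flagged NaN (excluded
    pairwise, not per-unit) and counted.
    """
    X = binned.counts.astype(float)
    if X.shape[1] < 2:
        raise ValueError("need at least two units")
    if X.shape[0] < MIN_BINS:
        raise ValueError(f"need at least {MIN_BINS} bins")
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    zero = sd == 0
    R[zero, :] = np.nan
    R[:, zero] = np.nan
    np.fill_diagonal(R, 1.0)
    iu = np.triu_indices(X.shape[1], k=1)
    vec = R[iu]
    return CorrelationStructure(
        matrix=R, vector=vec, n_undefined_pairs=int(np.sum(~np.isfinite(vec))),
    )


def between_condition_similarity(a: CorrelationStructure,
                                 b: CorrelationStructure) -> float:
    """Pearson correlation between two conditions' correlation-structure vectors.

    Pairs undefined in either condition are dropped from both.
    """
    va, vb = a.vector, b.vector
    if va.shape != vb.shape:
        raise ValueError("conditions must share the same unit set")
    ok = np.isfinite(va) & np.isfinite(vb)
    if ok.sum() < 2:
        raise ValueError("too few defined pairs")
    return float(np.corrcoef(va[ok], vb[ok])[0, 1])


def condition_epochs(etho, condition: str, hemisphere: str) -> np.ndarray:
    """Food-handling (holding + oromanual) epochs for one condition.

    Unimanual conditions map through the hemisphere (the hand contralateral
    to the recorded hemisphere gives the contralateral condition); the mixed
    combined state is treated as non-food-handling.
    """
    from popcode.io import condition_for_hand

    if condition == "bimanual":
        states = ("both_holding", "both_oromanual")
    else:
        hand = hemisphere if condition == "ipsilateral" else (
            "left" if hemisphere == "right" else "right")
        states = (f"{hand}_holding", f"{hand}_oromanual")
    eps = [etho.epochs(s) for s in states]
    eps = [e for e in eps if len(e)]
    if not eps:
        return np.empty((0, 2))
    out = np.vstack(eps)
    return out[np.argsort(out[:, 0])]
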