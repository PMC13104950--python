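"""Shared machinery for the dependence-regime discrimination study.

Used by both the acceptance test and scripts/acceptance.py: generates one
matched synthetic session per (mode, replicate), measures the observed
cross-condition geometry / correlation / decoding statistics, and computes
the invariant and orthogonal finite-data bootstrap predictions.
"""

from __future__ import annotations

import numpy as np

from popcode import correlation as corr
from popcode import decoding as dec
from popcode import geometry as geo
from popcode import peth as pe
from popcode import synth

HEMISPHERE = "right"   # left hand -> contralateral, right hand -> ipsilateral


def _behavior():
    return synth.BehaviorConfig(
        cycles_per_condition=30,
        holding_duration_s=1.2,
        oromanual_duration_s=1.0,
        exp_decay_ms=150.0,
        block_gap_s=2.0,
        noise_sd_mm=0.4,
    )


def _condition_epochs_from_truth(kin, truth, hand):
    """Unimanual food-handling epochs for one hand from the ground-truth states.

    Matches the combined-ethogram convention: the hand is holding or
    oromanual while the other hand is 'other' (bimanual blocks excluded).
    """
    states = truth["states"][hand]
    other = truth["states"]["right" if hand == "left" else "left"]
    mask = ((states == "holding") | (states == "oromanual")) & (other == "other")
    dt = 1.0 / kin.frame_rate
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    starts, ends = idx[0::2], idx[1::2]
    return np.column_stack([kin.time_s[starts], kin.time_s[ends - 1] + dt])


def _trial_level_peths(rec, events_df, soft_norm_hz=5.0):
    """Per-hand-condition (trials, T, N) baseline-subtracted soft-normed stacks.

    The soft-norm denominator is shared across conditions (each unit's
    maximum trial-mean rate over all conditions, plus the constant) so that
    per-condition scaling noise cannot masquerade as subspace rotation.
    """
    raw = {}
    for cond in synth.HAND_CONDITIONS:
        onsets = events_df.loc[events_df["condition"] == cond,
                               "onset_s"].to_numpy()
        per_unit = []
        for u in rec.units:
            p = pe.build_peth(u.spike_times, onsets, rec.duration)
            p = pe.baseline_subtract(p)
            per_unit.append(np.nan_to_num(p.rates))
        arr = np.stack(per_unit)                       # (N, trials, T)
        raw[cond] = np.transpose(arr, (1, 2, 0))       # (trials, T, N)
    unit_max = np.max([raw[c].mean(axis=0).max(axis=0) for c in raw], axis=0)
    denom = unit_max + soft_norm_hz
    denom = np.where(denom > 0, denom, 1.0)
    return {c: arr / denom for c, arr in raw.items()}


def _decode_pct_change(kin, events_df, truth, rec, lam_grid, n_folds=3):
    """Cross-body generalization percent change, averaged over both directions.

    Decodes each unimanual condition's own hand-nose distance from the
    lagged spike design, then swaps decoders between the two unimanual
    conditions.
    """
    designs, targets = {}, {}
    for hand in ("left", "right"):
        eps = _condition_epochs_from_truth(kin, truth, hand)
        binned = corr.bin_and_slice(rec, eps)
        design = dec.build_lagged_design(binned)
        d = kin.d_left_nose if hand == "left" else kin.d_right_nose
        starts = eps[binned.epoch_ids, 0]
        within = np.concatenate([
            np.arange(np.sum(binned.epoch_ids == i))
            for i in np.unique(binned.epoch_ids)
        ])
        centers = starts + (within + 0.5) * binned.bin_s
        frames = np.clip((centers * kin.frame_rate).astype(int), 0,
                         kin.n_frames - 1)
        y = d[frames][design.rows]
        designs[hand] = design
        targets[hand] = y

    models, tests = {}, {}
    for hand in ("left", "right"):
        X, y = designs[hand].X, targets[hand]
        tune, train, test = dec.split_sets(len(y))
        m = dec.fit_decoder(X[tune], y[tune], X[train], y[train],
                            lam_grid=lam_grid, n_folds=n_folds)
        r2 = dec.evaluate_decoder(m, X[test], y[test])
        models[hand] = m
        tests[hand] = (X[test], y[test], r2)

    pcts = []
    for hand, other in (("left", "right"), ("right", "left")):
        X, y, r2 = tests[hand]
        if r2 <= 0:
            continue
        res = dec.generalize(models[other], X, y, r2)
        pcts.append(res.percent_change)
    return float(np.mean(pcts)) if pcts else np.nan


def run_replicate(mode: str, seed: int, n_units: int = 100,
                  n_boot: int = 120, decode_units: int = 12,
                  k: int = 1, d: int = 10) -> dict:
    """One matched dataset in the given dependence mode; all four statistics."""
    beh = _behavior()
    kin, events, truth = synth.generate_kinematics(beh, seed)

    # disjoint loading groups keep the fully-dependent condition subspaces
    # orthogonal even after per-unit soft normalization (a diagonal rescale
    # that tilts dense orthogonal blocks); baseline above the modulation
    # swing keeps rates in the near-linear regime
    pop = synth.PopulationConfig(
        n_units=n_units, dependence=mode, latent_dim=2, modulation_hz=16.0,
        baseline_rate_hz=20.0, profile="sustained", loading_style="disjoint")
    rec, _ = synth.generate_spikes(kin, events, pop, seed + 1)

    stacks = _trial_level_peths(rec, events)
    # ipsi = right hand (right hemisphere), contra = left hand
    pair = {"ipsilateral": stacks["right"], "contralateral": stacks["left"]}
    tm = {c: arr.mean(axis=0) for c, arr in pair.items()}
    pcas = {c: geo.pca_decompose(X) for c, X in tm.items()}
    angle = geo.first_principal_angle(pcas["ipsilateral"].loadings[:k],
                                      pcas["contralateral"].loadings[:k])
    C_ipsi = geo.condition_covariance(tm["ipsilateral"])
    align = geo.alignment_index(C_ipsi, pcas["contralateral"].loadings, d)

    inv_ang, inv_ali = geo.bootstrap_invariant_prediction(
        pair, ("ipsilateral", "contralateral"), n_boot=n_boot, seed=seed + 2,
        k=k, d=d)
    # orthogonalization rank matches the generator's latent dimensionality
    orth_ang, orth_ali = geo.bootstrap_orthogonal_prediction(
        pair, "laterality", n_boot=n_boot, seed=seed + 3, k=k, d=d,
        subspace_dim=2)

    sims = {}
    structures = {}
    for hand in ("left", "right"):
        eps = _condition_epochs_from_truth(kin, truth, hand)
        binned = corr.bin_and_slice(rec, eps)
        structures[hand] = corr.pairwise_correlation_matrix(binned)
    similarity = corr.between_condition_similarity(structures["left"],
                                                   structures["right"])

    dec_pop = synth.PopulationConfig(
        n_units=decode_units, dependence=mode, latent_dim=2,
        modulation_hz=0.0, baseline_rate_hz=25.0, baseline_rate_sd=3.0,
        encoding="linear_kinematic", kin_gain_hz=10.0)
    dec_rec, _ = synth.generate_spikes(kin, events, dec_pop, seed + 4)
    pct = _decode_pct_change(kin, events, truth, dec_rec,
                             lam_grid=np.logspace(0, 3, 4))

    return {
        "angle": angle,
        "alignment": align,
        "similarity": similarity,
        "pct_change": pct,
        "invariant_angle_ci": np.percentile(inv_ang, [2.5, 97.5]).tolist(),
        "invariant_align_ci": np.percentile(inv_ali, [2.5, 97.5]).tolist(),
        "orthogonal_angle_ci": np.percentile(orth_ang, [2.5, 97.5]).tolist(),
        "orthogonal_align_ci": np.percentile(orth_ali, [2.5, 97.5]).tolist(),
    }


def run_study(n_replicates: int = 20, seed: int = 0, **kw):
    out = {"invariant": [], "fully_dependent": []}
    for m_off, mode in enumerate(out):
        for r in range(n_replicates):
            out[mode].append(run_replicate(mode, seed + 1000 * r + 101 * m_off,
                                           **kw))
    return out
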