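"""End-to-end stage runners shared by the CLI and the smoke tests.

Each runner takes in-memory objects plus a config dict (see
``popcode.config.DEFAULTS``) and returns plain dict/DataFrame results that
the CLI serializes.  Single-recording stages: the cross-area permutation
tests need several recordings and live in their own modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from popcode import correlation as corr
from popcode import decoding as dec
from popcode import ethogram as eth
from popcode import geometry as geo
from popcode import peth as pe
from popcode import preference as pref
from popcode.io import Recording, apply_rate_filter, check_inclusion, condition_for_hand

CONDITIONS = ("ipsilateral", "contralateral", "bimanual")


def run_ethogram_stage(kin: eth.Kinematics, hemisphere: str, cfg: dict):
    """Segment behavior and detect condition-labeled transports."""
    eth.compute_distances(kin)
    ecfg = cfg["ethogram"]
    thr = {}
    for hand, d in (("left", kin.d_left_nose), ("right", kin.d_right_nose)):
        thr[hand] = eth.default_thresholds(d)
    etho = eth.segment_ethogram(
        kin,
        oromanual_threshold={h: t[0] for h, t in thr.items()},
        holding_threshold={h: t[1] for h, t in thr.items()},
        min_run_frames=ecfg["min_run_frames"],
        speed_threshold=np.inf if ecfg["speed_threshold_mm_s"] is None
        else ecfg["speed_threshold_mm_s"],
    )
    events = eth.detect_transports(
        etho, kin, hemisphere,
        synchrony_window_s=ecfg["synchrony_window_s"],
        fit_margin_s=ecfg["fit_margin_s"],
    )
    return etho, eth.events_to_frame(events)


def _oromanual_epochs(etho: eth.Ethogram) -> np.ndarray:
    eps = [etho.epochs(s) for s in
           ("left_oromanual", "right_oromanual", "both_oromanual")]
    eps = [e for e in eps if len(e)]
    if not eps:
        return np.empty((0, 2))
    out = np.vstack(eps)
    return out[np.argsort(out[:, 0])]


def run_peth_stage(
    recording: Recording,
    events: pd.DataFrame,
    etho: eth.Ethogram | None,
    cfg: dict,
    seed: int = 0,
):
    """Build baseline-subtracted PETHs and bootstrap responsiveness.

    ``events`` must carry resolved condition labels and excluded flags.
    Returns a dict with per-condition trial-level rate stacks
    (n_units, n_trials, n_bins), p-values, categories and the inclusion
    decision.
    """
    pcfg = cfg["peth"]
    retained = events[~events.get("excluded", False)] if "excluded" in events else events
    orom = _oromanual_epochs(etho) if etho is not None else None
    ev_counts = {c: int((retained["condition"] == c).sum()) for c in CONDITIONS}

    peths: dict[str, dict] = {}
    pvalues: dict[str, dict[str, float]] = {u.unit_id: {} for u in recording.units}
    rng = np.random.default_rng(seed)
    for cond in CONDITIONS:
        onsets = retained.loc[retained["condition"] == cond, "onset_s"].to_numpy()
        if onsets.size == 0:
            continue
        stacks, masks = [], []
        for u in recording.units:
            p = pe.build_peth(u.spike_times, onsets, recording.duration, orom,
                              window=tuple(pcfg["window_s"]),
                              bin_width=pcfg["bin_width_s"])
            p_bs = pe.baseline_subtract(
                p, orom, baseline_window=tuple(pcfg["baseline_window_s"]))
            stacks.append(p_bs.rates)
            masks.append(p_bs.mask)
            pvalues[u.unit_id][cond] = pe.bootstrap_significance(
                u.spike_times, onsets, recording.duration,
                n_boot=pcfg["n_boot"], seed=int(rng.integers(2**31)),
                orom_epochs=orom, stat_window=tuple(pcfg["stat_window_s"]),
                bin_width=pcfg["bin_width_s"])
        n_trials = min(s.shape[0] for s in stacks)
        peths[cond] = {
            "rates": np.stack([s[:n_trials] for s in stacks]),
            "mask": np.stack([m[:n_trials] for m in masks]),
            "bin_edges": pe._bin_edges(tuple(pcfg["window_s"]), pcfg["bin_width_s"]),
            "onsets": onsets,
        }

    categories, proportions = pe.categorize_responsiveness(
        pvalues, alpha=pcfg["alpha"])
    n_responsive = sum(
        1 for ps in pvalues.values()
        if any(p < pcfg["alpha"] for p in ps.values())
    )
    decision = check_inclusion(recording, ev_counts, profile="peth",
                               n_responsive=n_responsive)
    return {
        "peths": peths,
        "pvalues": pvalues,
        "categories": categories,
        "proportions": proportions,
        "n_responsive": n_responsive,
        "inclusion": decision,
        "event_counts": ev_counts,
    }


def trial_mean_stacks(peth_result: dict) -> dict[str, np.ndarray]:
    """Per-condition (T, N) trial-mean matrices from the stage output."""
    out = {}
    for cond, d in peth_result["peths"].items():
        rates = np.where(d["mask"], d["rates"], np.nan)
        with np.errstate(invalid="ignore"):
            out[cond] = np.nanmean(rates, axis=1).T  # (n_bins, n_units)
    return out


def run_preference_stage(peth_result: dict, cfg: dict):
    """Preference indices and strong-preference grid cells per unit."""
    pcfg = cfg["preference"]
    peths = peth_result["peths"]
    if not all(c in peths for c in CONDITIONS):
        raise ValueError("preference stage needs all three conditions")
    rows = []
    n_units = next(iter(peths.values()))["rates"].shape[0]
    bin_edges = next(iter(peths.values()))["bin_edges"]
    for ui in range(n_units):
        unit_p = {}
        for cond in CONDITIONS:
            d = peths[cond]
            unit_p[cond] = pe.Peth(rates=d["rates"][ui], mask=d["mask"][ui],
                                   bin_edges=bin_edges, event_times=d["onsets"])
        resp = {}
        for cond in CONDITIONS:
            A, pk, trunc = pref.response_magnitude(
                unit_p[cond], peak_window=tuple(pcfg["peak_window_s"]))
            resp[cond] = {"A": A, "peak": pk, "truncated": trunc}
        pi_lat = pref.preference_index(resp["ipsilateral"]["A"],
                                       resp["contralateral"]["A"])
        pref_uni = ("ipsilateral"
                    if resp["ipsilateral"]["A"] > resp["contralateral"]["A"]
                    else "contralateral")
        pi_man = pref.preference_index(resp["bimanual"]["A"], resp[pref_uni]["A"])

        lat_cell, man_cell, p_lat, p_man = "none", "none", np.nan, np.nan
        try:
            a = pref.trial_responses(unit_p["ipsilateral"],
                                     resp["ipsilateral"]["peak"])
            b = pref.trial_responses(unit_p["contralateral"],
                                     resp["contralateral"]["peak"])
            side, p_lat = pref.classify_strong_preference(a, b, pcfg["mw_alpha"])
            lat_cell = {"a": "ipsi", "b": "contra", "none": "none"}[side]
            c = pref.trial_responses(unit_p["bimanual"], resp["bimanual"]["peak"])
            u = pref.trial_responses(unit_p[pref_uni], resp[pref_uni]["peak"])
            side, p_man = pref.classify_strong_preference(c, u, pcfg["mw_alpha"])
            man_cell = {"a": "bi", "b": "uni", "none": "none"}[side]
        except ValueError:
            pass
        rows.append({
            "unit_index": ui,
            "A_ipsi": resp["ipsilateral"]["A"],
            "A_contra": resp["contralateral"]["A"],
            "A_bi": resp["bimanual"]["A"],
            "pi_laterality": pi_lat,
            "pi_manuality": pi_man,
            "laterality_cell": lat_cell,
            "manuality_cell": man_cell,
            "p_laterality": p_lat,
            "p_manuality": p_man,
        })
    return pd.DataFrame(rows)


def run_geometry_stage(peth_result: dict, cfg: dict, seed: int = 0):
    """Per-condition PCA statistics, pairwise angles/alignment, and bootstraps."""
    gcfg = cfg["geometry"]
    k = gcfg["angle_subspace_dim"]
    d = gcfg["alignment_dim"]
    peths = peth_result["peths"]
    conds = [c for c in CONDITIONS if c in peths]

    # soft-normalize by each unit's trial-mean maximum over all conditions,
    # so per-condition scaling noise cannot masquerade as subspace rotation
    tm = trial_mean_stacks(peth_result)
    denom = np.nanmax(np.stack([np.nanmax(tm[c], axis=0) for c in conds]),
                      axis=0) + gcfg["soft_norm_hz"]
    denom = np.where(denom > 0, denom, 1.0)
    trial_level: dict[str, np.ndarray] = {}
    norm_tm: dict[str, np.ndarray] = {}
    for c in conds:
        norm_tm[c] = np.nan_to_num(tm[c] / denom)
        rates = np.nan_to_num(np.where(peths[c]["mask"], peths[c]["rates"], 0.0))
        trial_level[c] = np.transpose(rates, (1, 2, 0)) / denom  # (trials, T, N)

    out: dict = {"per_condition": {}, "pairs": {}, "bootstrap": {}}
    pcas = {}
    for c in conds:
        p = geo.pca_decompose(norm_tm[c], center=gcfg["center"])
        pcas[c] = p
        C = geo.condition_covariance(norm_tm[c])
        out["per_condition"][c] = {
            "top_pc_evf": float(p.explained_variance_fractions[0]),
            "participation_ratio": geo.participation_ratio(C),
        }
    rng = np.random.default_rng(seed)
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            Ca = geo.condition_covariance(norm_tm[a])
            pair = {
                "first_principal_angle_deg": geo.first_principal_angle(
                    pcas[a].loadings[:k], pcas[b].loadings[:k]),
                "alignment_index": geo.alignment_index(Ca, pcas[b].loadings, d),
            }
            ang, ali = geo.bootstrap_invariant_prediction(
                trial_level, (a, b), n_boot=gcfg["n_boot"],
                seed=int(rng.integers(2**31)), k=k, d=d, center=gcfg["center"])
            pair["invariant_prediction"] = {
                "angle_deg": ang.tolist(), "alignment": ali.tolist()}
            out["pairs"][f"{a}|{b}"] = pair
    if all(c in trial_level for c in ("ipsilateral", "contralateral")):
        ang, ali = geo.bootstrap_orthogonal_prediction(
            trial_level, "laterality", n_boot=gcfg["n_boot"],
            seed=int(rng.integers(2**31)), k=k, d=d, center=gcfg["center"])
        out["bootstrap"]["orthogonal_laterality"] = {
            "angle_deg": ang.tolist(), "alignment": ali.tolist()}
    return out


def run_correlation_stage(recording: Recording, etho: eth.Ethogram, cfg: dict):
    """Pairwise 5 ms correlation structure per condition and pair similarities."""
    rec = apply_rate_filter(recording, cfg["inclusion"]["min_rate_hz"])
    structures = {}
    bins = {}
    for cond in CONDITIONS:
        eps = corr.condition_epochs(etho, cond, rec.hemisphere)
        if len(eps) == 0:
            continue
        binned = corr.bin_and_slice(rec, eps, bin_s=cfg["correlation"]["bin_s"])
        bins[cond] = binned.n_bins
        if binned.n_bins >= corr.MIN_BINS:
            structures[cond] = corr.pairwise_correlation_matrix(binned)
    sims = {}
    conds = list(structures)
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            sims[f"{a}|{b}"] = corr.between_condition_similarity(
                structures[a], structures[b])
    return {"structures": structures, "similarities": sims, "bins": bins}


def _sample_channel(kin: eth.Kinematics, limb: str, dim: int,
                    binned: corr.BinnedEpochActivity,
                    epochs: np.ndarray) -> np.ndarray:
    """Kinematic value for each 5 ms bin center (NaN where the marker is missing)."""
    pos = kin.left if limb == "left" else kin.right
    trace = pos[:, dim]
    starts = epochs[binned.epoch_ids, 0]
    within = np.concatenate([
        np.arange(np.sum(binned.epoch_ids == i)) for i in
        np.unique(binned.epoch_ids)
    ])
    centers = starts + (within + 0.5) * binned.bin_s
    frames = np.clip((centers * kin.frame_rate).astype(int), 0, kin.n_frames - 1)
    return trace[frames]


def run_decoding_stage(
    recording: Recording,
    kin: eth.Kinematics,
    etho: eth.Ethogram,
    events: pd.DataFrame,
    cfg: dict,
    seed: int = 0,
):
    """Fit per-condition decoders, evaluate generalization, and run the nulls."""
    dcfg = cfg["decoding"]
    rec = apply_rate_filter(recording, cfg["inclusion"]["min_rate_hz"])
    max_units = dcfg.get("max_units")
    if max_units and rec.n_units > max_units:
        rec = Recording(rec.mouse_id, rec.day_id, rec.probe_id, rec.area,
                        rec.hemisphere, rec.duration, rec.units[:max_units])
    g = dcfg["lambda_grid"]
    lam_grid = np.logspace(g["log10_min"], g["log10_max"], g["n"])
    dim_index = {"x": 0, "y": 1, "z": 2}
    hemi = rec.hemisphere
    limb_of = {"ipsilateral": hemi,
               "contralateral": "left" if hemi == "right" else "right"}

    retained = events[~events["excluded"]] if "excluded" in events else events
    ev_counts = {c: int((retained["condition"] == c).sum()) for c in CONDITIONS}

    designs, targets, bins = {}, {}, {}
    for cond in CONDITIONS:
        eps = corr.condition_epochs(etho, cond, hemi)
        if len(eps) == 0:
            continue
        binned = corr.bin_and_slice(rec, eps, bin_s=dcfg.get("bin_s", 0.005))
        bins[cond] = binned.n_bins
        design = dec.build_lagged_design(binned, dcfg["lag_before_s"],
                                         dcfg["lag_after_s"])
        designs[cond] = design
        limbs = ["left", "right"] if cond == "bimanual" else [limb_of[cond]]
        targets[cond] = {}
        for limb in limbs:
            for dname in dcfg["dims"]:
                y = _sample_channel(kin, limb, dim_index[dname], binned, eps)
                targets[cond][(limb, dname)] = y[design.rows]

    decision = check_inclusion(rec, ev_counts, bins, profile="corr_decode")

    models, results = {}, []
    for cond, design in designs.items():
        tune, train, test = dec.split_sets(design.X.shape[0])
        for (limb, dname), y in targets[cond].items():
            model = dec.fit_decoder(design.X[tune], y[tune],
                                    design.X[train], y[train], lam_grid,
                                    n_folds=dcfg["n_folds"])
            ok = np.isfinite(y[test])
            r2 = dec.evaluate_decoder(model, design.X[test][ok], y[test][ok])
            models[(cond, limb, dname)] = (model, test, r2)
            results.append({"condition": cond, "limb": limb, "dim": dname,
                            "lambda": model.lam, "r2": r2})

    gen_rows = []
    rng = np.random.default_rng(seed)
    # cross-body: decoder from the other unimanual condition
    uni = [c for c in ("ipsilateral", "contralateral") if c in designs]
    if len(uni) == 2:
        for cond, other in ((uni[0], uni[1]), (uni[1], uni[0])):
            for dname in dcfg["dims"]:
                key = (cond, limb_of[cond], dname)
                okey = (other, limb_of[other], dname)
                if key not in models or okey not in models:
                    continue
                model, test, r2_within = models[key]
                if r2_within <= 0:
                    continue
                cross_model = models[okey][0]
                y = targets[cond][(limb_of[cond], dname)][test]
                res = dec.generalize(cross_model, designs[cond].X[test], y,
                                     r2_within, kind="cross_body")
                gen_rows.append({"kind": "cross_body", "condition": cond,
                                 "limb": limb_of[cond], "dim": dname,
                                 "r2_within": res.r2_within,
                                 "r2_cross": res.r2_cross,
                                 "pct_change": res.percent_change})
    # uni-to-bimanual: same limb, decoder from the unimanual condition
    if "bimanual" in designs:
        for cond in uni:
            limb = limb_of[cond]
            for dname in dcfg["dims"]:
                key = ("bimanual", limb, dname)
                okey = (cond, limb, dname)
                if key not in models or okey not in models:
                    continue
                model, test, r2_within = models[key]
                if r2_within <= 0:
                    continue
                y = targets["bimanual"][(limb, dname)][test]
                res = dec.generalize(models[okey][0], designs["bimanual"].X[test],
                                     y, r2_within, kind="uni_to_bimanual")
                gen_rows.append({"kind": "uni_to_bimanual", "condition": "bimanual",
                                 "limb": limb, "dim": dname,
                                 "r2_within": res.r2_within,
                                 "r2_cross": res.r2_cross,
                                 "pct_change": res.percent_change})

    nulls = {}
    for (cond, limb, dname), (model, test, r2) in models.items():
        if r2 <= 0:
            continue
        y = targets[cond][(limb, dname)][test]
        X = designs[cond].X[test]
        try:
            nulls[f"{cond}|{limb}|{dname}"] = {
                mode: dec.bootstrap_generalization_null(
                    X, y, model, mode, n_boot=dcfg["n_boot"],
                    seed=int(rng.integers(2**31)), n_chunks=dcfg["n_chunks"]
                ).tolist()
                for mode in ("perfect", "none")
            }
        except ValueError:
            continue

    gen_cols = ["kind", "condition", "limb", "dim", "r2_within", "r2_cross",
                "pct_change"]
    return {
        "results": pd.DataFrame(results),
        "generalization": pd.DataFrame(gen_rows, columns=gen_cols),
        "nulls": nulls,
        "inclusion": decision,
        "bins": bins,
    }


def resolve_truth_events(events: pd.DataFrame, hemisphere: str) -> pd.DataFrame:
    """Map ground-truth hand-labeled events to condition labels."""
    ev = events.copy()
    ev["hand"] = ev["condition"]
    ev["condition"] = [condition_for_hand(h, hemisphere) for h in ev["hand"]]
    ev["excluded"] = False
    return ev
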