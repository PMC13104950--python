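"""Synthetic kinematics, ethogram ground truth, and Poisson spike trains.

Behavior is built from alternating holding/chewing and oromanual/ingestion
cycles: hand-nose distance sits on a holding plateau, drops sigmoidally at
each transport-to-mouth, sits on an oromanual plateau, and rises back
exponentially at lowering-from-mouth.  Spike trains are inhomogeneous Poisson
draws from rectified rates ``baseline + loadings . latent(t)``, where the
per-condition loading matrices realize the dependence taxonomy (invariant /
laterality-dependent / manuality-dependent / fully dependent), optionally
plus a lag-filtered linear drive from the kinematics for decoder-recovery
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from popcode import io as pio
from popcode.ethogram import Kinematics, compute_distances

HAND_CONDITIONS = ("left", "right", "bimanual")
DEPENDENCE_MODES = (
    "invariant", "laterality_dependent", "manuality_dependent", "fully_dependent",
)

_LOGIT95 = float(np.log(0.95 / 0.05))  # 5%-95% span of a logistic in rate units

# rate -> Poisson discretization step (seconds); spikes jittered within bin
SPIKE_DT = 1e-3


@dataclass
class BehaviorConfig:
    frame_rate: float = 200.0
    cycles_per_condition: int = 10
    schedule: tuple[str, ...] = ("left", "right", "bimanual")
    holding_duration_s: float = 2.0
    oromanual_duration_s: float = 1.5
    duration_jitter: float = 0.15          # fractional s.d. on epoch durations
    holding_dist_mm: float = 18.0
    holding_dist_sd_mm: float = 0.8        # across cycles
    oromanual_dist_mm: float = 5.0
    oromanual_dist_sd_mm: float = 0.4
    rest_dist_mm: float = 40.0
    sigmoid_rise_ms: float = 150.0         # 5%-95% drop time of the transport
    exp_decay_ms: float = 250.0            # lowering time constant
    noise_sd_mm: float = 0.0               # per-frame positional noise
    block_gap_s: float = 3.0
    occlusion_fraction: float = 0.7        # missing frames on the blocked hand

    def __post_init__(self):
        if not self.oromanual_dist_mm < self.holding_dist_mm:
            raise ValueError("oromanual distance mean must be below holding mean")
        for name in ("holding_duration_s", "oromanual_duration_s",
                     "sigmoid_rise_ms", "exp_decay_ms", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for cond in self.schedule:
            if cond not in HAND_CONDITIONS:
                raise ValueError(f"unknown schedule entry {cond!r}")


@dataclass
class PopulationConfig:
    n_units: int = 40
    baseline_rate_hz: float = 8.0
    baseline_rate_sd: float = 2.0
    latent_dim: int = 2
    dependence: str = "invariant"
    modulation_hz: float = 8.0             # per-unit event-locked rate swing
    profile: str = "transient"             # "transient" (fl-M1) | "sustained" (LOM)
    transient_sigma_s: float = 0.10
    sustained_tau_s: float = 1.2           # free parameter, not a claim
    latent_lag_s: float = 0.08             # lag spacing between latent dims
    encoding: str = "latent_only"          # | "linear_kinematic"
    kin_gain_hz: float = 0.0
    n_kin_taps: int = 11                   # 5 ms taps, centered on the frame
    kin_tap_step_s: float = 0.005
    #: "rotation": dense orthonormal loading blocks (orthogonality holds in
    #: raw rate space only); "disjoint": each condition drives its own unit
    #: subset with Walsh-pattern weights, so cross-condition orthogonality
    #: survives any per-unit rescaling (e.g. soft normalization)
    loading_style: str = "rotation"

    def __post_init__(self):
        if self.dependence not in DEPENDENCE_MODES:
            raise ValueError(f"unknown dependence mode {self.dependence!r}")
        if self.profile not in ("transient", "sustained"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.encoding not in ("latent_only", "linear_kinematic"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.baseline_rate_hz < 0:
            raise ValueError("baseline rate must be >= 0")
        if self.loading_style not in ("rotation", "disjoint"):
            raise ValueError(f"unknown loading style {self.loading_style!r}")


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def _jitter(rng, mean, frac):
    return max(mean * (1.0 + frac * rng.standard_normal()), 0.2 * mean)


def generate_kinematics(cfg: BehaviorConfig, seed: int):
    """Generate a session of kinematics plus ground-truth events and states.

    Returns (Kinematics, events DataFrame, truth dict).  Events carry the true
    transport onset (the 5% departure time of each sigmoid drop) and the hand
    condition; the truth dict holds the noiseless distance traces, the
    per-frame ground-truth states, and reproducible segmentation thresholds.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / cfg.frame_rate
    rise = cfg.sigmoid_rise_ms / 1000.0
    tau = cfg.exp_decay_ms / 1000.0
    rate_sig = 2.0 * _LOGIT95 / rise
    segments = {"left": [], "right": []}  # (t0, t1, kind, params)
    events = []
    t = cfg.block_gap_s

    for cond in cfg.schedule:
        hands = ["left", "right"] if cond == "bimanual" else [cond]
        hold = {h: _jitter(rng, cfg.holding_dist_mm, cfg.holding_dist_sd_mm
                           / cfg.holding_dist_mm) for h in hands}
        for h in hands:
            segments[h].append((t - cfg.block_gap_s, t, "rest", {}))
        for _ in range(cfg.cycles_per_condition):
            hd = _jitter(rng, cfg.holding_duration_s, cfg.duration_jitter)
            od = _jitter(rng, cfg.oromanual_duration_s, cfg.duration_jitter)
            orom = {h: _jitter(rng, cfg.oromanual_dist_mm, cfg.oromanual_dist_sd_mm
                               / cfg.oromanual_dist_mm) for h in hands}
            t_hold_end = t + hd
            t_mid = t_hold_end + rise            # sigmoid midpoint
            t_drop_end = t_hold_end + 2.0 * rise
            t_orom_end = t_drop_end + od
            t_rise_end = t_orom_end + 5.0 * tau
            next_hold = {h: _jitter(rng, cfg.holding_dist_mm, cfg.holding_dist_sd_mm
                                    / cfg.holding_dist_mm) for h in hands}
            for h in hands:
                segments[h].append((t, t_hold_end, "plateau", {"level": hold[h]}))
                segments[h].append((t_hold_end, t_drop_end, "sigmoid",
                                    {"upper": hold[h], "lower": orom[h],
                                     "t_mid": t_mid, "rate": rate_sig}))
                segments[h].append((t_drop_end, t_orom_end, "plateau",
                                    {"level": orom[h]}))
                segments[h].append((t_orom_end, t_rise_end, "exponential",
                                    {"start": orom[h], "asym": next_hold[h],
                                     "t_on": t_orom_end, "tau": tau}))
            onset = t_mid - rise / 2.0          # 5% departure of the drop
            events.append({"onset_s": onset, "condition": cond,
                           "kind": "transport"})
            hold = next_hold
            t = t_rise_end
        for h in hands:
            segments[h].append((t, t + cfg.block_gap_s, "rest", {}))
        t += cfg.block_gap_s
        # hand no longer scheduled: rest until its next block (filled below)

    duration = t
    n_frames = int(np.floor(duration / dt))
    time_s = np.arange(n_frames) * dt

    def eval_trace(segs):
        d = np.full(n_frames, cfg.rest_dist_mm)
        for (t0, t1, kind, p) in segs:
            sl = slice(int(np.ceil(t0 / dt)), min(int(np.ceil(t1 / dt)), n_frames))
            tt = time_s[sl]
            if kind == "plateau":
                d[sl] = p["level"]
            elif kind == "sigmoid":
                d[sl] = p["lower"] + (p["upper"] - p["lower"]) / (
                    1.0 + np.exp(p["rate"] * (tt - p["t_mid"])))
            elif kind == "exponential":
                d[sl] = p["asym"] - (p["asym"] - p["start"]) * np.exp(
                    -(tt - p["t_on"]) / p["tau"])
        return d

    model = {h: eval_trace(segments[h]) for h in ("left", "right")}

    # ground-truth states from pure thresholding of the noiseless model
    orom_thr = 0.5 * (cfg.oromanual_dist_mm + cfg.holding_dist_mm)
    hold_thr = 0.5 * (cfg.holding_dist_mm + cfg.rest_dist_mm)
    truth_states = {}
    for h in ("left", "right"):
        s = np.full(n_frames, "other", dtype=object)
        s[model[h] < hold_thr] = "holding"
        s[model[h] < orom_thr] = "oromanual"
        truth_states[h] = s

    # occlusion of the blocked hand during unimanual blocks
    active = {h: np.zeros(n_frames, dtype=bool) for h in ("left", "right")}
    for h in ("left", "right"):
        for (t0, t1, kind, _) in segments[h]:
            if kind != "rest":
                sl = slice(int(np.ceil(t0 / dt)), min(int(np.ceil(t1 / dt)), n_frames))
                active[h][sl] = True
    valid = {}
    for h in ("left", "right"):
        v = np.ones(n_frames, dtype=bool)
        blocked = ~active[h]
        occl = rng.random(n_frames) < cfg.occlusion_fraction
        v[blocked & occl] = False
        valid[h] = v
        truth_states[h][~v] = "other"

    nose = np.zeros((n_frames, 3))
    pos = {}
    for h in ("left", "right"):
        p = np.zeros((n_frames, 3))
        p[:, 2] = -model[h]
        if cfg.noise_sd_mm > 0:
            p += rng.normal(0.0, cfg.noise_sd_mm, size=p.shape)
        p[~valid[h]] = np.nan
        pos[h] = p

    kin = Kinematics(
        time_s=time_s, left=pos["left"], right=pos["right"], nose=nose,
        l_valid=valid["left"], r_valid=valid["right"],
        n_valid=np.ones(n_frames, dtype=bool),
    )
    compute_distances(kin)
    events_df = pd.DataFrame(events)
    truth = {
        "duration": duration,
        "model_distance": model,
        "states": truth_states,
        "oromanual_threshold": orom_thr,
        "holding_threshold": hold_thr,
        "sigmoid_rate": rate_sig,
        "exp_tau": tau,
    }
    return kin, events_df, truth


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def _walsh_block(m: int, L: int) -> np.ndarray:
    """m x L orthonormal columns of +-1/sqrt(m) Walsh sign patterns."""
    from scipy.linalg import hadamard

    size = 1 << (m.bit_length() - 1)      # largest power of two <= m
    if L > size:
        raise ValueError("latent dimension too large for the unit group")
    H = hadamard(size) / np.sqrt(size)
    block = np.zeros((m, L))
    block[:size] = H[:, :L]
    return block


def _disjoint_loadings(cfg: PopulationConfig, rng) -> dict[str, np.ndarray]:
    """Condition loadings on disjoint (randomly assigned) unit subsets.

    Cross-condition subspaces are orthogonal under any per-unit rescaling,
    because distinct conditions drive distinct units.
    """
    n, L = cfg.n_units, cfg.latent_dim
    m = n // 3
    perm = rng.permutation(n)
    groups = [perm[i * m:(i + 1) * m] for i in range(3)]
    amp = cfg.modulation_hz * np.sqrt(m)

    def block_on(group):
        W = np.zeros((n, L))
        W[np.sort(group)] = _walsh_block(m, L)
        return W

    if cfg.dependence == "invariant":
        b = block_on(groups[0])
        W = {c: b for c in HAND_CONDITIONS}
    elif cfg.dependence == "laterality_dependent":
        b0, b1 = block_on(groups[0]), block_on(groups[1])
        W = {"left": b0, "right": b1, "bimanual": (b0 + b1) / np.sqrt(2.0)}
    elif cfg.dependence == "manuality_dependent":
        b0, b1 = block_on(groups[0]), block_on(groups[1])
        W = {"left": b0, "right": b0, "bimanual": b1}
    else:
        bs = [block_on(g) for g in groups]
        W = dict(zip(HAND_CONDITIONS, bs))
    return {c: amp * w for c, w in W.items()}


def _condition_loadings(cfg: PopulationConfig, rng) -> dict[str, np.ndarray]:
    """Per-condition loading matrices (n_units x latent_dim).

    Column spaces are drawn from a single orthonormal frame so that the
    dependence modes are exact by construction: invariant shares one block,
    fully_dependent uses three mutually orthogonal blocks, etc.
    """
    if cfg.loading_style == "disjoint":
        return _disjoint_loadings(cfg, rng)
    n, L = cfg.n_units, cfg.latent_dim
    if 3 * L > n:
        raise ValueError("need n_units >= 3 * latent_dim")
    frame, _ = np.linalg.qr(rng.standard_normal((n, 3 * L)))
    blocks = [frame[:, i * L:(i + 1) * L] for i in range(3)]
    amp = cfg.modulation_hz * np.sqrt(n)
    if cfg.dependence == "invariant":
        W = {c: blocks[0] for c in HAND_CONDITIONS}
    elif cfg.dependence == "laterality_dependent":
        W = {"left": blocks[0], "right": blocks[1],
             "bimanual": (blocks[0] + blocks[1]) / np.sqrt(2.0)}
    elif cfg.dependence == "manuality_dependent":
        W = {"left": blocks[0], "right": blocks[0], "bimanual": blocks[1]}
    else:  # fully_dependent
        W = {"left": blocks[0], "right": blocks[1], "bimanual": blocks[2]}
    return {c: amp * w for c, w in W.items()}


def _latent_profiles(cfg: PopulationConfig, events_df, duration: float):
    """Latent trajectories z (latent_dim x T) on the SPIKE_DT grid, per condition."""
    T = int(np.round(duration / SPIKE_DT))
    tgrid = np.arange(T) * SPIKE_DT
    z = {c: np.zeros((cfg.latent_dim, T)) for c in HAND_CONDITIONS}
    for c in HAND_CONDITIONS:
        onsets = events_df.loc[events_df["condition"] == c, "onset_s"].to_numpy()
        for j in range(cfg.latent_dim):
            lag = j * cfg.latent_lag_s
            for t_e in onsets:
                if cfg.profile == "transient":
                    s = cfg.transient_sigma_s
                    lo = max(t_e + lag - 4 * s, 0.0)
                    hi = min(t_e + lag + 4 * s, duration)
                    sl = slice(int(lo / SPIKE_DT), int(hi / SPIKE_DT))
                    z[c][j, sl] += np.exp(
                        -0.5 * ((tgrid[sl] - t_e - lag) / s) ** 2)
                else:  # sustained: fast rise, slow decay
                    tau = cfg.sustained_tau_s * (1.0 + 0.3 * j)
                    hi = min(t_e + lag + 5 * tau, duration)
                    lo = max(t_e + lag - 0.2, 0.0)
                    sl = slice(int(lo / SPIKE_DT), int(hi / SPIKE_DT))
                    tt = tgrid[sl] - t_e - lag
                    rise = 1.0 / (1.0 + np.exp(-tt / 0.02))
                    z[c][j, sl] += rise * np.exp(-np.clip(tt, 0.0, None) / tau)
    return z


def _kinematic_drive(cfg: PopulationConfig, kin: Kinematics, events_df,
                     duration: float, rng):
    """Linear lagged kinematic drive per unit on the SPIKE_DT grid.

    Each condition drives its own hand-nose distance channel through a shared
    tap filter and a per-condition unit-space direction.  Invariant mode uses
    the same direction for the left and right conditions (a limb-invariant
    code); fully_dependent uses mutually orthogonal directions.  Returns
    (drive (n_units x T), truth dict).
    """
    n = cfg.n_units
    taps = np.hanning(cfg.n_kin_taps + 2)[1:-1]
    taps = taps / np.linalg.norm(taps)
    frame, _ = np.linalg.qr(rng.standard_normal((n, 4)))
    if cfg.dependence in ("invariant", "manuality_dependent"):
        dirs = {"left": frame[:, 0], "right": frame[:, 0],
                ("bimanual", "left"): frame[:, 0], ("bimanual", "right"): frame[:, 1]}
    else:
        dirs = {"left": frame[:, 0], "right": frame[:, 1],
                ("bimanual", "left"): frame[:, 2], ("bimanual", "right"): frame[:, 3]}

    T = int(np.round(duration / SPIKE_DT))
    step = int(round(cfg.kin_tap_step_s / SPIKE_DT))
    half = cfg.n_kin_taps // 2
    drive = np.zeros((n, T))
    channels = {"left": kin.d_left_nose, "right": kin.d_right_nose}
    frame_step = int(round((1.0 / kin.frame_rate) / SPIKE_DT))

    def z_channel(d):
        d = np.asarray(d, float).copy()
        ok = np.isfinite(d)
        if ok.sum() < 2:
            return np.zeros(T)
        mu, sd = d[ok].mean(), d[ok].std()
        d = np.where(ok, (d - mu) / (sd if sd > 0 else 1.0), 0.0)
        # upsample frames to the spike grid
        up = np.repeat(d, frame_step)[:T]
        if up.size < T:
            up = np.pad(up, (0, T - up.size))
        return up

    zch = {h: z_channel(channels[h]) for h in ("left", "right")}
    for cond in HAND_CONDITIONS:
        hands = ["left", "right"] if cond == "bimanual" else [cond]
        mask = _condition_mask(events_df, cond, duration)
        for h in hands:
            key = (cond, h) if cond == "bimanual" else cond
            filt = np.zeros(n)
            sig = np.zeros(T)
            for k in range(cfg.n_kin_taps):
                shift = (k - half) * step
                sig += taps[k] * np.roll(zch[h], shift)
            drive += cfg.kin_gain_hz * np.outer(dirs[key], sig * mask)
    truth = {
        "taps": taps.tolist(),
        "tap_step_s": cfg.kin_tap_step_s,
        "directions": {str(k): v.tolist() for k, v in dirs.items()},
        "gain_hz": cfg.kin_gain_hz,
    }
    return drive, truth


def _condition_mask(events_df, cond, duration):
    """1 inside [onset - 2 s, onset + 4 s] around the condition's events."""
    T = int(np.round(duration / SPIKE_DT))
    m = np.zeros(T)
    for t_e in events_df.loc[events_df["condition"] == cond, "onset_s"]:
        lo = max(int((t_e - 2.0) / SPIKE_DT), 0)
        hi = min(int((t_e + 4.0) / SPIKE_DT), T)
        m[lo:hi] = 1.0
    return m


def generate_spikes(
    kin: Kinematics,
    events_df: pd.DataFrame,
    cfg: PopulationConfig,
    seed: int,
    mouse_id: str = "m01",
    day_id: str = "d01",
    probe_id: str = "p01",
    area: str = "flM1",
    hemisphere: str = "right",
    return_rates: bool = False,
) -> tuple[pio.Recording, dict]:
    """Inhomogeneous-Poisson spike trains from latent + kinematic drive.

    Rates are ``max(0, baseline + W_cond @ z(t) [+ kinematic drive])``
    discretized at 1 ms; spikes are jittered uniformly within their bin.
    Returns (Recording, ground-truth parameter dict); with ``return_rates``
    the truth dict additionally carries the (n_units, T) rate matrix on the
    1 ms grid under ``"rates"`` (test/oracle use).
    """
    if events_df["condition"].nunique() < 1:
        raise ValueError("events must cover at least one condition")
    rng = np.random.default_rng(seed)
    duration = float(kin.time_s[-1] + 1.0 / kin.frame_rate)
    T = int(np.round(duration / SPIKE_DT))

    baselines = np.clip(
        cfg.baseline_rate_hz + cfg.baseline_rate_sd * rng.standard_normal(cfg.n_units),
        0.1, None)
    W = _condition_loadings(cfg, rng)
    z = _latent_profiles(cfg, events_df, duration)
    lat_drive = np.zeros((cfg.n_units, T))
    for c in HAND_CONDITIONS:
        if np.any(z[c]):
            lat_drive += W[c] @ z[c]

    truth: dict = {
        "dependence": cfg.dependence,
        "profile": cfg.profile,
        "modulation_hz": cfg.modulation_hz,
        "baselines": baselines.tolist(),
        "loadings": {c: W[c].tolist() for c in HAND_CONDITIONS},
    }
    if cfg.encoding == "linear_kinematic":
        kdrive, ktruth = _kinematic_drive(cfg, kin, events_df, duration, rng)
        lat_drive += kdrive
        truth["kinematic_encoding"] = ktruth

    units = []
    if return_rates:
        truth["rates"] = np.maximum(baselines[:, None] + lat_drive, 0.0)
    for u in range(cfg.n_units):
        rate = np.maximum(baselines[u] + lat_drive[u], 0.0)
        counts = rng.poisson(rate * SPIKE_DT)
        nz = np.flatnonzero(counts)
        reps = counts[nz]
        starts = np.repeat(nz * SPIKE_DT, reps)
        times = np.sort(starts + rng.random(starts.size) * SPIKE_DT)
        times = times[times < duration]
        units.append(pio.SpikeTrain(unit_id=f"u{u:03d}", spike_times=times))

    rec = pio.Recording(
        mouse_id=mouse_id, day_id=day_id, probe_id=probe_id, area=area,
        hemisphere=hemisphere, duration=duration, units=units,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# scenario bundles
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    recording: pio.Recording
    kinematics: Kinematics
    events: pd.DataFrame          # ground-truth hand-condition events
    truth: dict
    behavior: BehaviorConfig
    population: PopulationConfig

    def conditions(self) -> pd.DataFrame:
        """Events with conditions resolved against the recorded hemisphere."""
        ev = self.events.copy()
        ev["hand"] = ev["condition"]
        ev["condition"] = [
            pio.condition_for_hand(h, self.recording.hemisphere) for h in ev["hand"]
        ]
        return ev

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_spikes(self.recording, out / "spikes.csv")
        k = self.kinematics
        pio.write_kinematics_csv(k.time_s, k.left, k.right, k.nose,
                                 k.l_valid, k.r_valid, k.n_valid,
                                 out / "kinematics.csv")
        pio.write_events(self.events, out / "events.csv")
        truth = {k_: v for k_, v in self.truth.items()
                 if k_ not in ("model_distance", "states")}
        (out / "ground_truth.json").write_text(
            json.dumps(truth, indent=2, default=str) + "\n")


SCENARIOS = ("flM1_like", "LOM_like", "null", "linear_decode")


def make_scenario(name: str, seed: int = 0, **overrides) -> Bundle:
    """Build a full dataset bundle for one of the canonical scenarios.

    flM1_like      transient event-locked gain, laterality-dependent loadings
    LOM_like       sustained gain, invariant loadings
    null           no event-locked modulation at all
    linear_decode  invariant linear kinematic encoding with stored true taps
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}")
    beh_kw = overrides.pop("behavior", {})
    pop_kw = overrides.pop("population", {})
    presets = {
        "flM1_like": ({"cycles_per_condition": 16},
                      {"n_units": 48, "profile": "transient",
                       "dependence": "laterality_dependent"}),
        "LOM_like": ({"cycles_per_condition": 16},
                     {"n_units": 48, "profile": "sustained",
                      "dependence": "invariant"}),
        "null": ({"cycles_per_condition": 8},
                 {"n_units": 30, "modulation_hz": 0.0}),
        "linear_decode": ({"cycles_per_condition": 14, "noise_sd_mm": 0.3},
                          {"n_units": 24, "baseline_rate_hz": 20.0,
                           "modulation_hz": 0.0, "encoding": "linear_kinematic",
                           "kin_gain_hz": 30.0}),
    }
    beh_defaults, pop_defaults = presets[name]
    beh = BehaviorConfig(**{**beh_defaults, **beh_kw})
    pop = PopulationConfig(**{**pop_defaults, **pop_kw})
    kin, events, truth = generate_kinematics(beh, seed)
    rec, spike_truth = generate_spikes(kin, events, pop, seed + 1)
    truth = dict(truth)
    truth.update(spike_truth)
    truth["scenario"] = name
    if name == "null":
        truth.pop("loadings", None)  # no event-locked modulation parameter
    return Bundle(recording=rec, kinematics=kin, events=events, truth=truth,
                  behavior=beh, population=pop)
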