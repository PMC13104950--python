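"""Distance variables, behavioral segmentation, transition fits, transports.

Per-hand states: ``holding`` (holding/chewing), ``oromanual``
(oromanual/ingestion) and ``other``.  The combined ethogram enumerates the
seven joint states (left holding/right other, left oromanual/right other,
right holding/left other, right oromanual/left other, both holding, both
oromanual, both other); the two mixed pairs (one hand holding while the other
is oromanual) are carried as an explicit ``mixed`` label and treated as
non-food-handling downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from popcode.io import condition_for_hand

HOLDING, OROMANUAL, OTHER = "holding", "oromanual", "other"
HAND_STATES = (HOLDING, OROMANUAL, OTHER)

COMBINED_STATES = (
    "left_holding", "left_oromanual",
    "right_holding", "right_oromanual",
    "both_holding", "both_oromanual", "both_other",
    "mixed",
)

# onset/end of a fitted transition: fractional departure from the asymptote
ONSET_FRACTION = 0.05


@dataclass
class Kinematics:
    """Uniformly sampled 3D marker positions (mm) with validity flags."""

    time_s: np.ndarray
    left: np.ndarray    # (n, 3) left-hand D3
    right: np.ndarray   # (n, 3) right-hand D3
    nose: np.ndarray    # (n, 3)
    l_valid: np.ndarray
    r_valid: np.ndarray
    n_valid: np.ndarray
    d_left_nose: np.ndarray | None = None
    d_right_nose: np.ndarray | None = None
    d_both_nose: np.ndarray | None = None
    d_hand_hand: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.time_s)
        for name in ("left", "right", "nose"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must be (n, 3)")
        dts = np.diff(self.time_s)
        if dts.size and not np.allclose(dts, dts[0], rtol=1e-6):
            raise ValueError("time grid must be uniform")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    @property
    def n_frames(self) -> int:
        return len(self.time_s)


def compute_distances(kin: Kinematics) -> Kinematics:
    """Populate derived hand-nose / hand-hand distances, propagating missingness."""
    def dist(a, b):
        return np.linalg.norm(a - b, axis=1)

    nan = np.nan
    dl = dist(kin.left, kin.nose)
    dr = dist(kin.right, kin.nose)
    mid = 0.5 * (kin.left + kin.right)
    db = dist(mid, kin.nose)
    dh = dist(kin.left, kin.right)

    l_ok = kin.l_valid & np.isfinite(dl)
    r_ok = kin.r_valid & np.isfinite(dr)
    n_ok = kin.n_valid
    dl = np.where(l_ok & n_ok, dl, nan)
    dr = np.where(r_ok & n_ok, dr, nan)
    db = np.where(l_ok & r_ok & n_ok, db, nan)
    dh = np.where(l_ok & r_ok, dh, nan)

    kin.d_left_nose = dl
    kin.d_right_nose = dr
    kin.d_both_nose = db
    kin.d_hand_hand = dh
    return kin


@dataclass
class Ethogram:
    time_s: np.ndarray
    left_state: np.ndarray     # per-frame hand state strings
    right_state: np.ndarray
    combined: np.ndarray
    thresholds: dict

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    def epochs(self, state: str, hand: str = "combined") -> np.ndarray:
        """Contiguous (start_s, end_s) intervals of ``state`` (end exclusive)."""
        seq = {"left": self.left_state, "right": self.right_state,
               "combined": self.combined}[hand]
        return _state_epochs(self.time_s, seq, state)


def _state_epochs(time_s, seq, state) -> np.ndarray:
    dt = float(time_s[1] - time_s[0])
    mask = seq == state
    if not mask.any():
        return np.empty((0, 2))
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    starts, ends = idx[0::2], idx[1::2]
    return np.column_stack([time_s[starts], time_s[ends - 1] + dt])


def combine_states(left: str, right: str) -> str:
    """Deterministic seven-state (plus mixed) combination of per-hand states."""
    if left == right:
        return {HOLDING: "both_holding", OROMANUAL: "both_oromanual",
                OTHER: "both_other"}[left]
    if right == OTHER:
        return "left_holding" if left == HOLDING else "left_oromanual"
    if left == OTHER:
        return "right_holding" if right == HOLDING else "right_oromanual"
    return "mixed"


def _merge_short_runs(states: np.ndarray, min_run: int) -> np.ndarray:
    """Absorb runs shorter than ``min_run`` frames into the longer neighbor."""
    states = states.copy()
    if min_run <= 1:
        return states
    while True:
        # run-length encode
        change = np.flatnonzero(states[1:] != states[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(states)]))
        lengths = ends - starts
        if len(starts) == 1:
            return states
        short = np.flatnonzero(lengths < min_run)
        if short.size == 0:
            return states
        i = short[np.argmin(lengths[short])]  # shortest first
        if i == 0:
            new = states[starts[1]]
        elif i == len(starts) - 1:
            new = states[starts[i - 1]]
        else:
            prev_len, next_len = lengths[i - 1], lengths[i + 1]
            new = states[starts[i - 1]] if prev_len >= next_len else states[starts[i + 1]]
        states[starts[i]:ends[i]] = new


def segment_ethogram(
    kin: Kinematics,
    oromanual_threshold: float | dict[str, float],
    holding_threshold: float | dict[str, float],
    min_run_frames: int = 10,
    speed_threshold: float = np.inf,
    speed_window: int = 5,
) -> Ethogram:
    """Threshold hand-nose distances into the per-hand and combined ethograms.

    A frame is ``oromanual`` when the hand-nose distance is below the
    oromanual threshold, ``holding`` when it falls in the
    [oromanual, holding) band and the smoothed frame-to-frame distance speed
    is below ``speed_threshold`` (mm/s; default inf disables the motion
    criterion), and ``other`` otherwise (including missing frames).  Runs
    shorter than ``min_run_frames`` are merged into their longer neighbor.
    """
    if kin.d_left_nose is None:
        compute_distances(kin)

    def thr(x, hand):
        return x[hand] if isinstance(x, dict) else x

    per_hand = {}
    dt = 1.0 / kin.frame_rate
    for hand, d in (("left", kin.d_left_nose), ("right", kin.d_right_nose)):
        lo, hi = thr(oromanual_threshold, hand), thr(holding_threshold, hand)
        if not lo < hi:
            raise ValueError("oromanual threshold must be below holding threshold")
        states = np.full(len(d), OTHER, dtype=object)
        valid = np.isfinite(d)
        speed = np.full(len(d), np.inf)
        if np.isfinite(speed_threshold):
            raw = np.abs(np.gradient(np.where(valid, d, np.nan), dt))
            kernel = np.ones(speed_window) / speed_window
            speed = np.convolve(np.nan_to_num(raw, nan=np.inf), kernel, mode="same")
        else:
            speed = np.zeros(len(d))
        states[valid & (d < lo)] = OROMANUAL
        states[valid & (d >= lo) & (d < hi) & (speed < speed_threshold)] = HOLDING
        per_hand[hand] = _merge_short_runs(states, min_run_frames)

    combined = np.array(
        [combine_states(l, r) for l, r in zip(per_hand["left"], per_hand["right"])],
        dtype=object,
    )
    return Ethogram(
        time_s=kin.time_s,
        left_state=per_hand["left"],
        right_state=per_hand["right"],
        combined=combined,
        thresholds={
            "oromanual": oromanual_threshold,
            "holding": holding_threshold,
            "min_run_frames": min_run_frames,
            "speed_threshold": speed_threshold,
        },
    )


def default_thresholds(d: np.ndarray) -> tuple[float, float]:
    """Reproducible default thresholds from the multimodal distance histogram.

    The hand-nose distance typically shows up to three modes: oromanual
    (near the mouth), holding, and resting away from the face.  Returns
    (oromanual, holding) thresholds: midpoints between consecutive modes;
    when only two modes are visible, the holding threshold sits one half-gap
    above the upper mode.
    """
    d = d[np.isfinite(d)]
    if d.size < 10:
        raise ValueError("not enough valid frames to estimate thresholds")
    hist, edges = np.histogram(d, bins=60)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    span = d.max() - d.min()
    min_sep = 0.15 * span
    # greedy mode picking: strongest bins first, enforcing separation
    modes: list[float] = []
    floor = 0.02 * smooth.max()
    for i in np.argsort(smooth)[::-1]:
        if smooth[i] < floor:
            break
        if all(abs(centers[i] - m) > min_sep for m in modes):
            modes.append(float(centers[i]))
        if len(modes) == 3:
            break
    modes.sort()
    if len(modes) >= 3:
        return (0.5 * (modes[0] + modes[1]), 0.5 * (modes[1] + modes[2]))
    if len(modes) == 2:
        lo = 0.5 * (modes[0] + modes[1])
        return (lo, modes[1] + 0.5 * (modes[1] - lo))
    m = modes[0]
    return (m - 0.25 * span, m + 0.25 * span)


# ---------------------------------------------------------------------------
# transition model fits
# ---------------------------------------------------------------------------

@dataclass
class TransitionFit:
    kind: str                    # "sigmoid" | "exponential"
    params: dict
    onset_s: float
    end_s: float
    residual_variance_fraction: float
    low_confidence: bool = False


def _sigmoid_drop(t, lower, upper, t_mid, rate):
    return lower + (upper - lower) / (1.0 + np.exp(rate * (t - t_mid)))


def _exponential_rise(t, start, asym, t_on, tau):
    out = asym - (asym - start) * np.exp(-np.clip(t - t_on, 0.0, None) / tau)
    return np.where(t < t_on, start, out)


def fit_transition(time_s: np.ndarray, trace: np.ndarray, kind: str,
                   onset_fraction: float = ONSET_FRACTION) -> TransitionFit:
    """Least-squares fit of the transition model to one trace segment.

    ``sigmoid`` fits a falling logistic (transport-to-mouth: hand-nose
    distance drops); ``exponential`` fits a saturating rise
    (lowering-from-mouth).  The refined onset is where the model departs its
    pre-transition asymptote by ``onset_fraction`` of the asymptote gap.
    Non-convergence falls back to the mid-gap threshold crossing and flags
    the fit low-confidence.
    """
    valid = np.isfinite(trace)
    t, y = time_s[valid], trace[valid]
    if t.size < 8:
        raise ValueError("need at least 8 valid frames to fit a transition")
    lo, hi = float(np.min(y)), float(np.max(y))
    gap = hi - lo
    t_mid_guess = float(t[np.argmin(np.abs(y - (lo + hi) / 2.0))])
    span = float(t[-1] - t[0])
    logit = np.log((1 - onset_fraction) / onset_fraction)

    try:
        if kind == "sigmoid":
            p0 = [lo, hi, t_mid_guess, 10.0 / max(span, 1e-6)]
            popt, _ = curve_fit(
                _sigmoid_drop, t, y, p0=p0,
                bounds=([-np.inf, -np.inf, t[0] - span, 1e-9],
                        [np.inf, np.inf, t[-1] + span, np.inf]),
                maxfev=10000,
            )
            lower, upper, t_mid, rate = map(float, popt)
            onset = t_mid - logit / rate
            end = t_mid + logit / rate
            fitted = _sigmoid_drop(t, *popt)
            params = {"lower": lower, "upper": upper, "t_mid": t_mid, "rate": rate}
        elif kind == "exponential":
            p0 = [y[0], y[-1], float(t[0]) + 0.25 * span, max(span / 5.0, 1e-3)]
            popt, _ = curve_fit(
                _exponential_rise, t, y, p0=p0,
                bounds=([-np.inf, -np.inf, t[0] - span, 1e-9],
                        [np.inf, np.inf, t[-1], np.inf]),
                maxfev=10000,
            )
            start, asym, t_on, tau = map(float, popt)
            onset = t_on - tau * np.log(1.0 - onset_fraction)
            end = t_on + tau * np.log(1.0 / onset_fraction)
            fitted = _exponential_rise(t, *popt)
            params = {"start": start, "asym": asym, "t_on": t_on, "tau": tau}
        else:
            raise ValueError(f"unknown transition kind {kind!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown transition kind" in str(exc):
            raise
        return TransitionFit(
            kind=kind, params={}, onset_s=t_mid_guess, end_s=t_mid_guess,
            residual_variance_fraction=1.0, low_confidence=True,
        )

    var = float(np.var(y))
    rvf = float(np.var(y - fitted) / var) if var > 0 else 0.0
    return TransitionFit(kind=kind, params=params, onset_s=float(onset),
                         end_s=float(end), residual_variance_fraction=rvf)


# ---------------------------------------------------------------------------
# transport-to-mouth events
# ---------------------------------------------------------------------------

@dataclass
class TransportEvent:
    onset_s: float
    condition: str
    source: str                 # "left" | "right" | "bimanual"
    excluded: bool = False
    reason: str = ""
    fit: TransitionFit | None = None


def _hand_transitions(states: np.ndarray):
    """(frame, from_state, to_state) wherever the per-hand state changes."""
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    return [(int(f), states[f - 1], states[f]) for f in change]


def detect_transports(
    etho: Ethogram,
    kin: Kinematics,
    hemisphere: str,
    synchrony_window_s: float = 0.2,
    fit_margin_s: float = 0.5,
) -> list[TransportEvent]:
    """Detect holding -> oromanual transports and label their condition.

    Only transitions from holding into oromanual with the same hand(s) become
    retained events.  Bimanual events require both hands to transition within
    ``synchrony_window_s``.  Transitions from ``other`` into oromanual
    (resting on the armbar), uni-to-bimanual transitions, and hand swaps are
    recorded as excluded with a reason.  Onsets are refined with a sigmoid
    fit to the moving hand's hand-nose distance.
    """
    dt = 1.0 / etho.frame_rate
    margin = max(int(round(fit_margin_s / dt)), 4)
    traces = {"left": kin.d_left_nose, "right": kin.d_right_nose}
    cand = {"left": [], "right": []}
    events: list[TransportEvent] = []

    for hand in ("left", "right"):
        seq = etho.left_state if hand == "left" else etho.right_state
        for f, frm, to in _hand_transitions(seq):
            if to != OROMANUAL:
                continue
            if frm == OTHER:
                events.append(TransportEvent(
                    onset_s=float(etho.time_s[f]),
                    condition=condition_for_hand(hand, hemisphere),
                    source=hand, excluded=True, reason="from_other",
                ))
            else:
                cand[hand].append(f)

    def refine(hand, f):
        lo, hi = max(f - margin, 0), min(f + margin, len(etho.time_s))
        seg_t, seg_d = etho.time_s[lo:hi], traces[hand][lo:hi]
        if np.isfinite(seg_d).sum() < 8:
            return None, float(etho.time_s[f])
        fit = fit_transition(seg_t, seg_d, "sigmoid")
        return fit, fit.onset_s

    used_r: set[int] = set()
    for fl in cand["left"]:
        mate = None
        for fr in cand["right"]:
            if fr not in used_r and abs(etho.time_s[fl] - etho.time_s[fr]) <= synchrony_window_s:
                mate = fr
                break
        other_seq = etho.right_state
        if mate is not None:
            used_r.add(mate)
            fit_l, on_l = refine("left", fl)
            fit_r, on_r = refine("right", mate)
            events.append(TransportEvent(
                onset_s=float(min(on_l, on_r)), condition="bimanual",
                source="bimanual", fit=fit_l or fit_r,
            ))
        elif other_seq[fl] == OROMANUAL:
            events.append(TransportEvent(
                onset_s=float(etho.time_s[fl]),
                condition=condition_for_hand("left", hemisphere),
                source="left", excluded=True, reason="uni_to_bimanual",
            ))
        elif other_seq[fl] == HOLDING:
            events.append(TransportEvent(
                onset_s=float(etho.time_s[fl]),
                condition=condition_for_hand("left", hemisphere),
                source="left", excluded=True, reason="hand_swap_or_async",
            ))
        else:
            fit, onset = refine("left", fl)
            events.append(TransportEvent(
                onset_s=onset, condition=condition_for_hand("left", hemisphere),
                source="left", fit=fit,
            ))

    for fr in cand["right"]:
        if fr in used_r:
            continue
        if etho.left_state[fr] == OROMANUAL:
            events.append(TransportEvent(
                onset_s=float(etho.time_s[fr]),
                condition=condition_for_hand("right", hemisphere),
                source="right", excluded=True, reason="uni_to_bimanual",
            ))
        elif etho.left_state[fr] == HOLDING:
            events.append(TransportEvent(
                onset_s=float(etho.time_s[fr]),
                condition=condition_for_hand("right", hemisphere),
                source="right", excluded=True, reason="hand_swap_or_async",
            ))
        else:
            fit, onset = refine("right", fr)
            events.append(TransportEvent(
                onset_s=onset, condition=condition_for_hand("right", hemisphere),
                source="right", fit=fit,
            ))

    events.sort(key=lambda e: e.onset_s)
    return events


def events_to_frame(events: list[TransportEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in events],
            "condition": [e.condition for e in events],
            "kind": [e.source for e in events],
            "excluded": [e.excluded for e in events],
            "reason": [e.reason for e in events],
        }
    )
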