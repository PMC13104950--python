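"""Domain types, file I/O, inclusion filters, and hierarchical averaging.

File dialect: spikes and kinematics are UTF-8 CSV with header rows; session
metadata lives in a JSON sidecar next to the spikes file.  Everything is
desk-scale and diffable on purpose.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AREAS = ("flM1", "flM2", "LOM")
HEMISPHERES = ("left", "right")
CONDITIONS = ("ipsilateral", "contralateral", "bimanual")
UNIT_CLASSES = ("single", "multi")

#: Averaging order, outermost to innermost.  Aggregation collapses the
#: innermost present level first, so means are unweighted at every level.
HIERARCHY = ("mouse", "day", "probe", "unit", "trial")


@dataclass
class SpikeTrain:
    """Spike times (seconds) for one sorted unit."""

    unit_id: str
    spike_times: np.ndarray
    unit_class: str = "single"
    channel: int | None = None

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.unit_class not in UNIT_CLASSES:
            raise ValueError(f"unknown unit class {self.unit_class!r}")
        if self.spike_times.size and self.spike_times.min() < 0:
            raise ValueError(f"unit {self.unit_id}: negative spike times")
        if np.any(np.diff(self.spike_times) < 0):
            warnings.warn(f"unit {self.unit_id}: spike times unsorted; sorting")
            self.spike_times = np.sort(self.spike_times)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def rate(self, duration: float) -> float:
        return self.n_spikes / duration


@dataclass
class Recording:
    """Spike trains plus session metadata for one probe insertion."""

    mouse_id: str
    day_id: str
    probe_id: str
    area: str
    hemisphere: str
    duration: float
    units: list[SpikeTrain] = field(default_factory=list)

    def __post_init__(self):
        if self.area not in AREAS:
            raise ValueError(f"unknown area label {self.area!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for u in self.units:
            if u.spike_times.size and u.spike_times.max() > self.duration:
                raise ValueError(
                    f"unit {u.unit_id}: spike time exceeds duration {self.duration}"
                )

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.mouse_id, self.day_id, self.probe_id)


def condition_for_hand(hand: str, hemisphere: str) -> str:
    """Resolve a hand label to a condition given the recorded hemisphere.

    The hand contralateral to the recorded hemisphere maps to the
    ``contralateral`` condition; ``bimanual`` passes through.
    """
    if hand == "bimanual":
        return "bimanual"
    if hand not in HEMISPHERES:
        raise ValueError(f"unknown hand {hand!r}")
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"unknown hemisphere {hemisphere!r}")
    return "ipsilateral" if hand == hemisphere else "contralateral"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def read_spikes(path: str | Path) -> Recording:
    """Read a spikes CSV (unit_id, time_s) plus its JSON metadata sidecar."""
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path, dtype={"unit_id": str, "time_s": float})
    unit_classes = meta.get("unit_classes", {})
    channels = meta.get("channels", {})
    units = []
    ids_in_meta = meta.get("unit_ids")
    ids = ids_in_meta if ids_in_meta is not None else sorted(df["unit_id"].unique())
    grouped = {uid: g["time_s"].to_numpy() for uid, g in df.groupby("unit_id")}
    for uid in ids:
        units.append(
            SpikeTrain(
                unit_id=str(uid),
                spike_times=grouped.get(str(uid), np.empty(0)),
                unit_class=unit_classes.get(str(uid), "single"),
                channel=channels.get(str(uid)),
            )
        )
    return Recording(
        mouse_id=meta["mouse_id"],
        day_id=meta["day_id"],
        probe_id=meta["probe_id"],
        area=meta["area"],
        hemisphere=meta["hemisphere"],
        duration=float(meta["duration"]),
        units=units,
    )


def write_spikes(recording: Recording, path: str | Path) -> None:
    """Write a Recording as CSV + JSON sidecar in canonical ordering."""
    path = Path(path)
    rows = []
    for u in sorted(recording.units, key=lambda u: u.unit_id):
        for t in np.sort(u.spike_times):
            rows.append((u.unit_id, t))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("unit_id,time_s\n")
        for uid, t in rows:
            fh.write(f"{uid},{float(t)!r}\n")
    meta = {
        "mouse_id": recording.mouse_id,
        "day_id": recording.day_id,
        "probe_id": recording.probe_id,
        "area": recording.area,
        "hemisphere": recording.hemisphere,
        "duration": recording.duration,
        "unit_ids": [u.unit_id for u in sorted(recording.units, key=lambda u: u.unit_id)],
        "unit_classes": {
            u.unit_id: u.unit_class for u in sorted(recording.units, key=lambda u: u.unit_id)
        },
        "channels": {
            u.unit_id: u.channel
            for u in sorted(recording.units, key=lambda u: u.unit_id)
            if u.channel is not None
        },
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an events CSV (onset_s, condition, kind)."""
    df = pd.read_csv(path)
    required = {"onset_s", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events file missing columns: {sorted(missing)}")
    return df


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


KINEMATICS_COLUMNS = [
    "time_s", "lx", "ly", "lz", "rx", "ry", "rz", "nx", "ny", "nz",
    "l_valid", "r_valid", "n_valid",
]


def write_kinematics_csv(
    time_s: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    nose: np.ndarray,
    l_valid: np.ndarray,
    r_valid: np.ndarray,
    n_valid: np.ndarray,
    path: str | Path,
) -> None:
    """Write raw marker positions; invalid frames keep NaN positions."""
    df = pd.DataFrame(
        {
            "time_s": time_s,
            "lx": left[:, 0], "ly": left[:, 1], "lz": left[:, 2],
            "rx": right[:, 0], "ry": right[:, 1], "rz": right[:, 2],
            "nx": nose[:, 0], "ny": nose[:, 1], "nz": nose[:, 2],
            "l_valid": l_valid.astype(int),
            "r_valid": r_valid.astype(int),
            "n_valid": n_valid.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_kinematics_csv(path: str | Path):
    """Read a kinematics CSV back into arrays (see ``write_kinematics_csv``)."""
    df = pd.read_csv(path)
    missing = set(KINEMATICS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"kinematics file missing columns: {sorted(missing)}")
    return (
        df["time_s"].to_numpy(),
        df[["lx", "ly", "lz"]].to_numpy(),
        df[["rx", "ry", "rz"]].to_numpy(),
        df[["nx", "ny", "nz"]].to_numpy(),
        df["l_valid"].to_numpy().astype(bool),
        df["r_valid"].to_numpy().astype(bool),
        df["n_valid"].to_numpy().astype(bool),
    )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def apply_rate_filter(recording: Recording, min_rate: float) -> Recording:
    """Keep only units with all-time mean rate >= ``min_rate`` Hz.

    Exclusion is strict: a unit at exactly ``min_rate`` is kept.
    """
    if min_rate < 0:
        raise ValueError("min_rate must be >= 0")
    kept = [u for u in recording.units if u.rate(recording.duration) >= min_rate]
    return replace(recording, units=list(kept))


@dataclass
class InclusionDecision:
    include: bool
    reasons: list[str]
    included_conditions: list[str]


#: thresholds per inclusion profile
INCLUSION_PROFILES = {
    "peth": {"min_units": 10, "min_events": 5, "min_responsive": 5},
    "pca": {"min_units": 40, "min_events": 15},
    "corr_decode": {"min_units": 10, "min_events": 5, "min_bins": 1000},
}


def check_inclusion(
    recording: Recording,
    events_per_condition: dict[str, int],
    bins_per_condition: dict[str, int] | None = None,
    profile: str = "peth",
    n_responsive: int | None = None,
) -> InclusionDecision:
    """Pure predicate implementing the per-analysis inclusion rules.

    peth         >=10 units, >=5 events in every condition present and, when
                 ``n_responsive`` is given, >=5 significantly responsive units.
    pca          >=40 units; conditions below 15 events are dropped (not the
                 recording); at least one condition must survive.
    corr_decode  >=10 units and, for all three conditions, >=5 events and
                 >=1000 five-millisecond bins.
    """
    if profile not in INCLUSION_PROFILES:
        raise ValueError(f"unknown inclusion profile {profile!r}")
    rule = INCLUSION_PROFILES[profile]
    reasons: list[str] = []
    included = list(events_per_condition)

    if recording.n_units < rule["min_units"]:
        reasons.append(f"units<{rule['min_units']}")

    if profile == "pca":
        included = [
            c for c, n in events_per_condition.items() if n >= rule["min_events"]
        ]
        if not included:
            reasons.append(f"no condition with events>={rule['min_events']}")
    else:
        for cond in CONDITIONS:
            n = events_per_condition.get(cond, 0)
            if n < rule["min_events"]:
                reasons.append(f"events[{cond}]<{rule['min_events']}")
        if profile == "corr_decode":
            for cond in CONDITIONS:
                b = (bins_per_condition or {}).get(cond, 0)
                if b < rule["min_bins"]:
                    reasons.append(f"bins[{cond}]<{rule['min_bins']}")
        if profile == "peth" and n_responsive is not None:
            if n_responsive < rule["min_responsive"]:
                reasons.append(f"responsive<{rule['min_responsive']}")

    return InclusionDecision(include=not reasons, reasons=reasons,
                             included_conditions=included)


# ---------------------------------------------------------------------------
# hierarchical averaging
# ---------------------------------------------------------------------------

def hierarchical_average(
    values: pd.DataFrame,
    value_col: str = "value",
    target_level: str = "grand",
    keep: Sequence[str] = ("condition",),
) -> pd.DataFrame:
    """Average a keyed table up the hierarchy trials -> units -> probes -> days -> mice.

    The innermost level present in ``values`` is collapsed first with an
    unweighted mean, then the next, until ``target_level`` remains (or, for
    ``"grand"``, until all hierarchy levels are collapsed).  Columns named in
    ``keep`` (e.g. ``condition``) are preserved as grouping keys throughout;
    missing cells at any level are simply absent and never imputed, so a
    condition recorded in one mouse only contributes that mouse's mean.
    """
    if target_level != "grand" and target_level not in HIERARCHY:
        raise ValueError(f"unknown hierarchy level {target_level!r}")
    present = [lvl for lvl in HIERARCHY if lvl in values.columns]
    keep = [k for k in keep if k in values.columns]
    df = values

    if target_level == "grand":
        n_keep = 0
    else:
        if target_level not in present:
            raise ValueError(f"level {target_level!r} not present in table")
        n_keep = present.index(target_level) + 1

    while len(present) > n_keep:
        inner = present.pop()  # collapse innermost first
        group_cols = present + keep
        if group_cols:
            df = df.groupby(group_cols, as_index=False, dropna=False)[value_col].mean()
        else:
            df = pd.DataFrame({value_col: [df[value_col].mean()]})
    return df


def hierarchical_average_arrays(
    entries: Iterable[tuple[tuple[str, str, str], np.ndarray]],
) -> np.ndarray | None:
    """Average per-recording vectors over probes, then days, then mice.

    ``entries`` yields ((mouse, day, probe), vector).  NaNs propagate as
    missing at each level (nanmean).  Returns None when empty.
    """
    by_mouse: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for (mouse, day, probe), vec in entries:
        by_mouse.setdefault(mouse, {}).setdefault(day, {})[probe] = np.asarray(vec, float)
    if not by_mouse:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mouse_means = []
        for days in by_mouse.values():
            day_means = [
                np.nanmean(np.stack(list(probes.values())), axis=0)
                for probes in days.values()
            ]
            mouse_means.append(np.nanmean(np.stack(day_means), axis=0))
        return np.nanmean(np.stack(mouse_means), axis=0)
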