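"""From ground-truth tracks to the study's observables.

Converts continuous-time synapse tracks into presence/absence at the
imaging times, then into cohorts (stable vs new), lifetime categories,
two-time-point turnover summaries, Kaplan-Meier survival curves and
log-rank comparisons.

Conventions (interval censoring): a death is recorded at the first
scheduled time at which the synapse is absent after having been
detected; synapses still present at the final imaging time are
right-censored there. The new cohort's survival clock is re-zeroed at
its first detection time.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .params import ImagingSchedule

__all__ = [
    "PresenceTable",
    "CategoryCounts",
    "WindowSummary",
    "observe",
    "classify_cohorts",
    "lifetime_categories",
    "window_summary",
    "window_summary_by",
    "survival_records",
    "km_curve",
    "logrank",
]

PRESENCE_COLUMNS = ["fish_id", "dendrite_id", "synapse_id", "time_h", "present"]
LENGTH_COLUMNS = ["fish_id", "dendrite_id", "length_um"]

STABLE_COHORT = "stable_cohort"
NEW_COHORT = "new_cohort"
OTHER = "other"


@dataclass
class PresenceTable:
    """Long-format presence records plus per-dendrite lengths.

    ``data`` columns: fish_id, dendrite_id, synapse_id, time_h, present
    (0/1); every synapse has one record per schedule time. ``lengths``
    columns: fish_id, dendrite_id, length_um.
    """

    data: pd.DataFrame
    lengths: pd.DataFrame

    def __post_init__(self) -> None:
        for col in PRESENCE_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"presence table missing column {col!r}")
        for col in LENGTH_COLUMNS:
            if col not in self.lengths.columns:
                raise ValueError(f"dendrite table missing column {col!r}")
        bad = set(np.unique(self.data["present"])) - {0, 1}
        if bad:
            raise ValueError(f"present must be 0/1, found {sorted(bad)}")

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(sorted(self.data["time_h"].unique()))

    @property
    def total_length(self) -> float:
        return float(self.lengths["length_um"].sum())

    def wide(self) -> pd.DataFrame:
        """Pivot to one row per synapse, one 0/1 column per imaging time."""
        w = self.data.pivot_table(
            index=["fish_id", "dendrite_id", "synapse_id"],
            columns="time_h",
            values="present",
            fill_value=0,
        )
        return w[sorted(w.columns)]

    def write(self, presence_path: Union[str, Path],
              dendrites_path: Union[str, Path]) -> None:
        self.data.to_csv(presence_path, sep="\t", index=False, float_format="%.10g")
        self.lengths.to_csv(dendrites_path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, presence_path: Union[str, Path],
             dendrites_path: Union[str, Path]) -> "PresenceTable":
        str_cols = {"fish_id": str, "dendrite_id": str, "synapse_id": str}
        data = pd.read_csv(presence_path, sep="\t", dtype=str_cols)
        missing = [c for c in PRESENCE_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"{presence_path}: missing columns {missing}")
        lengths = pd.read_csv(dendrites_path, sep="\t",
                              dtype={"fish_id": str, "dendrite_id": str})
        missing = [c for c in LENGTH_COLUMNS if c not in lengths.columns]
        if missing:
            raise ValueError(f"{dendrites_path}: missing columns {missing}")
        return cls(data=data[PRESENCE_COLUMNS], lengths=lengths[LENGTH_COLUMNS])


def observe(tracks: pd.DataFrame, schedule: ImagingSchedule,
            horizon: Optional[float] = None) -> PresenceTable:
    """Sample tracks at the imaging times.

    ``present(t) = 1`` iff ``t_birth <= t`` and the synapse has not died
    by ``t`` (death exactly at ``t`` counts as absent). Synapses never
    present at any schedule time are omitted entirely. If the simulation
    ``horizon`` is given, a schedule reaching past it is rejected.
    """
    if horizon is not None and schedule.horizon > horizon:
        raise ValueError(
            f"schedule horizon {schedule.horizon} h exceeds simulation "
            f"horizon {horizon} h"
        )
    times = np.asarray(schedule.times)

    birth = tracks["t_birth_h"].to_numpy(dtype=float)[:, None]
    death = tracks["t_death_h"].to_numpy(dtype=float)
    death = np.where(np.isnan(death), np.inf, death)[:, None]
    present = ((birth <= times[None, :]) & (death[:, :] > times[None, :])).astype(np.int8)

    ever = present.any(axis=1)
    kept = tracks.loc[ever, ["fish_id", "dendrite_id", "synapse_id"]].reset_index(drop=True)
    present = present[ever]

    n, k = present.shape
    data = pd.DataFrame(
        {
            "fish_id": np.repeat(kept["fish_id"].to_numpy(), k),
            "dendrite_id": np.repeat(kept["dendrite_id"].to_numpy(), k),
            "synapse_id": np.repeat(kept["synapse_id"].to_numpy(), k),
            "time_h": np.tile(times, n),
            "present": present.ravel(),
        }
    )
    lengths = (
        tracks.groupby(["fish_id", "dendrite_id"], as_index=False)["dendrite_length_um"]
        .first()
        .rename(columns={"dendrite_length_um": "length_um"})
    )
    return PresenceTable(data=data, lengths=lengths)


def _schedule_from(presence: PresenceTable,
                   schedule: Optional[ImagingSchedule]) -> ImagingSchedule:
    if schedule is None:
        return ImagingSchedule(presence.times)
    observed = presence.times
    if tuple(schedule.times) != observed:
        raise ValueError(
            f"presence times {observed} do not match schedule {schedule.times}"
        )
    return schedule


def classify_cohorts(presence: PresenceTable,
                     schedule: Optional[ImagingSchedule] = None) -> pd.DataFrame:
    """Label each synapse stable_cohort / new_cohort / other.

    Stable cohort: present at t_0. New cohort: absent at t_0, present at
    t_1. Other: first detected at t_2 or later.
    """
    schedule = _schedule_from(presence, schedule)
    w = presence.wide()
    at0 = w.iloc[:, 0].to_numpy() > 0
    at1 = w.iloc[:, 1].to_numpy() > 0
    label = np.where(at0, STABLE_COHORT, np.where(at1, NEW_COHORT, OTHER))
    out = w.index.to_frame(index=False)
    out["cohort"] = label
    return out


@dataclass
class CategoryCounts:
    """Lifetime-category counts per dendrite: the likelihood's sufficient statistic.

    ``counts`` columns: fish_id, dendrite_id, first_idx, last_idx, count.
    Zero-count categories may be omitted; the likelihood treats missing
    (i, j) pairs as zeros.
    """

    counts: pd.DataFrame
    lengths: pd.DataFrame
    schedule: ImagingSchedule

    @property
    def total(self) -> int:
        return int(self.counts["count"].sum())

    @property
    def total_length(self) -> float:
        return float(self.lengths["length_um"].sum())

    def pooled(self) -> pd.DataFrame:
        """Counts summed over dendrites, one row per (first_idx, last_idx)."""
        return (
            self.counts.groupby(["first_idx", "last_idx"], as_index=False)["count"]
            .sum()
        )

    def fingerprint(self) -> str:
        """Content hash used to pair fits with the data they were run on."""
        pooled = self.pooled().sort_values(["first_idx", "last_idx"])
        payload = (
            repr(self.schedule.times)
            + pooled.to_csv(index=False)
            + self.lengths.sort_values(["fish_id", "dendrite_id"]).to_csv(index=False)
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def write(self, path: Union[str, Path]) -> None:
        out = self.counts.copy()
        times = self.schedule.times
        out.insert(2, "first_h", [times[i] for i in out["first_idx"]])
        out.insert(3, "last_h", [times[j] for j in out["last_idx"]])
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def lifetime_categories(presence: PresenceTable,
                        schedule: Optional[ImagingSchedule] = None) -> CategoryCounts:
    """Count synapses per (first-detected, last-detected) index pair per dendrite.

    Reappearance (present-absent-present) is impossible under the model
    with perfect detection but can occur in real tracking data; such a
    synapse is split at each gap into independent presence runs, with a
    warning.
    """
    schedule = _schedule_from(presence, schedule)
    w = presence.wide()
    mat = w.to_numpy(dtype=np.int8)
    n, k = mat.shape

    idx = np.arange(k)
    first = np.where(mat.any(axis=1), mat.argmax(axis=1), -1)
    last = k - 1 - mat[:, ::-1].argmax(axis=1)
    # a gap exists if the span [first, last] contains an absence
    span = (idx[None, :] >= first[:, None]) & (idx[None, :] <= last[:, None])
    has_gap = ((mat == 0) & span).any(axis=1)

    keys = w.index.to_frame(index=False)
    rows: list[tuple[str, str, int, int]] = []
    clean = ~has_gap & (first >= 0)
    for fid, did, i, j in zip(
        keys.loc[clean, "fish_id"], keys.loc[clean, "dendrite_id"],
        first[clean], last[clean]
    ):
        rows.append((fid, did, int(i), int(j)))

    n_split = int(has_gap.sum())
    if n_split:
        warnings.warn(
            f"{n_split} synapse(s) with internal absence gaps were split "
            "into separate presence runs",
            stacklevel=2,
        )
        for r in np.flatnonzero(has_gap):
            fid = keys.at[r, "fish_id"]
            did = keys.at[r, "dendrite_id"]
            run_start = None
            for t in range(k + 1):
                on = t < k and mat[r, t] == 1
                if on and run_start is None:
                    run_start = t
                elif not on and run_start is not None:
                    rows.append((fid, did, run_start, t - 1))
                    run_start = None

    counts = (
        pd.DataFrame(rows, columns=["fish_id", "dendrite_id", "first_idx", "last_idx"])
        .groupby(["fish_id", "dendrite_id", "first_idx", "last_idx"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return CategoryCounts(counts=counts, lengths=presence.lengths.copy(),
                          schedule=schedule)


@dataclass(frozen=True)
class WindowSummary:
    """Turnover between two imaging times: counts and per-µm densities."""

    newly_observed: int
    lost: int
    stable: int
    length_um: float

    @property
    def densities(self) -> tuple[float, float, float]:
        return (
            self.newly_observed / self.length_um,
            self.lost / self.length_um,
            self.stable / self.length_um,
        )


def _window_counts(w: pd.DataFrame, t_a: float, t_b: float) -> tuple[int, int, int]:
    a = w[t_a].to_numpy() > 0
    b = w[t_b].to_numpy() > 0
    return int((~a & b).sum()), int((a & ~b).sum()), int((a & b).sum())


def window_summary(presence: PresenceTable, t_a: float, t_b: float) -> WindowSummary:
    """Pooled newly-observed / lost / stable between two imaging times.

    Densities are normalized by the dendrite length averaged across the
    two time points (lengths are constant in simulated data, so this is
    the plain total length).
    """
    if not t_a < t_b:
        raise ValueError("need t_a < t_b")
    if len(presence.data) == 0:
        return WindowSummary(0, 0, 0, presence.total_length)
    times = presence.times
    if t_a not in times or t_b not in times:
        raise ValueError(f"window ({t_a}, {t_b}) h not within imaging times {times}")
    w = presence.wide()
    newly, lost, stable = _window_counts(w, float(t_a), float(t_b))
    return WindowSummary(newly, lost, stable, presence.total_length)


def window_summary_by(presence: PresenceTable, t_a: float, t_b: float,
                      by: str = "fish_id") -> pd.DataFrame:
    """Per-group turnover table (one row per fish or dendrite)."""
    times = presence.times
    if t_a not in times or t_b not in times:
        raise ValueError(f"window ({t_a}, {t_b}) h not within imaging times {times}")
    w = presence.wide().reset_index()
    lengths = presence.lengths.groupby(by, as_index=False)["length_um"].sum()
    rows = []
    for key, grp in w.groupby(by):
        newly, lost, stable = _window_counts(grp, float(t_a), float(t_b))
        length = float(lengths.loc[lengths[by] == key, "length_um"].iloc[0])
        rows.append(
            {
                by: key,
                "newly_observed": newly,
                "lost": lost,
                "stable": stable,
                "length_um": length,
                "newly_per_um": newly / length,
                "lost_per_um": lost / length,
                "stable_per_um": stable / length,
            }
        )
    return pd.DataFrame(rows)


def survival_records(presence: PresenceTable,
                     schedule: Optional[ImagingSchedule] = None,
                     cohort: str = STABLE_COHORT) -> pd.DataFrame:
    """Per-synapse (duration, observed) records for KM / log-rank.

    The event time is the first schedule time at which the synapse is
    absent after detection; synapses present at the final time are
    censored there. Durations are measured from t_0 for the stable
    cohort and from the first detection time (t_1) for the new cohort.
    """
    schedule = _schedule_from(presence, schedule)
    labels = classify_cohorts(presence, schedule)
    w = presence.wide()
    mat = w.to_numpy(dtype=np.int8)
    times = np.asarray(schedule.times)
    k = len(times)

    sel = (labels["cohort"] == cohort).to_numpy()
    if not sel.any():
        raise ValueError(f"cohort {cohort!r} is empty")
    mat = mat[sel]

    first = mat.argmax(axis=1)
    # first absence strictly after first detection; k if never absent again
    after = np.where(
        (np.arange(k)[None, :] > first[:, None]) & (mat == 0),
        np.arange(k)[None, :],
        k,
    ).min(axis=1)
    observed = after < k
    end_time = np.where(observed, times[np.minimum(after, k - 1)], times[-1])
    origin = times[first]
    out = w.index.to_frame(index=False).loc[sel].reset_index(drop=True)
    out["duration"] = end_time - origin
    out["observed"] = observed.astype(int)
    return out


def km_curve(presence: PresenceTable,
             schedule: Optional[ImagingSchedule] = None,
             cohort: str = STABLE_COHORT) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate on the interval-censored grid.

    Returns a table with columns time, at_risk, events, censored,
    survival, starting at (re-zeroed) time 0 with survival 1.
    """
    rec = survival_records(presence, schedule, cohort)
    return km_from_records(rec["duration"].to_numpy(), rec["observed"].to_numpy())


def km_from_records(durations: np.ndarray, observed: np.ndarray) -> pd.DataFrame:
    durations = np.asarray(durations, dtype=float)
    observed = np.asarray(observed).astype(bool)
    grid = np.unique(durations)
    rows = [{"time": 0.0, "at_risk": durations.size, "events": 0,
             "censored": 0, "survival": 1.0}]
    surv = 1.0
    for t in grid:
        if t == 0.0 and not (observed & (durations == 0.0)).any():
            continue
        at_risk = int((durations >= t).sum())
        events = int(((durations == t) & observed).sum())
        censored = int(((durations == t) & ~observed).sum())
        if at_risk > 0 and events > 0:
            surv *= 1.0 - events / at_risk
        rows.append({"time": float(t), "at_risk": at_risk, "events": events,
                     "censored": censored, "survival": surv})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float


def logrank(records_a: pd.DataFrame, records_b: pd.DataFrame) -> LogrankResult:
    """Two-sample log-rank test (1 df, hypergeometric variance, grouped ties).

    Inputs are (duration, observed) tables as produced by
    :func:`survival_records`. With no events in either group the
    statistic is 0 and p = 1.
    """
    for name, rec in (("a", records_a), ("b", records_b)):
        if len(rec) == 0:
            raise ValueError(f"cohort {name} is empty")

    dur_a = records_a["duration"].to_numpy(dtype=float)
    obs_a = records_a["observed"].to_numpy().astype(bool)
    dur_b = records_b["duration"].to_numpy(dtype=float)
    obs_b = records_b["observed"].to_numpy().astype(bool)

    event_times = np.unique(np.concatenate([dur_a[obs_a], dur_b[obs_b]]))
    if event_times.size == 0:
        return LogrankResult(0.0, 1.0)

    score = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((dur_a >= t).sum())
        n2 = int((dur_b >= t).sum())
        n = n1 + n2
        d1 = int(((dur_a == t) & obs_a).sum())
        d2 = int(((dur_b == t) & obs_b).sum())
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        score += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return LogrankResult(0.0, 1.0)
    chi = score * score / var
    return LogrankResult(float(chi), float(stats.chi2.sf(chi, df=1)))
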