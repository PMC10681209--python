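"""Accelerometer epoch processing: non-wear detection, day summaries,
inclusion rules and child-level activity compositions.

Processing rules applied to waist-worn ActiGraph count series recorded in
10-second epochs:

* data between midnight and 06:00 are excluded outright;
* non-wear is any run of zero counts lasting at least 60 minutes,
  where the run may include short non-zero interruptions (each at most
  2 minutes by default; a total-per-run budget is available as a config
  alternative);
* wear epochs are classified sedentary / light / MVPA by count cut-points
  applied per epoch (defaults are the children's 15-s cut-points linearly
  rescaled to 10 s: sedentary <= 16, MVPA >= 383 counts);
* a valid day has at least 500 minutes of wear;
* a child is included with at least two valid weekdays and one valid
  weekend day; daily minutes are averaged within day type and converted to
  proportions of wear time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: seconds per epoch, default recording resolution
DEFAULT_EPOCH_S = 10

#: counts-per-epoch thresholds (per 10-s epoch)
DEFAULT_SED_MAX = 16
DEFAULT_MVPA_MIN = 383

EXCLUDED_HOURS = (0, 6)   # [00:00, 06:00) removed before any processing


@dataclass(frozen=True)
class CutPoints:
    """Count thresholds per epoch: sedentary <= sed_max, MVPA >= mvpa_min."""

    sed_max: int = DEFAULT_SED_MAX
    mvpa_min: int = DEFAULT_MVPA_MIN

    def __post_init__(self):
        if not (0 <= self.sed_max < self.mvpa_min):
            raise ValueError("need 0 <= sed_max < mvpa_min")


@dataclass
class EpochSeries:
    """One child's epoch-level count stream.

    ``timestamps`` must be strictly increasing with constant spacing equal
    to ``epoch_s`` seconds; counts are non-negative integers.
    """

    child_id: object
    timestamps: pd.DatetimeIndex
    counts: np.ndarray
    epoch_s: int = DEFAULT_EPOCH_S

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.counts = np.asarray(self.counts)
        if len(self.timestamps) == 0:
            raise ValueError("empty epoch series")
        if len(self.timestamps) != len(self.counts):
            raise ValueError("timestamps and counts differ in length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.timestamps) > 1:
            deltas = np.diff(self.timestamps.asi8) / 1e9
            if np.any(deltas != self.epoch_s):
                raise ValueError("timestamps must be evenly spaced at epoch_s")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class DaySummary:
    child_id: object
    date: object
    day_type: str          # "weekday" | "weekend"
    wear_minutes: float
    sed_minutes: float
    lpa_minutes: float
    mvpa_minutes: float
    valid: bool


@dataclass
class ChildComposition:
    """Per-child weekday/weekend composition (the 4-dim LPA observation)."""

    child_id: object
    group: str | None = None
    p_mvpa_wd: float = np.nan
    p_sed_wd: float = np.nan
    p_mvpa_we: float = np.nan
    p_sed_we: float = np.nan
    wear_wd: float = np.nan
    wear_we: float = np.nan
    n_valid_weekdays: int = 0
    n_valid_weekend: int = 0

    @property
    def weekend_missing(self) -> bool:
        return bool(np.isnan(self.p_mvpa_we))


@dataclass
class Excluded:
    """Marker returned when a child fails the inclusion rule."""

    child_id: object
    reason: str


@dataclass
class ActivityScores:
    child_id: object
    structured_days: float = np.nan
    unstructured_days: float = np.nan


# ---------------------------------------------------------------------------
# non-wear detection
# ---------------------------------------------------------------------------

def _zero_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zeros as half-open (start, stop) index pairs."""
    z = np.concatenate(([0], (counts == 0).astype(np.int8), [0]))
    d = np.diff(z)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detect_nonwear(series: EpochSeries, window_min: float = 60,
                   interruption_max_min: float = 2,
                   interruption_mode: str = "per_interruption") -> np.ndarray:
    """Return indices of epochs flagged as non-wear.

    A non-wear interval is a span from the first to the last epoch of a
    group of zero-count runs whose non-zero gaps are admissible
    interruptions, with total span length at least ``window_min`` minutes.
    Under ``interruption_mode="per_interruption"`` each gap may last up to
    ``interruption_max_min`` minutes with no limit on their number; under
    ``"total_budget"`` the summed gap time within a span is capped instead.
    Epochs between midnight and 06:00 are flagged unconditionally.
    """
    if interruption_mode not in ("per_interruption", "total_budget"):
        raise ValueError(f"unknown interruption_mode {interruption_mode!r}")
    counts = np.asarray(series.counts)
    eps = series.epoch_s
    window_ep = int(round(window_min * 60 / eps))
    gap_ep = int(round(interruption_max_min * 60 / eps))

    flagged = np.zeros(len(counts), dtype=bool)
    hours = series.timestamps.hour
    flagged |= (hours >= EXCLUDED_HOURS[0]) & (hours < EXCLUDED_HOURS[1])

    runs = _zero_runs(counts)
    if runs:
        if interruption_mode == "per_interruption":
            # greedily chain runs whose separating gaps are each admissible
            i = 0
            while i < len(runs):
                j = i
                while (j + 1 < len(runs)
                       and runs[j + 1][0] - runs[j][1] <= gap_ep):
                    j += 1
                span = runs[j][1] - runs[i][0]
                if span >= window_ep:
                    flagged[runs[i][0]:runs[j][1]] = True
                i = j + 1
        else:
            # two-pointer over runs with a total interruption budget
            n = len(runs)
            for i in range(n):
                gap_sum = 0
                for j in range(i, n):
                    if j > i:
                        gap_sum += runs[j][0] - runs[j - 1][1]
                        if gap_sum > gap_ep:
                            break
                    span = runs[j][1] - runs[i][0]
                    if span >= window_ep:
                        flagged[runs[i][0]:runs[j][1]] = True
    return np.flatnonzero(flagged)


# ---------------------------------------------------------------------------
# day summaries and compositions
# ---------------------------------------------------------------------------

def _day_type(date) -> str:
    return "weekend" if pd.Timestamp(date).dayofweek >= 5 else "weekday"


def summarise_day(series: EpochSeries, date,
                  cutpoints: CutPoints = CutPoints(),
                  valid_day_min: float = 500,
                  window_min: float = 60,
                  interruption_max_min: float = 2,
                  interruption_mode: str = "per_interruption") -> DaySummary:
    """Classify one calendar day's wear epochs and total the minutes.

    Wear epochs are those within 06:00-24:00 and not flagged by
    :func:`detect_nonwear`; each is sedentary (counts <= sed_max), MVPA
    (counts >= mvpa_min) or light otherwise.  Sedentary + light + MVPA
    minutes equal wear minutes exactly.
    """
    date = pd.Timestamp(date).date()
    in_day = series.timestamps.date == date
    if not in_day.any():
        raise ValueError(f"date {date} not present in series")
    nonwear = np.zeros(len(series), dtype=bool)
    nonwear[detect_nonwear(series, window_min=window_min,
                           interruption_max_min=interruption_max_min,
                           interruption_mode=interruption_mode)] = True
    wear = in_day & ~nonwear
    counts = series.counts[wear]
    per_min = series.epoch_s / 60.0
    sed = float((counts <= cutpoints.sed_max).sum() * per_min)
    mvpa = float((counts >= cutpoints.mvpa_min).sum() * per_min)
    wear_min = float(len(counts) * per_min)
    lpa = wear_min - sed - mvpa
    return DaySummary(
        child_id=series.child_id, date=date, day_type=_day_type(date),
        wear_minutes=wear_min, sed_minutes=sed, lpa_minutes=lpa,
        mvpa_minutes=mvpa, valid=wear_min >= valid_day_min,
    )


def build_composition(days: list[DaySummary], min_weekdays: int = 2,
                      min_weekend: int = 1, group: str | None = None,
                      allow_missing_weekend: bool = False
                      ) -> ChildComposition | Excluded:
    """Average valid days within day type into a child composition.

    Children failing the inclusion rule (>= ``min_weekdays`` valid weekdays
    and >= ``min_weekend`` valid weekend days) are excluded.  With
    ``allow_missing_weekend=True`` (a sensitivity mode) children meeting
    the weekday criterion only are retained with the weekend block missing,
    for downstream full-information handling.
    """
    if not days:
        return Excluded(child_id=None, reason="no days")
    cid = days[0].child_id
    if any(d.child_id != cid for d in days):
        raise ValueError("days must belong to a single child")
    wd = [d for d in days if d.valid and d.day_type == "weekday"]
    we = [d for d in days if d.valid and d.day_type == "weekend"]
    if len(wd) < min_weekdays:
        return Excluded(cid, f"fewer than {min_weekdays} valid weekdays")
    if len(we) < min_weekend and not allow_missing_weekend:
        return Excluded(cid, f"fewer than {min_weekend} valid weekend days")

    def _block(ds):
        wear = float(np.mean([d.wear_minutes for d in ds]))
        mvpa = float(np.mean([d.mvpa_minutes for d in ds]))
        sed = float(np.mean([d.sed_minutes for d in ds]))
        return mvpa / wear, sed / wear, wear

    p_m_wd, p_s_wd, wear_wd = _block(wd)
    comp = ChildComposition(
        child_id=cid, group=group, p_mvpa_wd=p_m_wd, p_sed_wd=p_s_wd,
        wear_wd=wear_wd, n_valid_weekdays=len(wd), n_valid_weekend=len(we),
    )
    if len(we) >= min_weekend:
        comp.p_mvpa_we, comp.p_sed_we, comp.wear_we = _block(we)
    return comp


def meets_guidelines(comp: ChildComposition,
                     guideline_min: float = 60.0) -> bool | None:
    """Average at least ``guideline_min`` MVPA minutes per day, weighting
    weekdays and weekend days 5:2.  None when the weekend block is missing."""
    if comp.weekend_missing:
        return None
    wd_min = comp.p_mvpa_wd * comp.wear_wd
    we_min = comp.p_mvpa_we * comp.wear_we
    return (5.0 * wd_min + 2.0 * we_min) / 7.0 >= guideline_min


# ---------------------------------------------------------------------------
# questionnaire activity scores
# ---------------------------------------------------------------------------

#: ordinal response -> midpoint days per week
MIDPOINT_DAYS = {0: 0.0, 1: 1.5, 2: 3.5, 3: 6.0}


def score_activities(child_id, club_school, club_other, play_neighbourhood,
                     play_home) -> ActivityScores:
    """Midpoint-code the four frequency items and average into structured
    (clubs) and unstructured (play) days per week, each on 0-6.

    Items are 0='Never', 1='1-2 days', 2='3-4 days', 3='5-7 days'; None/NaN
    marks a missing response.  A score is the mean of its pair's available
    items and missing only when both are missing.
    """
    def _mid(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        v = int(v)
        if v not in MIDPOINT_DAYS:
            raise ValueError(f"invalid ordinal response {v}")
        return MIDPOINT_DAYS[v]

    def _pair(a, b):
        vals = [x for x in (_mid(a), _mid(b)) if x is not None]
        return float(np.mean(vals)) if vals else np.nan

    return ActivityScores(
        child_id=child_id,
        structured_days=_pair(club_school, club_other),
        unstructured_days=_pair(play_neighbourhood, play_home),
    )


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

def compositions_to_frame(comps: list[ChildComposition]) -> pd.DataFrame:
    rows = []
    for c in comps:
        rows.append({
            "child_id": c.child_id, "group": c.group,
            "p_mvpa_wd": c.p_mvpa_wd, "p_sed_wd": c.p_sed_wd,
            "p_mvpa_we": c.p_mvpa_we, "p_sed_we": c.p_sed_we,
            "wear_wd": c.wear_wd, "wear_we": c.wear_we,
            "n_valid_weekdays": c.n_valid_weekdays,
            "n_valid_weekend": c.n_valid_weekend,
            "meets_guidelines": meets_guidelines(c),
        })
    return pd.DataFrame(rows)


def process_epoch_table(epochs: pd.DataFrame,
                        cutpoints: CutPoints = CutPoints(),
                        epoch_s: int = DEFAULT_EPOCH_S,
                        valid_day_min: float = 500,
                        min_weekdays: int = 2, min_weekend: int = 1,
                        window_min: float = 60,
                        interruption_max_min: float = 2,
                        interruption_mode: str = "per_interruption",
                        allow_missing_weekend: bool = False,
                        group: str | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process a long epoch table (child_id, timestamp, counts) into a
    compositions table and an exclusion log.

    Returns ``(compositions, exclusions)`` data frames; the compositions
    schema matches the synthetic generator's output so either can feed the
    profile models.
    """
    required = {"child_id", "timestamp", "counts"}
    if not required.issubset(epochs.columns):
        raise ValueError(f"epoch table needs columns {sorted(required)}")
    comps: list[ChildComposition] = []
    excl: list[Excluded] = []
    for cid, sub in epochs.groupby("child_id", sort=True):
        sub = sub.sort_values("timestamp")
        series = EpochSeries(child_id=cid,
                             timestamps=pd.DatetimeIndex(sub["timestamp"]),
                             counts=sub["counts"].to_numpy(),
                             epoch_s=epoch_s)
        days = []
        for date in sorted(set(series.timestamps.date)):
            days.append(summarise_day(
                series, date, cutpoints=cutpoints,
                valid_day_min=valid_day_min, window_min=window_min,
                interruption_max_min=interruption_max_min,
                interruption_mode=interruption_mode))
        res = build_composition(days, min_weekdays=min_weekdays,
                                min_weekend=min_weekend, group=group,
                                allow_missing_weekend=allow_missing_weekend)
        if isinstance(res, Excluded):
            excl.append(res)
        else:
            comps.append(res)
    comp_df = compositions_to_frame(comps) if comps else pd.DataFrame()
    excl_df = pd.DataFrame([{"child_id": e.child_id, "reason": e.reason}
                            for e in excl])
    return comp_df, excl_df
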