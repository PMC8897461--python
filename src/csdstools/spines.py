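"""Longitudinal dendritic-spine turnover statistics.

Input is a long-format presence table — one row per (ROI, spine, imaging
session) with state ``present`` / ``absent`` / ``not_imaged`` — plus the
constant dendrite length of each ROI.  From it the module computes
baseline-normalized density time courses, per-interval gain and loss
fractions and their ratio (GLR; > 1 net gain, < 1 net loss), and survival
fractions of spines newly formed after a motor task.

Conventions: a protrusion counts as a spine from 0.4 um length (inclusive);
only ROIs imaged at baseline and at day 2 enter the analysis; gain and loss
fractions are normalized by the previous session's spine count (a
baseline-count denominator is available); a spine that disappears and
reappears must carry a new id, so survival is monotone by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SessionSchedule",
    "SurvivalRecord",
    "filter_protrusions",
    "apply_roi_inclusion",
    "density_timecourse",
    "interval_turnover",
    "survival_fraction",
    "relative_change_pct_points",
    "relative_change_ratio_pct",
    "group_aggregate",
]

MIN_SPINE_LENGTH_UM = 0.4

STATE_COLUMNS = [
    "roi_id", "animal_id", "spine_id", "session_day", "state",
    "length_um", "dendrite_length_um",
]


@dataclass(frozen=True)
class SessionSchedule:
    """Imaging days relative to the last defeat day (day 0); index 0 is baseline."""

    session_days: tuple[int, ...] = (-10, 2, 5, 11, 17)
    baseline_index: int = 0
    min_interval_days: int = 3
    max_interval_days: int = 12

    def __post_init__(self) -> None:
        d = self.session_days
        if len(d) < 2:
            raise ValueError("schedule needs at least two sessions")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("session days must be strictly increasing")
        gaps = [b - a for a, b in zip(d, d[1:])]
        if any(g < self.min_interval_days or g > self.max_interval_days for g in gaps):
            raise ValueError(
                f"re-imaging intervals {gaps} violate the "
                f"[{self.min_interval_days}, {self.max_interval_days}] day protocol"
            )

    @property
    def baseline_day(self) -> int:
        return self.session_days[self.baseline_index]


def filter_protrusions(
    candidates: pd.DataFrame, min_length_um: float = MIN_SPINE_LENGTH_UM
) -> pd.DataFrame:
    """Keep protrusions of at least ``min_length_um`` (0.4 um, inclusive)."""
    lengths = candidates["length_um"].to_numpy(dtype=float)
    if (lengths < 0).any():
        raise ValueError("protrusion lengths must be >= 0 um")
    return candidates.loc[lengths >= min_length_um].reset_index(drop=True)


def _imaged_sessions(df: pd.DataFrame) -> pd.DataFrame:
    """Per (roi, session) imaged flag: a session is imaged for an ROI unless
    every spine row of that ROI carries ``not_imaged``."""
    return (
        df.assign(imaged=df["state"] != "not_imaged")
        .groupby(["roi_id", "session_day"])["imaged"]
        .any()
        .reset_index()
    )


def apply_roi_inclusion(
    df: pd.DataFrame, schedule: SessionSchedule = SessionSchedule()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop ROIs not successfully imaged at baseline and at day 2.

    Later missing sessions are retained as gaps.  Returns the included table
    and an exclusion log (roi_id, reason).
    """
    required = {schedule.baseline_day, schedule.session_days[1]}
    imaged = _imaged_sessions(df)
    ok = (
        imaged[imaged["session_day"].isin(required)]
        .groupby("roi_id")["imaged"]
        .agg(["sum", "size"])
    )
    excluded = []
    keep = []
    for roi in df["roi_id"].unique():
        if roi in ok.index and ok.loc[roi, "sum"] == len(required) and ok.loc[roi, "size"] >= len(required):
            keep.append(roi)
        else:
            excluded.append((roi, "missing baseline or day-2 imaging"))
    log = pd.DataFrame(excluded, columns=["roi_id", "reason"])
    return df[df["roi_id"].isin(keep)].reset_index(drop=True), log


def _present_counts(df: pd.DataFrame) -> pd.DataFrame:
    c = (
        df.assign(present=df["state"] == "present")
        .groupby(["roi_id", "session_day"])["present"]
        .sum()
        .reset_index(name="count")
    )
    return c


def density_timecourse(
    df: pd.DataFrame, schedule: SessionSchedule = SessionSchedule()
) -> pd.DataFrame:
    """Spine count, density (per um) and baseline-normalized density (%) per
    ROI and session.

    Normalized density is 100 * count / baseline count; an ROI with zero
    spines at baseline cannot be normalized and is flagged.  Sessions not
    imaged for an ROI get NaN metrics.
    """
    counts = _present_counts(df)
    imaged = _imaged_sessions(df)
    counts = counts.merge(imaged, on=["roi_id", "session_day"])
    lengths = df.groupby("roi_id")["dendrite_length_um"].agg(["min", "max"])
    if (lengths["min"] != lengths["max"]).any():
        raise ValueError("dendrite_length_um must be constant within an ROI")
    counts = counts.merge(
        lengths["min"].rename("dendrite_length_um"), left_on="roi_id", right_index=True
    )
    counts.loc[~counts["imaged"], "count"] = np.nan
    counts["density_per_um"] = counts["count"] / counts["dendrite_length_um"]
    base = counts[counts["session_day"] == schedule.baseline_day].set_index("roi_id")["count"]
    counts["baseline_count"] = counts["roi_id"].map(base)
    counts["zero_baseline"] = counts["baseline_count"] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        counts["norm_density_pct"] = np.where(
            counts["zero_baseline"], np.nan,
            100.0 * counts["count"] / counts["baseline_count"],
        )
    return counts[[
        "roi_id", "session_day", "imaged", "count", "dendrite_length_um",
        "density_per_um", "norm_density_pct", "zero_baseline",
    ]]


def interval_turnover(
    df: pd.DataFrame,
    day_prev: int,
    day_next: int,
    denominator: str = "previous",
    baseline_day: int | None = None,
) -> pd.DataFrame:
    """Gain/loss fractions and gain-loss ratio per ROI for one interval.

    gained: present at ``day_next`` but not at ``day_prev``; lost: present at
    ``day_prev`` but absent at ``day_next``.  Fractions use the previous
    session's count (default) or the baseline count.  GLR = gain/loss
    fraction, undefined (NaN, flagged) when nothing was lost.  Count
    conservation N_next = N_prev + gained - lost is asserted per ROI.
    """
    if denominator not in ("previous", "baseline"):
        raise ValueError("denominator must be 'previous' or 'baseline'")
    wide = df.pivot_table(
        index=["roi_id", "spine_id"], columns="session_day", values="state",
        aggfunc="first",
    )
    rows = []
    for roi, sub in wide.groupby(level="roi_id"):
        for d in (day_prev, day_next):
            if d not in sub.columns:
                raise ValueError(f"session day {d} absent from table")
        s_prev, s_next = sub[day_prev], sub[day_next]
        if (s_prev == "not_imaged").all() or (s_next == "not_imaged").all():
            rows.append((roi, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                         np.nan, True, "session not imaged"))
            continue
        prev_present = s_prev == "present"
        next_present = s_next == "present"
        n_prev = int(prev_present.sum())
        n_next = int(next_present.sum())
        gained = int((next_present & ~prev_present).sum())
        lost = int((prev_present & ~next_present).sum())
        assert n_next == n_prev + gained - lost, "count conservation violated"
        if denominator == "previous":
            denom = n_prev
        else:
            if baseline_day is None:
                raise ValueError("baseline_day required for baseline denominator")
            denom = int((sub[baseline_day] == "present").sum())
        if denom == 0:
            rows.append((roi, n_prev, n_next, gained, lost, np.nan, np.nan,
                         np.nan, True, "zero-count denominator"))
            continue
        gf, lf = gained / denom, lost / denom
        if lf > 0:
            rows.append((roi, n_prev, n_next, gained, lost, gf, lf, gf / lf, False, ""))
        else:
            rows.append((roi, n_prev, n_next, gained, lost, gf, lf, np.nan,
                         True, "no loss; glr undefined"))
    out = pd.DataFrame(
        rows,
        columns=["roi_id", "n_prev", "n_next", "gained", "lost",
                 "gain_fraction", "loss_fraction", "glr", "flagged", "flag_reason"],
    )
    return out


@dataclass(frozen=True)
class SurvivalRecord:
    birth_day: int
    cohort_size: int
    surviving: dict[int, int]
    survival_fraction: dict[int, float]


def survival_fraction(
    df: pd.DataFrame,
    birth_day: int,
    assess_days: Sequence[int],
    schedule: SessionSchedule = SessionSchedule(),
) -> SurvivalRecord:
    """Survival of spines newly formed at ``birth_day``.

    The cohort is every spine first present at ``birth_day`` (absent or
    unobserved at all earlier imaged sessions).  For each later assessment
    day the surviving fraction is computed; because reappearing spines carry
    new ids the fraction must be non-increasing, and a violation raises.
    """
    days = list(schedule.session_days)
    if birth_day not in days or days.index(birth_day) == 0:
        raise ValueError("birth session must be a scheduled, non-baseline session")
    earlier = [d for d in days if d < birth_day]
    wide = df.pivot_table(
        index=["roi_id", "spine_id"], columns="session_day", values="state",
        aggfunc="first",
    )
    born = wide[birth_day] == "present"
    for d in earlier:
        if d in wide.columns:
            born &= wide[d] != "present"
    cohort = wide[born]
    surviving: dict[int, int] = {}
    fractions: dict[int, float] = {}
    prev = 1.0
    for d in sorted(assess_days):
        if d <= birth_day:
            raise ValueError("assessment days must follow the birth session")
        if d not in wide.columns:
            continue
        n = int((cohort[d] == "present").sum())
        surviving[d] = n
        frac = n / len(cohort) if len(cohort) else float("nan")
        if len(cohort) and frac > prev + 1e-12:
            raise ValueError(
                f"survival fraction increased at day {d} ({frac:.3f} > {prev:.3f}); "
                "reappearing spines must carry new ids"
            )
        fractions[d] = frac
        prev = frac if len(cohort) else prev
    return SurvivalRecord(birth_day, int(len(cohort)), surviving, fractions)


def relative_change_pct_points(a_pct: float, b_pct: float) -> float:
    """Difference of two baseline-normalized densities, in percentage points."""
    return float(a_pct) - float(b_pct)


def relative_change_ratio_pct(a_pct: float, b_pct: float) -> float:
    """Ratio-based alternative: percent change of ``a`` relative to ``b``."""
    return 100.0 * (float(a_pct) / float(b_pct) - 1.0)


def group_aggregate(
    metrics: pd.DataFrame,
    labels: pd.Series | dict,
    value_cols: Sequence[str],
    by: Sequence[str] = ("session_day",),
    unit: str = "roi",
) -> pd.DataFrame:
    """Mean +/- SEM of ROI metrics per phenotype group.

    ``labels`` maps animal_id -> phenotype.  ``unit='roi'`` treats each ROI as
    an observation; ``unit='animal'`` first averages within animal.  Both the
    ROI and animal n are reported.
    """
    if unit not in ("roi", "animal"):
        raise ValueError("unit must be 'roi' or 'animal'")
    m = metrics.copy()
    if "animal_id" not in m.columns:
        raise ValueError("metrics must carry animal_id")
    mapped = m["animal_id"].map(labels if isinstance(labels, dict) else labels.to_dict())
    if mapped.isna().any():
        missing = sorted(m.loc[mapped.isna(), "animal_id"].unique())
        raise ValueError(f"unlabeled animals: {missing}")
    m["phenotype"] = mapped
    keys = ["phenotype", *by]
    if unit == "animal":
        m = m.groupby([*keys, "animal_id"], as_index=False)[list(value_cols)].mean()
    rows = []
    for key, sub in m.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(keys, key))
        rec["n_obs"] = len(sub)
        rec["n_animals"] = sub["animal_id"].nunique() if "animal_id" in sub else np.nan
        for c in value_cols:
            vals = sub[c].dropna().to_numpy(dtype=float)
            rec[f"{c}_mean"] = vals.mean() if vals.size else np.nan
            rec[f"{c}_sem"] = stats.sem(vals) if vals.size > 1 else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
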