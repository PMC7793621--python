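"""Locomotor bout analysis and behavioural fingerprints for larval zebrafish.

The activity signal is the per-frame count of pixels changing intensity in
a well ("delta pixels"): a sequence of zeros and positive values denoting
stillness or movement.  Each trace decomposes exactly into alternating
maximal runs — active bouts (strictly positive frames) and inactive bouts
(zero frames).  Ten parameters summarise each larva separately for day and
night epochs (the first day + night are a habituation period and are
cropped):

1. active bout length (s)          6. active bout maximum (dpx)
2. active bout mean (dpx)          7. number of active bouts
3. active bout standard deviation  8. total time active (%)
4. active bout total (dpx)         9. total activity (dpx)
5. active bout minimum (dpx)      10. inactive bout length (s)

A larva's *behavioural fingerprint* is the vector of Z-scores of these
parameters relative to its paired wild-type siblings.  Fingerprints are
compared across groups by Pearson correlation of group means and by the
Euclidean distance of each larva to the paired wild-type mean fingerprint;
groups are compared by one-way ANOVA followed by pairwise Welch's t-tests
with Holm adjustment, two-way ANOVA (condition x day/night) for activity,
and a meta-analysis Z-test for contrasting two effect sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LightSchedule",
    "Epoch",
    "Bout",
    "PARAMETERS",
    "build_epochs",
    "bin_and_smooth",
    "extract_bouts",
    "compute_parameters",
    "parameter_table",
    "fingerprint",
    "mean_fingerprint",
    "fingerprint_pearson",
    "euclidean_distances",
    "group_stats",
    "two_way_anova",
    "effect_size_comparison",
    "GroupStatsReport",
]

#: Fixed parameter order of the fingerprint (x {day, night}).
PARAMETERS = [
    "active_bout_length",
    "active_bout_mean",
    "active_bout_std",
    "active_bout_total",
    "active_bout_min",
    "active_bout_max",
    "n_active_bouts",
    "total_time_active_pct",
    "total_activity",
    "inactive_bout_length",
]

EPOCH_CLASSES = ["day", "night"]


@dataclass(frozen=True)
class LightSchedule:
    """14 h:10 h light:dark cycle, lights on at 9 am (ZT0) by default."""

    day_hours: float = 14.0
    night_hours: float = 10.0


@dataclass(frozen=True)
class Epoch:
    label: str  # "day" | "night"
    index: int  # epoch counter from experiment start
    start_frame: int
    end_frame: int  # half-open
    habituation: bool = False


@dataclass(frozen=True)
class Bout:
    """A maximal run of active (positive) or inactive (zero) frames."""

    kind: str  # "active" | "inactive"
    start: int
    end: int  # half-open frame interval
    duration: float  # seconds
    values: tuple = ()  # per-frame delta-pixel values, active bouts only


def build_epochs(
    n_frames: int,
    frame_rate: float,
    schedule: LightSchedule = LightSchedule(),
    start_label: str = "day",
    crop_habituation: bool = True,
) -> list[Epoch]:
    """Tile a trace starting at lights-on into day/night epochs.

    The first day and first night are flagged as habituation (cropped from
    all statistics) when ``crop_habituation`` is set.
    """
    epochs: list[Epoch] = []
    frame = 0
    label = start_label
    index = 0
    seen = {"day": 0, "night": 0}
    while frame < n_frames:
        hours = schedule.day_hours if label == "day" else schedule.night_hours
        end = min(n_frames, frame + int(round(hours * 3600 * frame_rate)))
        habituation = crop_habituation and seen[label] == 0
        epochs.append(Epoch(label, index, frame, end, habituation))
        seen[label] += 1
        frame = end
        label = "night" if label == "day" else "day"
        index += 1
    return epochs


def bin_and_smooth(
    trace: np.ndarray,
    frame_rate: float,
    bin_seconds: float = 1.0,
    smooth_minutes: float = 15.0,
) -> np.ndarray:
    """One-second binned, rolling-average-smoothed activity (display only).

    Statistics always use the unbinned bout structure; this reduction sums
    delta-pixel values into ``bin_seconds`` bins and applies a centred
    rolling mean of width ``smooth_minutes``.
    """
    trace = np.asarray(trace, dtype=float)
    per_bin = int(round(bin_seconds * frame_rate))
    n_bins = trace.size // per_bin
    binned = trace[: n_bins * per_bin].reshape(n_bins, per_bin).sum(axis=1)
    window = max(1, int(round(smooth_minutes * 60 / bin_seconds)))
    return (
        pd.Series(binned).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def extract_bouts(trace: np.ndarray, frame_rate: float) -> list[Bout]:
    """Run-length decomposition into alternating active/inactive bouts.

    Bouts tile the trace exactly: every frame belongs to exactly one bout.
    """
    trace = np.asarray(trace)
    if trace.size == 0:
        return []
    if np.any(trace < 0):
        raise ValueError("delta-pixel values must be non-negative")
    active = trace > 0
    boundaries = np.flatnonzero(np.diff(active)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [trace.size]])
    bouts = []
    for s, e in zip(starts, ends):
        if active[s]:
            bouts.append(
                Bout("active", int(s), int(e), (e - s) / frame_rate, tuple(trace[s:e]))
            )
        else:
            bouts.append(Bout("inactive", int(s), int(e), (e - s) / frame_rate))
    return bouts


def _class_parameters(
    trace: np.ndarray, spans: list[tuple[int, int]], frame_rate: float
) -> dict[str, float]:
    """The 10 parameters over the pooled epochs of one class for one larva."""
    active_durs: list[float] = []
    active_means: list[float] = []
    active_stds: list[float] = []
    active_totals: list[float] = []
    active_mins: list[float] = []
    active_maxs: list[float] = []
    inactive_durs: list[float] = []
    n_frames = 0
    n_active_frames = 0
    total_activity = 0.0
    for s, e in spans:
        seg = np.asarray(trace[s:e], dtype=float)
        n_frames += seg.size
        n_active_frames += int((seg > 0).sum())
        total_activity += float(seg.sum())
        for bout in extract_bouts(seg, frame_rate):
            if bout.kind == "active":
                vals = np.asarray(bout.values, dtype=float)
                active_durs.append(bout.duration)
                active_means.append(float(vals.mean()))
                active_stds.append(float(vals.std(ddof=0)))
                active_totals.append(float(vals.sum()))
                active_mins.append(float(vals.min()))
                active_maxs.append(float(vals.max()))
            else:
                inactive_durs.append(bout.duration)
    nan = float("nan")
    has_active = len(active_durs) > 0
    return {
        "active_bout_length": float(np.mean(active_durs)) if has_active else nan,
        "active_bout_mean": float(np.mean(active_means)) if has_active else nan,
        "active_bout_std": float(np.mean(active_stds)) if has_active else nan,
        "active_bout_total": float(np.mean(active_totals)) if has_active else nan,
        "active_bout_min": float(np.mean(active_mins)) if has_active else nan,
        "active_bout_max": float(np.mean(active_maxs)) if has_active else nan,
        "n_active_bouts": float(len(active_durs)),
        "total_time_active_pct": 100.0 * n_active_frames / n_frames if n_frames else nan,
        "total_activity": total_activity,
        "inactive_bout_length": float(np.mean(inactive_durs)) if inactive_durs else nan,
    }


def compute_parameters(
    trace: np.ndarray, epochs: Sequence[Epoch], frame_rate: float
) -> pd.Series:
    """Per-larva day/night parameter summary.

    Habituation epochs are cropped; remaining epochs are pooled by class
    (bout-level parameters averaged across all bouts of the class).  A
    class with zero active bouts yields NaN for the bout-level parameters
    (flagged missing downstream).
    """
    out = {}
    for cls in EPOCH_CLASSES:
        spans = [
            (ep.start_frame, ep.end_frame)
            for ep in epochs
            if ep.label == cls and not ep.habituation
        ]
        params = _class_parameters(trace, spans, frame_rate)
        for name in PARAMETERS:
            out[(name, cls)] = params[name]
    index = pd.MultiIndex.from_tuples(out.keys(), names=["parameter", "epoch"])
    return pd.Series(out.values(), index=index, dtype=float)


def parameter_table(
    traces: Mapping[str, np.ndarray] | pd.DataFrame,
    epochs: Sequence[Epoch],
    frame_rate: float,
) -> pd.DataFrame:
    """Parameter summaries for many wells (rows) x (parameter, epoch) columns.

    ``traces`` maps well id -> frame series, or is a frames x wells frame.
    """
    if isinstance(traces, pd.DataFrame):
        items = [(str(c), traces[c].to_numpy()) for c in traces.columns]
    else:
        items = [(str(k), np.asarray(v)) for k, v in traces.items()]
    rows = {well: compute_parameters(tr, epochs, frame_rate) for well, tr in items}
    return pd.DataFrame(rows).T


def fingerprint(
    mutant_params: pd.DataFrame, wildtype_params: pd.DataFrame
) -> pd.DataFrame:
    """Z-score each mutant larva against the paired wild-type statistics.

    ``Z = (x_mutant - mean_WT) / sd_WT`` per (parameter, epoch) column;
    requires at least two wild-type larvae.  Columns with zero wild-type SD
    come back NaN (excluded pairwise from downstream comparisons).
    """
    if len(wildtype_params) < 2:
        raise ValueError("need >= 2 wild-type larvae to define the Z-score")
    if not mutant_params.columns.equals(wildtype_params.columns):
        raise ValueError("mutant and wild-type parameter sets differ")
    mu = wildtype_params.mean()
    sd = wildtype_params.std(ddof=1)
    sd = sd.where(sd > 0)
    return (mutant_params - mu) / sd


def mean_fingerprint(z: pd.DataFrame) -> pd.DataFrame:
    """Group fingerprint: mean and SEM across larvae per (parameter, epoch)."""
    return pd.DataFrame({"mean": z.mean(), "sem": z.sem()})


def fingerprint_pearson(fingerprints: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Pearson r matrix between mean group fingerprints (pairwise-complete)."""
    names = list(fingerprints)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in combinations(names, 2):
        joined = pd.concat([fingerprints[a], fingerprints[b]], axis=1).dropna()
        if joined.columns.size != 2 or len(joined) < 3:
            raise ValueError(f"fingerprints {a!r} and {b!r} share too few parameters")
        val = float(stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])[0])
        r.loc[a, b] = r.loc[b, a] = val
    return r


def euclidean_distances(z: pd.DataFrame) -> pd.Series:
    """Euclidean distance of each larva's fingerprint to the paired wild-type
    mean fingerprint (the origin in Z space).

    Missing parameters (zero bouts, zero wild-type SD) are excluded
    pairwise and the distance rescaled by sqrt(k_full / k_used)."""
    k_full = z.shape[1]
    used = z.notna().sum(axis=1)
    sq = (z**2).sum(axis=1, skipna=True)
    return np.sqrt(sq * (k_full / used.where(used > 0)))


@dataclass
class GroupStatsReport:
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # group_a, group_b, t, df, p, p_holm


def group_stats(values: Sequence[float], groups: Sequence[str]) -> GroupStatsReport:
    """One-way ANOVA, then pairwise Welch's t-tests with Holm adjustment."""
    df = pd.DataFrame({"value": np.asarray(values, float), "group": list(groups)}).dropna()
    by_group = {g: sub["value"].to_numpy() for g, sub in df.groupby("group")}
    if len(by_group) < 2:
        raise ValueError("need at least two groups")
    for g, v in by_group.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than two values")
    f, p = stats.f_oneway(*by_group.values())
    rows = []
    for a, b in combinations(sorted(by_group), 2):
        res = stats.ttest_ind(by_group[a], by_group[b], equal_var=False)
        rows.append({"group_a": a, "group_b": b, "t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["p_holm"] = multipletests(pairwise["p"], method="holm")[1]
    return GroupStatsReport(float(f), float(p), pairwise)


def two_way_anova(
    df: pd.DataFrame,
    value: str = "value",
    condition: str = "condition",
    time: str = "time",
) -> pd.DataFrame:
    """Two-way ANOVA with a condition x time (day/night) interaction term."""
    model = smf.ols(f"{value} ~ C({condition}) * C({time})", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def _se_d(d: float, n1: int, n2: int) -> float:
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes too small for the standard-error formula")
    return math.sqrt((n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2)))


def effect_size_comparison(
    d_a: float, n1_a: int, n2_a: int, d_b: float, n1_b: int, n2_b: int
) -> tuple[float, float]:
    """Meta-analysis Z-test comparing two Cohen's d effect sizes.

    ``se(d) = sqrt((n1 + n2)/(n1 n2) + d^2 / (2 (n1 + n2)))`` per study;
    ``z = (d_a - d_b) / sqrt(se_a^2 + se_b^2)`` with a two-sided p-value.
    """
    se_a = _se_d(d_a, n1_a, n2_a)
    se_b = _se_d(d_b, n1_b, n2_b)
    z = (d_a - d_b) / math.sqrt(se_a**2 + se_b**2)
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return float(z), float(p)
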