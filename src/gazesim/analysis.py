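"""Looking-time summaries and the simulation-vs-data fit measure.

Gaze samples in a window are summarized by the proportion of total looking
time (PTLT) per AOI: time in the AOI divided by total time on the *face*
(Eyes + Mouth + RoF).  Off-face and away samples are excluded from the
denominator entirely.  The Eyes-Mouth preference score is
PTLT(Eyes) - PTLT(Mouth): positive means an eyes preference.

Per-trial preference scores are baseline-corrected against the trial-1
score EM_t1, with the branch-wise rescaling

    EM_bc = (EM_tn - EM_t1) / (1 - EM_t1)   if EM_tn > EM_t1
    EM_bc = (EM_tn - EM_t1) / (1 + EM_t1)   otherwise,

which maps scores into [-1, 1] and makes a positive corrected score an
*increase* in eyes preference relative to the first, unexposed trial.

Learning curves (corrected scores over trials 2..n) are reduced to the
start and end points of an ordinary least-squares line, and simulation is
compared to data by the mean squared error over the available
(condition x {start, end}) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Zone
from .simulator import ExperimentResult, TrialTimeline

#: Value used for trials with no on-face looking time.
MISSING = np.nan


class ComparisonError(ValueError):
    """Raised when simulated and measured summaries are not comparable."""


@dataclass(frozen=True)
class WindowSummary:
    """PTLT per on-face AOI plus the Eyes-Mouth preference in one window."""

    ptlt_eyes: float
    ptlt_mouth: float
    ptlt_rof: float
    window: str = "anticipatory"
    trial: int = 1

    @property
    def preference(self) -> float:
        return self.ptlt_eyes - self.ptlt_mouth

    @property
    def missing(self) -> bool:
        return bool(np.isnan(self.ptlt_eyes))


@dataclass(frozen=True)
class ScoreSeries:
    """Baseline-corrected Eyes-Mouth scores for trials 2..n of one series.

    ``scores[i]`` belongs to ``trials[i]``; missing trials are NaN.
    ``baseline`` is the raw trial-1 score the correction used.
    """

    trials: np.ndarray
    scores: np.ndarray
    baseline: float
    condition: str = "ER"
    group: str = "sim"

    def __post_init__(self):
        tr = np.asarray(self.trials, dtype=int)
        sc = np.asarray(self.scores, dtype=float)
        if tr.shape != sc.shape:
            raise ValueError("trials and scores must have equal length")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(sc), initial=0.0) > 1 + 1e-9:
                raise ValueError("corrected scores must lie in [-1, 1]")
        object.__setattr__(self, "trials", tr)
        object.__setattr__(self, "scores", sc)


@dataclass(frozen=True)
class EndpointSummary:
    """Start/end of the OLS line fitted to a score series."""

    start: float
    end: float
    slope: float
    intercept: float


def compute_ptlt(zones_in_window, window: str = "anticipatory", trial: int = 1) -> WindowSummary:
    """PTLT summary of a window of gaze samples.

    ``zones_in_window`` is either a sequence of zone indices/labels (one per
    sample; ``"away"`` or negative values mark off-screen samples) or a
    length-4 array of per-zone dwell times.  The Other zone and away samples
    never enter the denominator; a window with zero on-face time yields a
    missing (NaN) summary rather than zeros.
    """
    arr = np.asarray(zones_in_window)
    if arr.size == 0:
        raise ValueError("window is empty")
    if arr.dtype.kind in "OU":  # labels
        arr = np.array(
            [-1 if str(z) == "away" else int(Zone.from_label(str(z))) for z in arr]
        )
    if arr.ndim != 1:
        raise ValueError("expected a zone sequence or 4 dwell times")
    # A length-4 vector is read as dwell times when it cannot be a zone
    # sequence (floats, or a value outside the zone index range).
    is_dwell = arr.size == 4 and (
        arr.dtype.kind == "f" or arr.min() < -1 or arr.max() > 3
    )
    if is_dwell:
        dwell = arr.astype(float)
        if np.any(dwell < 0):
            raise ValueError("dwell times must be non-negative")
    else:
        dwell = np.array([(arr == z).sum() for z in range(4)], dtype=float)
    on_face = dwell[:3].sum()
    if on_face <= 0:
        return WindowSummary(MISSING, MISSING, MISSING, window, trial)
    e, m, r = dwell[:3] / on_face
    return WindowSummary(float(e), float(m), float(r), window, trial)


def baseline_correct_value(em, em1):
    """Eq.-style branch-wise baseline correction (vectorized).

    The tie EM_tn == EM_t1 falls in the second branch and yields exactly 0;
    the doubly degenerate EM_t1 = EM_tn = -1 case is defined as 0.
    """
    em = np.asarray(em, dtype=float)
    em1 = np.asarray(em1, dtype=float)
    denom = np.where(em > em1, 1.0 - em1, 1.0 + em1)
    num = em - em1
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom == 0, 0.0, num / np.where(denom == 0, 1.0, denom))
    return out if out.ndim else float(out)


def baseline_correct(
    raw_scores, trial1: float, condition: str = "ER", group: str = "sim",
    first_trial: int = 2,
) -> ScoreSeries:
    """Baseline-correct per-trial raw preference scores against trial 1.

    ``raw_scores`` covers trials ``first_trial..first_trial+len-1``.  NaN
    raw scores (no on-face time) stay missing.
    """
    raw = np.asarray(raw_scores, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmax(np.abs(raw), initial=0.0) > 1 + 1e-9 or (
            not np.isnan(trial1) and abs(trial1) > 1 + 1e-9
        ):
            raise ValueError("raw scores must lie in [-1, 1]")
    trials = np.arange(first_trial, first_trial + raw.size)
    if np.isnan(trial1):
        scores = np.full(raw.size, np.nan)
    else:
        scores = baseline_correct_value(raw, trial1)
    return ScoreSeries(trials, scores, float(trial1), condition, group)


def group_mean_series(series_list) -> ScoreSeries:
    """Per-trial mean over participants with non-missing values.

    Trials where every participant is missing stay missing.
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("empty series collection")
    trials = series_list[0].trials
    for s in series_list:
        if not np.array_equal(s.trials, trials):
            raise ComparisonError("series cover different trials")
    stack = np.vstack([s.scores for s in series_list])
    counts = (~np.isnan(stack)).sum(axis=0)
    sums = np.nansum(stack, axis=0)
    means = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    baselines = np.array([s.baseline for s in series_list])
    return ScoreSeries(
        trials, means, float(np.nanmean(baselines)),
        series_list[0].condition, series_list[0].group,
    )


def regression_endpoints(series: ScoreSeries) -> EndpointSummary:
    """OLS fit of score on trial number; values at the first and last trial.

    Missing trials are dropped; fewer than two remaining points is an error.
    """
    ok = ~np.isnan(series.scores)
    if ok.sum() < 2:
        raise ValueError("need >= 2 non-missing points for a regression")
    slope, intercept = np.polyfit(series.trials[ok], series.scores[ok], 1)
    t0, t1 = series.trials[0], series.trials[-1]
    return EndpointSummary(
        start=float(slope * t0 + intercept),
        end=float(slope * t1 + intercept),
        slope=float(slope),
        intercept=float(intercept),
    )


def mse_endpoints(sim: dict, data: dict) -> float:
    """Mean squared start/end difference over the shared conditions.

    ``sim`` and ``data`` map condition labels to :class:`EndpointSummary`;
    their key sets must coincide.  An eyebrow-raise-only design averages 2
    squared differences, a two-condition design 4.
    """
    if set(sim) != set(data):
        raise ComparisonError(
            f"condition mismatch: sim={sorted(sim)} data={sorted(data)}"
        )
    if not sim:
        raise ComparisonError("no conditions to compare")
    diffs = []
    for cond in sorted(sim):
        diffs.append(sim[cond].start - data[cond].start)
        diffs.append(sim[cond].end - data[cond].end)
    return float(np.mean(np.square(diffs)))


def window_preferences(
    zones: np.ndarray, timeline: TrialTimeline, window: str = "anticipatory"
) -> np.ndarray:
    """Raw Eyes-Mouth preference per (participant, trial) in a window.

    ``zones`` has shape (n_pp, n_trials, n_steps); entries < 0 are away
    samples.  Trials with no on-face sample in the window are NaN.
    """
    win = timeline.window(window)
    sub = zones[:, :, win.start:win.stop]
    counts = np.stack([(sub == z).sum(axis=-1) for z in range(3)], axis=-1)
    on_face = counts.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pref = np.where(
            on_face > 0,
            (counts[..., 0] - counts[..., 1]) / np.where(on_face > 0, on_face, 1),
            np.nan,
        )
    return pref


def experiment_score_series(
    result: ExperimentResult,
    window: str = "anticipatory",
    baseline: str = "participant",
) -> dict:
    """Group-mean corrected score series per condition of an experiment.

    ``baseline="participant"`` corrects each virtual participant by its own
    trial-1 score before averaging (the behavioral procedure);
    ``baseline="group"`` corrects the group-mean raw series by the group's
    trial-1 mean; ``baseline="none"`` returns the uncorrected group-mean
    series over all trials (including trial 1), which retains the
    preference *level* that the correction removes.
    """
    tl = result.protocol.timeline
    out = {}
    for cond, zones in result.zones.items():
        pref = window_preferences(zones, tl, window)  # (n_pp, n_trials)
        if baseline == "none":
            with np.errstate(invalid="ignore"):
                mean_raw = np.where(
                    np.all(np.isnan(pref), axis=0), np.nan,
                    np.nanmean(pref, axis=0),
                )
            out[cond] = ScoreSeries(
                np.arange(1, pref.shape[1] + 1), mean_raw, np.nan, cond
            )
        elif baseline == "participant":
            per_pp = [
                baseline_correct(pref[p, 1:], pref[p, 0], condition=cond)
                for p in range(pref.shape[0])
            ]
            out[cond] = group_mean_series(per_pp)
        elif baseline == "group":
            with np.errstate(invalid="ignore"):
                mean_raw = np.nanmean(pref, axis=0)
            out[cond] = baseline_correct(mean_raw[1:], mean_raw[0], condition=cond)
        else:
            raise ValueError(f"unknown baseline mode {baseline!r}")
    return out


def experiment_endpoints(
    result: ExperimentResult,
    window: str = "anticipatory",
    baseline: str = "participant",
) -> dict:
    """Regression endpoints of the group-mean score series per condition."""
    return {
        cond: regression_endpoints(series)
        for cond, series in experiment_score_series(result, window, baseline).items()
    }


def scores_from_table(df, timeline: TrialTimeline, window: str = "anticipatory"):
    """Per-participant corrected score series from a long gaze table.

    ``df`` needs columns participant, condition, trial, step and zone (zone
    index, -1 for away).  Returns ``{condition: [ScoreSeries, ...]}`` plus a
    per-participant raw-preference table as a second value.
    """
    import pandas as pd

    win = timeline.window(window)
    n_trials = int(df["trial"].max())
    per_cond: dict = {}
    raw_rows = []
    for (cond, pp), sub in df.groupby(["condition", "participant"], sort=True):
        pref = np.full(n_trials, np.nan)
        in_win = sub[(sub["step"] >= win.start) & (sub["step"] < win.stop)]
        for trial, tsub in in_win.groupby("trial"):
            z = tsub["zone"].to_numpy()
            dwell = np.array([(z == k).sum() for k in range(3)], dtype=float)
            if dwell.sum() > 0:
                pref[int(trial) - 1] = (dwell[0] - dwell[1]) / dwell.sum()
        series = baseline_correct(pref[1:], pref[0], condition=cond, group=str(pp))
        per_cond.setdefault(cond, []).append(series)
        for trial in range(1, n_trials + 1):
            raw_rows.append({
                "participant": pp, "condition": cond, "trial": trial,
                "window": window, "preference": pref[trial - 1],
            })
    return per_cond, pd.DataFrame(raw_rows)


def endpoints_from_series(per_cond: dict) -> dict:
    """Condition-wise endpoints of the group mean of per-participant series."""
    return {
        cond: regression_endpoints(group_mean_series(series_list))
        for cond, series_list in per_cond.items()
    }


def raw_endpoints_from_table(
    df, timeline: TrialTimeline, window: str = "anticipatory"
) -> dict:
    """Endpoints of the raw group-mean preference series of a gaze table.

    The counterpart of ``experiment_endpoints(..., baseline="none")`` for
    behavioral data: per-participant raw preferences per trial, averaged
    over participants, regressed on trial number over all trials.
    """
    _, raw = scores_from_table(df, timeline, window=window)
    out = {}
    for cond, sub in raw.groupby("condition"):
        means = sub.groupby("trial")["preference"].mean()
        series = ScoreSeries(
            means.index.to_numpy(), means.to_numpy(), np.nan, str(cond)
        )
        out[str(cond)] = regression_endpoints(series)
    return out
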