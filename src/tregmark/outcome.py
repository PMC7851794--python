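"""Clinical-outcome evaluation of a candidate marker.

A marker's expression in bulk tumor tissue confounds Treg abundance with
per-Treg expression, so the marker is first normalized by a Treg-abundance
gene (FOXP3): the score is the log2 ratio of marker to normalizer expression.
Patients are stratified into High/Low groups by upper/lower score quantiles
and compared by Kaplan–Meier curves and the log-rank test; immunotherapy
cohorts are summarized by waterfall deltas from the cohort median paired with
response labels, and tumor-stage groups by the Mann–Whitney U test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .synth import SurvivalCohort

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCohort",
    "StrataAssignment",
    "marker_score",
    "stratify",
    "km_curve",
    "logrank_test",
    "waterfall_deltas",
    "stage_comparison",
]


@dataclass
class StrataAssignment:
    """High/Low/excluded label per subject plus the cut definition."""

    labels: pd.Series  # index = subject id, values in {"High","Low","excluded"}
    score_name: str
    upper: float
    lower: float

    @property
    def high(self) -> pd.Index:
        return self.labels.index[self.labels == "High"]

    @property
    def low(self) -> pd.Index:
        return self.labels.index[self.labels == "Low"]


def marker_score(cohort: SurvivalCohort, pseudocount: float = 1.0) -> pd.Series:
    """Treg-normalized marker score: log2((marker + pc) / (normalizer + pc))."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    d = cohort.data
    score = np.log2((d["marker_expr"] + pseudocount) / (d["normalizer_expr"] + pseudocount))
    return pd.Series(score.to_numpy(), index=d["subject"], name="marker_score")


def stratify(scores: pd.Series, upper: float = 0.3, lower: float = 0.3) -> StrataAssignment:
    """Quantile stratification into High (top) and Low (bottom) groups.

    High = scores strictly above the (1 - upper) empirical quantile; Low =
    strictly below the lower quantile.  Subjects tied exactly at a cut are
    excluded (and logged) so that group membership is unambiguous.
    """
    if upper + lower > 1.0:
        raise ValueError("upper + lower must not exceed 1")
    vals = scores.to_numpy(float)
    if np.all(vals == vals[0]):
        raise ValueError("degenerate scores: all values equal, no quantile cut exists")
    hi_cut = np.quantile(vals, 1.0 - upper)
    lo_cut = np.quantile(vals, lower)
    labels = pd.Series("excluded", index=scores.index, name="stratum")
    labels[vals > hi_cut] = "High"
    labels[vals < lo_cut] = "Low"
    n_tied = int(((vals == hi_cut) | (vals == lo_cut)).sum())
    if n_tied:
        logger.info("stratify: %d subject(s) tied at a quantile cut excluded", n_tied)
    return StrataAssignment(labels, scores.name or "score", upper, lower)


def km_curve(times: pd.Series | np.ndarray, events: pd.Series | np.ndarray) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate of the survival function.

    Returns one row per distinct observed time with columns ``time``,
    ``at_risk``, ``events``, ``censored``, ``survival``.  Censored subjects
    leave the risk set without producing a step.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("km_curve requires at least one subject")
    if (times < 0).any():
        raise ValueError("negative follow-up times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tbl = kmf.event_table.copy()
    tbl = tbl.loc[tbl.index.isin(np.unique(times))]  # drop the synthetic t=0 row
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": tbl.index.to_numpy(float),
            "at_risk": tbl["at_risk"].to_numpy(int),
            "events": tbl["observed"].to_numpy(int),
            "censored": tbl["censored"].to_numpy(int),
            "survival": surv.reindex(tbl.index).to_numpy(float),
        }
    )
    return out.reset_index(drop=True)


def logrank_test(
    times_a: np.ndarray | pd.Series,
    events_a: np.ndarray | pd.Series,
    times_b: np.ndarray | pd.Series,
    events_b: np.ndarray | pd.Series,
) -> tuple[float, float]:
    """Two-sided log-rank test between two cohort subsets.

    Returns (chi-square statistic with 1 df, p-value).  With no events in
    either group the test is undefined; (0, 1) is returned with a warning.
    """
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if len(ea) == 0 or len(eb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() == 0 and eb.sum() == 0:
        warnings.warn("logrank_test: no events in either group", stacklevel=2)
        return 0.0, 1.0
    res = _ll_logrank(np.asarray(times_a, float), np.asarray(times_b, float), ea, eb)
    return float(res.test_statistic), float(res.p_value)


def waterfall_deltas(cohort: SurvivalCohort, score: pd.Series) -> pd.DataFrame:
    """Per-subject deviation of the score from the cohort median, sorted.

    Returns subjects ordered by descending delta, paired with the response
    label when present — the data behind a waterfall plot.
    """
    if len(score) < 2:
        raise ValueError("waterfall requires at least 2 subjects")
    delta = score - float(np.median(score.to_numpy(float)))
    out = pd.DataFrame({"subject": delta.index, "delta": delta.to_numpy(float)})
    if "response" in cohort.data.columns:
        resp = cohort.data.set_index("subject")["response"]
        out["response"] = resp.reindex(out["subject"]).to_numpy()
    return out.sort_values("delta", ascending=False, kind="mergesort").reset_index(drop=True)


def stage_comparison(
    group_a: np.ndarray | pd.Series,
    group_b: np.ndarray | pd.Series,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann–Whitney U between two score groups (e.g., stage IV vs stage I).

    Exact enumeration when the combined sample is small (n1 + n2 <= 12, no
    ties); the normal approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    exact_ok = (a.size + b.size) <= 12 and len(np.unique(pooled)) == pooled.size
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
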