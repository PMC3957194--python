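"""Per-subject performance summaries and the switch-cost metric.

The performance measure fed into the path models is the switch cost:
the difference in median response time on correctly answered trials
between task-switching and single-task blocks.  Accuracy is summarised
as the proportion of correct trials per condition; trials without a
response count as incorrect unless they are no-go trials on which
withholding the response was the correct action.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError

CONDITIONS = ("single", "switch")

#: trial deadline in seconds; responses cannot be slower than this
TRIAL_DEADLINE_S = 1.9


@dataclass(frozen=True)
class PerformanceSummary:
    """One subject's condition medians, accuracies and difference scores."""

    subject_id: str
    median_rt_single: float
    median_rt_switch: float
    prop_correct_single: float
    prop_correct_switch: float
    missing: bool = False

    @property
    def switch_cost_rt(self) -> float:
        return self.median_rt_switch - self.median_rt_single

    @property
    def switch_cost_acc(self) -> float:
        return self.prop_correct_switch - self.prop_correct_single


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "condition", "rt", "correct"}
    missing = required - set(trials.columns)
    if missing:
        raise InsufficientDataError(f"trial table missing columns: {sorted(missing)}")
    bad = ~trials["condition"].isin(CONDITIONS)
    if bad.any():
        raise InsufficientDataError(
            f"unknown conditions: {sorted(trials.loc[bad, 'condition'].unique())}")
    rt = trials["rt"]
    responded = rt.notna()
    if ((rt[responded] <= 0) | (rt[responded] > TRIAL_DEADLINE_S)).any():
        raise InsufficientDataError(
            f"response times must lie in (0, {TRIAL_DEADLINE_S}] seconds")
    return trials


def summarize_performance(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject condition medians, accuracies and switch costs.

    Medians use correctly answered, responded trials only; proportions
    correct use all trials of the condition (a missing response counts
    as incorrect unless it was the correct action on a no-go trial,
    which the ``correct`` column already encodes).  A subject with no
    correct responded trial in some condition gets NaN medians and a
    ``missing`` flag instead of an error, so cohorts with one broken
    subject still summarise.
    """
    trials = _validate_trials(trials)
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        rec: dict[str, object] = {"subject_id": str(sid), "missing": False}
        for cond in CONDITIONS:
            ct = sub[sub["condition"] == cond]
            ok = ct["correct"].astype(bool) & ct["rt"].notna()
            if ok.any():
                rec[f"median_rt_{cond}"] = float(ct.loc[ok, "rt"].median())
            else:
                rec[f"median_rt_{cond}"] = np.nan
                rec["missing"] = True
            rec[f"prop_correct_{cond}"] = (
                float(ct["correct"].astype(bool).mean()) if len(ct) else np.nan)
        rec["switch_cost_rt"] = rec["median_rt_switch"] - rec["median_rt_single"]
        rec["switch_cost_acc"] = (rec["prop_correct_switch"]
                                  - rec["prop_correct_single"])
        rows.append(rec)
    return pd.DataFrame(rows)


def group_difference(costs, groups) -> tuple[float, float, float]:
    """Welch two-sample comparison of per-subject costs between groups.

    Returns (t, dof, p) with the Welch-Satterthwaite degrees of freedom
    (non-integer in general).  The statistic is young minus old
    (group 0 minus group 1), so a positive cost difference in the old
    group yields a negative t.
    """
    costs = np.asarray(costs, dtype=float)
    groups = np.asarray(groups)
    young = costs[groups == 0]
    old = costs[groups == 1]
    if young.size < 2 or old.size < 2:
        raise InsufficientDataError("need at least 2 subjects per group")
    if young.std(ddof=1) == 0.0 and old.std(ddof=1) == 0.0:
        # zero variance in both groups: no evidence either way
        t = 0.0 if young.mean() == old.mean() else np.inf * np.sign(young.mean() - old.mean())
        return float(t), float(young.size + old.size - 2), 1.0 if t == 0.0 else 0.0
    res = stats.ttest_ind(young, old, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
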