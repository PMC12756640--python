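"""Time-to-conversion survival analysis.

Builds right-censored time-to-keratoconus records from per-eye label
trajectories, age-matches healthy to subclinical eyes 1:1 without
replacement, and compares KC-free survival with the Kaplan–Meier estimator
(Greenwood confidence bands) and the two-group log-rank test. Eyes, not
patients, are the survival unit; the KM comparison is unadjusted beyond the
age matching.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .features import FEATURES

AGE = "Age"


def build_survival_records(trajectories: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-eye time-to-event records from labeled trajectories.

    The event is the first visit labeled KC after baseline (first-passage:
    later reclassification away from KC does not undo it); nonconverters
    are right-censored at their last visit. Eyes without follow-up are
    excluded; their count is returned alongside the records. Baseline group
    and age are taken from the first visit.
    """
    rows = []
    n_single = 0
    for (pid, eye), g in trajectories.groupby(["patient_id", "eye"], sort=False):
        g = g.sort_values("visit_date", kind="stable")
        if len(g) < 2:
            n_single += 1
            continue
        base = g.iloc[0]
        later = g.iloc[1:]
        kc = later.loc[later["state"] == "K"]
        if len(kc):
            t = float(kc.iloc[0]["visit_date"]) - float(base["visit_date"])
            event = 1
        else:
            t = float(later.iloc[-1]["visit_date"]) - float(base["visit_date"])
            event = 0
        rows.append({
            "patient_id": pid, "eye": eye,
            "baseline_state": base["state"],
            "baseline_age": float(base[AGE]) if AGE in g.columns else np.nan,
            "time": t, "event": event,
        })
    return pd.DataFrame(rows), n_single


def age_match(skc: pd.DataFrame, healthy: pd.DataFrame, seed: int = 0,
              age_col: str = "baseline_age", caliper: float | None = None,
              ) -> pd.DataFrame:
    """1:1 greedy nearest-neighbor age matching without replacement.

    Subclinical eyes are processed in seeded random order; each takes the
    unused healthy eye with the smallest absolute age difference (optionally
    within a caliper). Returns the matched healthy subset, one row per
    subclinical eye, with the age difference recorded.
    """
    if len(healthy) < len(skc):
        raise ValueError("healthy pool smaller than subclinical group")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(skc))
    pool_age = healthy[age_col].to_numpy(float).copy()
    used = np.zeros(len(healthy), dtype=bool)
    picks, diffs = [], []
    for i in order:
        target = float(skc.iloc[i][age_col])
        d = np.abs(pool_age - target)
        d[used] = np.inf
        j = int(np.argmin(d))
        if caliper is not None and d[j] > caliper:
            raise ValueError(f"no match within caliper for age {target}")
        used[j] = True
        picks.append(j)
        diffs.append(float(d[j]))
    out = healthy.iloc[picks].copy()
    out["matched_to"] = [f"{skc.iloc[i]['patient_id']}|{skc.iloc[i]['eye']}"
                         for i in order]
    out["age_difference"] = diffs
    return out.reset_index(drop=True)


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan–Meier product-limit curve with Greenwood 95% CI.

    Returns one row per distinct time with (time, survival, ci_low, ci_high,
    n_censored) starting from S(0) = 1.
    """
    if records.empty:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    ci = kmf.confidence_interval_survival_function_
    censor_times = records.loc[records["event"] == 0, "time"]
    out = pd.DataFrame({
        "time": kmf.survival_function_.index.to_numpy(float),
        "survival": kmf.survival_function_["KM_estimate"].to_numpy(float),
        "ci_low": ci.iloc[:, 0].to_numpy(float),
        "ci_high": ci.iloc[:, 1].to_numpy(float),
    })
    out["n_censored"] = [int((censor_times == t).sum()) for t in out["time"]]
    return out


def survival_at(curve: pd.DataFrame, t: float) -> float:
    """Step-function evaluation of a KM curve at time t."""
    past = curve.loc[curve["time"] <= t, "survival"]
    return float(past.iloc[-1]) if len(past) else 1.0


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> dict:
    """Two-group log-rank chi-square test (1 df)."""
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must be nonempty")
    res = _ll_logrank(group_a["time"], group_b["time"],
                      event_observed_A=group_a["event"],
                      event_observed_B=group_b["event"])
    return {"statistic": float(res.test_statistic), "p_value": float(res.p_value)}
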