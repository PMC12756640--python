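"""Longitudinal trajectory analysis.

Per-eye classification trajectories, first-order Markov summarization of
state transitions (H/S/K), structural progression per device-specific
change criteria, and the feature-level comparison of progressing versus
stable subclinical eyes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import FEATURES, STATES, TransitionMatrix

LABEL_TO_STATE = {"Healthy": "H", "SKC": "S", "KC": "K"}


@dataclass
class ProgressionCriteria:
    """Device-specific structural progression thresholds.

    An eye progresses when at least ``min_criteria_met`` of:

    A. steepest anterior curvature radius decrease  > 0.1 mm (strict);
    B. steepest posterior curvature radius decrease > 0.05 mm (strict);
    C. minimum pachymetry reduction                 >= 20 um (inclusive);

    hold between baseline and a later visit. A radius *decrease* is corneal
    steepening; the curvature features are radii in mm, so the thresholds
    apply directly without diopter conversion.
    """

    anterior_radius_decrease_mm: float = 0.1
    posterior_radius_decrease_mm: float = 0.05
    pachymetry_reduction_um: float = 20.0
    min_criteria_met: int = 2

    def __post_init__(self):
        if min(self.anterior_radius_decrease_mm,
               self.posterior_radius_decrease_mm,
               self.pachymetry_reduction_um) <= 0:
            raise ValueError("thresholds must be > 0")
        if self.min_criteria_met not in (1, 2, 3):
            raise ValueError("min_criteria_met must be 1, 2 or 3")


def build_trajectories(classified: pd.DataFrame) -> pd.DataFrame:
    """One date-ordered trajectory row stream per eye.

    Input: classification table with (patient_id, eye, visit_date, label,
    p_kc). Output: the same rows sorted per eye with a ``state`` column
    (H/S/K). Single-visit eyes are retained (they contribute no
    transitions). Duplicate (eye, date) pairs are a QC failure upstream and
    raise.
    """
    df = classified.sort_values(["patient_id", "eye", "visit_date"],
                                kind="stable").reset_index(drop=True)
    dup = df.duplicated(subset=["patient_id", "eye", "visit_date"])
    if dup.any():
        bad = df.loc[dup, ["patient_id", "eye", "visit_date"]].iloc[0].tolist()
        raise ValueError(f"duplicate (eye, date) after QC: {bad}")
    df["state"] = df["label"].map(LABEL_TO_STATE)
    if df["state"].isna().any():
        raise ValueError("labels must be Healthy / SKC / KC")
    return df


def transition_pairs(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Consecutive (state_from, state_to) visit pairs across all eyes."""
    g = trajectories.groupby(["patient_id", "eye"], sort=False)
    frm = trajectories["state"]
    to = g["state"].shift(-1)
    ok = to.notna()
    return pd.DataFrame({"state_from": frm[ok].to_numpy(),
                         "state_to": to[ok].to_numpy()})


def estimate_transition_matrix(trajectories: pd.DataFrame,
                               ) -> tuple[TransitionMatrix | None, pd.DataFrame]:
    """Maximum-likelihood first-order Markov estimate from trajectories.

    ``probs[i][j]`` is the fraction of consecutive visit pairs leaving state
    i that arrive in state j. Returns the matrix (or None when some state
    has no outgoing transitions, in which case only counts are usable) plus
    the 3x3 count table.
    """
    pairs = transition_pairs(trajectories)
    if pairs.empty:
        raise ValueError("no transitions observed")
    counts = pd.crosstab(pairs["state_from"], pairs["state_to"])
    counts = counts.reindex(index=list(STATES), columns=list(STATES),
                            fill_value=0)
    row_sums = counts.sum(axis=1)
    if (row_sums == 0).any():
        return None, counts
    probs = counts.div(row_sums, axis=0).to_numpy(float)
    return TransitionMatrix(probs=probs), counts


def progression_flags(first_visit: pd.Series, later_visit: pd.Series,
                      criteria: ProgressionCriteria | None = None) -> dict:
    """A/B/C criterion flags between two visits of one eye."""
    criteria = criteria or ProgressionCriteria()
    for col in ("KMax F", "KMax B", "ThkMin"):
        if pd.isna(first_visit.get(col)) or pd.isna(later_visit.get(col)):
            raise ValueError(f"missing required feature {col!r}")
    d_ant = float(first_visit["KMax F"]) - float(later_visit["KMax F"])
    d_post = float(first_visit["KMax B"]) - float(later_visit["KMax B"])
    d_thk = float(first_visit["ThkMin"]) - float(later_visit["ThkMin"])
    flags = {
        "A": d_ant > criteria.anterior_radius_decrease_mm,
        "B": d_post > criteria.posterior_radius_decrease_mm,
        "C": d_thk >= criteria.pachymetry_reduction_um,
    }
    flags["progressed"] = sum(flags.values()) >= criteria.min_criteria_met
    return flags


def evaluate_progression(eye_records: pd.DataFrame,
                         criteria: ProgressionCriteria | None = None,
                         mode: str = "baseline") -> dict:
    """Aggregate progression assessment for one eye across follow-ups.

    ``mode="baseline"`` (default) compares the baseline visit against every
    later visit and takes the worst case per criterion (cumulative change);
    ``mode="consecutive"`` evaluates consecutive visit pairs instead. Flags
    are combined so each criterion is true if any compared pair meets it,
    then ``progressed`` requires ``min_criteria_met`` criteria on the same
    pair.
    """
    criteria = criteria or ProgressionCriteria()
    df = eye_records.sort_values("visit_date", kind="stable")
    if len(df) < 2:
        return {"A": False, "B": False, "C": False, "progressed": False}
    if mode == "baseline":
        pairs = [(df.iloc[0], df.iloc[i]) for i in range(1, len(df))]
    elif mode == "consecutive":
        pairs = [(df.iloc[i], df.iloc[i + 1]) for i in range(len(df) - 1)]
    else:
        raise ValueError("mode must be 'baseline' or 'consecutive'")
    agg = {"A": False, "B": False, "C": False, "progressed": False}
    for first, later in pairs:
        f = progression_flags(first, later, criteria)
        for k in agg:
            agg[k] = agg[k] or f[k]
    return agg


def _per_eye_changes(records: pd.DataFrame) -> pd.DataFrame:
    """Per-eye mean signed and mean absolute per-visit change per feature."""
    rows = []
    for (pid, eye), g in records.groupby(["patient_id", "eye"], sort=False):
        g = g.sort_values("visit_date", kind="stable")
        if len(g) < 2:
            continue
        diffs = g[list(FEATURES)].astype(float).diff().iloc[1:]
        row = {"patient_id": pid, "eye": eye}
        for f in FEATURES:
            row[f"{f}|signed"] = diffs[f].mean()
            row[f"{f}|abs"] = diffs[f].abs().mean()
        rows.append(row)
    return pd.DataFrame(rows)


def progression_drivers(records: pd.DataFrame, progressor_keys: set,
                        n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Which features change differently in progressing subclinical eyes.

    ``records`` holds the longitudinal feature scans of subclinical-baseline
    eyes; ``progressor_keys`` the (patient_id, eye) pairs that reached the
    keratoconus band at some follow-up. Per feature:

    * direction: sign of the difference in median signed per-visit change
      (progressors minus nonprogressors);
    * signed log2 fold change: direction times the log2 ratio of mean
      absolute per-visit change (progressors over nonprogressors), with a
      seeded bootstrap 95% CI — so features that shrink faster in
      progressors (thinning) carry a negative fold change;
    * rank-sum p on the per-eye absolute changes, plus Benjamini-Hochberg
      adjusted p across the 21 features.
    """
    ch = _per_eye_changes(records)
    if ch.empty:
        raise ValueError("no eyes with at least two visits")
    is_prog = ch.apply(lambda r: (r["patient_id"], r["eye"]) in progressor_keys,
                       axis=1).to_numpy(bool)
    if is_prog.sum() < 5 or (~is_prog).sum() < 5:
        raise ValueError("need at least 5 eyes per group")
    rng = np.random.default_rng(seed)
    rows = []
    for f in FEATURES:
        a = ch.loc[is_prog, f"{f}|abs"].to_numpy(float)
        b = ch.loc[~is_prog, f"{f}|abs"].to_numpy(float)
        sa = ch.loc[is_prog, f"{f}|signed"].to_numpy(float)
        sb = ch.loc[~is_prog, f"{f}|signed"].to_numpy(float)
        direction = int(np.sign(np.median(sa) - np.median(sb)))
        sign = direction if direction != 0 else 1

        def l2fc(x, y):
            mx, my = np.mean(x), np.mean(y)
            if mx <= 0 or my <= 0:
                return np.nan
            return sign * np.log2(mx / my)

        est = l2fc(a, b)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = l2fc(rng.choice(a, size=len(a)),
                            rng.choice(b, size=len(b)))
        if np.isnan(boots).all():
            ci = np.array([np.nan, np.nan])
        else:
            ci = np.sort(np.nanpercentile(boots, [2.5, 97.5]))
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append({"feature": f, "direction": direction, "log2_fc": est,
                     "ci_low": ci[0], "ci_high": ci[1], "p_value": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
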