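"""Desk-scale validation experiments.

Self-contained simulation experiments that exercise the generator together
with the estimation machinery: one-step Markov transition recovery from the
subclinical state, and the age-matched subclinical-versus-healthy
time-to-conversion comparison. These are the quantitative checks run by the
acceptance script and the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortConfig, generate_cross_sectional, \
    generate_longitudinal, sample_next_states
from .features import GROUP_TO_STATE, TransitionMatrix, \
    default_transition_matrix
from .longitudinal import build_trajectories, estimate_transition_matrix
from .survival import age_match, build_survival_records, logrank_test

_STATE_TO_LABEL = {"H": "Healthy", "S": "SKC", "K": "KC"}


def one_step_transition_estimate(n: int = 5000, seed: int = 0,
                                 state: str = "S",
                                 transitions: TransitionMatrix | None = None,
                                 ) -> dict:
    """Estimate one-step transition frequencies from ``n`` simulated pairs.

    Simulates ``n`` eyes in the given state, advances each one Markov step
    under ``transitions`` (default matrix if omitted), then recovers the
    empirical row with the first-order Markov estimator over the resulting
    two-visit trajectories. Returns the estimated row as a dict keyed by
    destination state plus the sample size.
    """
    transitions = transitions or default_transition_matrix()
    rng = np.random.default_rng([seed, 8])
    nxt = sample_next_states([state] * n, transitions, rng)
    rows = []
    for i, s in enumerate(nxt):
        rows.append({"patient_id": f"P{i}", "eye": "OD", "visit_date": 0,
                     "label": _STATE_TO_LABEL[state], "p_kc": 0.5})
        rows.append({"patient_id": f"P{i}", "eye": "OD", "visit_date": 30,
                     "label": _STATE_TO_LABEL[s], "p_kc": 0.5})
    traj = build_trajectories(pd.DataFrame(rows))
    # only the sampled state has outgoing transitions, so take its row from
    # the estimator's count table
    _, counts = estimate_transition_matrix(traj)
    row = counts.loc[state] / counts.loc[state].sum()
    return {"H": float(row["H"]), "S": float(row["S"]), "K": float(row["K"]),
            "n": int(counts.loc[state].sum())}


def _baseline_eyes(group: str, n_eyes: int, seed: int) -> pd.DataFrame:
    """A baseline cross-section of exactly ``n_eyes`` eyes of one group."""
    n_pat = n_eyes // 2 + 1
    conc = {g: 1.0 for g in ("healthy", "subclinical", "keratoconus")}
    if group == "subclinical":
        cfg = CohortConfig(n_healthy_patients=1, n_kc_patients=n_pat,
                           skc_fraction=1.0, fellow_eye_concordance=conc,
                           seed=seed)
    else:
        cfg = CohortConfig(n_healthy_patients=n_pat, n_kc_patients=1,
                           skc_fraction=0.0, fellow_eye_concordance=conc,
                           seed=seed)
    df = generate_cross_sectional(cfg)
    df = df.loc[df["true_group"] == group].head(n_eyes).copy()
    if len(df) < n_eyes:
        raise ValueError(f"could not generate {n_eyes} {group} eyes")
    df["patient_id"] = group[0].upper() + df["patient_id"]
    return df


def conversion_survival_experiment(n_per_group: int = 337, seed: int = 0,
                                   horizon_days: int = 800,
                                   transitions: TransitionMatrix | None = None,
                                   ) -> dict:
    """Age-matched subclinical vs healthy time-to-conversion comparison.

    Simulates ``n_per_group`` subclinical-baseline and healthy-baseline
    eyes, evolves them over the follow-up horizon under the per-visit
    transition dynamics and group visit rates, builds right-censored
    time-to-KC records, age-matches healthy to subclinical 1:1 without
    replacement, and reports the two-group log-rank test.
    """
    transitions = transitions or default_transition_matrix()
    skc_base = _baseline_eyes("subclinical", n_per_group, seed)
    healthy_base = _baseline_eyes("healthy", n_per_group, seed + 1)
    baseline = pd.concat([skc_base, healthy_base], ignore_index=True)
    cfg = CohortConfig(seed=seed, followup_horizon_days=horizon_days)
    longi = generate_longitudinal(baseline, transitions, cfg)

    traj = longi[["patient_id", "eye", "visit_date", "Age"]].copy()
    traj["state"] = longi["true_group"].map(GROUP_TO_STATE)
    records, n_excluded = build_survival_records(traj)
    skc = records.loc[records["baseline_state"] == "S"].reset_index(drop=True)
    healthy = records.loc[records["baseline_state"] == "H"].reset_index(drop=True)
    if len(healthy) < len(skc):  # rare: more SKC than healthy retain follow-up
        rng = np.random.default_rng([seed, 9])
        keep = np.sort(rng.choice(len(skc), size=len(healthy), replace=False))
        skc = skc.iloc[keep].reset_index(drop=True)
    matched = age_match(skc, healthy, seed=seed)
    res = logrank_test(skc, matched)
    res.update(
        n_skc=int(len(skc)), n_matched_healthy=int(len(matched)),
        n_excluded_no_followup=int(n_excluded),
        skc_conversion_fraction=float(skc["event"].mean()),
        healthy_conversion_fraction=float(matched["event"].mean()),
        mean_age_skc=float(skc["baseline_age"].mean()),
        mean_age_matched=float(matched["baseline_age"].mean()),
    )
    return res
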