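"""Quality control: coverage rule, best-scan selection, plausibility,
outlier removal, repeatability, and report reconciliation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import skcpipe as sp
from skcpipe.features import FEATURES
from skcpipe.qc import (
    QCConfig,
    filter_by_coverage,
    plausibility_filter,
    remove_multivariate_outliers,
    select_best_same_day,
)


def _scan(oc=90.0, sc=95.0, **features):
    spec = sp.group_spec("healthy")
    row = dict(zip(FEATURES, spec.mean))
    row.update(features)
    row.update(patient_id="P0", eye="OD", visit_date=0, oc=oc, sc=sc,
               true_group="healthy", site="main", artifact_tag="")
    return row


def _frame(rows):
    return pd.DataFrame(rows)


# ------------------------------------------------------------- coverage

@pytest.mark.parametrize("oc,sc,kept", [
    (70, 10, True),    # primary criterion: OC above threshold
    (65, 85, False),   # both exactly at threshold: strict inequalities
    (40, 90, True),    # rescued by the secondary SC criterion
    (65.0001, 10, True),
    (40, 85, False),
])
def test_coverage_rule(oc, sc, kept):
    k, r = filter_by_coverage(_frame([_scan(oc=oc, sc=sc)]))
    assert (len(k) == 1) == kept


def test_missing_coverage_routed_with_reason():
    k, r = filter_by_coverage(_frame([_scan(oc=np.nan)]))
    assert len(k) == 0
    assert r["qc_reason"].iloc[0] == "missing_coverage"


@settings(max_examples=200, deadline=None, derandomize=True)
@given(oc=st.floats(0, 100), sc=st.floats(0, 100),
       bump=st.floats(0, 50))
def test_coverage_filter_monotone_in_oc(oc, sc, bump):
    """Raising OC never flips a kept scan to removed."""
    lo, _ = filter_by_coverage(_frame([_scan(oc=oc, sc=sc)]))
    hi, _ = filter_by_coverage(_frame([_scan(oc=min(oc + bump, 100), sc=sc)]))
    assert len(hi) >= len(lo)


# ------------------------------------------------------- same-day select

def test_same_day_selects_highest_composite():
    df = _frame([_scan(oc=90, sc=90), _scan(oc=80, sc=95)])
    kept, removed = select_best_same_day(df)
    assert len(kept) == 1 and kept.iloc[0]["oc"] == 90  # composite 90 > 87.5
    assert removed["qc_reason"].iloc[0] == "same_day_duplicate"


def test_same_day_single_scan_identity():
    df = _frame([_scan()])
    kept, removed = select_best_same_day(df)
    assert len(kept) == 1 and len(removed) == 0


def test_same_day_tie_broken_by_higher_oc():
    df = _frame([_scan(oc=90, sc=80), _scan(oc=80, sc=90)])
    kept, _ = select_best_same_day(df)
    assert kept.iloc[0]["oc"] == 90


def test_same_day_full_tie_keeps_first_input():
    df = _frame([_scan(oc=85, sc=85, **{"TSI": 1.0}),
                 _scan(oc=85, sc=85, **{"TSI": 2.0})])
    kept, _ = select_best_same_day(df)
    assert kept.iloc[0]["TSI"] == 1.0


# --------------------------------------------------------- plausibility

@pytest.mark.parametrize("feature,value,kept", [
    ("ThkMin", -5.0, False),    # non-positive thickness
    ("ThkMin", 0.0, False),
    ("RMS F", -0.01, False),    # negative RMS
    ("RMS F", 0.0, True),       # zero RMS is allowed
    ("KMax B", 0.0, False),     # non-positive keratometry radius
    ("NotablePtsR", -0.1, False),
])
def test_sign_rules(feature, value, kept):
    k, _ = plausibility_filter(_frame([_scan(**{feature: value})]))
    assert (len(k) == 1) == kept


def test_healthy_means_are_plausible():
    k, r = plausibility_filter(_frame([_scan()]))
    assert len(k) == 1 and len(r) == 0


# -------------------------------------------------------------- outliers

def _clean_cohort(n_patients=250, seed=13):
    cfg = sp.CohortConfig(n_healthy_patients=n_patients,
                          n_kc_patients=n_patients, skc_fraction=0.0, seed=seed)
    return sp.generate_cross_sectional(cfg)


def test_isolation_forest_recalls_injected_outliers():
    base = _clean_cohort()
    cfg = sp.CohortConfig(seed=3)
    cfg.artifact_rates["multivariate_outliers"] = 0.02
    injected = sp.inject_artifacts(base, cfg)
    n_out = int((injected["artifact_tag"] == "mv_outlier").sum())
    assert n_out >= 10
    qc_cfg = QCConfig(outlier_contamination=n_out / len(injected), seed=0)
    kept, removed = remove_multivariate_outliers(injected, qc_cfg)
    recalled = (removed["artifact_tag"] == "mv_outlier").sum()
    assert recalled >= int(0.8 * n_out)
    # never removes more than contamination * n + 1 records
    assert len(removed) <= qc_cfg.outlier_contamination * len(injected) + 1


def test_outlier_contamination_zero_is_identity():
    base = _clean_cohort(60)
    kept, removed = remove_multivariate_outliers(
        base, QCConfig(outlier_contamination=0.0))
    assert len(removed) == 0 and len(kept) == len(base)


def test_outlier_stage_deterministic():
    base = _clean_cohort(60)
    cfg = QCConfig(outlier_contamination=0.05, seed=7)
    _, r1 = remove_multivariate_outliers(base, cfg)
    _, r2 = remove_multivariate_outliers(base, cfg)
    assert list(r1.index) == list(r2.index)


def test_outlier_stage_skipped_below_minimum():
    base = _clean_cohort(10).head(20)
    with pytest.warns(UserWarning):
        kept, removed = remove_multivariate_outliers(base, QCConfig())
    assert len(kept) == 20 and len(removed) == 0


# ---------------------------------------------------------- repeatability

def test_repeatability_identical_repeats_zero_sd():
    rows = [_scan(), _scan()]
    table = sp.repeatability_analysis(_frame(rows))
    assert (table["within_subject_sd"] == 0).all()


def test_repeatability_two_point_closed_form():
    """Two repeats differing by d in one feature: within-subject SD = d/sqrt(2)."""
    d = 8.0
    rows = [_scan(), _scan(**{"ThkMin": sp.group_spec("healthy").mean[
        FEATURES.index("ThkMin")] + d})]
    table = sp.repeatability_analysis(_frame(rows))
    got = table.loc[(table["feature"] == "ThkMin")
                    & (table["coverage_metric"] == "oc"),
                    "within_subject_sd"].iloc[0]
    assert got == pytest.approx(d / np.sqrt(2))


def test_repeatability_detects_doubled_noise_at_low_coverage():
    """Repeat noise doubled below the OC threshold shows up as ~2x the
    within-subject SD of high-coverage bins."""
    rng = np.random.default_rng(0)
    spec = sp.group_spec("healthy")
    rows = []
    for i in range(300):
        low = i % 2 == 0
        oc = rng.uniform(40, 60) if low else rng.uniform(70, 90)
        noise = 2.0 if low else 1.0
        for rep in range(2):
            x = spec.mean + noise * rng.standard_normal(len(FEATURES))
            r = dict(zip(FEATURES, x))
            r.update(patient_id=f"P{i}", eye="OD", visit_date=0,
                     oc=oc, sc=90.0, true_group="healthy", site="main",
                     artifact_tag="")
            rows.append(r)
    table = sp.repeatability_analysis(_frame(rows))
    oc_tab = table[(table["coverage_metric"] == "oc")
                   & (table["feature"] == "TSI")]
    low_sd = oc_tab.loc[oc_tab["bin_high"] <= 65, "within_subject_sd"].mean()
    high_sd = oc_tab.loc[oc_tab["bin_low"] >= 65, "within_subject_sd"].mean()
    assert 1.5 < low_sd / high_sd < 2.5


def test_repeatability_no_repeats_warns_empty():
    with pytest.warns(UserWarning):
        table = sp.repeatability_analysis(_frame([_scan()]))
    assert table.empty


# ------------------------------------------------------------ full report

def test_qc_report_reconciles_exactly():
    cfg = sp.CohortConfig(n_healthy_patients=150, n_kc_patients=150,
                          skc_fraction=0.0, seed=21)
    cfg.artifact_rates.update(same_day_repeats=0.05, low_coverage=0.05,
                              implausible_values=0.03,
                              multivariate_outliers=0.01)
    raw = sp.inject_artifacts(sp.generate_cross_sectional(cfg), cfg)
    clean, report = sp.run_qc(raw, QCConfig(outlier_contamination=0.01, seed=0))
    assert report.n_input == len(raw)
    assert report.n_output == len(clean)
    assert sum(report.removed_counts.values()) == len(raw) - len(clean)
    all_removed = [i for ids in report.removed_ids.values() for i in ids]
    assert len(all_removed) == len(set(all_removed))  # removed at most once
    # tagged artifacts are overwhelmingly caught by some stage
    tagged = raw.index[raw["artifact_tag"].isin(
        ["low_coverage", "implausible"])].tolist()
    assert set(tagged) <= set(all_removed)
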