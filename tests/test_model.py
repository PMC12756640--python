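"""Core classifier: normalization, PCA, class-conditional Gaussians,
Bayes posterior, banding, frozen projection, band sensitivity, batch check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import skcpipe as sp
from skcpipe.features import FEATURES, GroupFeatureSpec
from skcpipe.model import gaussian_mle

from conftest import feature_frame


def test_gaussian_mle_hand_computed_moments():
    pts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
    mu, cov = gaussian_mle(pts)
    np.testing.assert_allclose(mu, [1.0, 1.0])
    np.testing.assert_allclose(cov, np.diag([4 / 3, 4 / 3]))


def test_mle_invariant_to_row_duplication(trained):
    model, df = trained
    coords = model.transform(df.head(100))
    mu1, cov1 = gaussian_mle(coords)
    mu2, _ = gaussian_mle(np.vstack([coords, coords]))
    np.testing.assert_allclose(mu1, mu2)


def test_fit_sign_convention_and_variance_ordering(trained):
    model, df = trained
    assert model.class_means_["KC"][0] > model.class_means_["Healthy"][0]
    evr = model.explained_variance_ratio_
    assert np.all(np.diff(evr) <= 0) and evr.sum() <= 1 + 1e-12
    assert evr[0] > evr[1]


def test_pca_loadings_orthonormal(trained):
    model, _ = trained
    gram = model.components_ @ model.components_.T
    np.testing.assert_allclose(gram, np.eye(2), atol=1e-8)


def test_full_rank_projection_reconstructs(trained):
    _, df = trained
    train = df[df["true_group"].isin(["healthy", "keratoconus"])]
    y = train["true_group"].map({"healthy": "Healthy",
                                 "keratoconus": "KC"}).to_numpy()
    full = sp.KCBayesClassifier(n_components=len(FEATURES)).fit(train, y)
    z = full.normalize(train)
    coords = full.transform(train)
    back = coords @ full.components_ + full.pca_mean_
    np.testing.assert_allclose(back, z, atol=1e-8)


def test_normalization_round_trip(trained):
    model, df = trained
    x = df.head(50)[list(FEATURES)].to_numpy(float)
    np.testing.assert_allclose(model.denormalize(model.normalize(x)), x,
                               atol=1e-10)


def test_fit_rejects_constant_feature(balanced_cohort):
    df = balanced_cohort.head(50).copy()
    df["TSI"] = 1.0
    y = np.array(["Healthy"] * 25 + ["KC"] * 25)
    with pytest.raises(ValueError, match="TSI"):
        sp.KCBayesClassifier().fit(df, y)


def test_fit_rejects_tiny_class(balanced_cohort):
    df = balanced_cohort.head(10)
    y = np.array(["Healthy"] * 8 + ["KC"] * 2)
    with pytest.raises(ValueError, match="KC"):
        sp.KCBayesClassifier().fit(df, y)


# ------------------------------------------------------------- posterior

def _brute_posterior(model, records):
    """Independent oracle: direct density quotient via scipy pdfs."""
    coords = model.transform(records)
    num = model.priors_[1] * stats.multivariate_normal.pdf(
        coords, model.class_means_["KC"], model.class_covs_["KC"])
    den = num + model.priors_[0] * stats.multivariate_normal.pdf(
        coords, model.class_means_["Healthy"], model.class_covs_["Healthy"])
    return np.atleast_1d(num / den)


def test_posterior_matches_bruteforce_oracle(trained):
    model, df = trained
    rng = np.random.default_rng(0)
    spec = sp.group_spec("healthy")
    x = spec.mean + rng.standard_normal((1000, len(FEATURES))) * spec.sd * 2
    records = feature_frame(x)
    np.testing.assert_allclose(model.posterior_kc(records),
                               _brute_posterior(model, records), atol=1e-10)


def test_posterior_complementarity(trained):
    model, df = trained
    proba = model.predict_proba(df.head(200))
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)


def test_posterior_half_at_equidistant_point(toy_model):
    x = np.zeros((1, len(FEATURES)))
    x[0, 0] = 2.0  # midpoint of the class means under shared covariance
    assert toy_model.posterior_kc(x)[0] == pytest.approx(0.5, abs=1e-12)


def test_posterior_at_kc_mean_dominates(toy_model):
    x = np.zeros((1, len(FEATURES)))
    x[0, 0] = 4.0
    assert toy_model.posterior_kc(x)[0] >= 0.95


def test_toy_1d_posterior_closed_form(toy_model):
    """Classes N(0,1) and N(4,1) on PC1: at z=1 the posterior equals the
    direct density quotient 1 / (1 + exp((d_K - d_H)/2))."""
    x = np.zeros((1, len(FEATURES)))
    x[0, 0] = 1.0
    expected = 1.0 / (1.0 + np.exp(((4 - 1) ** 2 - 1 ** 2) / 2))
    assert toy_model.posterior_kc(x)[0] == pytest.approx(expected, abs=1e-12)
    brute = _brute_posterior(toy_model, x)[0]
    assert toy_model.posterior_kc(x)[0] == pytest.approx(brute, abs=1e-12)


def test_missing_feature_error_names_it(trained):
    model, df = trained
    with pytest.raises(ValueError, match="ThkMin"):
        model.posterior_kc(df.head(3).drop(columns=["ThkMin"]))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(t=st.floats(-10, 10), step=st.floats(0.001, 5))
def test_equal_covariance_posterior_monotone_along_axis(t, step):
    """With shared covariance the posterior is a logistic in a linear score,
    hence monotone along the healthy->KC direction."""
    m = sp.KCBayesClassifier()
    n = len(FEATURES)
    m.norm_mean_, m.norm_scale_ = np.zeros(n), np.ones(n)
    m.pca_mean_, m.components_ = np.zeros(n), np.eye(2, n)
    m.class_means_ = {"Healthy": np.zeros(2), "KC": np.array([3.0, 1.0])}
    cov = np.array([[2.0, 0.3], [0.3, 1.0]])
    m.class_covs_ = {"Healthy": cov, "KC": cov}
    m.priors_ = np.array([0.5, 0.5])
    direction = m.class_means_["KC"] - m.class_means_["Healthy"]
    x = np.zeros((2, n))
    x[0, :2] = t * direction
    x[1, :2] = (t + step) * direction
    p = m.posterior_kc(x)
    assert p[1] >= p[0]


# ----------------------------------------------------------------- bands

@pytest.mark.parametrize("p,label,tier", [
    (0.75, "SKC", "subclinical"),        # closed band upper endpoint
    (0.25, "SKC", "subclinical"),        # closed band lower endpoint
    (0.751, "KC", "likely_kc"),
    (0.249, "Healthy", "likely_healthy"),
    (0.04, "Healthy", "high_conf_healthy"),
    (0.05, "Healthy", "likely_healthy"),  # high-confidence tier is strict <
    (0.951, "KC", "high_conf_kc"),
    (0.95, "KC", "likely_kc"),
])
def test_band_and_tier_semantics(toy_model, p, label, tier):
    arr = np.array([p])
    assert toy_model._label(arr)[0] == label
    assert toy_model._tier(arr)[0] == tier


def test_invalid_bands_rejected(balanced_cohort):
    df = balanced_cohort.head(20)
    y = np.array(["Healthy"] * 10 + ["KC"] * 10)
    with pytest.raises(ValueError):
        sp.KCBayesClassifier(bands=(0.25, 0.05, 0.75, 0.95)).fit(df, y)


# ---------------------------------------------------- frozen projection

def test_followup_projection_is_frozen(trained):
    model, df = trained
    p_train = model.posterior_kc(df)
    shuffled = df.sample(frac=1.0, random_state=1)
    p_shuf = model.posterior_kc(shuffled)
    np.testing.assert_allclose(p_shuf, p_train[shuffled.index.to_numpy()],
                               atol=1e-12)
    sub = sp.project_followup(model, df.head(7))
    np.testing.assert_allclose(sub["p_kc"].to_numpy(), p_train[:7], atol=1e-12)


def test_posterior_increases_toward_kc_mean(trained):
    model, _ = trained
    h, k = sp.group_spec("healthy").mean, sp.group_spec("keratoconus").mean
    steps = np.linspace(0, 1, 8)
    x = np.array([h + t * (k - h) for t in steps])
    p = model.posterior_kc(feature_frame(x))
    assert np.all(np.diff(p) > -1e-9)
    assert p[-1] > 0.95 and p[0] < 0.05


# -------------------------------------------------------- band sensitivity

def test_band_sensitivity_default_band_full_overlap(trained):
    model, df = trained
    table = sp.band_sensitivity(model, df, [(0.25, 0.75)])
    assert table["overlap_with_default"].iloc[0] == 1.0


def test_band_sensitivity_wider_band_gains_skc(trained):
    model, df = trained
    table = sp.band_sensitivity(model, df, [(0.25, 0.75), (0.20, 0.80),
                                            (0.30, 0.70)])
    n_default, n_wide, n_narrow = table["n_skc"]
    assert n_wide >= n_default >= n_narrow
    assert (table["overlap_with_default"] >= 0.9).all()


# ----------------------------------------------------------- batch effect

def test_batch_effect_zero_jitter_zero_distance(trained):
    model, _ = trained
    pairs = sp.generate_paired_site_scans(4, jitter_sd=0.0, seed=3)
    res = sp.batch_effect_check(model, pairs)
    assert res["mean_distance"] == pytest.approx(0.0, abs=1e-9)
    assert res["p_value"] == 1.0


def test_batch_effect_distances_match_hand_norms(trained):
    model, _ = trained
    pairs = sp.generate_paired_site_scans(9, seed=4)
    res = sp.batch_effect_check(model, pairs)
    assert res["n_pairs"] == 18  # nine bilateral patients
    a = pairs[pairs["site"] == "site_a"].sort_values(["patient_id", "eye"])
    b = pairs[pairs["site"] == "site_b"].sort_values(["patient_id", "eye"])
    hand = np.linalg.norm(model.transform(a) - model.transform(b), axis=1)
    assert res["mean_distance"] == pytest.approx(hand.mean())
    assert res["mean_distance"] > 0


def test_batch_effect_orphan_detection(trained):
    model, _ = trained
    pairs = sp.generate_paired_site_scans(3, seed=5).iloc[:-1]
    with pytest.raises(ValueError, match="unpaired"):
        sp.batch_effect_check(model, pairs)


# ------------------------------------------------------------ downsampling

def _patients_frame(n_healthy, n_kc, eyes_per_patient=1):
    rows = []
    spec = sp.group_spec("healthy")
    for i in range(n_healthy + n_kc):
        label = "Healthy" if i < n_healthy else "KC"
        for e in range(eyes_per_patient):
            row = dict(zip(FEATURES, spec.mean))
            row.update(patient_id=f"P{i:05d}", eye="OD" if e == 0 else "OS",
                       visit_date=0, label=label)
            rows.append(row)
    return pd.DataFrame(rows)


def test_downsample_balances_patient_counts():
    df = _patients_frame(40, 90, eyes_per_patient=2)
    out = sp.downsample_majority(df, seed=0)
    counts = out.groupby("label")["patient_id"].nunique()
    assert counts["Healthy"] == counts["KC"] == 40
    # all eyes of every sampled patient retained
    assert (out.groupby("patient_id").size() == 2).all()


def test_downsample_equal_groups_identity():
    df = _patients_frame(30, 30)
    out = sp.downsample_majority(df, seed=1)
    assert len(out) == len(df)


def test_downsample_deterministic():
    df = _patients_frame(40, 90)
    a = sp.downsample_majority(df, seed=5)
    b = sp.downsample_majority(df, seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_downsample_keeps_earliest_scan_per_eye():
    df = _patients_frame(5, 5)
    later = df.copy()
    later["visit_date"] = 100
    out = sp.downsample_majority(pd.concat([later, df]), seed=0)
    assert (out["visit_date"] == 0).all()


# ---------------------------------------------------------- serialization

def test_json_round_trip_preserves_posteriors(trained, tmp_path):
    model, df = trained
    path = tmp_path / "model.json"
    model.to_json(path)
    clone = sp.KCBayesClassifier.from_json(path)
    np.testing.assert_array_equal(clone.posterior_kc(df.head(100)),
                                  model.posterior_kc(df.head(100)))
    assert clone.bands == model.bands


# --------------------------------------------------------- label recovery

def test_label_recovery_on_well_separated_groups():
    """With tightened group spread the classifier recovers >=99% of the
    generated extremes; generated-subclinical eyes concentrate in the band."""
    specs = {}
    for g in ("healthy", "subclinical", "keratoconus"):
        s = sp.group_spec(g)
        specs[g] = GroupFeatureSpec(group=g, mean=s.mean, sd=0.3 * s.sd)
    cfg = sp.CohortConfig(n_healthy_patients=400, n_kc_patients=400,
                          skc_fraction=0.08, seed=31)
    df = sp.generate_cross_sectional(cfg, specs=specs)
    train = df[df["true_group"].isin(["healthy", "keratoconus"])]
    y = train["true_group"].map({"healthy": "Healthy",
                                 "keratoconus": "KC"}).to_numpy()
    model = sp.KCBayesClassifier().fit(train, y)
    out = model.classify(df)
    for g, lab in (("healthy", "Healthy"), ("keratoconus", "KC")):
        mask = df["true_group"] == g
        assert (out.loc[mask.to_numpy(), "label"] == lab).mean() >= 0.99
    skc = out.loc[(df["true_group"] == "subclinical").to_numpy()]
    extremes = out.loc[(df["true_group"] != "subclinical").to_numpy()]
    assert (skc["label"] == "SKC").mean() > 3 * (extremes["label"] == "SKC").mean()
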