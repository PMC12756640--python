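import warnings

import numpy as np
import pandas as pd
import pytest

import skcpipe as sp

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def balanced_cohort() -> pd.DataFrame:
    """Cross-sectional cohort with both extremes and a subclinical track."""
    cfg = sp.CohortConfig(n_healthy_patients=300, n_kc_patients=300,
                          skc_fraction=0.05, seed=11)
    return sp.generate_cross_sectional(cfg)


@pytest.fixture(scope="session")
def trained(balanced_cohort):
    """(model, cohort) with the classifier fitted on the labeled extremes."""
    df = balanced_cohort
    train = df[df["true_group"].isin(["healthy", "keratoconus"])]
    y = train["true_group"].map({"healthy": "Healthy",
                                 "keratoconus": "KC"}).to_numpy()
    model = sp.KCBayesClassifier().fit(train, y)
    return model, df


@pytest.fixture()
def toy_model():
    """Hand-constructed fitted model: identity preprocessing, unit-variance
    class Gaussians at PC1 = 0 (healthy) and PC1 = 4 (keratoconus)."""
    m = sp.KCBayesClassifier()
    n = len(sp.FEATURES)
    m.norm_mean_ = np.zeros(n)
    m.norm_scale_ = np.ones(n)
    m.pca_mean_ = np.zeros(n)
    m.components_ = np.eye(2, n)
    m.explained_variance_ratio_ = np.array([0.7, 0.1])
    m.class_means_ = {"Healthy": np.zeros(2), "KC": np.array([4.0, 0.0])}
    m.class_covs_ = {"Healthy": np.eye(2), "KC": np.eye(2)}
    m.ridge_eps_ = {"Healthy": 0.0, "KC": 0.0}
    m.priors_ = np.array([0.5, 0.5])
    m.n_per_class_ = {"Healthy": 0, "KC": 0}
    m.classes_ = np.array(["Healthy", "SKC", "KC"])
    return m


def feature_frame(matrix: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(np.asarray(matrix, dtype=float),
                        columns=list(sp.FEATURES))
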