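"""Semi-supervised keratoconus probability model.

The central computation: z-score normalization and PCA (top two components)
fitted on pooled labeled extremes (healthy and keratoconus eyes), one
Gaussian class-conditional density per class in PC1–PC2 space with equal
priors, and a Bayes posterior keratoconus probability

    P(KC | x) = pi_K N(z; mu_K, Sigma_K) /
                (pi_H N(z; mu_H, Sigma_H) + pi_K N(z; mu_K, Sigma_K))

evaluated in log-density space. Labels derive from the posterior:

* Healthy      iff P(KC|x) < 0.25
* Subclinical  iff 0.25 <= P(KC|x) <= 0.75   (closed intermediate band)
* Keratoconus  iff P(KC|x) > 0.75

with high-confidence tiers at P < 0.05 and P > 0.95. The subclinical label
is not a third fitted cluster: it marks eyes near the decision boundary
where the Bayes factor is close to one.

The per-class "single-component EM" fit is the closed-form Gaussian maximum
likelihood estimate, which is the fixed point of EM with one component.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA

from .features import FEATURES, LABELS, N_FEATURES, TRAIN_CLASSES

TIERS = ("high_conf_healthy", "likely_healthy", "subclinical",
         "likely_kc", "high_conf_kc")


def gaussian_mle(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and unbiased (n-1 denominator) covariance of a point cloud.

    With a single Gaussian component, expectation-maximization converges in
    one step to exactly these moments, so this closed form *is* the EM fit.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need a 2-D array with at least 2 points")
    return pts.mean(axis=0), np.cov(pts, rowvar=False, ddof=1)


def _as_matrix(X) -> np.ndarray:
    """Coerce input to an (n, 21) float matrix in canonical feature order."""
    if isinstance(X, pd.DataFrame):
        missing = [f for f in FEATURES if f not in X.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {', '.join(missing)}")
        x = X[list(FEATURES)].to_numpy(float)
    else:
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {x.shape[1]}")
    if np.isnan(x).any():
        j = int(np.argwhere(np.isnan(x))[0, 1])
        raise ValueError(f"missing value in feature {FEATURES[j]!r}")
    return x


def downsample_majority(records: pd.DataFrame, seed: int = 0,
                        label_col: str = "label") -> pd.DataFrame:
    """Balance the two training classes at the patient level.

    Keeps only the earliest scan per eye, then randomly downsamples the
    majority class's *patients* to match the minority class's patient count
    (all eyes of a sampled patient are retained). Balancing the classes
    stops the class-conditional fit from inheriting priors from sample
    sizes. Deterministic given ``seed``.
    """
    df = records.sort_values(["patient_id", "eye", "visit_date"], kind="stable")
    df = df.drop_duplicates(subset=["patient_id", "eye"], keep="first")
    counts = {c: df.loc[df[label_col] == c, "patient_id"].nunique()
              for c in TRAIN_CLASSES}
    minority = min(counts, key=counts.get)
    majority = max(counts, key=counts.get)
    if counts[majority] <= counts[minority]:
        if counts[majority] < counts[minority]:
            warnings.warn("majority class smaller than minority: no downsampling")
        return df.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    maj_patients = np.sort(df.loc[df[label_col] == majority, "patient_id"].unique())
    keep = set(rng.choice(maj_patients, size=counts[minority], replace=False))
    mask = (df[label_col] != majority) | df["patient_id"].isin(keep)
    return df.loc[mask].reset_index(drop=True)


class KCBayesClassifier(BaseEstimator, ClassifierMixin):
    """PCA + dual class-conditional Gaussian posterior classifier.

    Parameters
    ----------
    n_components:
        Number of retained principal components (default 2).
    bands:
        Posterior thresholds ``(high_conf_low, band_low, band_high,
        high_conf_high)``, strictly increasing in (0, 1). The closed
        ``[band_low, band_high]`` interval is the subclinical band.
    priors:
        Class priors (healthy, keratoconus); equal by default so the
        posterior reflects morphology, not cohort composition.
    ridge_cond, ridge_eps:
        If a class covariance's condition number exceeds ``ridge_cond``,
        ``ridge_eps`` is added to its diagonal (recorded in ``ridge_eps_``).

    Fitted attributes (all set by :meth:`fit`)
    ------------------------------------------
    ``norm_mean_``, ``norm_scale_`` : per-feature training moments;
    ``components_`` : (n_components, 21) orthonormal loadings, sign-fixed so
    the keratoconus class mean has positive PC1;
    ``explained_variance_ratio_`` : per-component variance fractions;
    ``class_means_``, ``class_covs_`` : per-class Gaussian parameters in PC
    space; ``classes_`` : the three output labels.
    """

    def __init__(self, n_components: int = 2,
                 bands: tuple = (0.05, 0.25, 0.75, 0.95),
                 priors: tuple = (0.5, 0.5),
                 ridge_cond: float = 1e10, ridge_eps: float = 1e-8):
        self.n_components = n_components
        self.bands = bands
        self.priors = priors
        self.ridge_cond = ridge_cond
        self.ridge_eps = ridge_eps

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        b = tuple(self.bands)
        if not (len(b) == 4 and 0 < b[0] < b[1] < b[2] < b[3] < 1):
            raise ValueError("bands must be strictly increasing in (0, 1)")
        x = _as_matrix(X)
        y = np.asarray(y)
        if set(np.unique(y)) - set(TRAIN_CLASSES):
            raise ValueError(f"labels must be in {TRAIN_CLASSES}")
        for c in TRAIN_CLASSES:
            if (y == c).sum() < 3:
                raise ValueError(f"class {c!r} has fewer than 3 eyes")

        self.norm_mean_ = x.mean(axis=0)
        self.norm_scale_ = x.std(axis=0, ddof=0)
        zero = self.norm_scale_ == 0
        if zero.any():
            bad = [FEATURES[i] for i in np.flatnonzero(zero)]
            raise ValueError(f"constant feature(s) at fit: {', '.join(bad)}")
        z = (x - self.norm_mean_) / self.norm_scale_

        pca = PCA(n_components=self.n_components, svd_solver="full")
        coords = pca.fit_transform(z)
        self.pca_mean_ = pca.mean_
        components = pca.components_.copy()
        self.explained_variance_ratio_ = pca.explained_variance_ratio_.copy()

        # Sign convention: disease severity increases along +PC1.
        if coords[y == "KC", 0].mean() < coords[y == "Healthy", 0].mean():
            components[0] *= -1.0
            coords[:, 0] *= -1.0
        self.components_ = components

        self.class_means_ = {}
        self.class_covs_ = {}
        self.ridge_eps_ = {}
        for c in TRAIN_CLASSES:
            mu, cov = gaussian_mle(coords[y == c])
            eps = 0.0
            if np.linalg.cond(cov) > self.ridge_cond:
                eps = self.ridge_eps
                cov = cov + eps * np.eye(cov.shape[0])
            self.class_means_[c] = mu
            self.class_covs_[c] = cov
            self.ridge_eps_[c] = eps
        self.priors_ = np.asarray(self.priors, dtype=float)
        self.priors_ = self.priors_ / self.priors_.sum()
        self.n_per_class_ = {c: int((y == c).sum()) for c in TRAIN_CLASSES}
        self.classes_ = np.array(LABELS)
        return self

    # ----------------------------------------------------------- transforms
    def _check_fitted(self):
        if not hasattr(self, "components_"):
            raise ValueError("model is not fitted")

    def normalize(self, X) -> np.ndarray:
        self._check_fitted()
        return (_as_matrix(X) - self.norm_mean_) / self.norm_scale_

    def denormalize(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return np.asarray(Z, dtype=float) * self.norm_scale_ + self.norm_mean_

    def transform(self, X) -> np.ndarray:
        """Project records into the learned PC space (frozen parameters)."""
        z = self.normalize(X)
        return (z - self.pca_mean_) @ self.components_.T

    # ------------------------------------------------------------ posterior
    def _log_joint(self, coords: np.ndarray) -> np.ndarray:
        out = np.empty((len(coords), 2))
        for j, c in enumerate(TRAIN_CLASSES):
            out[:, j] = np.log(self.priors_[j]) + stats.multivariate_normal.logpdf(
                coords, mean=self.class_means_[c], cov=self.class_covs_[c])
        return out

    def posterior_kc(self, X) -> np.ndarray:
        """P(KC | x) for each record, computed in log-density space."""
        self._check_fitted()
        lj = self._log_joint(self.transform(X))
        # p = exp(lK) / (exp(lH) + exp(lK)), evaluated stably
        return 1.0 / (1.0 + np.exp(lj[:, 0] - lj[:, 1]))

    def predict_proba(self, X) -> np.ndarray:
        """Columns (P(Healthy|x), P(KC|x)); rows sum to one."""
        p = self.posterior_kc(X)
        return np.column_stack([1.0 - p, p])

    # -------------------------------------------------------------- labels
    def _label(self, p: np.ndarray) -> np.ndarray:
        _, lo, hi, _ = self.bands
        lab = np.where(p < lo, "Healthy", np.where(p > hi, "KC", "SKC"))
        return lab.astype(object)

    def _tier(self, p: np.ndarray) -> np.ndarray:
        t0, lo, hi, t1 = self.bands
        out = np.empty(len(p), dtype=object)
        out[p < t0] = "high_conf_healthy"
        out[(p >= t0) & (p < lo)] = "likely_healthy"
        out[(p >= lo) & (p <= hi)] = "subclinical"
        out[(p > hi) & (p <= t1)] = "likely_kc"
        out[p > t1] = "high_conf_kc"
        return out

    def predict(self, X) -> np.ndarray:
        """Three-way label per record: Healthy / SKC / KC."""
        return self._label(self.posterior_kc(X))

    def classify(self, records: pd.DataFrame) -> pd.DataFrame:
        """Full classification table: PC coordinates, posterior, label, tier.

        Carries through identifier columns when present so longitudinal
        stages can join on (patient, eye, day).
        """
        coords = self.transform(records)
        lj = self._log_joint(coords)
        p = 1.0 / (1.0 + np.exp(lj[:, 0] - lj[:, 1]))
        out = pd.DataFrame({
            "pc1": coords[:, 0], "pc2": coords[:, 1],
            "p_kc": p, "label": self._label(p), "tier": self._tier(p),
        })
        if isinstance(records, pd.DataFrame):
            for c in ("patient_id", "eye", "visit_date", "true_group", "site"):
                if c in records.columns:
                    out.insert(0, c, records[c].to_numpy())
        return out

    # -------------------------------------------------------- serialization
    def to_json(self, path=None) -> str:
        self._check_fitted()
        payload = {
            "params": self.get_params(),
            "norm_mean": self.norm_mean_.tolist(),
            "norm_scale": self.norm_scale_.tolist(),
            "pca_mean": self.pca_mean_.tolist(),
            "components": self.components_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "class_means": {c: m.tolist() for c, m in self.class_means_.items()},
            "class_covs": {c: v.tolist() for c, v in self.class_covs_.items()},
            "ridge_eps": self.ridge_eps_,
            "priors": self.priors_.tolist(),
            "n_per_class": self.n_per_class_,
            "features": list(FEATURES),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "KCBayesClassifier":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        params = payload["params"]
        params["bands"] = tuple(params["bands"])
        params["priors"] = tuple(params["priors"])
        model = cls(**params)
        model.norm_mean_ = np.array(payload["norm_mean"])
        model.norm_scale_ = np.array(payload["norm_scale"])
        model.pca_mean_ = np.array(payload["pca_mean"])
        model.components_ = np.array(payload["components"])
        model.explained_variance_ratio_ = np.array(
            payload["explained_variance_ratio"])
        model.class_means_ = {c: np.array(m)
                              for c, m in payload["class_means"].items()}
        model.class_covs_ = {c: np.array(v)
                             for c, v in payload["class_covs"].items()}
        model.ridge_eps_ = payload["ridge_eps"]
        model.priors_ = np.array(payload["priors"])
        model.n_per_class_ = payload["n_per_class"]
        model.classes_ = np.array(LABELS)
        return model


def project_followup(model: KCBayesClassifier, records: pd.DataFrame,
                     ) -> pd.DataFrame:
    """Classify follow-up scans under the frozen model (no refitting).

    Identical records receive identical posteriors regardless of batch
    composition or ordering, so longitudinal trajectories live in the same
    morphological space as the training fit.
    """
    return model.classify(records)


def band_sensitivity(model: KCBayesClassifier, records: pd.DataFrame,
                     bands: list[tuple[float, float]]) -> pd.DataFrame:
    """Stability of the subclinical label under alternative band limits.

    For each candidate ``(lo, hi)`` band: the subclinical count and the
    fraction of eyes whose three-way label matches their default-band label.
    """
    p = model.posterior_kc(records)
    _, lo0, hi0, _ = model.bands
    base = np.where(p < lo0, "Healthy", np.where(p > hi0, "KC", "SKC"))
    rows = []
    for lo, hi in bands:
        if not 0 < lo < hi < 1:
            raise ValueError("band limits must satisfy 0 < lo < hi < 1")
        lab = np.where(p < lo, "Healthy", np.where(p > hi, "KC", "SKC"))
        rows.append({
            "band_low": lo, "band_high": hi,
            "n_skc": int((lab == "SKC").sum()),
            "skc_fraction": float((lab == "SKC").mean()),
            "overlap_with_default": float((lab == base).mean()),
        })
    return pd.DataFrame(rows)


def batch_effect_check(model: KCBayesClassifier, paired_records: pd.DataFrame,
                       ) -> dict:
    """Paired-site displacement test in PC space.

    Pairs records of the same (patient, eye) across the two sites, computes
    the Euclidean PC1–PC2 distance per pair, and runs a one-sample t-test of
    the distances against zero mean displacement. Distances are non-negative
    by construction, so this test is degenerate except when every distance
    is exactly zero; it is reported as specified, with that caveat noted in
    the package documentation.
    """
    sites = sorted(paired_records["site"].unique())
    if len(sites) != 2:
        raise ValueError(f"expected exactly 2 sites, got {sites}")
    a = paired_records[paired_records["site"] == sites[0]]
    b = paired_records[paired_records["site"] == sites[1]]
    key = ["patient_id", "eye"]
    ka = set(map(tuple, a[key].itertuples(index=False)))
    kb = set(map(tuple, b[key].itertuples(index=False)))
    orphans = ka ^ kb
    if orphans:
        raise ValueError(f"unpaired record keys: {sorted(orphans)}")
    a = a.sort_values(key, kind="stable")
    b = b.sort_values(key, kind="stable")
    da = model.transform(a)
    db = model.transform(b)
    dist = np.linalg.norm(da - db, axis=1)
    if np.allclose(dist.std(ddof=1) if len(dist) > 1 else 0.0, 0.0):
        p_value = 1.0 if np.allclose(dist, 0.0) else 0.0
        t_stat = 0.0 if np.allclose(dist, 0.0) else np.inf
    else:
        t_stat, p_value = stats.ttest_1samp(dist, 0.0)
    return {
        "n_pairs": int(len(dist)),
        "mean_distance": float(dist.mean()),
        "sd_distance": float(dist.std(ddof=1)) if len(dist) > 1 else 0.0,
        "t_statistic": float(t_stat),
        "p_value": float(p_value),
        "distances": dist,
    }
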