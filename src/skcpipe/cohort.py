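"""Synthetic cohort generation.

Emulates the statistical structure of a two-site anterior-segment OCT
keratoconus dataset so that every downstream stage (quality control, model
fitting, longitudinal tracking, survival analysis) can be exercised without
any patient data:

* cross-sectional eyes drawn from per-group marginal distributions with a
  one-factor latent severity axis inducing realistic inter-feature
  correlation;
* fellow-eye group concordance at configurable per-group rates;
* longitudinal follow-up visits at exponential inter-visit times with
  first-order Markov evolution of the classification state;
* acquisition artifacts (same-day repeat scans, low-coverage scans,
  physiologically implausible values, multivariate outliers), each tagged so
  QC recall is measurable;
* paired same-patient scans from two sites for batch-effect checking.

All generation is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (
    DEFAULT_VISIT_RATES,
    FEATURES,
    GROUPS,
    GROUP_TO_STATE,
    N_FEATURES,
    NONNEGATIVE_FEATURES,
    POSITIVE_FEATURES,
    SCHEMA_COLUMNS,
    STATE_TO_GROUP,
    STATES,
    GroupFeatureSpec,
    TransitionMatrix,
    default_specs,
    default_transition_matrix,
    severity_directions,
)

AGE_INDEX = FEATURES.index("Age")
AGE_RANGE = (6.0, 97.0)

#: Fraction of each feature's SD carried by the shared latent severity factor.
DEFAULT_LATENT_SHARE = 0.7

#: Fellow-eye same-group concordance rates observed in the reference cohort.
DEFAULT_CONCORDANCE = {"healthy": 0.949, "subclinical": 0.096, "keratoconus": 0.841}

#: Given a discordant subclinical index eye, the fellow is keratoconic or
#: healthy in roughly this ratio (54.6% : 42.5% renormalised).
_SKC_FELLOW_KC_SHARE = 0.546 / (0.546 + 0.425)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Counts are patients (each contributing two eyes). ``skc_fraction`` is the
    fraction of all patients whose index eye is on the subclinical track.
    ``artifact_rates`` are per-record Bernoulli rates for each artifact kind.
    """

    n_healthy_patients: int = 100
    n_kc_patients: int = 100
    skc_fraction: float = 0.034
    fellow_eye_concordance: dict = field(default_factory=lambda: dict(DEFAULT_CONCORDANCE))
    latent_loading: np.ndarray | None = None
    visit_rate_per_year: dict = field(default_factory=lambda: dict(DEFAULT_VISIT_RATES))
    followup_horizon_days: int = 800
    artifact_rates: dict = field(default_factory=lambda: {
        "same_day_repeats": 0.0, "low_coverage": 0.0,
        "implausible_values": 0.0, "multivariate_outliers": 0.0,
    })
    seed: int = 0

    def __post_init__(self):
        if self.n_healthy_patients <= 0 or self.n_kc_patients <= 0:
            raise ValueError("patient counts must be > 0")
        props = [self.skc_fraction, *self.fellow_eye_concordance.values(),
                 *self.artifact_rates.values()]
        if any(not (0.0 <= p <= 1.0) for p in props):
            raise ValueError("all proportions must lie in [0, 1]")
        for g in self.fellow_eye_concordance:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in concordance")
        for g, r in self.visit_rate_per_year.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in visit rates")
            if r <= 0:
                raise ValueError("visit rates must be > 0")


def _age_beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) parameters on [6, 97] matching the requested moments."""
    lo, hi = AGE_RANGE
    m = (mean - lo) / (hi - lo)
    v = (sd / (hi - lo)) ** 2
    if v >= m * (1 - m):
        raise ValueError("age SD infeasible on the [6, 97] range")
    a = m * (m * (1 - m) / v - 1)
    return a, a * (1 - m) / m


def _draw_ages(group: str, n: int, specs, rng) -> np.ndarray:
    mean = specs[group].mean[AGE_INDEX]
    sd = specs[group].sd[AGE_INDEX]
    if sd == 0:
        return np.full(n, mean)
    a, b = _age_beta_params(mean, sd)
    lo, hi = AGE_RANGE
    return lo + (hi - lo) * rng.beta(a, b, size=n)


def _loadings(spec: GroupFeatureSpec, override: np.ndarray | None) -> np.ndarray:
    """Signed latent loadings in feature units; age carries no loading."""
    if override is not None:
        lo = np.asarray(override, dtype=float)
        if lo.shape != (N_FEATURES,):
            raise ValueError(f"latent_loading must have length {N_FEATURES}")
        return lo
    lo = severity_directions() * DEFAULT_LATENT_SHARE * spec.sd
    lo[AGE_INDEX] = 0.0
    return lo


#: Sign-constrained features whose marginals are drawn as moment-matched
#: Gamma rather than Gaussian (positive support; Gamma -> Gaussian as the
#: shape parameter grows, so well-separated-from-zero features are
#: effectively unchanged).
_GAMMA_FEATURES = frozenset(POSITIVE_FEATURES) | frozenset(NONNEGATIVE_FEATURES)
_GAMMA_IDX = np.array([i for i, f in enumerate(FEATURES) if f in _GAMMA_FEATURES])


def _draw_features(group: str, n: int, specs, rng, override=None,
                   latent: np.ndarray | None = None) -> np.ndarray:
    """Draw n feature vectors under the one-factor latent severity model.

    A standard-normal severity score s (shared across the eye's features)
    induces inter-feature correlation: each feature's standardized value is
    z = c*s + sqrt(1-c^2)*eps with c = loading/sd, so every marginal stays
    standard normal and the latent share of variance is c^2. Marginals are
    then mapped to the group spec: Gaussian mean + sd*z for unconstrained
    features, and a moment-matched Gamma through the Gaussian copula
    (x = F^-1(Phi(z))) for sign-constrained thickness/keratometry/RMS/
    distance metrics, so their support is positive while the requested
    mean and SD are preserved exactly. Age is drawn from a moment-matched
    Beta on [6, 97]; callers that assign ages at the patient level
    overwrite it.
    """
    from scipy import stats as _st

    spec = specs[group]
    load = _loadings(spec, override)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(spec.sd > 0, load / spec.sd, 0.0)
    frac = np.clip(frac, -1.0, 1.0)
    s = rng.standard_normal(n) if latent is None else np.asarray(latent, dtype=float)
    eps = rng.standard_normal((n, N_FEATURES))
    z = np.outer(s, frac) + eps * np.sqrt(1.0 - frac ** 2)

    x = spec.mean + spec.sd * z
    for j in _GAMMA_IDX:
        m, sd = spec.mean[j], spec.sd[j]
        if sd == 0 or m <= 0:
            continue
        shape = (m / sd) ** 2
        scale = sd ** 2 / m
        u = _st.norm.cdf(z[:, j])
        x[:, j] = _st.gamma.ppf(u, a=shape, scale=scale)
    x[:, AGE_INDEX] = _draw_ages(group, n, specs, rng)
    return x


def _fellow_group(group: str, concordant: np.ndarray, rng) -> list[str]:
    out = []
    for c in concordant:
        if c:
            out.append(group)
        elif group == "subclinical":
            out.append("keratoconus" if rng.random() < _SKC_FELLOW_KC_SHARE
                       else "healthy")
        else:
            out.append("subclinical")
    return out


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=list(SCHEMA_COLUMNS))


def generate_cross_sectional(config: CohortConfig,
                             specs: dict[str, GroupFeatureSpec] | None = None,
                             ) -> pd.DataFrame:
    """Generate one baseline scan per eye for a synthetic cross-section.

    Patients are assigned a primary group (healthy / keratoconus, with a
    ``skc_fraction`` share of all patients reassigned to the subclinical
    track); the index eye (OD) takes the primary group and the fellow eye
    (OS) matches it with the configured concordance probability. Patient age
    is shared by both eyes; the remaining 20 indices are drawn per eye from
    the eye's group spec through the latent severity model.
    """
    specs = default_specs() if specs is None else specs
    for g in ("healthy", "keratoconus"):
        if g not in specs:
            raise ValueError(f"specs must cover group {g!r}")
    rng = np.random.default_rng([config.seed, 1])

    n_total = config.n_healthy_patients + config.n_kc_patients
    n_skc = int(round(config.skc_fraction * n_total))
    if n_skc > 0 and "subclinical" not in specs:
        raise ValueError("specs must cover group 'subclinical'")
    primary = (["healthy"] * config.n_healthy_patients
               + ["keratoconus"] * config.n_kc_patients)
    # Reassign a deterministic subset of patients to the subclinical track.
    skc_idx = rng.choice(n_total, size=n_skc, replace=False) if n_skc else []
    for i in skc_idx:
        primary[i] = "subclinical"

    rows: dict[str, list] = {c: [] for c in ("patient_id", "eye", "true_group", "age")}
    for i, grp in enumerate(primary):
        pid = f"P{i:05d}"
        conc = config.fellow_eye_concordance.get(grp, 1.0)
        fellow = _fellow_group(grp, np.array([rng.random() < conc]), rng)[0]
        for eye, g in (("OD", grp), ("OS", fellow)):
            rows["patient_id"].append(pid)
            rows["eye"].append(eye)
            rows["true_group"].append(g)
    ages = {}
    pids = sorted(set(rows["patient_id"]))
    for pid, grp in zip(pids, primary):
        ages[pid] = None  # filled per group below
    # patient-level ages drawn per primary group
    by_group: dict[str, list[str]] = {}
    for pid, grp in zip(pids, primary):
        by_group.setdefault(grp, []).append(pid)
    for grp, members in by_group.items():
        vals = _draw_ages(grp, len(members), specs, rng)
        for pid, a in zip(members, vals):
            ages[pid] = a
    rows["age"] = [ages[p] for p in rows["patient_id"]]

    df = pd.DataFrame({k: rows[k] for k in ("patient_id", "eye", "true_group", "age")})
    feats = np.empty((len(df), N_FEATURES))
    for grp in GROUPS:
        mask = (df["true_group"] == grp).to_numpy()
        if mask.any():
            feats[mask] = _draw_features(grp, int(mask.sum()), specs, rng,
                                         override=config.latent_loading)
    feats[:, AGE_INDEX] = df["age"].to_numpy()

    out = pd.DataFrame(feats, columns=list(FEATURES))
    out.insert(0, "patient_id", df["patient_id"].to_numpy())
    out.insert(1, "eye", df["eye"].to_numpy())
    out.insert(2, "visit_date", 0)
    out["oc"] = rng.uniform(66.0, 100.0, size=len(out))
    out["sc"] = rng.uniform(86.0, 100.0, size=len(out))
    out["true_group"] = df["true_group"].to_numpy()
    out["site"] = "main"
    out["artifact_tag"] = ""
    return out[list(SCHEMA_COLUMNS)]


def sample_next_states(states: list[str] | np.ndarray,
                       transitions: TransitionMatrix,
                       rng: np.random.Generator) -> np.ndarray:
    """One Markov step for a vector of H/S/K states."""
    states = np.asarray(states)
    out = np.empty(states.shape, dtype=object)
    for s in STATES:
        mask = states == s
        if mask.any():
            out[mask] = rng.choice(STATES, size=int(mask.sum()),
                                   p=transitions.row(s))
    return out


def generate_longitudinal(baseline: pd.DataFrame,
                          transitions: TransitionMatrix | None = None,
                          config: CohortConfig | None = None,
                          specs: dict[str, GroupFeatureSpec] | None = None,
                          ) -> pd.DataFrame:
    """Extend a baseline cross-section with follow-up visits.

    Each eye attends follow-up visits at exponential inter-visit intervals
    (rate set by the baseline group, visits per year) until the follow-up
    horizon. The classification state evolves per visit by the first-order
    Markov chain; at each visit the 20 indices are redrawn from the current
    state's group spec (so an S->K transition drifts features toward the
    keratoconus distribution: thicknesses fall, elevation and RMS indices
    rise), while age advances with elapsed time. Returns baseline and
    follow-up rows concatenated, sorted by (patient, eye, day).
    """
    if baseline.empty:
        raise ValueError("baseline must be nonempty")
    transitions = default_transition_matrix() if transitions is None else transitions
    config = CohortConfig() if config is None else config
    specs = default_specs() if specs is None else specs
    horizon = config.followup_horizon_days
    if horizon <= 0:
        raise ValueError("followup_horizon_days must be > 0")
    rng = np.random.default_rng([config.seed, 2])

    new_rows = []
    for _, row in baseline.iterrows():
        group = row["true_group"]
        state = GROUP_TO_STATE[group]
        rate = config.visit_rate_per_year.get(group, DEFAULT_VISIT_RATES["healthy"])
        latent = rng.standard_normal()
        t = 0.0
        day_prev = 0
        while True:
            t += rng.exponential(365.25 / rate)
            day = int(np.ceil(t))
            if day > horizon:
                break
            if day <= day_prev:  # keep one scan per day per eye
                day = day_prev + 1
            day_prev = day
            state = sample_next_states([state], transitions, rng)[0]
            grp = STATE_TO_GROUP[state]
            x = _draw_features(grp, 1, specs, rng, override=config.latent_loading,
                               latent=np.array([latent]))[0]
            x[AGE_INDEX] = row["Age"] + day / 365.25
            rec = {c: row[c] for c in ("patient_id", "eye", "site")}
            rec.update(dict(zip(FEATURES, x)))
            rec["visit_date"] = day
            rec["oc"] = rng.uniform(66.0, 100.0)
            rec["sc"] = rng.uniform(86.0, 100.0)
            rec["true_group"] = grp
            rec["artifact_tag"] = ""
            new_rows.append(rec)

    follow = pd.DataFrame(new_rows, columns=list(SCHEMA_COLUMNS)) if new_rows \
        else _empty_frame()
    out = pd.concat([baseline, follow], ignore_index=True)
    return out.sort_values(["patient_id", "eye", "visit_date"],
                           kind="stable").reset_index(drop=True)


def inject_artifacts(records: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Inject tagged acquisition artifacts at the configured per-record rates.

    Artifact kinds (mutually exclusive per record; duplicates are appended):

    - ``same_day_repeat``: an extra scan of the same eye on the same day with
      degraded coverage and extra measurement noise;
    - ``low_coverage``: coverage metrics forced below the inclusion
      thresholds;
    - ``implausible``: one sign-rule feature set to a physiologically
      impossible value (non-positive thickness/keratometry or negative RMS/
      distance);
    - ``mv_outlier``: every feature displaced by at least 6 pooled SDs with
      a random sign, emulating grossly abnormal or mislabeled scans.
    """
    rates = config.artifact_rates
    rng = np.random.default_rng([config.seed, 3])
    out = records.copy().reset_index(drop=True)
    n = len(out)
    if n == 0:
        return out
    pooled_sd = np.mean(
        [default_specs()[g].sd for g in GROUPS], axis=0)
    feat_cols = list(FEATURES)

    taken = np.zeros(n, dtype=bool)

    def pick(rate):
        sel = (rng.random(n) < rate) & ~taken
        taken[sel] = True
        return np.flatnonzero(sel)

    dup_rows = []
    for i in pick(rates.get("same_day_repeats", 0.0)):
        rec = out.loc[i].copy()
        rec[feat_cols] = (rec[feat_cols].to_numpy(dtype=float)
                          + rng.standard_normal(N_FEATURES) * 0.1 * pooled_sd)
        rec["oc"] = float(rec["oc"]) * rng.uniform(0.5, 0.9)
        rec["sc"] = float(rec["sc"]) * rng.uniform(0.5, 0.9)
        rec["artifact_tag"] = "same_day_repeat"
        dup_rows.append(rec)

    for i in pick(rates.get("low_coverage", 0.0)):
        out.loc[i, "oc"] = rng.uniform(10.0, 60.0)
        out.loc[i, "sc"] = rng.uniform(10.0, 80.0)
        out.loc[i, "artifact_tag"] = "low_coverage"

    sign_feats = list(POSITIVE_FEATURES) + list(NONNEGATIVE_FEATURES)
    for i in pick(rates.get("implausible_values", 0.0)):
        f = sign_feats[rng.integers(len(sign_feats))]
        out.loc[i, f] = (0.0 if f in POSITIVE_FEATURES else -1.0) \
            - abs(rng.standard_normal())
        out.loc[i, "artifact_tag"] = "implausible"

    for i in pick(rates.get("multivariate_outliers", 0.0)):
        # grossly abnormal scan (edema, mislabel): every index displaced by
        # at least 6 pooled SDs in a random direction
        sign = rng.choice([-1.0, 1.0], N_FEATURES)
        d = 6.0 + rng.exponential(2.0, N_FEATURES)
        out.loc[i, feat_cols] = (out.loc[i, feat_cols].to_numpy(dtype=float)
                                 + sign * d * pooled_sd)
        out.loc[i, "artifact_tag"] = "mv_outlier"

    if dup_rows:
        out = pd.concat([out, pd.DataFrame(dup_rows)], ignore_index=True)
    return out


def generate_paired_site_scans(n_patients: int,
                               jitter_sd: np.ndarray | float | None = None,
                               seed: int = 0) -> pd.DataFrame:
    """Bilateral scans of healthy patients acquired at two sites.

    For every patient and eye, two records are produced that are identical
    except for independent per-feature jitter, with a ``site`` label
    (``site_a`` / ``site_b``). The default jitter SD is 5% of the healthy
    per-feature SD, emulating pure acquisition noise between sessions.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    specs = default_specs()
    spec = specs["healthy"]
    if jitter_sd is None:
        jit = 0.05 * spec.sd
    else:
        jit = np.broadcast_to(np.asarray(jitter_sd, dtype=float),
                              (N_FEATURES,)).copy()
    jit = jit.astype(float).copy()
    jit[AGE_INDEX] = 0.0  # age identical between same-day sessions
    rng = np.random.default_rng([seed, 4])

    rows = []
    ages = _draw_ages("healthy", n_patients, specs, rng)
    for i in range(n_patients):
        pid = f"B{i:03d}"
        for eye in ("OD", "OS"):
            base = _draw_features("healthy", 1, specs, rng)[0]
            base[AGE_INDEX] = ages[i]
            for site in ("site_a", "site_b"):
                x = base + rng.standard_normal(N_FEATURES) * jit
                rec = {"patient_id": pid, "eye": eye, "visit_date": 0}
                rec.update(dict(zip(FEATURES, x)))
                rec.update(oc=rng.uniform(80.0, 100.0), sc=rng.uniform(90.0, 100.0),
                           true_group="healthy", site=site, artifact_tag="")
                rows.append(rec)
    return pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))
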