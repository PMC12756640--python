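"""Canonical feature set, per-group reference distributions, and schema constants.

The pipeline operates on 21 features per scan: 20 device-derived keratoconus
indices from a combined Placido / AS-OCT tomographer plus patient age. Feature
names follow the device's metric labels; the ``B``/``F`` suffixes denote the
posterior (back) and anterior (front) corneal surfaces.

Reference group distributions (mean, SD per feature for the healthy,
subclinical and keratoconus groups) drive the synthetic cohort generator and
are used by tests as ground truth for moment-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The 21 model features, in canonical column order. "Age" is in years; the
#: thickness metrics (ThkMin, StrThkMin, EpiThkMin) in micrometres; the Kmax
#: metrics are radii of curvature in millimetres (smaller radius = steeper);
#: TSI, PD-TSI, PTI and PEpiTI are percentages.
FEATURES: tuple[str, ...] = (
    "Age",
    "SI B", "SI F",
    "CSI B", "CSI F",
    "EI B", "EI F",
    "RMS B", "RMS F",
    "KMax B", "KMax F",
    "Δzmax B", "Δzmax F",
    "NotablePtsR",
    "TSI", "PD-TSI", "PTI", "PEpiTI",
    "ThkMin", "StrThkMin", "EpiThkMin",
)

N_FEATURES = len(FEATURES)

GROUPS: tuple[str, ...] = ("healthy", "subclinical", "keratoconus")

#: Short state codes used for Markov-chain summaries of longitudinal labels.
STATES: tuple[str, ...] = ("H", "S", "K")

GROUP_TO_STATE = {"healthy": "H", "subclinical": "S", "keratoconus": "K"}
STATE_TO_GROUP = {v: k for k, v in GROUP_TO_STATE.items()}

#: Classifier output labels (three-way) and the two training classes.
LABELS: tuple[str, ...] = ("Healthy", "SKC", "KC")
TRAIN_CLASSES: tuple[str, ...] = ("Healthy", "KC")

# Per-group (mean, sd) for every feature. These are the reference group
# statistics of the study population the generator emulates.
_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "healthy": {
        "Age": (40.18, 25.58),
        "SI B": (0.03, 0.12), "SI F": (0.30, 0.49),
        "CSI B": (0.18, 0.13), "CSI F": (0.51, 0.77),
        "EI B": (4.19, 4.45), "EI F": (3.60, 2.66),
        "RMS B": (5.86, 2.69), "RMS F": (3.63, 1.63),
        "KMax B": (6.11, 0.39), "KMax F": (7.52, 0.34),
        "Δzmax B": (9.61, 4.88), "Δzmax F": (5.91, 3.04),
        "NotablePtsR": (1.34, 0.53),
        "TSI": (5.94, 4.68), "PD-TSI": (0.18, 0.38),
        "PTI": (0.18, 2.48), "PEpiTI": (8.85, 5.92),
        "ThkMin": (519.73, 42.62), "StrThkMin": (465.79, 43.23),
        "EpiThkMin": (49.56, 3.91),
    },
    "subclinical": {
        "Age": (31.39, 11.07),
        "SI B": (0.23, 0.19), "SI F": (0.98, 0.66),
        "CSI B": (0.25, 0.26), "CSI F": (0.69, 0.97),
        "EI B": (15.93, 7.81), "EI F": (8.21, 3.78),
        "RMS B": (10.14, 5.47), "RMS F": (5.52, 1.83),
        "KMax B": (5.59, 0.57), "KMax F": (7.21, 0.40),
        "Δzmax B": (20.59, 10.46), "Δzmax F": (10.38, 3.86),
        "NotablePtsR": (0.82, 0.60),
        "TSI": (10.76, 5.04), "PD-TSI": (0.55, 0.33),
        "PTI": (1.53, 2.00), "PEpiTI": (11.82, 9.46),
        "ThkMin": (488.46, 34.90), "StrThkMin": (436.95, 35.12),
        "EpiThkMin": (48.30, 4.77),
    },
    "keratoconus": {
        "Age": (30.76, 7.99),
        "SI B": (1.34, 0.76), "SI F": (5.10, 3.07),
        "CSI B": (1.11, 0.99), "CSI F": (3.57, 3.50),
        "EI B": (75.45, 38.23), "EI F": (34.55, 18.32),
        "RMS B": (30.28, 31.80), "RMS F": (15.77, 7.62),
        "KMax B": (4.41, 0.68), "KMax F": (6.26, 0.62),
        "Δzmax B": (77.97, 57.25), "Δzmax F": (35.16, 18.05),
        "NotablePtsR": (0.37, 0.37),
        "TSI": (24.96, 11.48), "PD-TSI": (1.03, 0.49),
        "PTI": (5.87, 2.78), "PEpiTI": (34.42, 21.67),
        "ThkMin": (450.82, 41.46), "StrThkMin": (405.58, 40.41),
        "EpiThkMin": (41.24, 5.44),
    },
}

#: Features whose plausibility rule is strict positivity (thicknesses and
#: keratometry radii can never be <= 0 on a real cornea).
POSITIVE_FEATURES: tuple[str, ...] = (
    "ThkMin", "StrThkMin", "EpiThkMin", "KMax B", "KMax F",
)

#: Features whose plausibility rule is non-negativity (RMS errors and
#: distance metrics).
NONNEGATIVE_FEATURES: tuple[str, ...] = ("RMS B", "RMS F", "NotablePtsR")


@dataclass(frozen=True)
class GroupFeatureSpec:
    """Per-feature marginal moments for one generating group.

    Attributes
    ----------
    group:
        One of ``"healthy"``, ``"subclinical"``, ``"keratoconus"``.
    mean, sd:
        Arrays of length 21, ordered as :data:`FEATURES`. All SDs must be
        non-negative and all thickness means positive.
    """

    group: str
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if mean.shape != (N_FEATURES,) or sd.shape != (N_FEATURES,):
            raise ValueError(f"mean/sd must have length {N_FEATURES}")
        if np.any(sd < 0):
            raise ValueError("all sd must be >= 0")
        thick = [FEATURES.index(f) for f in ("ThkMin", "StrThkMin", "EpiThkMin")]
        if np.any(mean[thick] <= 0):
            raise ValueError("thickness means must be > 0")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)


def group_spec(group: str) -> GroupFeatureSpec:
    """Return the reference :class:`GroupFeatureSpec` for one group."""
    stats = _GROUP_STATS[group]
    mean = np.array([stats[f][0] for f in FEATURES])
    sd = np.array([stats[f][1] for f in FEATURES])
    return GroupFeatureSpec(group=group, mean=mean, sd=sd)


def default_specs() -> dict[str, GroupFeatureSpec]:
    """Reference specs for all three generating groups."""
    return {g: group_spec(g) for g in GROUPS}


def severity_directions() -> np.ndarray:
    """Sign of the healthy -> keratoconus mean shift per feature (+1/-1/0).

    Positive entries rise with disease severity (elevation, RMS, asymmetry
    indices); negative entries fall (thicknesses, curvature radii, age).
    """
    h = group_spec("healthy").mean
    k = group_spec("keratoconus").mean
    return np.sign(k - h)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic one-step transition matrix over the states H, S, K."""

    probs: np.ndarray
    states: tuple[str, ...] = STATES

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (3, 3):
            raise ValueError("transition matrix must be 3x3")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each row must sum to 1 within 1e-12")
        object.__setattr__(self, "probs", p)

    def row(self, state: str) -> np.ndarray:
        return self.probs[self.states.index(state)]


def default_transition_matrix() -> TransitionMatrix:
    """Default one-step transition matrix between classification states.

    The subclinical row (retention 0.562, progression to K 0.352,
    reclassification to healthy 0.086) is the reference summary of observed
    per-visit transitions; the healthy and keratoconus rows encode the strong
    (>90%) retention of those states with rare direct H->K jumps.
    """
    return TransitionMatrix(probs=np.array([
        [0.950, 0.040, 0.010],   # H
        [0.086, 0.562, 0.352],   # S
        [0.010, 0.040, 0.950],   # K
    ]))


#: Canonical scan-table schema: identifier and metadata columns surrounding
#: the 21 feature columns.
ID_COLUMNS: tuple[str, ...] = ("patient_id", "eye", "visit_date")
META_COLUMNS: tuple[str, ...] = ("oc", "sc", "true_group", "site", "artifact_tag")
SCHEMA_COLUMNS: tuple[str, ...] = ID_COLUMNS + FEATURES + META_COLUMNS

#: Default clinic attendance rates (visits per year) by group; SKC-track and
#: established-disease eyes attend more often than healthy screening patients.
DEFAULT_VISIT_RATES: dict[str, float] = {
    "healthy": 2.3, "subclinical": 3.2, "keratoconus": 3.2,
}
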