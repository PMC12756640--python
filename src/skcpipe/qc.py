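"""Scan quality control.

Reproduces a four-stage fidelity pipeline for tomography scan tables:

1. coverage-based inclusion (primary Placido/OCT coverage with a secondary
   section-coverage rescue rule),
2. same-day best-scan selection (highest composite quality),
3. physiological plausibility filtering (sign rules on thickness,
   keratometry, RMS and distance metrics),
4. multivariate outlier removal with an isolation forest.

A :class:`QCReport` reconciles exactly: every removed record is attributed
to the first stage that rejects it, and stage counts sum to the difference
between input and output sizes. The module also provides the within-subject
repeatability analysis used to justify coverage thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

from .features import (
    FEATURES,
    NONNEGATIVE_FEATURES,
    POSITIVE_FEATURES,
)

#: Normal ranges per feature (lower, upper) provided for interpretation;
#: :func:`widened_range_rules` turns them into optional loose bounds.
NORMAL_RANGES: dict[str, tuple[float, float]] = {
    "SI B": (-0.1, 0.1), "SI F": (-0.1, 0.1),
    "CSI B": (-0.1, 0.1), "CSI F": (-0.1, 0.1),
    "EI B": (0.0, 0.5), "EI F": (0.0, 0.5),
    "RMS B": (0.0, 0.02), "RMS F": (0.0, 0.02),
    "KMax B": (7.70, 7.90), "KMax F": (7.70, 7.90),
    "Δzmax B": (0.0, 20.0), "Δzmax F": (0.0, 20.0),
    "NotablePtsR": (0.6, 3.0),
    "TSI": (-10.0, 10.0), "PD-TSI": (-10.0, 10.0),
    "PTI": (45.0, 55.0), "PEpiTI": (5.0, 15.0),
    "ThkMin": (500.0, 600.0), "StrThkMin": (470.0, 550.0),
    "EpiThkMin": (45.0, 60.0),
}


def sign_rules() -> dict[str, tuple[float, float]]:
    """Mandatory plausibility bounds: (lower, upper) with +/- inf open ends.

    Thickness and keratometry metrics must be strictly positive; RMS and
    distance metrics non-negative. A value equal to a strict lower bound is
    a violation (encoded by an open interval at 0 for positives).
    """
    rules: dict[str, tuple[float, float]] = {}
    for f in POSITIVE_FEATURES:
        rules[f] = (np.nextafter(0.0, 1.0), np.inf)
    for f in NONNEGATIVE_FEATURES:
        rules[f] = (0.0, np.inf)
    return rules


def widened_range_rules(widen: float = 0.5) -> dict[str, tuple[float, float]]:
    """Optional loose bounds: normal ranges widened by ``widen`` x range width.

    These are deliberately *not* part of the defaults: diseased eyes fall far
    outside normal ranges, so range-based rules are only meaningful for
    cohorts known to be healthy. Sign rules always apply on top.
    """
    out = {}
    for f, (lo, hi) in NORMAL_RANGES.items():
        w = (hi - lo) * widen
        out[f] = (lo - w, hi + w)
    return out


@dataclass
class QCConfig:
    """Quality-control thresholds and settings.

    ``oc_threshold`` / ``sc_threshold`` are coverage percentages (strict
    inclusion: kept iff oc > oc_threshold, or sc > sc_threshold when oc is
    at or below its threshold). ``plausibility_rules`` maps feature name to
    a closed (lower, upper) interval of acceptable values.
    """

    oc_threshold: float = 65.0
    sc_threshold: float = 85.0
    plausibility_rules: dict = field(default_factory=sign_rules)
    outlier_contamination: float = 0.005
    n_estimators: int = 100
    seed: int = 0

    def __post_init__(self):
        for t in (self.oc_threshold, self.sc_threshold):
            if not 0.0 < t < 100.0:
                raise ValueError("coverage thresholds must lie in (0, 100)")
        for f, (lo, hi) in self.plausibility_rules.items():
            if not lo < hi:
                raise ValueError(f"plausibility rule for {f!r} has lower >= upper")


@dataclass
class QCReport:
    """Per-stage removal accounting for one QC run."""

    n_input: int = 0
    n_output: int = 0
    removed_counts: dict = field(default_factory=dict)
    removed_ids: dict = field(default_factory=dict)

    @property
    def retained_fraction(self) -> float:
        return self.n_output / self.n_input if self.n_input else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "retained_fraction": self.retained_fraction,
            "removed_counts": dict(self.removed_counts),
            "removed_ids": {k: list(map(int, v)) for k, v in self.removed_ids.items()},
        }


def filter_by_coverage(records: pd.DataFrame, config: QCConfig | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (kept, removed) by the hierarchical coverage rule.

    A scan is kept iff its primary coverage exceeds the OC threshold, or —
    when OC is at or below threshold — its section coverage exceeds the SC
    threshold. Both comparisons are strict. Records with missing coverage
    are removed with reason ``missing_coverage``.
    """
    config = config or QCConfig()
    oc = pd.to_numeric(records["oc"], errors="coerce")
    sc = pd.to_numeric(records["sc"], errors="coerce")
    missing = oc.isna() | sc.isna()
    keep = (~missing) & ((oc > config.oc_threshold) | (sc > config.sc_threshold))
    removed = records.loc[~keep].copy()
    removed["qc_reason"] = np.where(missing.loc[~keep], "missing_coverage",
                                    "low_coverage")
    return records.loc[keep].copy(), removed


def select_best_same_day(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep the highest composite-quality scan per (patient, eye, day).

    Composite quality is the arithmetic mean of the two coverage metrics;
    ties are broken by higher OC, then by stable input order.
    """
    df = records.copy()
    composite = (pd.to_numeric(df["oc"], errors="coerce")
                 + pd.to_numeric(df["sc"], errors="coerce")) / 2.0
    order = np.lexsort((
        np.arange(len(df)),                                  # stable input order
        -pd.to_numeric(df["oc"], errors="coerce").to_numpy(float),
        -composite.to_numpy(float),
    ))
    ranked = df.iloc[order]
    first = ~ranked.duplicated(subset=["patient_id", "eye", "visit_date"])
    kept_idx = ranked.index[first]
    kept = df.loc[df.index.isin(kept_idx)]
    removed = df.loc[~df.index.isin(kept_idx)].copy()
    removed["qc_reason"] = "same_day_duplicate"
    return kept.copy(), removed


def plausibility_filter(records: pd.DataFrame, config: QCConfig | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove records with any feature outside its plausibility interval."""
    config = config or QCConfig()
    bad = np.zeros(len(records), dtype=bool)
    for f, (lo, hi) in config.plausibility_rules.items():
        if f not in records.columns:
            continue
        v = pd.to_numeric(records[f], errors="coerce").to_numpy(float)
        bad |= ~((v >= lo) & (v <= hi))
    removed = records.loc[bad].copy()
    removed["qc_reason"] = "implausible_value"
    return records.loc[~bad].copy(), removed


def remove_multivariate_outliers(records: pd.DataFrame,
                                 config: QCConfig | None = None,
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag and remove extreme multivariate outliers with an isolation forest.

    Scores are computed on the standardized 21-feature matrix. With fewer
    than 50 records the stage is skipped with a warning (the forest is not
    meaningful on tiny samples). Deterministic given the configured seed.
    """
    config = config or QCConfig()
    if len(records) < 50:
        warnings.warn("fewer than 50 records: outlier stage skipped")
        return records.copy(), records.iloc[0:0].assign(qc_reason=[])
    if config.outlier_contamination == 0:
        return records.copy(), records.iloc[0:0].assign(qc_reason=[])
    x = records[list(FEATURES)].to_numpy(float)
    z = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    forest = IsolationForest(
        n_estimators=config.n_estimators,
        contamination=config.outlier_contamination,
        random_state=config.seed,
    )
    flags = forest.fit_predict(z) == -1
    removed = records.loc[flags].copy()
    removed["qc_reason"] = "multivariate_outlier"
    return records.loc[~flags].copy(), removed


def run_qc(records: pd.DataFrame, config: QCConfig | None = None,
           ) -> tuple[pd.DataFrame, QCReport]:
    """Run the full QC pipeline in fixed order and reconcile the report.

    Order: coverage -> same-day selection -> plausibility -> outliers. Each
    record is removed by at most one stage (the first that rejects it).
    """
    config = config or QCConfig()
    report = QCReport(n_input=len(records))
    df = records.reset_index(drop=True)
    df.index.name = "record_id"
    stages = (
        ("coverage", lambda d: filter_by_coverage(d, config)),
        ("same_day", lambda d: select_best_same_day(d)),
        ("plausibility", lambda d: plausibility_filter(d, config)),
        ("outliers", lambda d: remove_multivariate_outliers(d, config)),
    )
    for name, fn in stages:
        df, removed = fn(df)
        report.removed_counts[name] = len(removed)
        report.removed_ids[name] = removed.index.tolist()
    report.n_output = len(df)
    assert sum(report.removed_counts.values()) == report.n_input - report.n_output
    return df.reset_index(drop=True), report


def repeatability_analysis(records: pd.DataFrame, bin_width: float = 5.0,
                           ) -> pd.DataFrame:
    """Within-subject SD of each index per coverage bin, for OC and SC.

    Uses same-day repeat scans: for each (patient, eye, day) group with at
    least two scans, the per-feature sample variance across repeats is
    computed; the within-subject SD of a coverage bin is the square root of
    the mean of those variances over all repeat groups whose mean coverage
    falls in the bin. Returned long-form with columns
    (coverage_metric, bin_low, bin_high, n_groups, feature, within_subject_sd).
    """
    groups = records.groupby(["patient_id", "eye", "visit_date"])
    rows = []
    per_group = []
    for _, g in groups:
        if len(g) < 2:
            continue
        var = g[list(FEATURES)].astype(float).var(ddof=1)
        per_group.append((g["oc"].astype(float).mean(),
                          g["sc"].astype(float).mean(), var))
    if not per_group:
        warnings.warn("no same-day repeat scans: repeatability table is empty")
        return pd.DataFrame(columns=["coverage_metric", "bin_low", "bin_high",
                                     "n_groups", "feature", "within_subject_sd"])
    for metric, pos in (("oc", 0), ("sc", 1)):
        cov = np.array([t[pos] for t in per_group])
        lo_edge = np.floor(cov.min() / bin_width) * bin_width
        hi_edge = np.ceil(cov.max() / bin_width) * bin_width
        edges = np.arange(lo_edge, max(hi_edge, lo_edge + bin_width) + bin_width / 2,
                          bin_width)
        which = np.clip(np.digitize(cov, edges) - 1, 0, len(edges) - 2)
        for b in range(len(edges) - 1):
            sel = [per_group[i][2] for i in np.flatnonzero(which == b)]
            if not sel:
                continue
            mean_var = pd.concat(sel, axis=1).mean(axis=1)
            for f in FEATURES:
                rows.append({
                    "coverage_metric": metric,
                    "bin_low": edges[b], "bin_high": edges[b + 1],
                    "n_groups": len(sel), "feature": f,
                    "within_subject_sd": float(np.sqrt(mean_var[f])),
                })
    return pd.DataFrame(rows)
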