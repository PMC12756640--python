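"""ABCD-style staging, label/stage agreement, and group feature comparisons.

Computes Belin–Ambrósio-style ABCD stages (anterior curvature radius,
posterior curvature radius, thinnest pachymetry, best-corrected visual
acuity) from generic tabular inputs, cross-tabulates them against the
model's three-way labels, and runs the pairwise rank-sum comparison of all
21 features between adjacent severity groups. Stage boundaries ship as
configuration with published defaults, since grading tables are revised and
device conventions differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURES

ABCD_COLUMNS = ("a_steep_anterior_k", "b_steep_posterior_k",
                "c_min_pachymetry_um", "d_bcva_logmar")


@dataclass
class StageBoundaries:
    """Per-component stage cutoffs for stages 0-4.

    For A/B/C (radii in mm, pachymetry in um) a value *above* cutoff[i]
    belongs to stage <= i, so four descending cutoffs define five stages
    (smaller radius / thinner cornea = worse). For D (logMAR, higher =
    worse acuity) four ascending cutoffs: stage 0 iff value <= cutoff[0].

    Defaults follow the published ABCD grading: A (anterior radius of
    curvature) 7.25/7.05/6.35/6.15 mm; B (posterior) 5.90/5.70/5.15/4.95 mm;
    C (thinnest pachymetry) 490/450/400/300 um; D (BCVA) 0.0/0.3/0.7/1.3
    logMAR (20/20, 20/40, 20/100, 20/400).
    """

    a: tuple = (7.25, 7.05, 6.35, 6.15)
    b: tuple = (5.90, 5.70, 5.15, 4.95)
    c: tuple = (490.0, 450.0, 400.0, 300.0)
    d: tuple = (0.0, 0.3, 0.7, 1.3)

    def __post_init__(self):
        for name in "abc":
            cuts = getattr(self, name)
            if not all(x > y for x, y in zip(cuts, cuts[1:])):
                raise ValueError(f"component {name!r} cutoffs must be descending")
        if not all(x < y for x, y in zip(self.d, self.d[1:])):
            raise ValueError("component 'd' cutoffs must be ascending")


def _stage_descending(value: float, cuts: tuple) -> int:
    for i, c in enumerate(cuts):
        if value > c:
            return i
    return 4


def _stage_ascending(value: float, cuts: tuple) -> int:
    for i, c in enumerate(cuts):
        if value <= c:
            return i
    return 4


def abcd_stage(record: pd.Series | dict,
               boundaries: StageBoundaries | None = None) -> dict:
    """Per-component stages plus the composite (modal) stage for one eye.

    The composite is the most frequent stage among A-D; ties break toward
    the higher (worse) stage. Raises on non-positive pachymetry.
    """
    boundaries = boundaries or StageBoundaries()
    rec = dict(record)
    if rec["c_min_pachymetry_um"] <= 0:
        raise ValueError("pachymetry must be > 0")
    comp = {
        "A": _stage_descending(float(rec["a_steep_anterior_k"]), boundaries.a),
        "B": _stage_descending(float(rec["b_steep_posterior_k"]), boundaries.b),
        "C": _stage_descending(float(rec["c_min_pachymetry_um"]), boundaries.c),
        "D": _stage_ascending(float(rec["d_bcva_logmar"]), boundaries.d),
    }
    vals, counts = np.unique(list(comp.values()), return_counts=True)
    best = counts.max()
    comp["composite"] = int(vals[counts == best].max())  # tie -> worse stage
    return comp


def stage_table(inputs: pd.DataFrame,
                boundaries: StageBoundaries | None = None) -> pd.DataFrame:
    """Vectorized :func:`abcd_stage` over an ABCD input table."""
    rows = [abcd_stage(r, boundaries) for _, r in inputs.iterrows()]
    out = pd.DataFrame(rows, index=inputs.index)
    for c in ("patient_id", "eye"):
        if c in inputs.columns:
            out.insert(0, c, inputs[c])
    return out


def stage_agreement(labels: pd.DataFrame, stages: pd.DataFrame,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label x composite-stage contingency table with row fractions.

    Joined on (patient_id, eye); unmatched keys are dropped with a warning
    column in the returned fractions' attrs. Returns (counts, row_fractions)
    as 3x5 tables (label rows Healthy/SKC/KC, stage columns 0-4); label rows
    absent from the data are omitted.
    """
    key = ["patient_id", "eye"]
    merged = labels.merge(stages, on=key, how="inner")
    n_unmatched = len(labels) + len(stages) - 2 * len(merged)
    counts = pd.crosstab(merged["label"], merged["composite"])
    counts = counts.reindex(columns=range(5), fill_value=0)
    counts = counts.reindex([l for l in ("Healthy", "SKC", "KC")
                             if l in counts.index])
    fractions = counts.div(counts.sum(axis=1), axis=0)
    fractions.attrs["n_unmatched"] = int(n_unmatched)
    return counts, fractions


def group_feature_comparisons(records: pd.DataFrame, label_col: str = "label",
                              ) -> pd.DataFrame:
    """Adjacent-group rank-sum comparison of all 21 features.

    For each feature: mean and SD per group (Healthy, SKC, KC) and the
    two-sided Wilcoxon rank-sum p for Healthy-vs-SKC and SKC-vs-KC. A
    feature constant across a compared pair is reported with p = 1 and a
    flag.
    """
    pairs = (("Healthy", "SKC"), ("SKC", "KC"))
    groups = {g: records.loc[records[label_col] == g] for g in
              ("Healthy", "SKC", "KC")}
    for g, df in groups.items():
        if len(df) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 eyes")
    rows = []
    for f in FEATURES:
        row = {"feature": f}
        for g, df in groups.items():
            v = df[f].astype(float)
            row[f"mean_{g}"] = v.mean()
            row[f"sd_{g}"] = v.std(ddof=1)
        for a, b in pairs:
            va = groups[a][f].to_numpy(float)
            vb = groups[b][f].to_numpy(float)
            pooled = np.concatenate([va, vb])
            if np.all(pooled == pooled[0]):
                row[f"p_{a}_vs_{b}"] = 1.0
                row[f"constant_{a}_vs_{b}"] = True
            else:
                row[f"p_{a}_vs_{b}"] = stats.mannwhitneyu(
                    va, vb, alternative="two-sided").pvalue
                row[f"constant_{a}_vs_{b}"] = False
        rows.append(row)
    return pd.DataFrame(rows)


class CXLRiskProvider(Protocol):
    """Pluggable cross-linking risk scorer.

    Implementations take per-eye age (years), Kmax (mm radius), front K1
    (mm radius) and minimum pachymetry (um) and return the probability that
    the eye will require cross-linking within 1-4 years. The production
    scorer is an external service and out of scope; tests use the
    deterministic mock below.
    """

    def predict_risk(self, age: float, kmax: float, front_k1: float,
                     min_pachymetry: float) -> dict[int, float]:
        ...


@dataclass
class MockCXLRisk:
    """Deterministic logistic stand-in for an external CXL risk scorer.

    Synthetic: scores rise with steeper corneas (smaller Kmax radius),
    thinner pachymetry and younger age, saturating by year 4. Useful only
    for wiring and monotonicity tests, not clinical inference.
    """

    steepness: float = 2.0

    def predict_risk(self, age: float, kmax: float, front_k1: float,
                     min_pachymetry: float) -> dict[int, float]:
        z = (self.steepness * (7.0 - kmax) + 0.01 * (500.0 - min_pachymetry)
             + 0.02 * (40.0 - age) + 0.5 * (7.8 - front_k1))
        base = 1.0 / (1.0 + np.exp(-z))
        return {yr: float(1.0 - (1.0 - base) ** yr) for yr in (1, 2, 3, 4)}
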