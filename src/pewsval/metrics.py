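"""Discrimination and operating-point metrics for score validation.

The primary metric is the (optionally population-weighted) AUC — the
probability that a randomly chosen death outranks a randomly chosen
survivor, with ties counted half.  With per-child weights w the AUC is the
weighted pairwise concordance

    AUC = sum_{i in cases, j in controls} w_i w_j [1(s_i > s_j) + 0.5 1(s_i = s_j)]
          / (W_cases * W_controls)

computed here by an O(n log n) rank formulation; unit weights recover the
familiar Mann-Whitney estimator.  Secondary metrics at a cutoff (score >=
cutoff predicts death) come from weighted confusion counts: sensitivity,
specificity, PPV, NPV and likelihood ratios.  Scores without a published
mortality-risk cutoff get a Youden-optimal one (argmax of
J = sensitivity + specificity - 1 over all integer cutoffs, lowest cutoff
winning ties).  AUCs are labelled with the conventional interpretation
bands: >= 0.8 excellent, 0.7-0.8 acceptable/good, 0.5-0.7 poor, < 0.5 not
useful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from pewsval.records import SYNDROMES, age_band_column
from pewsval.registry import ScoreDefinition, score_frame
from pewsval.simulate import horizon_outcome_column

__all__ = [
    "ConfusionCounts", "MetricSet", "AUCResult", "CutoffResult",
    "confusion_at_cutoff", "metrics_from_counts", "weighted_auc",
    "brute_force_auc", "auc_ci", "classify_auc", "youden_optimal_cutoff",
    "validate_score",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ConfusionCounts:
    """Weighted confusion counts at a cutoff (unit weights -> integers)."""
    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total_cases(self) -> float:
        return self.tp + self.fn

    @property
    def total_controls(self) -> float:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricSet:
    """Operating-point metrics; sens/spec as proportions, PPV/NPV as %."""
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float

    @property
    def ppv_defined(self) -> bool:
        return not math.isnan(self.ppv)

    @property
    def npv_defined(self) -> bool:
        return not math.isnan(self.npv)


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    band: str
    weighted: bool
    n_cases: float
    n_controls: float


@dataclass(frozen=True)
class CutoffResult:
    cutoff: int
    youden_j: float
    table: pd.DataFrame  # columns: cutoff, sensitivity, specificity, youden_j


# ---------------------------------------------------------------------------
# input plumbing


def _as_arrays(scores, outcomes, weights):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    if not (len(s) == len(y) == len(w)):
        raise ValueError("scores, outcomes and weights must have equal length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if np.isnan(s).any():
        raise ValueError("scores contain missing values")
    if not y.any() or y.all():
        raise ValueError("need at least one case and one control")
    return s, y, w


# ---------------------------------------------------------------------------
# operations


def confusion_at_cutoff(scores, outcomes, weights=None,
                        cutoff: float = 1) -> ConfusionCounts:
    """Weighted confusion counts with 'score >= cutoff' as high risk."""
    s, y, w = _as_arrays(scores, outcomes, weights)
    pos = s >= cutoff
    return ConfusionCounts(
        tp=float(w[pos & y].sum()),
        fp=float(w[pos & ~y].sum()),
        tn=float(w[~pos & ~y].sum()),
        fn=float(w[~pos & y].sum()),
    )


def metrics_from_counts(counts: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, PPV/NPV (%) and likelihood ratios.

    LRs are computed from the unrounded sensitivity/specificity; PPV or
    NPV is NaN (flagged undefined) when its denominator is zero.
    """
    if counts.total_cases <= 0 or counts.total_controls <= 0:
        raise ValueError("need both cases and controls to compute metrics")
    sens = counts.tp / counts.total_cases
    spec = counts.tn / counts.total_controls
    n_pos = counts.tp + counts.fp
    n_neg = counts.tn + counts.fn
    ppv = 100.0 * counts.tp / n_pos if n_pos > 0 else math.nan
    npv = 100.0 * counts.tn / n_neg if n_neg > 0 else math.nan
    lr_pos = sens / (1.0 - spec) if spec < 1.0 else math.inf
    lr_neg = (1.0 - sens) / spec if spec > 0.0 else math.inf
    return MetricSet(sens, spec, ppv, npv, lr_pos, lr_neg)


def weighted_auc(scores, outcomes, weights=None) -> float:
    """Weighted pairwise-concordance AUC, O(n log n).

    Sorts once, then for each distinct score level accumulates the case
    weight at that level against the cumulative control weight strictly
    below (concordant) plus half the control weight at the same level
    (ties).
    """
    s, y, w = _as_arrays(scores, outcomes, weights)
    order = np.argsort(s, kind="mergesort")
    s, y, w = s[order], y[order], w[order]
    case_w = np.where(y, w, 0.0)
    ctrl_w = np.where(y, 0.0, w)
    # group by distinct score value
    boundaries = np.flatnonzero(np.diff(s)) + 1
    groups = np.split(np.arange(len(s)), boundaries)
    concordant = 0.0
    ctrl_below = 0.0
    for g in groups:
        cw = case_w[g].sum()
        uw = ctrl_w[g].sum()
        concordant += cw * (ctrl_below + 0.5 * uw)
        ctrl_below += uw
    denom = case_w.sum() * ctrl_w.sum()
    return float(concordant / denom)


def brute_force_auc(scores, outcomes, weights=None) -> float:
    """O(n^2) pairwise concordance; the definitional oracle for testing."""
    s, y, w = _as_arrays(scores, outcomes, weights)
    cases, ctrls = np.flatnonzero(y), np.flatnonzero(~y)
    num = 0.0
    for i in cases:
        for j in ctrls:
            if s[i] > s[j]:
                num += w[i] * w[j]
            elif s[i] == s[j]:
                num += 0.5 * w[i] * w[j]
    return float(num / (w[cases].sum() * w[ctrls].sum()))


def auc_ci(scores, outcomes, weights=None, n_boot: int = 2000,
           seed: int = 0, alpha: float = 0.05,
           max_retries: int = 1000) -> tuple[float, float]:
    """Percentile-bootstrap CI for the (weighted) AUC.

    Children are resampled with replacement, weights carried along;
    replicates that lose one outcome class are redrawn (bounded retries).
    Deterministic given ``seed``.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    s, y, w = _as_arrays(scores, outcomes, weights)
    rng = np.random.default_rng(seed)
    n = len(s)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_retries):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.any() and not yb.all():
                break
        else:
            raise RuntimeError("could not draw a bootstrap replicate with "
                               "both outcome classes")
        stats[b] = weighted_auc(s[idx], yb, w[idx])
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def classify_auc(auc: float) -> str:
    """Conventional AUC interpretation band."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC outside [0, 1]")
    if auc >= 0.8:
        return "excellent"
    if auc >= 0.7:
        return "acceptable_good"
    if auc >= 0.5:
        return "poor"
    return "not_useful"


def youden_optimal_cutoff(scores, outcomes, weights=None,
                          range_min: Optional[int] = None,
                          range_max: Optional[int] = None) -> CutoffResult:
    """Youden-optimal integer cutoff by exhaustive scan.

    Evaluates J = sensitivity + specificity - 1 at every candidate cutoff
    in [range_min, range_max + 1]; the lowest cutoff attaining the maximum
    J wins (favouring sensitivity).
    """
    s, y, w = _as_arrays(scores, outcomes, weights)
    if range_min is None:
        range_min = int(np.min(s))
    if range_max is None:
        range_max = int(np.max(s))
    rows = []
    for c in range(range_min, range_max + 2):
        m = metrics_from_counts(confusion_at_cutoff(s, y, w, cutoff=c))
        rows.append((c, m.sensitivity, m.specificity,
                     m.sensitivity + m.specificity - 1.0))
    table = pd.DataFrame(rows, columns=["cutoff", "sensitivity",
                                        "specificity", "youden_j"])
    best = int(table["youden_j"].idxmax())  # idxmax -> first (lowest) maximum
    return CutoffResult(cutoff=int(table.loc[best, "cutoff"]),
                        youden_j=float(table.loc[best, "youden_j"]),
                        table=table)


# ---------------------------------------------------------------------------
# one-score validation rows


def _not_evaluable(definition, reason, weighted, subgroup, horizon):
    return {
        "score": definition.name, "range": f"{definition.range_min}-{definition.range_max}",
        "subgroup": subgroup or "all", "horizon": horizon or "inpatient",
        "weighted": weighted, "evaluable": False, "reason": reason,
    }


def validate_score(definition: ScoreDefinition, cohort: pd.DataFrame,
                   weighted: bool = True,
                   subgroup: Optional[Mapping[str, object]] = None,
                   horizon: Optional[int] = None,
                   restrict_to_applicable: bool = False,
                   n_boot: int = 2000, seed: int = 0) -> dict:
    """One validation-report row for a score on a (sub)cohort.

    ``subgroup`` filters by ``stratum``, ``site``, ``age_band`` (e.g.
    '6-12m') or ``syndrome`` (flag column name).  Full-cohort analyses use
    population weights; pass ``weighted=False`` for within-stratum /
    site / age analyses, which are unweighted by design.  ``horizon``
    switches the outcome from inpatient death to death by that day.
    Returns a plain dict (a 'not evaluable' row, never an exception, when
    the filter empties an outcome class).
    """
    df = cohort
    label_parts = []
    if subgroup:
        for key, value in subgroup.items():
            if key == "age_band":
                df = df[age_band_column(df) == value]
            elif key == "syndrome":
                if value not in SYNDROMES:
                    raise ValueError(f"unknown syndrome flag {value!r}")
                df = df[df[value].fillna(False).astype(bool)]
            elif key in ("stratum", "site"):
                df = df[df[key] == value]
            else:
                raise ValueError(f"unknown subgroup key {key!r}")
            label_parts.append(f"{key}={value}")
    label = ";".join(label_parts) if label_parts else None

    sf = score_frame(definition, df)
    keep = sf["total_points"].notna()
    if restrict_to_applicable:
        keep &= sf["applicable"]
    df, sf = df[keep], sf[keep]
    if len(df) == 0:
        return _not_evaluable(definition, "no scoreable children",
                              weighted, label, horizon)

    scores = sf["total_points"].to_numpy()
    if horizon is None:
        outcomes = df["died_inpatient"].fillna(False).to_numpy(dtype=bool)
    else:
        outcomes = horizon_outcome_column(df, horizon)
    weights = df["pop_weight"].to_numpy(dtype=float) if weighted else None
    if not outcomes.any() or outcomes.all():
        return _not_evaluable(definition, "a filter left a single outcome class",
                              weighted, label, horizon)

    auc = weighted_auc(scores, outcomes, weights)
    ci_low, ci_high = auc_ci(scores, outcomes, weights, n_boot=n_boot, seed=seed)
    w = np.ones(len(df)) if weights is None else weights
    auc_res = AUCResult(auc=auc, ci_low=ci_low, ci_high=ci_high,
                        band=classify_auc(auc), weighted=weighted,
                        n_cases=float(w[outcomes].sum()),
                        n_controls=float(w[~outcomes].sum()))

    if definition.predefined_cutoff is not None:
        cutoff = definition.predefined_cutoff
        cutoff_source = "predefined"
    else:
        cutoff = youden_optimal_cutoff(
            scores, outcomes, weights,
            definition.range_min, definition.range_max).cutoff
        cutoff_source = "youden"
    counts = confusion_at_cutoff(scores, outcomes, weights, cutoff=cutoff)
    metrics = metrics_from_counts(counts)

    return {
        "score": definition.name,
        "range": f"{definition.range_min}-{definition.range_max}",
        "subgroup": label or "all",
        "horizon": horizon or "inpatient",
        "weighted": weighted,
        "evaluable": True,
        "reason": "",
        "cutoff": cutoff,
        "cutoff_source": cutoff_source,
        "auc": auc_res.auc,
        "ci_low": auc_res.ci_low,
        "ci_high": auc_res.ci_high,
        "band": auc_res.band,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
        "ppv_pct": metrics.ppv, "npv_pct": metrics.npv,
        "lr_pos": metrics.lr_pos, "lr_neg": metrics.lr_neg,
        "deaths": counts.total_cases,
        "n_children": int(len(df)),
    }
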