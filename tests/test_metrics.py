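"""Validation engine: confusion metrics, weighted AUC, Youden, bands, CIs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pewsval.metrics import (
    ConfusionCounts, auc_ci, brute_force_auc, classify_auc,
    confusion_at_cutoff, metrics_from_counts, validate_score, weighted_auc,
    youden_optimal_cutoff,
)
from pewsval.registry import score_frame
from pewsval.simulate import CohortConfig, generate_cohort


# ---------------------------------------------------------------------------
# confusion counts and operating-point metrics


def test_confusion_perfect_separation():
    c = confusion_at_cutoff([0, 1, 2, 3], [0, 0, 1, 1], cutoff=2)
    assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)


def test_confusion_counts_are_weight_sums():
    c = confusion_at_cutoff([0, 1, 2, 3], [0, 0, 1, 1], [2, 1, 1, 1], cutoff=2)
    assert c.tn == 3


def test_confusion_cutoff_zero_marks_everyone_positive():
    c = confusion_at_cutoff([0, 1, 2, 3], [0, 0, 1, 1], cutoff=0)
    assert c.tn == 0 and c.fn == 0


def test_confusion_input_errors():
    with pytest.raises(ValueError):
        confusion_at_cutoff([1, 2], [0, 1, 1], cutoff=1)
    with pytest.raises(ValueError):
        confusion_at_cutoff([1, 2], [0, 1], [1, -1], cutoff=1)


def test_metrics_round_trip_small_example():
    m = metrics_from_counts(ConfusionCounts(tp=60, fp=157, tn=5604, fn=174))
    assert m.sensitivity == pytest.approx(60 / 234)
    assert m.ppv == pytest.approx(27.65, abs=0.005)
    assert m.lr_pos == pytest.approx(9.41, abs=0.005)


def test_metrics_undefined_ppv_flagged():
    m = metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=5, fn=3))
    assert m.sensitivity == 0.0
    assert math.isnan(m.ppv) and not m.ppv_defined
    assert m.npv_defined


def test_metrics_require_both_classes():
    with pytest.raises(ValueError):
        metrics_from_counts(ConfusionCounts(tp=1, fp=0, tn=0, fn=1))


# ---------------------------------------------------------------------------
# weighted AUC


def test_auc_perfect_ranking():
    assert weighted_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0


def test_auc_all_ties_is_half():
    assert weighted_auc([2, 2, 2, 2], [0, 0, 1, 1]) == 0.5


def test_auc_handles_partial_ties():
    # four case-control pairs, one tied at half credit
    assert weighted_auc([1, 2, 2, 3], [0, 0, 1, 1]) == pytest.approx(0.875)


def test_auc_degenerate_outcomes_rejected():
    with pytest.raises(ValueError):
        weighted_auc([1, 2], [1, 1])


def test_auc_matches_brute_force_on_500_random_instances():
    """Rank formulation == definitional pairwise concordance to 1e-12."""
    rng = np.random.default_rng(2024)
    for _ in range(500):
        n = rng.integers(4, 51)
        s = rng.integers(0, 6, n).astype(float)   # heavy ties
        y = rng.integers(0, 2, n).astype(bool)
        if y.all() or not y.any():
            continue
        w = rng.uniform(0.1, 3.0, n)
        assert abs(weighted_auc(s, y, w) - brute_force_auc(s, y, w)) < 1e-12


def test_auc_matches_sklearn_with_sample_weights(cohort, registry):
    """Independent cross-check against sklearn's weighted ROC AUC."""
    from sklearn.metrics import roc_auc_score
    s = score_frame(registry["PEDIA_early"], cohort)["total_points"].to_numpy()
    y = cohort["died_inpatient"].to_numpy(dtype=bool)
    w = cohort["pop_weight"].to_numpy()
    assert weighted_auc(s, y, w) == pytest.approx(
        roc_auc_score(y, s, sample_weight=w), abs=1e-10)
    assert weighted_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-10)


@given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 50.0))
@settings(max_examples=60, deadline=None)
def test_auc_invariant_to_weight_scale(seed, scale):
    rng = np.random.default_rng(seed)
    n = 30
    s = rng.integers(0, 8, n).astype(float)
    y = np.r_[np.ones(5, bool), rng.integers(0, 2, n - 10).astype(bool),
              np.zeros(5, bool)]
    w = rng.uniform(0.2, 2.0, n)
    base = weighted_auc(s, y, w)
    assert weighted_auc(s, y, w * scale) == pytest.approx(base, abs=1e-12)
    m1 = metrics_from_counts(confusion_at_cutoff(s, y, w, cutoff=4))
    m2 = metrics_from_counts(confusion_at_cutoff(s, y, w * scale, cutoff=4))
    for attr in ("sensitivity", "specificity", "ppv", "npv", "lr_pos", "lr_neg"):
        assert getattr(m2, attr) == pytest.approx(getattr(m1, attr), nan_ok=True)


def test_auc_complement_symmetry_without_ties():
    rng = np.random.default_rng(5)
    s = rng.permutation(40).astype(float)
    y = rng.integers(0, 2, 40).astype(bool)
    y[:2] = [True, False]
    w = rng.uniform(0.5, 2.0, 40)
    assert weighted_auc(s, y, w) + weighted_auc(-s, y, w) == pytest.approx(1.0)


def test_auc_converges_to_closed_form_under_probit_model():
    """Death = 1{a + b*s + e > 0}: empirical AUC matches the value implied
    by the generator (numerical integral of the probabilistic index)."""
    from scipy.stats import norm

    a, b = -2.0, 0.9
    grid = np.linspace(-9, 9, 6001)
    phi = norm.pdf(grid)
    link = norm.cdf(a + b * grid)
    p = np.trapezoid(phi * link, grid)
    g0 = phi * (1 - link)
    f0_cdf = np.concatenate(([0.0], np.cumsum((g0[1:] + g0[:-1]) / 2
                                              * np.diff(grid))))
    expected = np.trapezoid(phi * link * f0_cdf, grid) / (p * (1 - p))

    rng = np.random.default_rng(77)
    n = 100_000
    s = rng.standard_normal(n)
    y = rng.standard_normal(n) < a + b * s
    assert weighted_auc(s, y) == pytest.approx(expected, abs=0.01)


# ---------------------------------------------------------------------------
# AUC bands


@pytest.mark.parametrize("auc,band", [
    (1.0, "excellent"), (0.80, "excellent"), (0.79, "acceptable_good"),
    (0.70, "acceptable_good"), (0.69, "poor"), (0.50, "poor"),
    (0.49, "not_useful"), (0.0, "not_useful"),
])
def test_classify_auc_bands(auc, band):
    assert classify_auc(auc) == band


def test_classify_auc_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_auc(1.2)


# ---------------------------------------------------------------------------
# Youden cutoffs


def test_youden_perfect_separation():
    res = youden_optimal_cutoff([0, 1, 2, 3], [0, 0, 1, 1])
    assert res.cutoff == 2 and res.youden_j == pytest.approx(1.0)


def test_youden_worked_example():
    res = youden_optimal_cutoff([0, 1, 2, 3, 4, 5], [0, 0, 0, 1, 0, 1])
    assert res.cutoff == 3
    assert res.youden_j == pytest.approx(0.75)
    assert len(res.table) == 7  # cutoffs 0..6


def test_youden_null_case_flat_j():
    rng = np.random.default_rng(0)
    s = rng.integers(0, 5, 20_000).astype(float)
    y = rng.integers(0, 2, 20_000).astype(bool)  # independent of score
    res = youden_optimal_cutoff(s, y)
    assert res.table["youden_j"].abs().max() < 0.03


def test_youden_tie_breaks_to_lowest_cutoff():
    res = youden_optimal_cutoff([1, 1, 1, 1], [0, 1, 0, 1],
                                range_min=0, range_max=3)
    assert res.table["youden_j"].abs().max() == pytest.approx(0.0)
    assert res.cutoff == 0


def test_youden_equals_exhaustive_scan_on_random_instances():
    """Argmax matches an independently coded exhaustive scan."""
    rng = np.random.default_rng(99)
    for _ in range(200):
        n = rng.integers(6, 60)
        s = rng.integers(0, 10, n).astype(float)
        y = rng.integers(0, 2, n).astype(bool)
        if y.all() or not y.any():
            continue
        w = rng.uniform(0.2, 2.0, n)
        best_c, best_j = None, -2.0
        for c in range(0, 11):
            pos = s >= c
            sens = w[pos & y].sum() / w[y].sum()
            spec = w[~pos & ~y].sum() / w[~y].sum()
            j = sens + spec - 1
            if j > best_j + 1e-15:
                best_c, best_j = c, j
        res = youden_optimal_cutoff(s, y, w, range_min=0, range_max=9)
        assert res.cutoff == best_c
        assert res.youden_j == pytest.approx(best_j, abs=1e-12)


# ---------------------------------------------------------------------------
# bootstrap CI


def test_auc_ci_deterministic_and_bounded():
    rng = np.random.default_rng(1)
    s = rng.integers(0, 9, 300).astype(float)
    y = (rng.random(300) < 0.1 + 0.08 * s).astype(bool)
    y[:3] = [True, False, True]
    a = auc_ci(s, y, n_boot=300, seed=4)
    b = auc_ci(s, y, n_boot=300, seed=4)
    assert a == b
    assert 0.0 <= a[0] <= a[1] <= 1.0


def test_auc_ci_perfect_separation_reaches_one():
    s = np.r_[np.zeros(30), np.ones(30)]
    y = np.r_[np.zeros(30, bool), np.ones(30, bool)]
    lo, hi = auc_ci(s, y, n_boot=200, seed=0)
    assert hi == 1.0


def test_auc_ci_requires_enough_replicates():
    with pytest.raises(ValueError):
        auc_ci([0, 1], [0, 1], n_boot=10)


def test_bootstrap_ci_covers_large_sample_auc():
    """Percentile CIs from n=1500 cohorts contain the generator's
    large-sample weighted AUC in >=90% of 50 seeded repetitions."""
    from pewsval.registry import default_registry
    reg = default_registry()
    d = reg["PEDIA_early"]
    big = generate_cohort(CohortConfig(n_children=100_000, seed=123))
    s_big = score_frame(d, big)["total_points"].to_numpy()
    ref = weighted_auc(s_big, big["died_inpatient"].astype(bool),
                       big["pop_weight"])
    hits = 0
    for i in range(50):
        df = generate_cohort(CohortConfig(n_children=1500, seed=1000 + i))
        s = score_frame(d, df)["total_points"].to_numpy()
        y = df["died_inpatient"].to_numpy(dtype=bool)
        lo, hi = auc_ci(s, y, df["pop_weight"].to_numpy(),
                        n_boot=500, seed=i)
        hits += lo <= ref <= hi
    assert hits >= 45


# ---------------------------------------------------------------------------
# validate_score rows


def test_validate_score_weighting_changes_the_estimate(cohort, registry):
    """Full-cohort rows use population weights; they must differ from the
    unweighted analysis on a deliberately over-sampled cohort."""
    d = registry["PEDIA_early"]
    weighted = validate_score(d, cohort, weighted=True, n_boot=300, seed=2)
    unweighted = validate_score(d, cohort, weighted=False, n_boot=300, seed=2)
    assert weighted["deaths"] != pytest.approx(unweighted["deaths"])
    assert weighted["auc"] != pytest.approx(unweighted["auc"], abs=1e-6)


def test_validate_score_row_shape_and_band(cohort, registry):
    row = validate_score(registry["PEDIA_early"], cohort, n_boot=300, seed=2)
    assert row["evaluable"]
    assert row["cutoff_source"] == "youden"
    assert row["ci_low"] <= row["auc"] <= row["ci_high"]
    assert row["band"] == classify_auc(row["auc"])
    assert row["deaths"] == pytest.approx(row["tp"] + row["fn"])


def test_validate_score_malaria_restriction(cohort, registry):
    row = validate_score(registry["LODS"], cohort,
                         subgroup={"syndrome": "malaria"},
                         n_boot=300, seed=2)
    assert row["subgroup"] == "syndrome=malaria"
    n_malaria = int(cohort["malaria"].fillna(False).astype(bool).sum())
    assert row["n_children"] == n_malaria


def test_validate_score_unevaluable_subgroup_is_a_row_not_a_crash(registry,
                                                                  cohort):
    survivors = cohort[~cohort["died_inpatient"].astype(bool)]
    row = validate_score(registry["LODS"], survivors, n_boot=300)
    assert row["evaluable"] is False
    assert "outcome class" in row["reason"]


def test_horizon_discrimination_declines_with_longer_horizon(registry):
    """Early deaths are the sickest children, so day-2 discrimination is
    at least as good as day-30 on the default generator."""
    d = registry["PEDIA_early"]
    df = generate_cohort(CohortConfig(n_children=6000, seed=17))
    s = score_frame(d, df)["total_points"].to_numpy()
    w = df["pop_weight"].to_numpy()
    from pewsval.simulate import horizon_outcome_column
    auc2 = weighted_auc(s, horizon_outcome_column(df, 2), w)
    auc30 = weighted_auc(s, horizon_outcome_column(df, 30), w)
    assert auc2 >= auc30
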