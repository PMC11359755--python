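import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from wetspec.evaluation import (
    classify_rpd,
    classify_success,
    compute_metrics,
    grid_search_lvs,
    group_split,
    kfold_cv,
    se_from_rmse_bias,
    secv_metrics,
)


class TestGroupSplit:
    def test_groups_are_atomic(self):
        ids = ["a", "b", "c"]
        groups = ["g1", "g1", "g2"]
        for seed in range(20):
            plan = group_split(ids, groups, 0.33, seed)
            val = set(plan.validation_ids)
            assert val in ({"c"}, {"a", "b"})

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(200)]
        groups = rng.integers(0, 30, 200).astype(str)
        p1 = group_split(ids, groups, 0.1, 7)
        p2 = group_split(ids, groups, 0.1, 7)
        assert p1.validation_ids == p2.validation_ids
        assert p1.calibration_ids == p2.calibration_ids

    def test_validation_share_reaches_target(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(600)]
        groups = rng.integers(0, 111, 600).astype(str)
        sizes = np.bincount(rng.integers(0, 111, 0))  # noqa: silence unused
        plan = group_split(ids, groups, 0.10, 3)
        n_val = len(plan.validation_ids)
        max_group = max(np.unique(groups, return_counts=True)[1])
        assert 60 <= n_val <= 60 + max_group
        assert len(plan.calibration_ids) + n_val == 600

    def test_no_group_straddles_the_split(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(300)]
        groups = rng.integers(0, 40, 300).astype(str)
        lut = dict(zip(ids, groups))
        for seed in range(20):
            plan = group_split(ids, groups, 0.15, seed)
            cal = {lut[i] for i in plan.calibration_ids}
            val = {lut[i] for i in plan.validation_ids}
            assert not cal & val

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="groups"):
            group_split(["a", "b"], ["g", "g"], 0.5, 0)


class TestKFold:
    def test_partition_properties(self):
        rng = np.random.default_rng(3)
        ids = [f"s{i}" for i in range(540)]
        groups = rng.integers(0, 100, 540).astype(str)
        folds = kfold_cv(ids, groups, 5, 0)
        held = [set(h) for _, h in folds]
        assert set().union(*held) == set(ids)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not held[i] & held[j]
        for tr, he in folds:
            assert set(tr) | set(he) == set(ids)
            assert not set(tr) & set(he)
        sizes = sorted(len(h) for h in held)
        assert sizes[-1] - sizes[0] <= max(np.unique(groups, return_counts=True)[1])

    def test_group_aware_no_straddling(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(120)]
        groups = rng.integers(0, 15, 120).astype(str)
        lut = dict(zip(ids, groups))
        for _, he in kfold_cv(ids, groups, 5, 1):
            hg = {lut[i] for i in he}
            for g in hg:
                members = [i for i in ids if lut[i] == g]
                assert set(members) <= set(he)

    def test_singleton_groups_reduce_to_plain_kfold(self):
        ids = [f"s{i}" for i in range(100)]
        folds = kfold_cv(ids, ids, 5, 2)
        sizes = [len(h) for _, h in folds]
        assert sizes == [20] * 5

    def test_fewer_groups_than_folds_rejected(self):
        with pytest.raises(ValueError, match="group"):
            kfold_cv(["a", "b", "c"], ["g1", "g1", "g2"], 3, 0)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rep = compute_metrics(y, y)
        assert rep.bias == 0 and rep.rmse == 0
        assert rep.r2 == pytest.approx(1.0)
        assert rep.slope == pytest.approx(1.0)
        assert rep.intercept == pytest.approx(0.0, abs=1e-12)
        assert math.isinf(rep.rpd)

    @pytest.mark.parametrize("seed", range(5))
    def test_se_identity(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(10, 3, size=50)
        yh = y + rng.normal(0.5, 1.0, size=50)
        rep = compute_metrics(y, yh)
        implied = se_from_rmse_bias(rep.rmse, rep.bias, rep.n)
        assert rep.se == pytest.approx(implied, rel=1e-10)
        assert rep.rmse >= abs(rep.bias)

    def test_slope_intercept_convention_predicted_on_reference(self):
        y = np.linspace(0, 10, 20)
        yh = 2.0 * y + 1.0
        rep = compute_metrics(y, yh)
        assert rep.slope == pytest.approx(2.0)
        assert rep.intercept == pytest.approx(1.0)

    def test_rpd_uses_bias_corrected_se_and_reference_sd(self):
        rng = np.random.default_rng(9)
        y = rng.normal(50, 5, size=200)
        yh = y + rng.normal(1.0, 2.0, size=200)
        rep = compute_metrics(y, yh)
        assert rep.rpd == pytest.approx(np.std(y, ddof=1) / rep.se, rel=1e-12)
        rep2 = compute_metrics(y, yh, sd_reference=10.0)
        assert rep2.rpd == pytest.approx(10.0 / rep.se, rel=1e-12)

    def test_constant_prediction_null_model_anchor(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=100)
        rep = compute_metrics(y, np.full(100, y.mean()))
        assert rep.r2 <= 1e-12
        assert rep.rpd == pytest.approx(1.0, rel=1e-10)

    def test_zero_reference_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            compute_metrics([1.0, 1.0, 1.0], [1.0, 1.1, 0.9])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0, 2.0], [1.0])


class TestClassification:
    @pytest.mark.parametrize(
        "r2, label",
        [
            (0.79, "Not Useful"),
            (0.80, "Moderately Successful"),
            (0.89, "Moderately Successful"),
            (0.90, "Successful"),
            (0.9499, "Successful"),
            (0.95, "Excellent"),
        ],
    )
    def test_success_tiers(self, r2, label):
        assert classify_success(r2) == label

    @pytest.mark.parametrize(
        "rpd, label",
        [
            (1.99, "Very poor"),
            (2.0, "Poor"),
            (2.5, "Fair"),
            (3.0, "Good"),
            (3.5, "Very good"),
            (4.0, "Excellent"),
        ],
    )
    def test_rpd_tiers(self, rpd, label):
        assert classify_rpd(rpd) == label

    def test_monotone_step_functions(self):
        r2_grid = np.linspace(0, 1, 101)
        order = ["Not Useful", "Moderately Successful", "Successful", "Excellent"]
        ranks = [order.index(classify_success(r)) for r in r2_grid]
        assert np.all(np.diff(ranks) >= 0)
        rpd_grid = np.linspace(0, 6, 121)
        order = ["Very poor", "Poor", "Fair", "Good", "Very good", "Excellent"]
        ranks = [order.index(classify_rpd(r)) for r in rpd_grid]
        assert np.all(np.diff(ranks) >= 0)


def simple_folds(n, k, seed):
    idx = np.random.default_rng(seed).permutation(n)
    parts = np.array_split(idx, k)
    return [
        (np.concatenate(parts[:i] + parts[i + 1 :]), parts[i]) for i in range(k)
    ]


class TestGridSearch:
    def test_calibration_rmse_non_increasing(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(80, 20))
        y = X @ rng.normal(size=20) + rng.normal(size=80)
        res = grid_search_lvs(X, y, simple_folds(80, 5, 0), max_lv=12)
        assert np.all(np.diff(res.rmse_cal) <= 1e-10)

    def test_noiseless_low_rank_recovered(self):
        rng = np.random.default_rng(21)
        S = rng.normal(size=(120, 3))
        X = S @ rng.normal(size=(3, 30)) + 0.02 * rng.normal(size=(120, 30))
        y = S @ np.array([1.0, -0.5, 0.8])
        res = grid_search_lvs(X, y, simple_folds(120, 5, 1), max_lv=10)
        assert 2 <= res.selected_lv <= 4

    def test_pure_noise_overfitting_signature(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(60, 40))
        y = rng.normal(size=60)
        res = grid_search_lvs(X, y, simple_folds(60, 5, 2), max_lv=15)
        assert np.all(np.diff(res.rmse_cal) <= 1e-10)
        # held-out error of a pure-noise response never improves on small
        # component counts in a sustained way
        assert res.rmse_cv[-1] >= res.rmse_cv.min()
        assert res.selected_lv <= 5 or res.rmse_cv.min() >= 0.9 * res.rmse_cv[0]

    def test_one_se_criterion_never_selects_more_components(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(90, 25))
        y = X[:, :3] @ np.ones(3) + 0.5 * rng.normal(size=90)
        folds = simple_folds(90, 5, 3)
        a = grid_search_lvs(X, y, folds, max_lv=12, criterion="min")
        b = grid_search_lvs(X, y, folds, max_lv=12, criterion="one_se")
        assert b.selected_lv <= a.selected_lv

    def test_incomplete_folds_rejected(self):
        rng = np.random.default_rng(24)
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        bad = [(np.arange(10, 30), np.arange(5))]  # rows 5..9 never held out
        with pytest.raises(ValueError, match="cover"):
            grid_search_lvs(X, y, bad, max_lv=3)


class TestSECV:
    def test_perfect_cv_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        secv, r2cv, rpdcv = secv_metrics(y, y.copy())
        assert secv == 0.0
        assert r2cv == pytest.approx(1.0)
        assert math.isinf(rpdcv)

    def test_missing_coverage_rejected(self):
        y = np.arange(5.0)
        pred = y.copy()
        pred[2] = np.nan
        with pytest.raises(ValueError, match="cover"):
            secv_metrics(y, pred)

    def test_matches_pooled_metric_formulas(self):
        rng = np.random.default_rng(25)
        y = rng.normal(40, 6, 100)
        pred = y + rng.normal(0, 2, 100)
        secv, r2cv, rpdcv = secv_metrics(y, pred)
        rep = compute_metrics(y, pred)
        assert (secv, r2cv, rpdcv) == (rep.se, rep.r2, rep.rpd)


@settings(derandomize=True, max_examples=50)
@given(
    y=hnp.arrays(np.float64, st.integers(5, 40),
                 elements=st.floats(-50, 50, allow_nan=False)),
    data=st.data(),
)
def test_metric_identities_hold_for_arbitrary_inputs(y, data):
    """se, rmse and bias always satisfy their defining identity and the
    rmse >= |bias| inequality, whatever the prediction errors look like."""
    e = data.draw(
        hnp.arrays(np.float64, y.size, elements=st.floats(-20, 20,
                                                          allow_nan=False))
    )
    if np.std(y) == 0:
        with pytest.raises(ValueError):
            compute_metrics(y, y + e)
        return
    rep = compute_metrics(y, y + e)
    assert rep.rmse + 1e-12 >= abs(rep.bias)
    # rmse^2 - bias^2 cancels catastrophically when errors are (near-)
    # constant, so the identity can only hold to ~sqrt(eps) of the scale
    assert rep.se == pytest.approx(
        se_from_rmse_bias(rep.rmse, rep.bias, rep.n),
        rel=1e-7,
        abs=1e-6 * max(1.0, rep.rmse),
    )


def test_se_from_rmse_bias_validates_inputs():
    with pytest.raises(ValueError):
        se_from_rmse_bias(0.5, 1.0, 60)
    with pytest.raises(ValueError):
        se_from_rmse_bias(1.0, 0.0, 1)
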