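"""Differential statistics: ANOVA vs an explicit sums-of-squares oracle,
BH adjustment, t-tests and the volcano rule."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import f as f_dist

from woundmetab.datamodel import ValidationError
from woundmetab.stats import (
    bh_adjust,
    day_ttest,
    features_of_interest,
    two_way_anova_scan,
    volcano_classify,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# independent Type-II sums-of-squares oracle (explicit projections)
# ---------------------------------------------------------------------------

def _dummies(levels):
    uniq = sorted(set(levels))
    return np.column_stack([[1.0 if l == u else 0.0 for l in levels] for u in uniq[1:]])


def _rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def anova_type2_oracle(y, fa, fb):
    """Type-II F/p for factors A, B and interaction via residual sums of
    squares of explicitly constructed nested models."""
    y = np.asarray(y, dtype=float)
    n = y.size
    A = _dummies(fa)
    B = _dummies(fb)
    AB = np.column_stack([A[:, i] * B[:, j] for i in range(A.shape[1])
                          for j in range(B.shape[1])])
    one = np.ones((n, 1))
    X_full = np.hstack([one, A, B, AB])
    X_ab = np.hstack([one, A, B])
    X_a = np.hstack([one, A])
    X_b = np.hstack([one, B])
    df_resid = n - np.linalg.matrix_rank(X_full)
    mse = _rss(X_full, y) / df_resid
    out = {}
    for name, ss, df in (
        ("time", _rss(X_b, y) - _rss(X_ab, y), A.shape[1]),
        ("treatment", _rss(X_a, y) - _rss(X_ab, y), B.shape[1]),
        ("interaction", _rss(X_ab, y) - _rss(X_full, y), AB.shape[1]),
    ):
        F = ss / df / mse
        out[name] = f_dist.sf(F, df, df_resid)
    return out


def _anova_table(y_log2, days, treatments):
    n = len(y_log2)
    return make_table(
        np.array([2.0 ** np.asarray(y_log2, dtype=float)]),
        study_orders=list(range(1, n + 1)), days=days, treatments=treatments,
    )


class TestTwoWayAnova:
    def test_hand_computed_balanced_toy(self):
        # 2 days x 2 treatments, n=2/cell: SS_time=8, SS_treat=0, SS_int=0,
        # SS_res=2 (df 4) -> F_time=16, p=sf(16;1,4)
        days = [7, 7, 7, 7, 14, 14, 14, 14]
        treats = ["AFSG", "AFSG", "FBD", "FBD"] * 2
        y = [1, 2, 1, 2, 3, 4, 3, 4]
        res = two_way_anova_scan(_anova_table(y, days, treats), "DPT").iloc[0]
        assert res["p_time"] == pytest.approx(f_dist.sf(16.0, 1, 4), rel=1e-10)
        assert res["p_treatment"] == pytest.approx(1.0)
        assert res["p_interaction"] == pytest.approx(1.0)

    def test_agrees_with_projection_oracle_on_random_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_days = rng.integers(2, 4)
            n_treat = rng.integers(2, 4)
            reps = rng.integers(2, 4)
            days, treats = [], []
            for d in range(n_days):
                for t in range(n_treat):
                    days += [int(7 * (d + 1))] * int(reps)
                    treats += [["AFSG", "FBD", "CS"][t]] * int(reps)
            y = rng.normal(size=len(days))
            res = two_way_anova_scan(_anova_table(y, days, treats), "DPT").iloc[0]
            oracle = anova_type2_oracle(y, days, treats)
            assert res["p_time"] == pytest.approx(oracle["time"], abs=1e-10)
            assert res["p_treatment"] == pytest.approx(oracle["treatment"], abs=1e-10)
            assert res["p_interaction"] == pytest.approx(oracle["interaction"], abs=1e-10)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        days = [7, 7, 14, 14, 21, 21, 7, 7, 14, 14, 21, 21]
        treats = ["AFSG"] * 6 + ["FBD"] * 6
        y = rng.normal(size=12)
        base = two_way_anova_scan(_anova_table(y, days, treats), "DPT").iloc[0]
        perm = rng.permutation(12)
        shuffled = two_way_anova_scan(
            _anova_table(np.asarray(y)[perm], list(np.asarray(days)[perm]),
                         list(np.asarray(treats)[perm])), "DPT").iloc[0]
        for col in ("p_time", "p_treatment", "p_interaction"):
            assert base[col] == pytest.approx(shuffled[col], rel=1e-9)

    def test_single_level_factor_is_error(self):
        days = [7, 7, 14, 14]
        treats = ["AFSG"] * 4
        with pytest.raises(ValidationError, match="Treatment"):
            two_way_anova_scan(_anova_table([1, 2, 3, 4], days, treats), "DPT")


class TestBhAdjust:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04, 0.05]), [0.04, 0.04, 0.05, 0.05]
        )

    def test_single_and_equal_inputs(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and not np.isnan(out[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_dominates_p_and_preserves_order(self, ps):
        q = bh_adjust(ps)
        assert np.all(q <= 1 + 1e-12)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        # monotone in the order statistics: sorting p sorts q the same way
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestDayTtest:
    @staticmethod
    def _table(a_vals, b_vals):
        n = len(a_vals) + len(b_vals)
        treats = ["AFSG"] * len(a_vals) + ["FBD"] * len(b_vals)
        return make_table(np.array([list(a_vals) + list(b_vals)], dtype=float),
                          study_orders=list(range(1, n + 1)),
                          days=[7] * n, treatments=treats)

    def test_identical_groups_give_p1_fc1(self):
        res = day_ttest(self._table([16, 16, 16], [16, 16, 16]), "DPT", 7,
                        "AFSG", "FBD").iloc[0]
        assert res["p_raw"] == pytest.approx(1.0)
        assert res["fc"] == pytest.approx(1.0)

    def test_fold_change_is_linear_mean_ratio(self):
        res = day_ttest(self._table([250, 300, 350], [90, 100, 110]), "DPT", 7,
                        "AFSG", "FBD").iloc[0]
        assert res["fc"] == pytest.approx(3.0)

    def test_bonferroni_multiplies_by_family_size(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(50, 150, size=(100, 6))
        treats = ["AFSG"] * 3 + ["FBD"] * 3
        t = make_table(vals, study_orders=list(range(1, 7)), days=[7] * 6,
                       treatments=treats)
        res = day_ttest(t, "DPT", 7, "AFSG", "FBD")
        ok = res.dropna(subset=["p_raw"])
        np.testing.assert_allclose(
            ok["p_bonf"], np.minimum(1.0, ok["p_raw"] * len(ok)), rtol=1e-12
        )

    def test_insufficient_group_size_gives_missing(self):
        res = day_ttest(self._table([100, 110], [90]), "DPT", 7, "AFSG", "FBD").iloc[0]
        assert np.isnan(res["p_raw"])


class TestVolcano:
    @pytest.mark.parametrize(
        "fc,p_bonf,responder,direction",
        [
            (2.0, 0.05, True, "up_in_a"),
            (1.4, 0.001, False, ""),
            (0.5, 0.09, True, "up_in_b"),
            (2.0, 0.2, False, ""),
        ],
    )
    def test_threshold_rule(self, fc, p_bonf, responder, direction):
        import pandas as pd

        tt = pd.DataFrame({"p_bonf": [p_bonf], "fc": [fc]},
                          index=pd.Index(["F1"], name="feature_id"))
        out = volcano_classify(tt, p_thresh=0.1, fc_thresh=1.5).iloc[0]
        assert bool(out["responder"]) is responder
        assert out["direction"] == direction


def test_features_of_interest_conjunction_rule():
    import pandas as pd

    anova = pd.DataFrame(
        {
            "p_time": [0.001, 0.04, 0.2, np.nan],
            "q_time": [0.01, 0.06, 0.5, np.nan],
        },
        index=pd.Index(list("abcd"), name="feature_id"),
    )
    assert features_of_interest(anova) == ["a"]
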