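import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screversal.hurdle import (
    ContrastSpec,
    HurdleModel,
    bh_adjust,
    compute_lnfc,
    fit_hurdle,
    hurdle_lrt,
    run_de_contrast,
)
from screversal.preprocess import NormMatrix
from screversal.simulate import planted_effect_table


def _norm_from(values):
    values = np.asarray(values, dtype=float)
    return NormMatrix(
        values=values,
        gene_ids=np.array([f"g{i}" for i in range(values.shape[0])], dtype=object),
        barcodes=np.array([f"c{j}" for j in range(values.shape[1])], dtype=object),
    )


class TestLnFC:
    def test_identical_groups_zero(self):
        rng = np.random.default_rng(0)
        V = rng.random((5, 8))
        norm = _norm_from(np.hstack([V, V]))
        lnfc = compute_lnfc(norm, np.arange(8), np.arange(8, 16))
        np.testing.assert_allclose(lnfc, 0.0, atol=1e-12)

    def test_hand_arithmetic_ln2(self):
        norm = _norm_from([[np.log(2.0), 0.0]])
        lnfc = compute_lnfc(norm, [0], [1])
        assert lnfc[0] == pytest.approx(np.log(2.0), abs=1e-12)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        norm = _norm_from(rng.random((10, 20)))
        a, b = np.arange(10), np.arange(10, 20)
        np.testing.assert_allclose(
            compute_lnfc(norm, a, b), -compute_lnfc(norm, b, a), atol=1e-12
        )

    def test_empty_group_is_error(self):
        norm = _norm_from(np.ones((2, 4)))
        with pytest.raises(ValueError):
            compute_lnfc(norm, [], [0, 1])


class TestHurdleFit:
    def test_intercept_only_closed_form(self):
        y = np.array([0.0, 0.0, 1.0, 2.0, 3.0])
        res = fit_hurdle(y, np.ones((5, 1)))
        # logistic intercept = logit(detection rate 3/5)
        assert res.detection_params[0] == pytest.approx(np.log(0.6 / 0.4), abs=1e-5)
        assert res.continuous_params[0] == pytest.approx(2.0)
        assert res.sigma2 == pytest.approx(2.0 / 3.0)

    def test_no_zeros_saturates_detection(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = fit_hurdle(y, np.ones((4, 1)))
        assert not res.detection_testable
        assert any("saturated" in f for f in res.flags)
        assert res.continuous_params[0] == pytest.approx(2.5)

    def test_too_few_detected_marks_continuous_untestable(self):
        y = np.array([0.0, 0.0, 0.0, 0.0, 1.5])
        res = fit_hurdle(y, np.ones((5, 1)))
        assert not res.continuous_testable
        assert res.continuous_params is None

    def test_summary_renders(self):
        y = np.array([0.0, 1.0, 2.0, 0.0, 3.0])
        text = fit_hurdle(y, np.ones((5, 1))).summary()
        assert "log-likelihood" in text

    def test_matches_brute_force_maximization(self):
        """Hurdle ML log-likelihood equals an independent numerical optimum."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(60):
            n = 40
            X = np.column_stack(
                [np.ones(n), rng.integers(0, 2, n), rng.normal(size=n)]
            )
            y = np.where(
                rng.random(n) < 0.6, np.abs(rng.normal(1.5, 1.0, n)), 0.0
            )
            d = (y > 0).astype(float)
            if d.sum() < 5 or d.sum() == n:
                continue
            fit = HurdleModel(y, X).fit()
            if fit.separated:
                continue
            k = X.shape[1]
            pos = y > 0
            n_pos = int(pos.sum())

            def negll(params):
                bd, bc, ls = params[:k], params[k : 2 * k], params[-1]
                eta = X @ bd
                ll_det = d @ eta - np.logaddexp(0, eta).sum()
                s2 = np.exp(ls)
                r = y[pos] - X[pos] @ bc
                ll_c = -0.5 * n_pos * np.log(2 * np.pi * s2) - 0.5 * (r @ r) / s2
                return -(ll_det + ll_c)

            best = None
            for x0 in ([0.0] * (2 * k) + [0.0], [0.1] * (2 * k) + [-1.0]):
                r = minimize(
                    negll,
                    np.array(x0),
                    method="Nelder-Mead",
                    options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
                )
                if best is None or r.fun < best.fun:
                    best = r
            assert fit.llf == pytest.approx(-best.fun, abs=1e-6)
            checked += 1
        assert checked >= 50


class TestHurdleLRT:
    def test_identical_groups_null(self):
        y = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        a = np.array([1, 1, 1, 0, 0, 0])
        chi2, df, p = hurdle_lrt(y, a)
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_chi2_nonnegative_and_group_relabel_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = np.where(rng.random(30) < 0.5, np.abs(rng.normal(1, 1, 30)), 0.0)
            a = rng.integers(0, 2, 30)
            if len(np.unique(a)) < 2:
                continue
            c1, d1, p1 = hurdle_lrt(y, a)
            c2, d2, p2 = hurdle_lrt(y, 1 - a)
            if np.isnan(c1):
                assert np.isnan(c2)
                continue
            assert c1 >= 0
            assert c1 == pytest.approx(c2, abs=1e-6)
            assert d1 == d2

    def test_matches_closed_form_fast_path(self):
        from screversal.hurdle import _grouped_lrt_closed_form

        rng = np.random.default_rng(4)
        Y = np.where(rng.random((30, 50)) < 0.5, np.abs(rng.normal(1, 1, (30, 50))), 0.0)
        in_A = np.zeros(50, dtype=bool)
        in_A[:25] = True
        chi2_v, df_v, p_v = _grouped_lrt_closed_form(Y, in_A)
        for g in range(30):
            chi2, df, p = hurdle_lrt(Y[g], in_A.astype(float))
            if np.isnan(chi2):
                assert np.isnan(chi2_v[g])
                continue
            assert chi2_v[g] == pytest.approx(chi2, abs=1e-5)
            assert df_v[g] == df

    def test_untestable_gene_returns_na(self):
        y = np.zeros(10)
        a = np.array([1] * 5 + [0] * 5)
        chi2, df, p = hurdle_lrt(y, a)
        assert df == 0 and np.isnan(p)

    def test_oracle_example_two_groups(self):
        # y = [0, 1, 2 | 0, 0, 3]: both parts testable, df = 2
        y = np.array([0.0, 1.0, 2.0, 0.0, 0.0, 3.0])
        a = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        chi2, df, p = hurdle_lrt(y, a)
        assert df == 2
        # detection part: 2/3 vs 1/3 detected; G-test by hand
        def bll(k, n):
            out = 0.0
            if k:
                out += k * np.log(k / n)
            if n - k:
                out += (n - k) * np.log(1 - k / n)
            return out

        det = 2 * (bll(2, 3) + bll(1, 3) - bll(3, 6))
        # continuous part: values [1,2] vs [3]; ML variances by hand
        full_rss = 0.5 + 0.0
        red_rss = ((np.array([1, 2, 3]) - 2.0) ** 2).sum()
        cont = 3 * np.log(red_rss / full_rss)
        assert chi2 == pytest.approx(det + cont, abs=1e-6)


class TestBH:
    def test_hand_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_passthrough(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_nan_passthrough_not_counted(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # m = 2, not 3
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_direct_formula(self, pvals):
        """Oracle: q_i = min_{j >= i} (m * p_(j) / j), capped at 1."""
        p = np.array(pvals)
        q = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        running = np.inf
        for rank in range(m - 1, -1, -1):
            running = min(running, m * p[order[rank]] / (rank + 1))
            expected[order[rank]] = min(running, 1.0)
        np.testing.assert_allclose(q, expected, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestRunDeContrast:
    def test_degenerate_detection_filter_gives_empty_table(self, caplog):
        # sparse data: every gene has a dropout in each group
        rng = np.random.default_rng(0)
        V = rng.random((6, 12))
        V[V < 0.4] = 0.0
        V[:, 0] = 0.0
        V[:, 6] = 0.0
        norm = _norm_from(V)
        meta = pd.DataFrame(
            {
                "barcode": norm.barcodes,
                "group": ["aged"] * 6 + ["young"] * 6,
                "cell_type": "type0",
            }
        )
        spec = ContrastSpec(
            cell_type="type0",
            group_A="aged",
            group_B="young",
            min_detection_fraction=1.0,
        )
        table = run_de_contrast(norm, meta, spec)
        assert len(table) == 0

    def test_empty_group_is_error(self, small_norm):
        norm, meta, _ = small_norm
        spec = ContrastSpec(cell_type="type0", group_A="vehicle", group_B="young")
        with pytest.raises(ValueError):
            run_de_contrast(norm, meta, spec)

    def test_sign_recovery_of_planted_effects(self, deg_tables, small_dataset):
        _, _, truth = small_dataset
        da = deg_tables["type0"]["aging"]
        tab = planted_effect_table(truth, "type0").set_index("gene")
        sig = da[da.q_value < 0.05].set_index("gene").join(tab)
        sig = sig[sig.delta != 0]
        agree = (np.sign(sig.lnFC) == np.sign(sig.delta)).mean()
        assert agree >= 0.95

    def test_lnfc_correlates_with_planted_effect(self, deg_tables, small_dataset):
        _, _, truth = small_dataset
        da = deg_tables["type0"]["aging"]
        tab = planted_effect_table(truth, "type0").set_index("gene")
        j = da.set_index("gene").join(tab)
        r = np.corrcoef(j.lnFC, j.delta)[0, 1]
        assert r >= 0.8

    def test_sorted_by_q_then_abs_lnfc(self, deg_tables):
        t = deg_tables["type0"]["aging"]
        q = t.q_value.to_numpy()
        finite = ~np.isnan(q)
        assert (np.diff(q[finite]) >= -1e-15).all()

    def test_cdr_covariate_path_runs(self, small_norm):
        norm, meta, _ = small_norm
        sub = meta["cell_type"] == "type0"
        spec = ContrastSpec(
            cell_type="type0",
            group_A="aged",
            group_B="young",
            covariates=("cdr",),
            min_detection_fraction=0.5,
        )
        table = run_de_contrast(norm, meta, spec)
        assert len(table) > 0
        assert table.p_value.dropna().between(0, 1).all()
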