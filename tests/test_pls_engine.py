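"""NIPALS PLS, LOO cross-validation, component selection and statistics."""

import numpy as np
import pytest

from qsar3d import (
    DescriptorMatrix,
    apply_onc_rule,
    bootstrap_stats,
    field_contributions,
    fit_pls,
    loo_q2,
    predict,
    press_q2,
    select_onc,
)
from qsar3d.pls_engine import PLSModel


def _random_problem(rng, n=8, p=5, noise=0.0):
    X = rng.normal(0, 1, (n, p))
    beta = rng.normal(0, 1, p)
    y = X @ beta + rng.normal(0, noise, n)
    return X, y


class TestFitPls:
    def test_noiseless_single_factor_is_exact(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 12)
        X = np.column_stack([x])
        y = 2.5 * x + 1.0
        m = fit_pls(X, y, 1)
        assert m.r2 == pytest.approx(1.0, abs=1e-9)
        assert np.sum((y - m.fitted) ** 2) == pytest.approx(0.0, abs=1e-9)

    def test_full_rank_equals_least_squares(self):
        """At ncomp = rank, PLS reproduces the OLS fit (normal-equations
        oracle computed independently)."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            X, y = _random_problem(rng, n=12, p=4, noise=0.5)
            m = fit_pls(X, y, 4)
            Xc = X - X.mean(axis=0)
            beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
            ols_fitted = Xc @ beta + y.mean()
            assert np.max(np.abs(m.fitted - ols_fitted)) < 1e-8

    def test_matches_sklearn_nipals(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(4)
        X, y = _random_problem(rng, n=15, p=8, noise=0.3)
        for ncomp in (1, 2, 3):
            m = fit_pls(X, y, ncomp)
            sk = PLSRegression(n_components=ncomp, scale=False).fit(X, y)
            assert np.max(np.abs(sk.predict(X).ravel() - m.fitted)) < 1e-8

    def test_overfit_direction_r2_at_least_q2(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (10, 50))
        y = rng.permutation(X[:, 0] * 2 + rng.normal(0, 0.1, 10))
        m = fit_pls(X, y, 2)
        q2, _ = loo_q2(X, y, 2)
        assert m.r2 >= q2

    def test_see_and_f_formulas(self):
        rng = np.random.default_rng(3)
        X, y = _random_problem(rng, n=10, p=3, noise=0.4)
        m = fit_pls(X, y, 2)
        ss_res = float(np.sum((y - m.fitted) ** 2))
        assert m.see == pytest.approx(np.sqrt(ss_res / (10 - 2 - 1)), rel=1e-12)
        assert m.f_stat == pytest.approx(
            (m.r2 / 2) / ((1 - m.r2) / (10 - 2 - 1)), rel=1e-12
        )

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(5)
        X, _ = _random_problem(rng, n=6, p=3)
        with pytest.raises(ValueError, match="zero variance"):
            fit_pls(X, np.ones(6), 1)
        with pytest.raises(ValueError, match="ncomp"):
            fit_pls(X, rng.normal(0, 1, 6), 5)

    def test_centering_invariance(self):
        rng = np.random.default_rng(6)
        X, y = _random_problem(rng, n=10, p=4, noise=0.3)
        m0 = fit_pls(X, y, 2)
        m1 = fit_pls(X, y + 100.0, 2)
        assert np.max(np.abs(m1.coefficients - m0.coefficients)) < 1e-10
        assert m1.r2 == pytest.approx(m0.r2, abs=1e-10)
        assert m1.intercept - m0.intercept == pytest.approx(100.0, abs=1e-8)
        q0 = loo_q2(X, y, 2)[0]
        q1 = loo_q2(X, y + 100.0, 2)[0]
        assert q1 == pytest.approx(q0, abs=1e-10)

    def test_column_scaling_covariance(self):
        rng = np.random.default_rng(7)
        X, y = _random_problem(rng, n=10, p=4, noise=0.3)
        m0 = fit_pls(X, y, 4)  # full rank: unique coefficient vector
        Xs = X.copy()
        Xs[:, 1] *= 5.0
        m1 = fit_pls(Xs, y, 4)
        assert m1.coefficients[1] == pytest.approx(m0.coefficients[1] / 5.0,
                                                   rel=1e-8)
        assert np.max(np.abs(predict(m1, Xs) - predict(m0, X))) < 1e-8


class TestLooQ2:
    def test_identifiable_signal_gives_high_q2(self):
        rng = np.random.default_rng(8)
        X, y = _random_problem(rng, n=20, p=3, noise=0.02)
        q2, _ = loo_q2(X, y, 3)
        assert q2 > 0.95

    def test_mean_prediction_gives_q2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        q2, press = press_q2(y, np.full(4, y.mean()))
        assert q2 == 0.0
        assert press == pytest.approx(np.sum((y - y.mean()) ** 2))

    def test_perfect_prediction_gives_q2_one(self):
        y = np.array([1.0, 2.0, 3.0])
        q2, press = press_q2(y, y.copy())
        assert q2 == 1.0 and press == 0.0

    def test_matches_explicit_refit_oracle(self):
        """LOO q2 equals an oracle that literally rebuilds the model n times
        (independent loop, including SEP bookkeeping)."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            X, y = _random_problem(rng, n=8, p=5, noise=0.3)
            q2, sep = loo_q2(X, y, 2)
            preds = []
            for i in range(8):
                mask = [j for j in range(8) if j != i]
                m = fit_pls(X[mask], y[mask], 2)
                preds.append(predict(m, X[i : i + 1])[0])
            press = np.sum((y - np.array(preds)) ** 2)
            q2_ref = 1 - press / np.sum((y - y.mean()) ** 2)
            assert q2 == pytest.approx(q2_ref, abs=1e-10)
            assert sep == pytest.approx(np.sqrt(press / (8 - 2 - 1)), abs=1e-10)

    def test_permuted_response_has_no_predictivity(self):
        rng = np.random.default_rng(10)
        X, y = _random_problem(rng, n=16, p=10, noise=0.1)
        q2s = [loo_q2(X, rng.permutation(y), 2)[0] for _ in range(20)]
        assert np.mean(q2s) <= 0.1


class TestOncRule:
    @pytest.mark.parametrize(
        "q2s,seps,expected",
        [
            # SEP minimized at 3 but step 2->3 gains < 10 %
            ((0.50, 0.58, 0.585), (0.60, 0.50, 0.45), 2),
            # every step gains >= 10 %
            ((0.30, 0.40, 0.60), (0.70, 0.60, 0.50), 3),
            # single candidate
            ((0.40,), (0.50,), 1),
        ],
    )
    def test_parsimony_rule_tables(self, q2s, seps, expected):
        assert apply_onc_rule(q2s, seps) == expected

    def test_absolute_variant(self):
        # 0.50 -> 0.58 is +0.08 absolute: rejected at a 0.10 absolute bar
        assert apply_onc_rule((0.50, 0.58), (0.6, 0.5), relative=False) == 1
        assert apply_onc_rule((0.50, 0.62), (0.6, 0.5), relative=False) == 2

    def test_select_onc_scans_and_selects(self):
        rng = np.random.default_rng(11)
        X, y = _random_problem(rng, n=20, p=6, noise=0.05)
        onc, table = select_onc(X, y, max_comp=4)
        assert len(table) == 4
        assert 1 <= onc <= 4
        assert onc == apply_onc_rule([r["q2"] for r in table],
                                     [r["sep"] for r in table])

    def test_max_comp_one(self):
        rng = np.random.default_rng(12)
        X, y = _random_problem(rng, n=10, p=4, noise=0.2)
        onc, table = select_onc(X, y, max_comp=1)
        assert onc == 1 and len(table) == 1


class TestBootstrap:
    def test_noiseless_data_keeps_r2_one(self):
        rng = np.random.default_rng(13)
        X, y = _random_problem(rng, n=12, p=3, noise=0.0)
        boot_r2, _, _ = bootstrap_stats(X, y, 3, n_runs=20, seed=42)
        assert boot_r2 == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(14)
        X, y = _random_problem(rng, n=12, p=4, noise=0.5)
        a = bootstrap_stats(X, y, 2, n_runs=25, seed=7)
        b = bootstrap_stats(X, y, 2, n_runs=25, seed=7)
        assert a == b


def _matrix_from_columns(cols, labels, y=None):
    X = np.column_stack(cols)
    idx = [(lab, j) for j, lab in enumerate(labels)]
    if y is None:
        y = np.arange(X.shape[0], dtype=float)
    return DescriptorMatrix(X, y, idx)


def _model_with_coefficients(coefs, block_index):
    n = len(coefs)
    return PLSModel(
        ncomp=1, coefficients=np.asarray(coefs, dtype=float),
        intercept=0.0, x_mean=np.zeros(n), y_mean=0.0, r2=1.0, see=0.0,
        f_stat=1.0, fitted=np.zeros(3), block_index=block_index,
    )


class TestFieldContributions:
    def test_single_field_takes_all(self):
        dm = _matrix_from_columns(
            [np.array([-1.0, 0, 1]), np.array([2.0, 0, -2])], ["steric", "steric"]
        )
        model = _model_with_coefficients([1.0, -0.5], dm.block_index)
        assert field_contributions(model, dm) == {"steric": 1.0}

    def test_symmetric_fields_split_evenly(self):
        col = np.array([-1.0, 0.0, 1.0])
        dm = _matrix_from_columns([col, col], ["a", "b"])
        model = _model_with_coefficients([0.7, 0.7], dm.block_index)
        out = field_contributions(model, dm)
        assert out["a"] == pytest.approx(0.5) and out["b"] == pytest.approx(0.5)

    def test_hand_computed_fractions(self):
        # |coef|*sd masses: field A = 1*1, field B = 2*1 + 0*4 -> 1/3, 2/3
        cols = [
            np.array([-1.0, 0.0, 1.0]),  # sd 1
            np.array([-1.0, 0.0, 1.0]),  # sd 1
            np.array([-4.0, 0.0, 4.0]),  # sd 4
        ]
        dm = _matrix_from_columns(cols, ["A", "B", "B"])
        model = _model_with_coefficients([1.0, 2.0, 0.0], dm.block_index)
        out = field_contributions(model, dm)
        assert out["A"] == pytest.approx(1 / 3)
        assert out["B"] == pytest.approx(2 / 3)

    def test_contributions_sum_to_one(self, comsia_result):
        total = sum(comsia_result.model.contributions.values())
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_coefficients_rejected(self):
        dm = _matrix_from_columns([np.array([-1.0, 0, 1])], ["A"])
        model = _model_with_coefficients([0.0], dm.block_index)
        with pytest.raises(ValueError):
            field_contributions(model, dm)
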