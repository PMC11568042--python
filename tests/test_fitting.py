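"""Likelihood, fit statistics and the ML fitter."""

import itertools
import math

import numpy as np
import pytest

from mptdc import (
    CountTable,
    MPTEstimator,
    ValidationError,
    aicc_correction,
    build_model,
    default_parameters,
    expected_counts,
    fit,
    g_squared,
    negative_log_likelihood,
    pearson_chi2,
)


class TestNegativeLogLikelihood:
    def test_certain_model_has_zero_nll(self, classic_2ht):
        params = {"do": 1.0, "dn": 1.0, "g_1": 0.5, "g_2": 0.5, "g_3": 0.5}
        counts = [np.array([50.0, 0.0]) if t.stimulus == "old" else np.array([0.0, 50.0])
                  for t in classic_2ht.trees]
        assert negative_log_likelihood(classic_2ht, params, counts) == pytest.approx(0.0)

    def test_fair_coin_kernel_value(self):
        m = build_model("2HT", "classic", 1, [0.5])
        params = {"do": 0.0, "dn": 0.0, "g_1": 0.5}
        counts = [np.array([1.0, 1.0]), np.array([0.0, 0.0])]
        # -2 ln(.5) = 1.3863
        assert negative_log_likelihood(m, params, counts) == pytest.approx(
            -2 * math.log(0.5), abs=1e-12
        )

    def test_zero_probability_with_counts_is_inf(self, classic_2ht):
        params = {"do": 1.0, "dn": 1.0, "g_1": 1.0, "g_2": 1.0, "g_3": 1.0}
        counts = [np.array([0.0, 1.0]) for _ in classic_2ht.trees]
        assert negative_log_likelihood(classic_2ht, params, counts) == math.inf

    def test_layout_mismatch_rejected(self, classic_2ht):
        params = default_parameters(classic_2ht)
        with pytest.raises(ValidationError):
            negative_log_likelihood(classic_2ht, params, [np.array([1.0, 2.0, 3.0])] * 6)


class TestPearsonChi2:
    def test_basic_values_and_scaling(self):
        assert pearson_chi2(np.array([5.0, 5.0]), np.array([5.0, 5.0])) == 0.0
        assert pearson_chi2(np.array([10.0, 0.0]), np.array([5.0, 5.0])) == 10.0
        o, e = np.array([7.0, 3.0]), np.array([5.0, 5.0])
        assert pearson_chi2(2 * o, 2 * e) == pytest.approx(2 * pearson_chi2(o, e))

    def test_zero_expected_cells(self):
        # E = 0, O = 0 contributes nothing
        assert pearson_chi2(np.array([4.0, 0.0]), np.array([4.0, 0.0])) == 0.0
        with pytest.warns(UserWarning):
            assert pearson_chi2(np.array([1.0, 1.0]), np.array([2.0, 0.0])) == math.inf

    def test_g_squared_zero_at_perfect_fit(self):
        o = np.array([30.0, 70.0])
        assert g_squared(o, o) == pytest.approx(0.0, abs=1e-12)


class TestAicc:
    def test_worked_case(self):
        # AIC = 100, p = 5, n = 12 -> AICc = 110
        assert 100 + aicc_correction(5, 12) == pytest.approx(110.0)

    def test_formula_on_grid(self):
        for p, n in itertools.product([1, 3, 5, 9, 21, 25], [30, 100, 300, 600]):
            if n <= p + 1:
                continue
            assert aicc_correction(p, n) == pytest.approx(2 * p * (p + 1) / (n - p - 1))
            assert aicc_correction(p, n) > 0  # AICc always exceeds AIC

    def test_undefined_when_n_too_small(self):
        assert aicc_correction(5, 6) == math.inf


def _classic_counts(model):
    """Counts whose relative frequencies invert analytically to
    (do, dn, g) = (.5, .5, (.3, .5, .7))."""
    by_cond = {0: (65, 35, 15, 85), 1: (75, 25, 25, 75), 2: (85, 15, 35, 65)}
    arrays = []
    for tree in model.trees:
        h, m, f, c = by_cond[tree.condition]
        arrays.append(
            np.array([h, m], dtype=float) if tree.stimulus == "old"
            else np.array([f, c], dtype=float)
        )
    return arrays


class TestFit:
    def test_2ht_classic_analytic_inversion(self, classic_2ht):
        """h_j = do + (1-do) g_j and f_j = (1-dn) g_j invert exactly for
        these frequencies; a coarse grid search confirms the optimum."""
        arrays = _classic_counts(classic_2ht)
        res = fit(classic_2ht, arrays, n_restarts=4, seed=0)
        expected = {"do": 0.5, "dn": 0.5, "g_1": 0.3, "g_2": 0.5, "g_3": 0.7}
        for k, v in expected.items():
            assert res.estimates[k] == pytest.approx(v, abs=1e-5)
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)
        # independent grid-search oracle
        grid = np.linspace(0.05, 0.95, 19)
        best = min(
            negative_log_likelihood(
                classic_2ht,
                {"do": do, "dn": dn, "g_1": 0.3, "g_2": 0.5, "g_3": 0.7},
                arrays,
            )
            for do in grid
            for dn in grid
        )
        assert -res.loglik <= best + 1e-9

    def test_fit_statistics_fields(self, classic_2ht):
        res = fit(classic_2ht, _classic_counts(classic_2ht), n_restarts=2, seed=0)
        assert res.df == 6 - 5
        assert res.n == 600 and res.p == 5
        assert res.aic == pytest.approx(-2 * res.loglik + 2 * res.p)
        assert res.aicc == pytest.approx(res.aic + aicc_correction(res.p, res.n))
        assert res.converged

    @pytest.mark.parametrize("fam,var", [("2HT", "classic"), ("SDT", "CL"),
                                         ("2HT", "CL_RT")])
    def test_expected_count_fit_recovers_generator(self, fam, var):
        """Fitting the model-implied expected counts (non-integer) returns
        the generating parameters and a vanishing chi-square."""
        m = build_model(fam, var)
        params = default_parameters(m)
        exp = expected_counts(m, params, [100.0] * len(m.trees))
        res = fit(m, exp, n_restarts=2, seed=1, compute_se=False)
        for k, v in params.items():
            assert res.estimates[k] == pytest.approx(v, abs=1e-4)
        assert res.chi2 < 1e-6

    def test_restart_seed_invariance(self, classic_sdt, rng):
        from mptdc import SimulationDesign, simulate_counts

        design = SimulationDesign(
            model=classic_sdt, params=default_parameters(classic_sdt),
            n_subjects=1, trials_per_tree=200, seed=9,
        )
        table = simulate_counts(design)[0]
        r1 = fit(classic_sdt, table, n_restarts=4, seed=11, compute_se=False)
        r2 = fit(classic_sdt, table, n_restarts=4, seed=999, compute_se=False)
        for k in r1.estimates:
            assert r1.estimates[k] == pytest.approx(r2.estimates[k], abs=1e-5)

    def test_boundary_estimate_flags_se_undefined(self, classic_2ht):
        # zero misses force do toward its upper bound
        arrays = []
        for tree in classic_2ht.trees:
            arrays.append(np.array([100.0, 0.0]) if tree.stimulus == "old"
                          else np.array([20.0, 80.0]))
        res = fit(classic_2ht, arrays, n_restarts=2, seed=3)
        assert res.estimates["do"] > 0.99
        assert math.isnan(res.se["do"]) or not res.se_defined

    def test_empty_tree_rejected(self, classic_2ht):
        arrays = [np.array([0.0, 0.0])] * 6
        with pytest.raises(ValidationError):
            fit(classic_2ht, arrays)


class TestEstimator:
    def test_sklearn_interface_round_trip(self, classic_2ht):
        est = MPTEstimator(family="2HT", variant="classic", n_restarts=2,
                           random_state=0)
        assert est.get_params()["family"] == "2HT"
        est.set_params(n_restarts=3)
        arrays = _classic_counts(classic_2ht)
        table = CountTable.from_arrays("s1", classic_2ht, arrays)
        est.fit(table)
        assert est.estimates_["do"] == pytest.approx(0.5, abs=1e-4)
        assert est.aicc_ > est.aic_
        probs = est.predict_proba()
        for p in probs:
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert est.score(table) == pytest.approx(est.loglik_, abs=1e-8)
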