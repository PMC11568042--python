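"""Model construction, category probabilities and serialization."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from mptdc import (
    ConfigurationError,
    DomainError,
    build_model,
    category_probabilities,
    branch_probabilities,
    normal_cdf,
)
from mptdc.models import ModelSpec

from conftest import random_params


class TestBuildModel:
    def test_two_trees_per_condition(self, any_model):
        assert len(any_model.trees) == 2 * any_model.n_conditions
        keys = {(t.condition, t.stimulus) for t in any_model.trees}
        assert len(keys) == len(any_model.trees)

    def test_degenerate_single_condition_2ht(self):
        m = build_model("2HT", "classic", 1, [0.5])
        assert m.n_free_parameters == 3
        assert set(m.parameter_names) == {"do", "dn", "g_1"}

    def test_unknown_family_or_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            build_model("3HT", "classic")
        with pytest.raises(ConfigurationError):
            build_model("2HT", "CLRT")
        with pytest.raises(ConfigurationError):
            build_model("2HT", "classic", 0)

    def test_high_threshold_structural_zeros(self):
        """No detect-new branch on old-item trees and vice versa."""
        for variant in ("classic", "CL", "RT", "CL_RT"):
            m = build_model("2HT", variant)
            for tree in m.trees:
                states = {b.state for b in tree.branches}
                if tree.stimulus == "old":
                    assert "detect_new" not in states
                else:
                    assert "detect_old" not in states

    def test_categories_shared_across_trees(self, any_model):
        cats = {t.categories for t in any_model.trees}
        assert len(cats) == 1
        expected = {
            (1, 1): 2,
            (3, 1): 6,
            (1, 2): 4,
            (3, 2): 12,
        }[(any_model.n_cl_bins, any_model.n_rt_bins)]
        assert len(any_model.trees[0].categories) == expected


class TestNormalCdf:
    def test_symmetry_and_limits(self):
        assert normal_cdf(0.0) == 0.5
        assert abs(normal_cdf(40.0) - 1.0) < 1e-15
        for x in (0.3, 1.0, 1.96, 3.5):
            assert normal_cdf(-x) == pytest.approx(1.0 - normal_cdf(x), abs=1e-15)

    def test_against_erf_oracle(self):
        for x in np.linspace(-6, 6, 41):
            oracle = 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))
            assert abs(normal_cdf(x) - oracle) < 1e-12
        assert normal_cdf(1.96) == pytest.approx(0.975, abs=1e-3)


class TestCategoryProbabilities:
    def test_2ht_classic_hand_values(self, classic_2ht):
        params = {"do": 0.5, "dn": 0.5, "g_1": 0.5, "g_2": 0.5, "g_3": 0.5}
        old = category_probabilities(classic_2ht, params, classic_2ht.tree(0, "old"))
        # P(Hit) = do + (1-do) g = .75
        assert old == pytest.approx([0.75, 0.25], abs=1e-15)
        new = category_probabilities(classic_2ht, params, classic_2ht.tree(0, "new"))
        # P(FA) = (1-dn) g = .25
        assert new == pytest.approx([0.25, 0.75], abs=1e-15)

    def test_2ht_certainty_case(self, classic_2ht):
        params = {"do": 1.0, "dn": 0.2, "g_1": 0.7, "g_2": 0.7, "g_3": 0.7}
        old = category_probabilities(classic_2ht, params, classic_2ht.tree(0, "old"))
        assert old == pytest.approx([1.0, 0.0], abs=1e-15)

    def test_sdt_symmetric_null(self, classic_sdt):
        params = {"d_prime": 0.0, "sigma": 1.0, "c_1": 0.0, "c_2": 0.0, "c_3": 0.0}
        for stim in ("old", "new"):
            p = category_probabilities(classic_sdt, params, classic_sdt.tree(0, stim))
            assert p == pytest.approx([0.5, 0.5], abs=1e-15)

    def test_sdt_false_alarm_tail(self, classic_sdt):
        params = {"d_prime": 0.0, "sigma": 1.0, "c_1": 1.645, "c_2": 0.0, "c_3": 0.0}
        p = category_probabilities(classic_sdt, params, classic_sdt.tree(0, "new"))
        oracle = 1.0 - 0.5 * (1.0 + math.erf(1.645 / math.sqrt(2.0)))
        assert p[0] == pytest.approx(oracle, abs=1e-12)
        assert p[0] == pytest.approx(0.05, abs=1e-3)

    def test_probabilities_normalize_random_draws(self, any_model, rng):
        for _ in range(200):
            params = random_params(any_model, rng)
            for tree in any_model.trees:
                p = category_probabilities(any_model, params, tree)
                assert np.all(p >= 0.0) and np.all(p <= 1.0)
                assert abs(p.sum() - 1.0) < 1e-12

    def test_branch_probabilities_refine_categories(self, any_model, rng):
        params = random_params(any_model, rng)
        tree = any_model.trees[0]
        bp = branch_probabilities(any_model, params, tree)
        cp = category_probabilities(any_model, params, tree)
        pooled = np.zeros_like(cp)
        index = {c: i for i, c in enumerate(tree.categories)}
        for b, v in zip(tree.branches, bp):
            pooled[index[b.category]] += v
        assert pooled == pytest.approx(cp, abs=1e-14)

    def test_out_of_bounds_params_rejected(self, classic_2ht):
        bad = {"do": 1.5, "dn": 0.5, "g_1": 0.5, "g_2": 0.5, "g_3": 0.5}
        with pytest.raises(DomainError):
            category_probabilities(classic_2ht, bad, classic_2ht.tree(0, "old"))
        with pytest.raises(DomainError):
            category_probabilities(classic_2ht, {"do": 0.5}, classic_2ht.tree(0, "old"))

    def test_sdt_hit_rate_monotone_in_dprime_and_criterion(self, classic_sdt):
        base = {"d_prime": 0.0, "sigma": 1.0, "c_1": 0.5, "c_2": 0.5, "c_3": 0.5}
        tree = classic_sdt.tree(0, "old")
        hits = []
        for dp in np.linspace(-1, 3, 17):
            p = category_probabilities(classic_sdt, {**base, "d_prime": dp}, tree)
            hits.append(p[0])
        assert np.all(np.diff(hits) > 0)
        hits = []
        for c in np.linspace(-2, 2, 17):
            p = category_probabilities(
                classic_sdt, {**base, "d_prime": 1.0, "c_1": c}, tree
            )
            hits.append(p[0])
        assert np.all(np.diff(hits) < 0)


class TestSdtConfidenceRegions:
    def test_masses_match_quadrature(self, rng):
        """CL category masses equal numerical integration of the familiarity
        density over the criterion intervals."""
        m = build_model("SDT", "CL")
        for _ in range(5):
            params = random_params(m, rng)
            for tree in m.trees:
                crit = m.criteria(params, tree.condition)
                mu = params["d_prime"] if tree.stimulus == "old" else 0.0
                sd = params["sigma"] if tree.stimulus == "old" else 1.0
                edges = np.concatenate([[-np.inf], crit, [np.inf]])
                p = category_probabilities(m, params, tree)
                # category order: old high/med/low, new high/med/low;
                # regions run new-high..old-high from the left
                region_to_cat = ["new:high", "new:medium", "new:low",
                                 "old:low", "old:medium", "old:high"]
                index = {c: i for i, c in enumerate(tree.categories)}
                for k, cat in enumerate(region_to_cat):
                    val, _ = quad(norm(mu, sd).pdf, edges[k], edges[k + 1])
                    assert abs(p[index[cat]] - val) < 1e-8

    def test_criteria_ordered(self, rng):
        m = build_model("SDT", "CL")
        params = random_params(m, rng)
        for j in range(m.n_conditions):
            crit = m.criteria(params, j)
            assert np.all(np.diff(crit) >= 0)


class TestSerialization:
    def test_json_round_trip_is_exact(self, any_model):
        assert ModelSpec.from_json(any_model.to_json()) == any_model

    def test_yaml_round_trip_is_exact(self, any_model):
        assert ModelSpec.from_yaml(any_model.to_yaml()) == any_model
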