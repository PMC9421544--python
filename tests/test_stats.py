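import numpy as np
import pytest

import oracles
from restconn import (
    auc_over_densities,
    demographic_tests,
    fdr_correct_joint,
    nbs,
    nodal_test_suite,
    partial_correlation_perm,
    permutation_ttest,
)
from restconn.stats import (
    chi_square_2x2,
    permutation_schedule,
    permutation_ttest_matrix,
    two_sample_t_from_summary,
)
from restconn.types import ValidationError


class TestAUC:
    def test_constant_curve(self):
        d = np.round(np.arange(0.10, 0.41, 0.01), 10)
        assert auc_over_densities(d, np.full(31, 2.0)) == pytest.approx(0.60)

    def test_linear_curve_exact(self):
        d = np.round(np.arange(0.10, 0.41, 0.01), 10)
        assert auc_over_densities(d, d) == pytest.approx(0.075)

    def test_single_interval(self):
        assert auc_over_densities([0.1, 0.4], [0.0, 1.0]) == pytest.approx(0.15)

    def test_nan_errors_with_density_named(self):
        with pytest.raises(ValidationError, match="0.2"):
            auc_over_densities([0.1, 0.2, 0.3], [0.0, np.nan, 1.0])


class TestPermutationTTest:
    def test_identical_groups_null_result(self):
        values = np.tile([1.0, 2.0, 3.0], 4)
        groups = np.repeat([0, 1], 6)
        t, p = permutation_ttest(values, groups, n_perm=99, seed=0)
        assert t == 0.0
        assert p == 1.0

    def test_p_lower_bound(self, rng):
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10)])
        groups = np.repeat([0, 1], 10)
        _, p = permutation_ttest(values, groups, n_perm=99, seed=1)
        assert p >= 1 / 100

    def test_type_i_error_calibrated(self, rng):
        """Null rejection rate at alpha=.05 over 500 replicates, B=999."""
        n_rep, n = 500, 57
        groups = np.repeat([0, 1], [28, 29])
        values = rng.standard_normal((n, n_rep))
        ages = rng.standard_normal(n)
        # replicates share one schedule: each column is an independent null
        _, p = permutation_ttest_matrix(values, groups, ages, n_perm=999, seed=5)
        rate = (p <= 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_power_at_one_sd_shift(self, rng):
        n_rep = 200
        groups = np.repeat([0, 1], [28, 29])
        values = rng.standard_normal((57, n_rep))
        values[groups == 1] += 1.0
        _, p = permutation_ttest_matrix(values, groups, None, n_perm=999, seed=6)
        assert (p <= 0.05).mean() > 0.9

    def test_shared_schedule_is_deterministic(self):
        a = permutation_schedule(20, 50, 7)
        b = permutation_schedule(20, 50, 7)
        assert np.array_equal(a, b)

    def test_nuisance_covariate_absorbs_confound(self, rng):
        # group difference entirely explained by age: residual test is null
        groups = np.repeat([0, 1], [30, 30])
        age = rng.standard_normal(60) + 2.0 * groups
        values = 3.0 * age + rng.standard_normal(60) * 0.5
        _, p_adj = permutation_ttest(values, groups, age, n_perm=999, seed=8)
        _, p_raw = permutation_ttest(values, groups, None, n_perm=999, seed=8)
        assert p_raw < 0.01
        assert p_adj > 0.05


class TestFDR:
    def test_stepup_examples(self):
        q, flags = fdr_correct_joint(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert flags.all()
        _, flags = fdr_correct_joint(np.ones(5), q=0.05)
        assert not flags.any()

    def test_matches_stepup_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(0.001, 1.0, size=int(rng.integers(3, 40)))
            _, flags = fdr_correct_joint(p, q=0.05)
            assert np.array_equal(flags, oracles.bh_stepup_oracle(p, 0.05))

    def test_flags_monotone_in_q(self, rng):
        p = rng.uniform(0.0001, 1.0, 50)
        _, strict = fdr_correct_joint(p, q=0.01)
        _, loose = fdr_correct_joint(p, q=0.05)
        assert np.all(loose[strict])

    def test_empty_input_errors(self):
        with pytest.raises(ValidationError):
            fdr_correct_joint(np.array([]))


class TestNodalSuite:
    def test_row_count_and_joint_family(self, rng):
        tables = {m: rng.standard_normal((20, 7)) for m in ("pc", "pc_norm", "wmz")}
        groups = np.repeat([0, 1], 10)
        out = nodal_test_suite(tables, groups, None, n_perm=199, seed=0)
        assert len(out) == 7 * 3
        assert set(out["measure"]) == {"pc", "pc_norm", "wmz"}
        assert (out["q"] >= out["p"] - 1e-12).all()


class TestNBS:
    def _stack(self, rng, n_sub, n_nodes, effect_edges=None, delta=0.0):
        stack = rng.standard_normal((n_sub, n_nodes, n_nodes)) * 0.2
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        for s in range(n_sub):
            np.fill_diagonal(stack[s], 0.0)
        if effect_edges is not None:
            for i, j in effect_edges:
                stack[:, i, j] += delta
                stack[:, j, i] += delta
        return stack

    def test_threshold_above_max_t_gives_empty_result(self, rng):
        stack = self._stack(rng, 20, 8)
        groups = np.repeat([0, 1], 10)
        res = nbs(stack, groups, t_init=50.0, n_perm=49, seed=0)
        assert res.components == []

    def test_planted_component_recovery(self, rng):
        # 10-edge path component among nodes 0..10 shifted in group B
        effect = [(i, i + 1) for i in range(10)]
        stack = self._stack(rng, 40, 15)
        groups = np.repeat([0, 1], 20)
        for i, j in effect:
            stack[groups == 1, i, j] += 1.0
            stack[groups == 1, j, i] += 1.0
        res = nbs(stack, groups, t_init=3.0, n_perm=499, seed=1)
        assert res.components, "planted component not found"
        best = max(range(len(res.components)), key=lambda k: res.sizes[k])
        assert res.fwe_p[best] < 0.05
        found = {tuple(sorted(e)) for e in res.components[best]}
        planted = {tuple(sorted(e)) for e in effect}
        jaccard = len(found & planted) / len(found | planted)
        assert jaccard >= 0.8

    def test_invariant_under_node_relabeling(self, rng):
        effect = [(0, 1), (1, 2), (2, 3)]
        stack = self._stack(rng, 30, 10)
        groups = np.repeat([0, 1], 15)
        for i, j in effect:
            stack[groups == 1, i, j] += 1.2
            stack[groups == 1, j, i] += 1.2
        perm = rng.permutation(10)
        stack_perm = stack[:, perm][:, :, perm]
        res1 = nbs(stack, groups, t_init=3.0, n_perm=99, seed=2)
        res2 = nbs(stack_perm, groups, t_init=3.0, n_perm=99, seed=2)
        assert sorted(res1.sizes) == sorted(res2.sizes)
        inv = np.argsort(perm)
        # permuted node i holds original node perm[i], so original node a
        # appears at permuted index inv[a]
        remapped = {
            frozenset(tuple(sorted((int(inv[a]), int(inv[b])))) for a, b in comp)
            for comp in res1.components
        }
        found = {
            frozenset(tuple(sorted((int(a), int(b)))) for a, b in comp)
            for comp in res2.components
        }
        assert remapped == found

    def test_invalid_threshold_errors(self, rng):
        stack = self._stack(rng, 10, 5)
        with pytest.raises(ValidationError):
            nbs(stack, np.repeat([0, 1], 5), t_init=0.0, n_perm=9)


class TestPartialCorrelation:
    def test_constant_covariate_equals_plain_pearson(self, rng):
        x = rng.standard_normal((15, 1))
        y = 0.5 * x[:, 0] + rng.standard_normal(15)
        r, _ = partial_correlation_perm(x, y, np.ones((15, 1)), n_perm=99, seed=0)
        assert r[0] == pytest.approx(np.corrcoef(x[:, 0], y)[0, 1], abs=1e-12)

    def test_matches_residualize_then_correlate_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0]).reshape(-1, 1)
        y = np.array([1.0, 2.0, 3.0, 5.0])
        z = np.array([1.0, 1.0, 2.0, 2.0]).reshape(-1, 1)
        design = np.column_stack([np.ones(4), z[:, 0] - z.mean()])
        rx = x[:, 0] - design @ np.linalg.lstsq(design, x[:, 0], rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        expected = np.corrcoef(rx, ry)[0, 1]
        r, _ = partial_correlation_perm(x, y, z, n_perm=23, seed=1)
        assert r[0] == pytest.approx(expected, abs=1e-12)

    def test_too_few_subjects_error(self):
        with pytest.raises(ValidationError):
            partial_correlation_perm(np.ones((3, 1)), np.ones(3), None)


class TestDemographics:
    def test_gender_chi_square_matches_printed_value(self):
        chi2, p = chi_square_2x2([[13, 15], [14, 15]])
        assert chi2 == pytest.approx(0.020, abs=1e-3)
        assert p == pytest.approx(0.889, abs=1e-3)

    def test_age_t_from_summary_matches_printed_p(self):
        t, p = two_sample_t_from_summary(11.91, 1.39, 29, 10.92, 1.55, 28)
        assert t == pytest.approx(2.546, abs=0.01)
        assert p == pytest.approx(0.014, abs=1e-3)

    def test_identical_proportions_give_zero_chi2(self):
        chi2, _ = chi_square_2x2([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_table_builder(self):
        rows = [
            {"variable": "age", "kind": "continuous", "mean1": 11.91, "sd1": 1.39,
             "n1": 29, "mean2": 10.92, "sd2": 1.55, "n2": 28},
            {"variable": "gender", "kind": "categorical",
             "counts": [[13, 15], [14, 15]]},
        ]
        table = demographic_tests(rows)
        assert list(table["test"]) == ["t", "chi2"]
        assert (table["p"] <= 1).all()
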