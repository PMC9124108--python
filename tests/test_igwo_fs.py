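import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwanfis import AbhcConfig, GWOConfig, WrapperConfig, run_igwo_fs
from gwanfis.exceptions import InvalidConfigError, InvalidInputError
from gwanfis.igwo_fs import (
    abhc_bandwidth,
    abhc_refine,
    binarize,
    coefficient_b,
    leader_update,
    sample_coefficients,
    subset_fitness,
)


class TestCoefficientSchedule:
    @pytest.mark.parametrize("u, m, expected", [(0, 100, 2.0), (100, 100, 0.0), (50, 100, 1.0)])
    def test_linear_endpoints_and_midpoint(self, u, m, expected):
        assert coefficient_b(u, m) == pytest.approx(expected)

    def test_zero_budget_rejected(self):
        with pytest.raises(InvalidConfigError):
            coefficient_b(0, 0)

    @given(st.integers(1, 1000))
    @settings(max_examples=25, derandomize=True)
    def test_monotone_non_increasing(self, m):
        vals = [coefficient_b(u, m) for u in range(m + 1)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestSampleCoefficients:
    def test_component_ranges(self, rng):
        for b in (0.0, 0.5, 2.0):
            a, c = sample_coefficients(b, rng, dim=200)
            assert np.all(np.abs(a) <= b + 1e-12)
            assert np.all((c >= 0) & (c <= 2))

    def test_zero_b_gives_zero_attack(self, rng):
        a, _ = sample_coefficients(0.0, rng, dim=10)
        np.testing.assert_array_equal(a, 0.0)


class TestLeaderUpdate:
    def test_hand_traced_scalar_case(self):
        # X=0.5, leaders at 0.8, C=1, A=0.5 -> D=0.3, candidates 0.65, mean 0.65
        class FixedRng:
            def uniform(self, size=None):
                # s1 such that A = 2*b*s1 - b = 0.5 with b = 1 -> s1 = 0.75;
                # s2 such that C = 2*s2 = 1 -> s2 = 0.5; alternating calls
                self.calls = getattr(self, "calls", 0) + 1
                return np.full(size, 0.75 if self.calls % 2 == 1 else 0.5)

        x = np.array([0.5])
        leaders = [np.array([0.8])] * 3
        out = leader_update(x, leaders, b=1.0, rng=FixedRng())
        assert out[0] == pytest.approx(0.65)

    def test_zero_attack_gives_leader_mean(self, rng):
        leaders = [np.full(4, v) for v in (0.2, 0.4, 0.9)]
        out = leader_update(np.full(4, 0.5), leaders, b=0.0, rng=rng)
        np.testing.assert_allclose(out, (0.2 + 0.4 + 0.9) / 3)

    def test_fixed_point_at_shared_position(self, rng):
        x = np.full(6, 0.5)
        out = leader_update(x, [x.copy()] * 3, b=0.0, rng=rng)
        np.testing.assert_allclose(out, x)

    def test_clipped_to_unit_cube(self, rng):
        for _ in range(20):
            out = leader_update(
                rng.uniform(size=10), [rng.uniform(size=10) for _ in range(3)],
                b=2.0, rng=rng,
            )
            assert np.all((out >= 0) & (out <= 1))

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(Exception):
            leader_update(np.zeros(3), [np.zeros(4)] * 3, 1.0, rng)


class TestBinarize:
    def test_threshold_semantics(self):
        np.testing.assert_array_equal(
            binarize(np.array([0.2, 0.7, 0.5]), 0.5), [False, True, False]
        )

    def test_all_above(self):
        assert binarize(np.full(5, 0.9), 0.5).all()

    def test_empty_mask_repaired_to_argmax(self):
        mask = binarize(np.array([0.1, 0.3, 0.2]), 0.5)
        np.testing.assert_array_equal(mask, [False, True, False])


class TestSubsetFitness:
    def test_weighted_combination(self, separable_dataset):
        # full mask: parsimony term is 0 so fitness = 0.9 * quality
        full = np.ones(separable_dataset.n_genes, dtype=bool)
        sub = subset_fitness(full, separable_dataset)
        assert sub.fitness == pytest.approx(0.9 * sub.quality)

    def test_parsimony_reward_arithmetic(self, separable_dataset):
        # single perfectly separating gene: quality 1 and |S|=1 of |D|=20
        mask = np.zeros(separable_dataset.n_genes, dtype=bool)
        mask[0] = True
        sub = subset_fitness(mask, separable_dataset)
        assert sub.quality == pytest.approx(1.0)
        assert sub.fitness == pytest.approx(0.9 * 1.0 + 0.1 * (19 / 20))

    def test_alpha_one_equals_accuracy(self, separable_dataset):
        mask = np.zeros(separable_dataset.n_genes, dtype=bool)
        mask[:3] = True
        sub = subset_fitness(mask, separable_dataset, alpha_weight=1.0, beta_weight=0.0)
        assert sub.fitness == pytest.approx(sub.quality)

    def test_empty_mask_rejected(self, separable_dataset):
        with pytest.raises(InvalidInputError):
            subset_fitness(np.zeros(separable_dataset.n_genes, dtype=bool),
                           separable_dataset)

    def test_fitness_in_unit_interval(self, separable_dataset, rng):
        for _ in range(5):
            mask = rng.uniform(size=separable_dataset.n_genes) > 0.5
            if not mask.any():
                continue
            sub = subset_fitness(mask, separable_dataset)
            assert 0.0 <= sub.fitness <= 1.0


class TestAbhcBandwidth:
    @pytest.mark.parametrize("t, K, m, expected", [
        (0, 4, 100, 1.0),
        (100, 4, 100, 0.0),
        (50, 1, 100, 0.5),
    ])
    def test_schedule_values(self, t, K, m, expected):
        assert abhc_bandwidth(t, K, m) == pytest.approx(expected)

    @given(st.floats(1.0, 10.0), st.integers(1, 500))
    @settings(max_examples=25, derandomize=True)
    def test_monotone_and_bounded(self, K, m):
        vals = [abhc_bandwidth(t, K, m) for t in range(m + 1)]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_zero_maxiter_rejected(self):
        with pytest.raises(InvalidConfigError):
            abhc_bandwidth(0, 4, 0)


class TestAbhcRefine:
    def test_no_perturbation_at_schedule_end(self, rng):
        x = np.array([0.3, 0.6])
        cfg = AbhcConfig(K=2.0, beta_rate=0.0, inner_iters=10)
        out, _ = abhc_refine(x, lambda v: float(-np.sum(v)), cfg, t=50, maxiter=50, rng=rng)
        np.testing.assert_array_equal(out, x)

    def test_greedy_never_worsens(self, rng):
        def f(v):
            return float(-np.sum((v - 0.3) ** 2))

        x = rng.uniform(size=8)
        fx = f(x)
        cfg = AbhcConfig(K=2.0, beta_rate=0.1, inner_iters=50)
        _, f_out = abhc_refine(x, f, cfg, t=0, maxiter=1, rng=rng)
        assert f_out >= fx

    def test_converges_on_smooth_1d_objective(self):
        # seeded oracle: maximize 1 - (x - 0.6)^2 from x = 0.1
        rng = np.random.default_rng(0)
        cfg = AbhcConfig(K=2.0, beta_rate=0.05, inner_iters=200)
        out, _ = abhc_refine(
            np.array([0.1]), lambda v: float(1 - (v[0] - 0.6) ** 2),
            cfg, t=0, maxiter=1, rng=rng,
        )
        assert abs(out[0] - 0.6) < 0.05

    def test_output_stays_in_unit_cube(self, rng):
        cfg = AbhcConfig(K=2.0, beta_rate=0.5, inner_iters=40)
        out, _ = abhc_refine(
            rng.uniform(size=12), lambda v: float(np.sum(v)), cfg,
            t=0, maxiter=1, rng=rng,
        )
        assert np.all((out >= 0) & (out <= 1))


class TestRunIgwoFs:
    def test_recovers_perfectly_separating_gene(self, separable_dataset):
        subset, _ = run_igwo_fs(
            separable_dataset,
            GWOConfig(pack_size=8, max_iter=20, seed=5),
            AbhcConfig(inner_iters=15),
        )
        assert subset.mask[0]

    def test_zero_iterations_returns_initial_best(self, separable_dataset):
        subset, history = run_igwo_fs(
            separable_dataset,
            GWOConfig(pack_size=4, max_iter=0, seed=1),
            AbhcConfig(),
        )
        assert len(history["best_fitness_per_iter"]) == 1
        assert subset.n_selected >= 1

    def test_deterministic_given_seed(self, separable_dataset):
        cfg = GWOConfig(pack_size=6, max_iter=8, seed=9)
        a_sub, a_hist = run_igwo_fs(separable_dataset, cfg, AbhcConfig(inner_iters=10))
        b_sub, b_hist = run_igwo_fs(separable_dataset, cfg, AbhcConfig(inner_iters=10))
        assert np.array_equal(a_sub.mask, b_sub.mask)
        assert a_hist["best_fitness_per_iter"] == b_hist["best_fitness_per_iter"]

    def test_best_trace_monotone(self, separable_dataset):
        _, history = run_igwo_fs(
            separable_dataset,
            GWOConfig(pack_size=6, max_iter=15, seed=2),
            AbhcConfig(inner_iters=10),
        )
        trace = history["best_fitness_per_iter"]
        assert all(a <= b for a, b in zip(trace, trace[1:]))

    def test_config_invariants(self):
        with pytest.raises(InvalidConfigError):
            GWOConfig(pack_size=3)
        with pytest.raises(InvalidConfigError):
            GWOConfig(alpha_weight=0.9, beta_weight=0.2)

    def test_wrapper_needs_enough_samples(self, separable_dataset):
        with pytest.raises(InvalidInputError):
            tiny = separable_dataset.select_samples(np.array([0, 1, 2]))
            run_igwo_fs(tiny, GWOConfig(pack_size=4, max_iter=1, seed=0),
                        AbhcConfig(), WrapperConfig(cv_folds=3))
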