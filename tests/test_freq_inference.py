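import math

import numpy as np
import pytest

from lineagetrack.freq_inference import (
    FrequencyEstimate,
    InferenceConfig,
    cell_fractions,
    exclusive_frequencies,
    expected_marker_freq,
    grid_search_max_loglik,
    infer_frequencies_at_t,
    infer_trajectories,
    log_likelihood,
)

from .conftest import manual_model, single_sample_counts


class TestExpectedMarkerFreq:
    def test_is_the_product(self):
        assert expected_marker_freq(0.6, 0.5, 0.001) == pytest.approx(0.30)

    def test_floor_at_zero_frequency(self):
        assert expected_marker_freq(0.0, 1.0, 0.001) == 0.001

    def test_ceiling_at_fixation(self):
        assert expected_marker_freq(1.0, 1.0, 0.001) == pytest.approx(0.999)


class TestLogLikelihood:
    def test_single_marker_matches_exact_binomial(self):
        model = manual_model({"P": None}, {"P": [(0, 1.0)]})
        counts = single_sample_counts([(30, 100)])
        ll = log_likelihood(
            {"P": 0.3}, model, counts, "meta", InferenceConfig(epsilon=1e-12)
        )
        exact = (
            math.log(math.comb(100, 30)) + 30 * math.log(0.3) + 70 * math.log(0.7)
        )
        assert exact == pytest.approx(-2.444334564532987, abs=1e-12)
        assert ll == pytest.approx(exact, abs=1e-9)

    def test_boundary_frequency_is_finite(self):
        model = manual_model({"P": None}, {"P": [(0, 1.0)]})
        counts = single_sample_counts([(0, 100)])
        ll = log_likelihood({"P": 1.0}, model, counts, "meta")
        assert np.isfinite(ll)

    def test_depth_gate_skips_thin_markers(self):
        model = manual_model({"P": None}, {"P": [(0, 1.0), (1, 1.0)]})
        counts = single_sample_counts([(3, 5), (30, 100)])
        cfg = InferenceConfig(min_marker_depth=10, epsilon=1e-12)
        ll = log_likelihood({"P": 0.3}, model, counts, "meta", cfg)
        only_deep = log_likelihood(
            {"P": 0.3},
            manual_model({"P": None}, {"P": [(0, 1.0)]}),
            single_sample_counts([(30, 100)]),
            "meta",
            cfg,
        )
        assert ll == pytest.approx(only_deep)


class TestInferAtOneTimepoint:
    def test_pooled_mle_full_copy_markers(self):
        model = manual_model({"P": None}, {"P": [(0, 1.0), (1, 1.0), (2, 1.0)]})
        counts = single_sample_counts([(30, 100), (28, 100), (32, 100)])
        est = infer_frequencies_at_t(
            model, counts, "meta", 0.0, InferenceConfig(epsilon=1e-9)
        )
        assert est.inclusive["P"] == pytest.approx(0.300, abs=1e-3)
        assert est.converged

    def test_pooled_mle_half_copy_markers(self):
        model = manual_model({"P": None}, {"P": [(0, 0.5), (1, 0.5)]})
        counts = single_sample_counts([(20, 100), (20, 100)])
        est = infer_frequencies_at_t(
            model, counts, "meta", 0.0, InferenceConfig(epsilon=1e-9)
        )
        assert est.inclusive["P"] == pytest.approx(0.400, abs=1e-3)

    def test_parent_child_constraint_binds_at_shared_optimum(self):
        # parent markers pool at 0.20, child at 0.30: the unconstrained
        # optimum is infeasible (child > parent), so both meet near 0.25
        model = manual_model(
            {"P": None, "C": "P"},
            {"P": [(0, 1.0), (1, 1.0)], "C": [(2, 1.0), (3, 1.0)]},
        )
        counts = single_sample_counts([(20, 100), (20, 100), (30, 100), (30, 100)])
        cfg = InferenceConfig(epsilon=1e-9, seed=4)
        est = infer_frequencies_at_t(model, counts, "meta", 0.0, cfg)
        assert est.inclusive["C"] == pytest.approx(est.inclusive["P"], abs=2e-3)
        assert est.inclusive["P"] == pytest.approx(0.25, abs=5e-3)
        grid_ll, grid_f = grid_search_max_loglik(model, counts, "meta", config=cfg)
        assert est.loglik >= grid_ll - 1e-3
        assert est.inclusive["P"] == pytest.approx(grid_f["P"], abs=0.005)

    def test_scaling_depth_preserves_argmax(self):
        model = manual_model({"P": None}, {"P": [(0, 1.0), (1, 1.0), (2, 1.0)]})
        cfg = InferenceConfig(epsilon=1e-9)
        c1 = single_sample_counts([(30, 100), (28, 100), (32, 100)])
        c2 = single_sample_counts([(60, 200), (56, 200), (64, 200)])
        e1 = infer_frequencies_at_t(model, c1, "meta", 0.0, cfg)
        e2 = infer_frequencies_at_t(model, c2, "meta", 0.0, cfg)
        assert e1.inclusive["P"] == pytest.approx(e2.inclusive["P"], abs=1e-3)

    def test_no_usable_markers_names_the_timepoint(self):
        model = manual_model({"P": None}, {"P": [(0, 1.0)]})
        counts = single_sample_counts([(0, 3)])  # below depth gate
        with pytest.raises(ValueError, match="42"):
            infer_frequencies_at_t(model, counts, "meta", 42.0)

    def test_estimates_satisfy_nesting_invariants(self):
        from lineagetrack.simulator import (
            SimConfig,
            sample_metagenome_series,
            simulate_truth,
            truth_lineage_model,
        )

        truth = simulate_truth(SimConfig(seed=31, n_timepoints=4))
        model = truth_lineage_model(truth)
        vm, pairs = sample_metagenome_series(truth)
        for est in infer_trajectories(model, vm, pairs, InferenceConfig(seed=1)):
            excl, r = exclusive_frequencies(est)
            assert all(v >= 0 for v in excl.values()) and r >= 0
            assert sum(excl.values()) + r == pytest.approx(1.0, abs=1e-6)


class TestTrajectories:
    def test_timepoint_order_invariance(self):
        model = manual_model({"P": None}, {"P": [(0, 1.0)]})
        import numpy as np

        from lineagetrack.io_formats import VariantMatrix
        from .conftest import make_sites

        vm = VariantMatrix(
            make_sites(1), ["m0", "m1"], np.array([[30, 60]]), np.array([[100, 100]])
        )
        fwd = infer_trajectories(model, vm, [(0.0, "m0"), (1.0, "m1")])
        rev = infer_trajectories(model, vm, [(1.0, "m1"), (0.0, "m0")])
        assert [e.inclusive for e in fwd] == [e.inclusive for e in rev]

    def test_invasion_crossing_time_recovered(self):
        from lineagetrack.simulator import (
            SimConfig,
            sample_metagenome_series,
            simulate_truth,
            truth_lineage_model,
        )

        cfg = SimConfig(
            seed=13,
            n_lineages=4,
            n_top=2,
            n_invaders=1,
            fitness=[0.0, 1.0, 0.0, 0.0],  # T1 is the sweeping invader
            invasion_freq=0.02,
            background_sites=100,
        )
        truth = simulate_truth(cfg)
        incl_true = truth.inclusive_traj()[:, truth.lineage_index("T1")]
        assert incl_true[0] == 0.0 and incl_true[-1] > 0.5  # it does sweep
        model = truth_lineage_model(truth)
        vm, pairs = sample_metagenome_series(truth)
        ests = infer_trajectories(model, vm, pairs, InferenceConfig(seed=2))
        incl_hat = np.array([e.inclusive["T1"] for e in ests])
        cross_true = int(np.argmax(incl_true > 0.5))
        cross_hat = int(np.argmax(incl_hat > 0.5))
        assert abs(cross_true - cross_hat) <= 1

    def test_constant_truth_fluctuations_match_binomial_scale(self):
        from lineagetrack.simulator import (
            SimConfig,
            sample_metagenome_series,
            simulate_truth,
            truth_lineage_model,
        )

        cfg = SimConfig(
            seed=17,
            n_lineages=2,
            n_top=2,
            n_invaders=0,
            fitness=[0.0, 0.0],
            background_sites=0,
            n_timepoints=20,
        )
        truth = simulate_truth(cfg)
        model = truth_lineage_model(truth)
        vm, pairs = sample_metagenome_series(truth)
        ests = infer_trajectories(model, vm, pairs, InferenceConfig(seed=3))
        for lid in truth.lineage_ids:
            f_true = truth.inclusive_traj()[0, truth.lineage_index(lid)]
            errs = np.array([e.inclusive[lid] for e in ests]) - f_true
            gs = np.array([g for _, g in truth.markers[lid]])
            dg = cfg.metagenome_depth * gs
            analytic_sd = math.sqrt(
                float(np.sum(dg * gs * f_true * (1 - gs * f_true)))
                / float(np.sum(dg * gs)) ** 2
            ) if np.sum(dg * gs) > 0 else 0.0
            assert np.std(errs) < 3 * analytic_sd + 1e-3
            assert abs(np.mean(errs)) < 3 * analytic_sd + 1e-3


class TestExclusiveFrequencies:
    def _est(self, inclusive, children):
        return FrequencyEstimate(0.0, inclusive, children, 0.0, True, 1)

    def test_root_and_child(self):
        est = self._est({"R": 1.0, "C": 0.4}, {"": ["R"], "R": ["C"], "C": []})
        excl, r = exclusive_frequencies(est)
        assert excl == {"R": pytest.approx(0.6), "C": pytest.approx(0.4)}
        assert r == pytest.approx(0.0)

    def test_empty_population_is_all_residual(self):
        est = self._est({"R": 0.0}, {"": ["R"], "R": []})
        _, r = exclusive_frequencies(est)
        assert r == pytest.approx(1.0)

    def test_three_level_chain(self):
        est = self._est(
            {"A": 0.9, "B": 0.5, "C": 0.2},
            {"": ["A"], "A": ["B"], "B": ["C"], "C": []},
        )
        excl, r = exclusive_frequencies(est)
        assert excl["A"] == pytest.approx(0.4)
        assert excl["B"] == pytest.approx(0.3)
        assert excl["C"] == pytest.approx(0.2)
        assert r == pytest.approx(0.1)

    def test_violation_beyond_tolerance_raises(self):
        est = self._est({"P": 0.2, "C": 0.4}, {"": ["P"], "P": ["C"], "C": []})
        with pytest.raises(ValueError, match="exceed"):
            est.exclusive()

    def test_cell_fraction_conversion(self):
        est = self._est(
            {"D": 0.4, "T": 0.6}, {"": ["D", "T"], "D": [], "T": []}
        )
        cells, cr = cell_fractions(est, {"D": 2, "T": 3}, residual_ploidy=2.0)
        # 0.4/2 : 0.6/3 : 0/2 -> 0.2 : 0.2 -> 50/50
        assert cells["D"] == pytest.approx(0.5)
        assert cells["T"] == pytest.approx(0.5)
        assert cr == pytest.approx(0.0)
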