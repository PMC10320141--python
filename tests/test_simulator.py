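import numpy as np
import pytest

from lineagetrack.simulator import (
    ConfigError,
    SimConfig,
    add_unmodeled_lineage,
    clone_tree,
    rarefaction_experiment,
    recovery_rmse,
    sample_clone_set,
    sample_clones,
    sample_metagenome,
    sample_metagenome_series,
    simulate_truth,
    true_ploidy_calls,
    truth_lineage_model,
)


def small_config(**over):
    base = dict(
        seed=1,
        n_lineages=3,
        n_top=2,
        n_invaders=0,
        markers_per_lineage=5,
        background_sites=20,
        n_timepoints=6,
    )
    base.update(over)
    return SimConfig(**base)


class TestSimulateTruth:
    def test_neutral_no_invader_trajectories_are_constant(self):
        truth = simulate_truth(small_config(fitness=[0.0, 0.0, 0.0]))
        assert np.allclose(truth.exclusive_traj, truth.exclusive_traj[0])

    def test_two_lineage_selection_closed_form(self):
        cfg = SimConfig(
            seed=2,
            n_lineages=2,
            n_top=2,
            n_invaders=0,
            fitness=[0.0, 0.5],
            initial_residual=0.0,
            markers_per_lineage=3,
            background_sites=0,
            n_timepoints=10,
        )
        truth = simulate_truth(cfg)
        e = truth.exclusive_traj
        ratio = e[:, 1] / e[:, 0]
        # logistic competition: the frequency ratio grows by exp(s) per step
        np.testing.assert_allclose(ratio[1:] / ratio[:-1], np.exp(0.5), rtol=1e-9)

    def test_same_seed_reproduces_truth_exactly(self):
        t1 = simulate_truth(small_config())
        t2 = simulate_truth(small_config())
        assert t1.ploidy == t2.ploidy
        assert t1.markers == t2.markers
        np.testing.assert_array_equal(t1.exclusive_traj, t2.exclusive_traj)

    def test_nesting_invariant_holds_at_every_timepoint(self):
        truth = simulate_truth(SimConfig(seed=9))
        incl = truth.inclusive_traj()
        for lid in truth.lineage_ids:
            j = truth.lineage_index(lid)
            kids = truth.children_of(lid)
            if kids:
                ksum = incl[:, [truth.lineage_index(k) for k in kids]].sum(axis=1)
                assert np.all(ksum <= incl[:, j] + 1e-9)
        assert np.all(truth.residual_traj() >= -1e-9)

    def test_infeasible_invasion_config_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_top=3, n_invaders=2, invasion_freq=0.6)


class TestSampleMetagenome:
    def test_fixed_lineage_markers_saturate_without_error(self):
        cfg = small_config(
            n_lineages=1, n_top=1, initial_residual=0.0, error_rate=0.0,
            background_sites=0,
        )
        truth = simulate_truth(cfg)
        vm = sample_metagenome(truth, 0)
        full = [s for s, g in truth.markers["T0"] if g == 1.0]
        covered = vm.depths[full, 0] > 0
        assert np.array_equal(
            vm.alt_counts[full, 0][covered], vm.depths[full, 0][covered]
        )

    def test_absent_lineage_markers_are_silent(self):
        cfg = small_config(n_invaders=1, error_rate=0.0)
        truth = simulate_truth(cfg)
        invader = [l for l in truth.children_of(None)
                   if truth.exclusive_traj[0, truth.lineage_index(l)] == 0][0]
        vm = sample_metagenome(truth, 0)
        sites = [s for s, _ in truth.markers[invader]]
        assert np.all(vm.alt_counts[sites, 0] == 0)

    def test_replicate_mean_matches_binomial_expectation(self):
        cfg = small_config(error_rate=0.0)
        truth = simulate_truth(cfg)
        lid = truth.children_of(None)[0]
        site, g = truth.markers[lid][0]
        f = truth.inclusive_traj()[2, truth.lineage_index(lid)]
        freqs = []
        for k in range(1000):
            vm = sample_metagenome(truth, 2, seed=k)
            if vm.depths[site, 0] > 0:
                freqs.append(vm.alt_counts[site, 0] / vm.depths[site, 0])
        mean = np.mean(freqs)
        se = np.std(freqs) / np.sqrt(len(freqs))
        assert abs(mean - g * f) < 3 * se + 1e-9

    def test_same_seed_same_counts(self):
        truth = simulate_truth(small_config())
        v1 = sample_metagenome(truth, 1, seed=5)
        v2 = sample_metagenome(truth, 1, seed=5)
        np.testing.assert_array_equal(v1.alt_counts, v2.alt_counts)
        np.testing.assert_array_equal(v1.depths, v2.depths)


class TestSampleClones:
    def test_single_lineage_population_yields_only_that_lineage(self):
        cfg = small_config(n_lineages=1, n_top=1, initial_residual=0.0)
        truth = simulate_truth(cfg)
        _, cmap = sample_clones(truth, 0, 10)
        assert set(cmap.values()) == {"T0"}

    def test_zero_frequency_lineage_never_sampled(self):
        cfg = small_config(n_invaders=1)
        truth = simulate_truth(cfg)
        invader = [l for l in truth.children_of(None)
                   if truth.exclusive_traj[0, truth.lineage_index(l)] == 0][0]
        _, cmap = sample_clones(truth, 0, 50)
        assert invader not in set(cmap.values())

    def test_sampled_proportions_match_exclusive_frequencies(self):
        truth = simulate_truth(small_config(seed=3))
        _, cmap = sample_clones(truth, 3, 2000)
        excl = truth.exclusive_traj[3]
        probs = excl / excl.sum()
        counts = np.array(
            [sum(1 for v in cmap.values() if v == l) for l in truth.lineage_ids]
        )
        obs = counts / counts.sum()
        se = np.sqrt(probs * (1 - probs) / 2000)
        assert np.all(np.abs(obs - probs) <= 3 * se + 1e-9)

    def test_clone_tree_prunes_unsampled_lineages(self):
        truth = simulate_truth(small_config(seed=4))
        cmap = {"a": "T0", "b": "T0", "c": "T1"}
        tree = clone_tree(truth, cmap)
        labels = {l.taxon.label for l in tree.leaf_node_iter()}
        assert labels == {"a", "b", "c"}


class TestTruthModelAndPairing:
    def test_truth_model_passes_synapomorphy_rules(self):
        from lineagetrack.lineage_model import find_synapomorphies

        truth = simulate_truth(small_config(seed=6))
        model = truth_lineage_model(truth)
        for lid, lin in model.lineages.items():
            markers, reason = find_synapomorphies(
                lin.members, model.genotypes, min_markers=1
            )
            assert {(s, g) for s, g in truth.markers[lid]} <= set(markers)

    def test_unmodeled_lineage_preserves_shared_site_draws(self):
        truth = simulate_truth(small_config(seed=8))
        paired = add_unmodeled_lineage(truth, n_markers=5, seed=8)
        n_shared = len(truth.sites)
        v1, _ = sample_metagenome_series(truth, seed=2)
        v2, _ = sample_metagenome_series(paired, seed=2)
        np.testing.assert_array_equal(
            v1.alt_counts, v2.alt_counts[:n_shared]
        )
        np.testing.assert_array_equal(v1.depths, v2.depths[:n_shared])
        # modeled lineages keep their exact trajectories
        np.testing.assert_array_equal(
            truth.exclusive_traj, paired.exclusive_traj[:, :-1]
        )

    def test_rarefaction_full_subsample_equals_full_model(self):
        from lineagetrack.freq_inference import InferenceConfig, infer_trajectories
        from lineagetrack.genotyping import call_genotypes
        from lineagetrack.lineage_model import build_lineage_model
        from lineagetrack.ploidy import call_all_ploidies

        cfg = SimConfig(seed=12, n_timepoints=8, clones_per_timepoint=2)
        truth = simulate_truth(cfg)
        clone_vm, cmap, _ = sample_clone_set(truth)
        meta_vm, pairs = sample_metagenome_series(truth)
        inf = InferenceConfig(seed=7)
        n_all = len(clone_vm.samples)
        table = rarefaction_experiment(
            truth, clone_vm, cmap, meta_vm, pairs, [n_all], seeds=[1],
            inference_config=inf,
        )
        # reference: the same pipeline on all clones
        chosen = sorted(clone_vm.samples)
        calls = call_all_ploidies(clone_vm.take_samples(chosen), chosen)
        geno, _ = call_genotypes(clone_vm.take_samples(chosen), calls)
        model = build_lineage_model(
            clone_tree(truth, {c: cmap[c] for c in geno.clones}), geno, min_markers=5
        )
        ests = infer_trajectories(model, meta_vm, pairs, inf)
        assert table.rmse.iloc[0] == pytest.approx(
            recovery_rmse(ests, model, truth), abs=1e-12
        )
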