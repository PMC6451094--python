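"""Generator tests: state paths, traces, populations, beads, survival."""

import numpy as np
import pytest

from smfret.config import ConfigurationError, SimulationConfig, linear_chain_matrix
from smfret import simulate as sim
from smfret.imaging import ChannelMap
from smfret.workflows import subpopulation_mixture


class TestStatePath:
    def test_absorbing_identity_matrix_gives_constant_path(self):
        cfg = SimulationConfig(
            n_molecules=3, n_frames=100, seed=1,
            emission_states=((0.2, 0.05), (0.7, 0.05)),
            transition_matrix=np.eye(2),
        )
        path = sim.generate_state_path(cfg, 0)
        assert len(set(path.tolist())) == 1

    def test_linear_chain_forbids_direct_outer_transitions(self, three_state_chain):
        cfg = SimulationConfig(n_molecules=1, n_frames=20000, seed=2,
                               transition_matrix=three_state_chain)
        path = sim.generate_state_path(cfg, 0)
        pairs = set(zip(path[:-1].tolist(), path[1:].tolist()))
        assert (0, 2) not in pairs and (2, 0) not in pairs

    def test_two_state_switch_frequency_matches_probability(self):
        p = 0.1
        cfg = SimulationConfig(
            n_molecules=1, n_frames=100_000, seed=3,
            emission_states=((0.2, 0.05), (0.7, 0.05)),
            transition_matrix=np.array([[1 - p, p], [p, 1 - p]]),
        )
        path = sim.generate_state_path(cfg, 0)
        freq = float(np.mean(path[:-1] != path[1:]))
        assert freq == pytest.approx(p, abs=0.005)

    def test_static_molecule_returns_constant_path(self):
        cfg = SimulationConfig(n_molecules=1, n_frames=500, seed=4,
                               static_fraction=1.0)
        path = sim.generate_state_path(cfg, 0)
        assert np.all(path == path[0])

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(
                emission_states=((0.2, 0.05), (0.7, 0.05)),
                transition_matrix=np.array([[0.8, 0.1], [0.1, 0.9]]),
            )

    def test_empirical_transition_frequencies_match_matrix(self, three_state_chain):
        """Per-cell agreement within 3 binomial SE on a long dynamic path."""
        cfg = SimulationConfig(n_molecules=1, n_frames=50_000, seed=5,
                               transition_matrix=three_state_chain)
        path = sim.generate_state_path(cfg, 0)
        for i in range(3):
            mask = path[:-1] == i
            n_i = int(mask.sum())
            for j in range(3):
                p_ij = three_state_chain[i, j]
                obs = float(np.mean(path[1:][mask] == j))
                se = np.sqrt(max(p_ij * (1 - p_ij), 1e-12) / n_i)
                assert abs(obs - p_ij) < max(3 * se, 1e-9), (i, j)


class TestTrace:
    def test_noiseless_proximity_ratio_equals_apparent_e(self, noiseless_config):
        cfg = noiseless_config.with_overrides(
            emission_states=((0.25, 0.0),), transition_matrix=np.eye(1))
        path = np.zeros(cfg.n_frames, dtype=int)
        trace, truth = sim.generate_trace(cfg, path, 0)
        ratio = trace.acceptor / (trace.acceptor + trace.donor)
        np.testing.assert_allclose(ratio, 0.25, atol=1e-12)
        np.testing.assert_allclose(ratio, truth.apparent_e, atol=1e-12)

    def test_noiseless_ratio_equals_drawn_e_with_state_width(self, noiseless_config):
        """Exact inversion holds frame-by-frame even with emission spread."""
        path = np.zeros(noiseless_config.n_frames, dtype=int)
        trace, truth = sim.generate_trace(noiseless_config, path, 1)
        ratio = trace.acceptor / (trace.acceptor + trace.donor)
        np.testing.assert_allclose(ratio, truth.apparent_e, atol=1e-10)

    def test_acceptor_bleach_raises_donor_in_single_step(self, noiseless_config):
        cfg = noiseless_config.with_overrides(
            bleach_rate_acceptor=2.0, n_frames=300,
            emission_states=((0.5, 0.0),), transition_matrix=np.eye(1))
        for idx in range(10):
            path = np.zeros(cfg.n_frames, dtype=int)
            trace, truth = sim.generate_trace(cfg, path, idx)
            fa = truth.acceptor_bleach_frame
            if fa is None or fa < 2 or fa > cfg.n_frames - 2:
                continue
            assert trace.donor[fa] > trace.donor[fa - 1]
            assert trace.donor[fa] == pytest.approx(cfg.total_intensity)
            assert trace.acceptor[fa] == pytest.approx(0.0)
            break
        else:
            pytest.fail("no usable bleach event drawn")

    def test_crosstalk_gamma_forward_model_hand_value(self):
        # E=0.5, total=100, alpha=0.1, gamma=0.8:
        # I_D = 50, I_A = 0.8*50 = 40, acceptor channel = 40 + 0.1*50 = 45
        cfg = SimulationConfig(
            n_molecules=1, n_frames=10, seed=0,
            emission_states=((0.5, 0.0),), transition_matrix=np.eye(1),
            total_intensity=100.0, crosstalk_alpha=0.1, gamma=0.8,
            background=(0.0, 0.0), noise_model="gaussian_read",
            read_noise_sd=0.0, bleach_rate_donor=0.0, bleach_rate_acceptor=0.0,
        )
        trace, _ = sim.generate_trace(cfg, np.zeros(10, dtype=int), 0)
        np.testing.assert_allclose(trace.donor, 50.0)
        np.testing.assert_allclose(trace.acceptor, 45.0)

    def test_donor_bleach_drops_both_channels_to_background(self, noiseless_config):
        cfg = noiseless_config.with_overrides(
            bleach_rate_donor=5.0, background=(7.0, 11.0), n_frames=300)
        for idx in range(10):
            path = np.zeros(cfg.n_frames, dtype=int)
            trace, truth = sim.generate_trace(cfg, path, idx)
            fd = truth.donor_bleach_frame
            fa = truth.acceptor_bleach_frame
            if fd is None or (fa is not None and fa < fd):
                continue
            np.testing.assert_allclose(trace.donor[fd:], 7.0)
            np.testing.assert_allclose(trace.acceptor[fd:], 11.0)
            break
        else:
            pytest.fail("no donor-first bleach drawn")

    def test_seed_reproducibility_is_bitwise(self, default_config):
        t1, _ = sim.generate_molecule(default_config, 3)
        t2, _ = sim.generate_molecule(default_config, 3)
        np.testing.assert_array_equal(t1.donor, t2.donor)
        np.testing.assert_array_equal(t1.acceptor, t2.acceptor)


class TestPopulation:
    def test_single_class_gets_one_label(self, default_config):
        traces, truth = sim.generate_population(
            default_config, [sim.MixtureClass(1.0, "only")])
        assert truth.label_counts() == {"only": len(traces)}

    def test_static_dynamic_split_matches_weights(self):
        cfg = SimulationConfig(n_molecules=500, n_frames=20, seed=6,
                               static_fraction=0.6)
        _, truth = sim.generate_population(cfg)
        n_static = sum(m.static for m in truth.molecules)
        se = np.sqrt(0.6 * 0.4 * 500)
        assert abs(n_static - 300) < 3 * se

    def test_subpopulation_weights_recovered(self):
        """Published two-subpopulation weights reproduced within 3 SE."""
        cfg = SimulationConfig(n_molecules=500, n_frames=20, seed=7)
        mixture = subpopulation_mixture("DNA/TBP")  # 43.5% / 56.4%
        _, truth = sim.generate_population(cfg, mixture)
        counts = truth.label_counts()
        p = 0.435 / (0.435 + 0.564)
        se = np.sqrt(p * (1 - p) * 500)
        assert abs(counts["P1"] - p * 500) < 3 * se

    def test_no_molecule_switches_subpopulation(self):
        cfg = SimulationConfig(n_molecules=50, n_frames=50, seed=8)
        _, truth = sim.generate_population(cfg, subpopulation_mixture("DNA/TBP"))
        assert all(isinstance(m.subpopulation, str) for m in truth.molecules)
        # regenerating yields identical labels: assignment is a per-run constant
        _, truth2 = sim.generate_population(cfg, subpopulation_mixture("DNA/TBP"))
        assert [m.subpopulation for m in truth.molecules] == \
            [m.subpopulation for m in truth2.molecules]

    def test_bad_weight_sum_rejected(self, default_config):
        with pytest.raises(ConfigurationError):
            sim.generate_population(default_config,
                                    [sim.MixtureClass(0.5, "a"),
                                     sim.MixtureClass(0.3, "b")])


class TestBeadStack:
    def test_identity_map_gives_coincident_centroids(self):
        beads = sim.generate_bead_stack(ChannelMap.identity(), 5, noise=0.0,
                                        seed=9)
        np.testing.assert_allclose(beads.positions1, beads.positions2)

    def test_translation_offsets_centroids_exactly(self):
        cm = ChannelMap.translation(3.2, -1.7)
        beads = sim.generate_bead_stack(cm, 8, noise=0.0, seed=10)
        offsets = beads.positions2 - beads.positions1
        np.testing.assert_allclose(offsets, np.tile([3.2, -1.7], (8, 1)),
                                   atol=1e-9)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ConfigurationError):
            sim.generate_bead_stack(ChannelMap.identity(), 2)


class TestSurvivalExperiment:
    def test_zero_dissociation_gives_identical_distributions(self):
        from scipy.stats import ks_2samp
        cfg = sim.SurvivalExperimentConfig(n_molecules=500, bleach_rate=0.1,
                                           dissociation_rate=0.0, seed=11)
        exp = sim.generate_survival_experiment(cfg)
        _, p = ks_2samp(exp.control.times, exp.treatment.times)
        assert p > 0.01

    def test_exponential_mean_lifetime(self):
        cfg = sim.SurvivalExperimentConfig(
            n_molecules=10_000, bleach_rate=0.1, dissociation_rate=0.0,
            frame_time=0.03, n_frames=40_000, seed=12)
        exp = sim.generate_survival_experiment(cfg)
        assert not exp.control.censored.any()
        assert exp.control.times.mean() == pytest.approx(10.0, abs=0.3)

    def test_treatment_stochastically_smaller(self):
        from scipy.stats import mannwhitneyu
        cfg = sim.SurvivalExperimentConfig(n_molecules=500, bleach_rate=0.1,
                                           dissociation_rate=0.05,
                                           frame_time=0.03, seed=13)
        exp = sim.generate_survival_experiment(cfg)
        _, p = mannwhitneyu(exp.treatment.times, exp.control.times,
                            alternative="less")
        assert p < 0.01

    def test_censoring_flags_respect_horizon(self):
        cfg = sim.SurvivalExperimentConfig(n_molecules=200, bleach_rate=0.02,
                                           n_frames=200, frame_time=0.03,
                                           seed=14)
        exp = sim.generate_survival_experiment(cfg)
        assert exp.control.censored.any()
        assert np.all(exp.control.times <= cfg.horizon + 1e-12)
        np.testing.assert_allclose(
            exp.control.times[exp.control.censored], cfg.horizon)
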