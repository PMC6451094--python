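"""Bleach-step detection, correction factors and FRET calculation tests."""

import numpy as np
import pytest

from smfret.config import SimulationConfig
from smfret import simulate as sim
from smfret.corrections import (
    CorrectionFactors,
    CorrectionUnavailable,
    call_mot1_presence,
    compute_fret,
    correct_direct_excitation,
    detect_bleach_steps,
    estimate_crosstalk,
    estimate_gamma,
    estimate_population_factors,
)
from smfret.traces import BleachAnnotation, IntensityTrace


def _trace(donor, acceptor, frame_time=0.015, **kwargs):
    return IntensityTrace(molecule_id=0, frame_time=frame_time,
                          donor=np.asarray(donor, dtype=float),
                          acceptor=np.asarray(acceptor, dtype=float), **kwargs)


def _step_trace(fa=120, n=400, pre=(60.0, 80.0), post=(160.0, 4.0), noise=2.0,
                seed=0):
    rng = np.random.default_rng(seed)
    donor = np.where(np.arange(n) < fa, pre[0], post[0]) + rng.normal(0, noise, n)
    acceptor = np.where(np.arange(n) < fa, pre[1], post[1]) + rng.normal(0, noise, n)
    return _trace(donor, acceptor)


class TestBleachDetection:
    def test_constant_trace_has_no_events(self, rng):
        trace = _trace(100 + rng.normal(0, 2, 300), 50 + rng.normal(0, 2, 300))
        ann = detect_bleach_steps(trace)
        assert ann.order == "none"
        assert ann.acceptor_frame is None and ann.donor_frame is None

    def test_synthetic_acceptor_bleach_located_within_two_frames(self):
        ann = detect_bleach_steps(_step_trace(fa=120))
        assert ann.order == "acceptor_first"
        assert abs(ann.acceptor_frame - 120) <= 2

    def test_simultaneous_drop_is_donor_or_total_loss(self, rng):
        n = 300
        donor = np.where(np.arange(n) < 150, 100.0, 3.0) + rng.normal(0, 2, n)
        acceptor = np.where(np.arange(n) < 150, 60.0, 3.0) + rng.normal(0, 2, n)
        ann = detect_bleach_steps(_trace(donor, acceptor))
        assert ann.order == "donor_or_total"
        assert ann.acceptor_frame is None

    def test_fret_transition_not_mistaken_for_bleach(self):
        """A dynamic low/high-FRET square wave has no bleach events."""
        rng = np.random.default_rng(1)
        n = 400
        state = (np.arange(n) // 50) % 2  # alternating dwells
        e = np.where(state == 0, 0.25, 0.69)
        donor = 500 * (1 - e) + rng.normal(0, 5, n)
        acceptor = 500 * e + rng.normal(0, 5, n)
        ann = detect_bleach_steps(_trace(donor, acceptor))
        assert ann.order != "acceptor_first"

    def test_generated_population_bleach_frames_recovered(self):
        cfg = SimulationConfig(n_molecules=40, n_frames=600, seed=1,
                               bleach_rate_acceptor=0.15,
                               bleach_rate_donor=0.05,
                               crosstalk_alpha=0.08, gamma=0.9)
        traces, truth = sim.generate_population(cfg)
        hits, errors = 0, []
        for trace, mol in zip(traces, truth.molecules):
            ann = detect_bleach_steps(trace, background=(50.0, 50.0))
            fa = mol.acceptor_bleach_frame
            acc_first = fa is not None and (mol.donor_bleach_frame is None
                                            or fa < mol.donor_bleach_frame)
            if acc_first and 10 < fa < 590 and ann.order == "acceptor_first":
                hits += 1
                errors.append(abs(ann.acceptor_frame - fa))
        assert hits >= 10
        assert np.median(errors) <= 2


class TestCorrectionFactors:
    def test_zero_postbleach_acceptor_gives_zero_alpha(self):
        trace = _step_trace(post=(160.0, 0.0), noise=0.0)
        ann = BleachAnnotation(acceptor_frame=120, order="acceptor_first")
        assert estimate_crosstalk(trace, ann) == pytest.approx(0.0, abs=1e-12)

    def test_alpha_is_postbleach_channel_ratio(self):
        trace = _step_trace(post=(100.0, 5.0), noise=0.0)
        ann = BleachAnnotation(acceptor_frame=120, order="acceptor_first")
        assert estimate_crosstalk(trace, ann) == pytest.approx(0.05, abs=1e-12)

    def test_gamma_from_step_amplitudes(self):
        # pre (60, 80) -> post (160, 0): gamma = 80 / 100 = 0.8
        trace = _step_trace(pre=(60.0, 80.0), post=(160.0, 0.0), noise=0.0)
        ann = BleachAnnotation(acceptor_frame=120, order="acceptor_first")
        assert estimate_gamma(trace, ann) == pytest.approx(0.8, abs=1e-12)

    def test_equal_steps_give_gamma_one(self):
        trace = _step_trace(pre=(50.0, 50.0), post=(100.0, 0.0), noise=0.0)
        ann = BleachAnnotation(acceptor_frame=120, order="acceptor_first")
        assert estimate_gamma(trace, ann) == pytest.approx(1.0, abs=1e-12)

    def test_population_recovery_of_generator_factors(self):
        """alpha=0.08 and gamma=0.9 recovered from acceptor-first molecules."""
        cfg = SimulationConfig(n_molecules=100, n_frames=600, seed=2,
                               bleach_rate_acceptor=0.15,
                               bleach_rate_donor=0.05,
                               crosstalk_alpha=0.08, gamma=0.9)
        traces, _ = sim.generate_population(cfg)
        bleaches = [detect_bleach_steps(t, background=(50.0, 50.0))
                    for t in traces]
        factors = estimate_population_factors(traces, bleaches,
                                              background=(50.0, 50.0))
        per_mol = [f for f in factors if f.source == "per_molecule"]
        assert len(per_mol) >= 20
        assert np.median([f.alpha for f in per_mol]) == pytest.approx(0.08,
                                                                      abs=0.01)
        assert np.median([f.gamma for f in per_mol]) == pytest.approx(0.9,
                                                                      abs=0.05)

    def test_donor_first_trace_never_yields_estimates(self):
        """Correction estimators refuse anything but acceptor-first events."""
        trace = _step_trace()
        for ann in (BleachAnnotation(),
                    BleachAnnotation(donor_frame=100, order="donor_or_total")):
            with pytest.raises(CorrectionUnavailable):
                estimate_crosstalk(trace, ann)
            with pytest.raises(CorrectionUnavailable):
                estimate_gamma(trace, ann)


class TestComputeFret:
    def test_uncorrected_arithmetic(self):
        trace = _trace([75.0] * 20, [25.0] * 20)
        ft = compute_fret(trace, CorrectionFactors(0.0, 1.0))
        np.testing.assert_allclose(ft.efficiency, 0.25)

    def test_background_level_acceptor_gives_zero(self):
        trace = _trace([100.0] * 20, [5.0] * 20)
        ft = compute_fret(trace, CorrectionFactors(0.0, 1.0),
                          background=(0.0, 5.0))
        np.testing.assert_allclose(ft.efficiency, 0.0, atol=1e-12)

    def test_corrected_formula_hand_value(self):
        # I_D=100, I_A=60, alpha=0.1, gamma=0.8 -> 50/130
        trace = _trace([100.0] * 20, [60.0] * 20)
        ft = compute_fret(trace, CorrectionFactors(0.1, 0.8))
        np.testing.assert_allclose(ft.efficiency, 50.0 / 130.0, atol=1e-12)

    def test_window_truncated_at_bleach(self):
        trace = _trace([100.0] * 50, [50.0] * 50)
        ann = BleachAnnotation(acceptor_frame=30, order="acceptor_first")
        ft = compute_fret(trace, CorrectionFactors(0.0, 1.0), bleach=ann)
        assert ft.window == (0, 30)
        assert ft.n_usable == 30

    def test_zero_noise_round_trip_recovers_apparent_e(self):
        """generator (alpha, gamma) -> estimate -> compute_fret is exact."""
        cfg = SimulationConfig(
            n_molecules=1, n_frames=400, seed=3,
            crosstalk_alpha=0.08, gamma=0.85, background=(20.0, 30.0),
            noise_model="gaussian_read", read_noise_sd=0.0,
            bleach_rate_acceptor=0.6, bleach_rate_donor=0.0,
            frame_time=0.015)
        for idx in range(20):
            trace, truth = sim.generate_molecule(cfg, idx)
            fa = truth.acceptor_bleach_frame
            if fa is None or not 30 < fa < 360:
                continue
            ann = detect_bleach_steps(trace, background=(20.0, 30.0))
            assert ann.order == "acceptor_first"
            assert ann.acceptor_frame == fa
            alpha = estimate_crosstalk(trace, ann, background=(20.0, 30.0))
            gamma = estimate_gamma(trace, ann, alpha, background=(20.0, 30.0))
            assert alpha == pytest.approx(0.08, abs=1e-9)
            assert gamma == pytest.approx(0.85, abs=1e-9)
            ft = compute_fret(trace, CorrectionFactors(alpha, gamma),
                              background=(20.0, 30.0), bleach=ann)
            np.testing.assert_allclose(ft.windowed, truth.apparent_e[:fa],
                                       atol=1e-6)
            return
        pytest.fail("no usable acceptor-first molecule drawn")

    def test_histogram_mean_invariant_under_intensity_budget(self):
        """Corrected E means shift <0.01 across a 4x photon-budget range."""
        means = []
        for total in (250.0, 1000.0):
            cfg = SimulationConfig(
                n_molecules=40, n_frames=300, seed=4, total_intensity=total,
                background=(total / 10, total / 10),
                emission_states=((0.4, 0.0),), transition_matrix=np.eye(1),
                bleach_rate_donor=0.0, bleach_rate_acceptor=0.0,
                crosstalk_alpha=0.05, gamma=0.9)
            traces, _ = sim.generate_population(cfg)
            fret = [compute_fret(t, CorrectionFactors(0.05, 0.9),
                                 background=cfg.background) for t in traces]
            means.append(np.mean([ft.windowed.mean() for ft in fret]))
        assert abs(means[0] - means[1]) < 0.01


class TestThreeColor:
    def test_zero_fraction_is_identity(self):
        trace = _trace([500.0] * 10, [100.0] * 10,
                       ex488=np.full(10, 200.0),
                       excitation_scheme="alternating_488_532")
        np.testing.assert_allclose(correct_direct_excitation(trace, 0.0),
                                   trace.ex488)

    def test_direct_excitation_arithmetic(self):
        trace = _trace([500.0] * 10, [100.0] * 10,
                       ex488=np.full(10, 200.0),
                       excitation_scheme="alternating_488_532")
        np.testing.assert_allclose(correct_direct_excitation(trace, 0.1), 150.0)

    def test_pure_direct_excitation_cancels(self):
        donor = np.full(10, 400.0)
        trace = _trace(donor, [100.0] * 10, ex488=0.12 * donor,
                       excitation_scheme="alternating_488_532")
        np.testing.assert_allclose(correct_direct_excitation(trace, 0.12),
                                   0.0, atol=1e-12)

    def test_missing_488_series_rejected(self):
        with pytest.raises(ValueError):
            correct_direct_excitation(_trace([1.0] * 10, [1.0] * 10), 0.1)

    def test_presence_calls(self, rng):
        assert not call_mot1_presence(np.zeros(50), background_sd=1.0)
        spike = np.zeros(50)
        spike[20] = 100.0
        assert not call_mot1_presence(spike, background_sd=1.0)
        assert call_mot1_presence(np.full(50, 10.0), background_sd=1.0)

    def test_presence_accuracy_on_labeled_population(self):
        """>=95% correct calls at SNR ~5 on a half-labeled population."""
        cfg = SimulationConfig(
            n_molecules=100, n_frames=200, seed=5,
            excitation_scheme="alternating_488_532", mot1_fraction=0.5,
            mot1_intensity=150.0, read_noise_sd=10.0,
            bleach_rate_donor=0.0, bleach_rate_acceptor=0.0)
        traces, truth = sim.generate_population(cfg)
        bg_sd = np.sqrt(cfg.background[0] + cfg.read_noise_sd**2)
        correct = 0
        for trace, mol in zip(traces, truth.molecules):
            corrected = correct_direct_excitation(
                trace, cfg.direct_excitation_fraction)
            call = call_mot1_presence(corrected - cfg.background[0],
                                      background_sd=bg_sd)
            correct += call == mol.mot1_labeled
        assert correct >= 95
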