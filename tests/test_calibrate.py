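"""Calibration: sensitivity fits, transport efficiency (both estimators),
counts->mass conversion with unit tracking, LODs and spike recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sptof.calibrate import (
    MassCalibrationModel,
    ReferenceParticleStandard,
    fit_sensitivity,
    mass_lod,
    ml_per_min_to_l_per_s,
    spike_recovery,
    transport_efficiency_frequency,
    transport_efficiency_size,
)
from sptof.detect import DetectionConfig, detect_events
from sptof.simulate import InstrumentParams, simulate_dissolved_series, simulate_np_standard

from .oracles import sphere_mass_fg


class TestFitSensitivity:
    def test_exact_linear_data(self):
        levels, runs = simulate_dissolved_series(
            {"Fe": 200.0}, [0.0, 0.5, 1.0, 5.0], n_acquisitions=100, noise="none"
        )
        cal = fit_sensitivity("Fe", levels, runs)
        assert cal.slope == pytest.approx(200.0, abs=1e-9)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_seven_level_series_recovers_slope_within_1pct(self):
        levels, runs = simulate_dissolved_series(
            {"Fe": 100.0}, n_acquisitions=10_000, seed=3
        )
        cal = fit_sensitivity("Fe", levels, runs)
        assert cal.slope == pytest.approx(100.0, rel=0.01)

    def test_all_zero_counts_flagged_uncalibratable(self):
        levels, runs = simulate_dissolved_series(
            {"Fe": 0.0}, [0.0, 1.0, 5.0], n_acquisitions=100, noise="none"
        )
        cal = fit_sensitivity("Fe", levels, runs)
        assert cal.slope == 0.0 and not cal.calibratable

    def test_fewer_than_three_levels_rejected(self):
        levels, runs = simulate_dissolved_series(
            {"Fe": 100.0}, [0.0, 1.0], n_acquisitions=100
        )
        with pytest.raises(ValueError, match=">= 3"):
            fit_sensitivity("Fe", levels, runs)

    def test_weighted_fit_agrees_on_clean_data(self):
        levels, runs = simulate_dissolved_series(
            {"Fe": 150.0}, n_acquisitions=100, noise="none"
        )
        unw = fit_sensitivity("Fe", levels, runs)
        w = fit_sensitivity("Fe", levels, runs, weighted=True)
        assert w.slope == pytest.approx(unw.slope, rel=1e-9)


class TestTransportEfficiency:
    def test_frequency_ratio_arithmetic(self, au_standard):
        # q*duration*C_N = 1 mL/min for 60 s at 1e5/mL = 1e5 aspirated
        eta = transport_efficiency_frequency(
            5000, au_standard, q_sample=1.0, duration=60.0
        )
        assert eta.eta == pytest.approx(0.05)
        assert eta.se == pytest.approx(np.sqrt(5000) / 1e5)

    def test_zero_detected_raises(self, au_standard):
        with pytest.raises(ValueError, match="eta undefined"):
            transport_efficiency_frequency(0, au_standard, 1.0, 60.0)

    def test_eta_above_one_rejected(self, au_standard):
        with pytest.raises(ValueError, match="outside"):
            transport_efficiency_frequency(10**6, au_standard, 1.0, 60.0)

    def test_frequency_recovery_from_simulation(self):
        # low occupancy (~0.005 events/acquisition) keeps coincidence
        # merging well below the counting SE
        std = ReferenceParticleStandard(50.0, 19300.0, "Au", number_concentration=2e4)
        inst = InstrumentParams(q_sample=0.3, t_acq=1e-3, duration=200.0, eta=0.05)
        run, _ = simulate_np_standard(std, {"Au": 150.0}, inst, seed=0)
        events = detect_events(run, DetectionConfig())
        eta = transport_efficiency_frequency(
            len(events), std, inst.q_sample, inst.duration
        )
        assert abs(eta.eta - 0.05) < 3 * eta.se

    def test_size_method_noise_free_recovery(self, au_standard):
        from sptof.simulate import match_events_to_ledger

        inst = InstrumentParams(q_sample=0.3, t_acq=1e-3, duration=100.0, eta=0.05)
        run, ledger = simulate_np_standard(
            au_standard, {"Au": 150.0}, inst, seed=1, noise="none"
        )
        events = detect_events(run, DetectionConfig())
        matches = match_events_to_ledger(events, ledger)
        solo_events = matches.loc[matches["n_in_window"] == 1, "event"]
        mean_counts = np.mean([events[e].net_counts["Au"] for e in solo_events])
        eta = transport_efficiency_size(
            float(mean_counts), au_standard, 150.0, inst.q_sample, inst.t_acq
        )
        assert eta.eta == pytest.approx(0.05, rel=1e-6)

    def test_frequency_and_size_methods_agree(self, au_standard):
        inst = InstrumentParams(q_sample=0.3, t_acq=1e-3, duration=300.0, eta=0.05)
        run, _ = simulate_np_standard(au_standard, {"Au": 150.0}, inst, seed=2)
        events = detect_events(run, DetectionConfig())
        nets = np.array([ev.net_counts["Au"] for ev in events])
        eta_f = transport_efficiency_frequency(
            len(events), au_standard, inst.q_sample, inst.duration
        )
        eta_s = transport_efficiency_size(
            float(nets.mean()), au_standard, 150.0, inst.q_sample, inst.t_acq,
            se_mean_counts=float(nets.std(ddof=1) / np.sqrt(nets.size)),
        )
        combined_se = np.hypot(eta_f.se, max(eta_s.se, 1e-4))
        assert abs(eta_f.eta - eta_s.eta) < 3 * combined_se

    def test_sphere_mass_oracle(self, au_standard):
        assert au_standard.particle_mass_fg == pytest.approx(
            sphere_mass_fg(50.0, 19300.0), rel=1e-12
        )


class TestCountsToMass:
    def test_zero_maps_to_zero(self, unit_model):
        assert unit_model.counts_to_mass(0.0, "Fe") == 0.0

    def test_hand_arithmetic_five_fg(self, unit_model):
        # eta=0.05, q=0.6 mL/min = 1e-5 L/s, t=1e-3 s, S=100, net=1000
        # -> 5e-9 ug = 5 fg
        assert unit_model.counts_to_mass(1000.0, "Fe") == pytest.approx(5.0, rel=1e-12)

    def test_linearity_to_machine_precision(self, unit_model):
        a, b = 123.4, 567.8
        assert unit_model.counts_to_mass(a + b, "Fe") == pytest.approx(
            unit_model.counts_to_mass(a, "Fe") + unit_model.counts_to_mass(b, "Fe"),
            rel=1e-14,
        )

    def test_uncalibrated_element_raises(self, unit_model):
        with pytest.raises(KeyError, match="not calibrated"):
            unit_model.counts_to_mass(10.0, "Zn")

    def test_dimensional_consistency_of_flow_units(self, unit_model):
        """Re-expressing the flow via the explicit converter leaves the
        fg-per-count factor unchanged."""
        q_l_s = ml_per_min_to_l_per_s(unit_model.q_sample)
        manual = (
            unit_model.eta * q_l_s * unit_model.t_acq
            / unit_model.sensitivities["Fe"] * 1e9
        )
        assert unit_model.fg_per_count("Fe") == pytest.approx(manual, rel=1e-15)


class TestLodAndRecovery:
    def test_noiseless_blank_gives_zero_lod(self, unit_model):
        assert mass_lod(0.0, unit_model, "Fe") == 0.0

    def test_lod_hand_arithmetic(self, unit_model):
        # 3 * sqrt(10) * 5e-3 fg/count ~ 0.04743 fg
        lod = mass_lod(np.sqrt(10.0), unit_model, "Fe")
        assert lod == pytest.approx(3 * np.sqrt(10) * 5e-3, rel=1e-12)
        assert lod == pytest.approx(0.0474, abs=5e-4)

    def test_lod_linear_in_blank_sigma(self, unit_model):
        assert mass_lod(2.0, unit_model, "Fe") == pytest.approx(
            2 * mass_lod(1.0, unit_model, "Fe")
        )

    def test_spike_recovery_identity_and_reported_value(self):
        assert spike_recovery(100.0, 100.0) == 100.0
        assert spike_recovery(73.0, 100.0) == 73.0

    def test_spike_recovery_zero_nominal_rejected(self):
        with pytest.raises(ValueError):
            spike_recovery(10.0, 0.0)

    def test_simulated_spike_recovers_near_100pct(self):
        """Measuring a simulated spiked standard with the true eta and S
        returns ~100% recovery of the nominal number concentration."""
        std = ReferenceParticleStandard(50.0, 19300.0, "Au", number_concentration=1e4)
        inst = InstrumentParams(q_sample=0.3, t_acq=1e-3, duration=200.0, eta=0.05)
        run, _ = simulate_np_standard(std, {"Au": 150.0}, inst, seed=7)
        events = detect_events(run, DetectionConfig())
        q_ml_s = inst.q_sample / 60.0
        measured_c = len(events) / (inst.eta * q_ml_s * inst.duration)
        rec = spike_recovery(measured_c, std.number_concentration)
        se_pct = 100 * np.sqrt(len(events)) / (inst.eta * q_ml_s * inst.duration * 1e4)
        assert abs(rec - 100.0) < 3 * se_pct


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    net=st.floats(min_value=0, max_value=1e6),
    scale=st.floats(min_value=0.1, max_value=10),
)
def test_mass_scales_inversely_with_sensitivity(net, scale):
    """Doubling S halves the mass for the same net counts (exact)."""
    m1 = MassCalibrationModel({"Fe": 100.0}, 0.05, 0.3, 1e-3)
    m2 = MassCalibrationModel({"Fe": 100.0 * scale}, 0.05, 0.3, 1e-3)
    assert m2.counts_to_mass(net, "Fe") * scale == pytest.approx(
        m1.counts_to_mass(net, "Fe"), rel=1e-12
    )
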