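"""Synthetic-instrument generative model: Poisson event statistics,
transport thinning, mass balance, seed determinism, and cohort scenario
structure."""

import numpy as np
import pandas as pd
import pytest

from sptof.calibrate import MassCalibrationModel, ReferenceParticleStandard
from sptof.detect import DetectionConfig, detect_events
from sptof.simulate import (
    AccessorySpec,
    CohortScenario,
    InstrumentParams,
    ParticlePopulation,
    SimulationConfig,
    TissueScenario,
    make_cohort_scenario,
    match_events_to_ledger,
    simulate_dissolved_series,
    simulate_np_standard,
    simulate_run,
)


class TestSimulateRun:
    def test_empty_generative_model(self, instrument, sensitivities):
        cfg = SimulationConfig(
            populations=(), sensitivities=sensitivities, instrument=instrument
        )
        run, ledger = simulate_run(cfg)
        assert not run.counts.any()
        assert len(ledger.particles) == 0

    def test_seed_determinism_is_bitwise(self, simple_config):
        run1, led1 = simulate_run(simple_config)
        run2, led2 = simulate_run(simple_config)
        np.testing.assert_array_equal(run1.counts, run2.counts)
        pd.testing.assert_frame_equal(led1.particles, led2.particles)

    def test_eligible_count_poisson_over_seeds(self, sensitivities):
        """At eta*q*t_total*C_N = 5000, the detected-eligible ledger size is
        Poisson(5000); over 50 seeds the mean must lie within 3 SE."""
        inst = InstrumentParams(q_sample=0.3, t_acq=1e-3, duration=20.0, eta=0.05)
        # q = 0.005 mL/s * 20 s * C_N * 0.05 = 5000 -> C_N = 1e6 per mL
        pop = ParticlePopulation(
            "magnetite", number_concentration=1e6, size_median_nm=140,
            size_gsd=1.5, phase_density=5170.0,
        )
        counts = []
        for seed in range(50):
            cfg = SimulationConfig(
                populations=(pop,), sensitivities=sensitivities,
                instrument=inst, seed=seed,
            )
            _, ledger = simulate_run(cfg)
            counts.append(ledger.n_detected_eligible)
        se = np.sqrt(5000 / 50)
        assert abs(np.mean(counts) - 5000) < 3 * se

    def test_thinning_is_binomial(self, sensitivities):
        """Detected-eligible size given n_generated is Binomial(n, eta)."""
        inst = InstrumentParams(duration=20.0, eta=0.2)
        pop = ParticlePopulation(
            "magnetite", number_concentration=5e5, size_median_nm=140,
            size_gsd=1.5, phase_density=5170.0,
        )
        fracs = []
        for seed in range(50):
            cfg = SimulationConfig(
                populations=(pop,), sensitivities=sensitivities,
                instrument=inst, seed=seed,
            )
            _, ledger = simulate_run(cfg)
            fracs.append(ledger.n_detected_eligible / len(ledger.particles))
        n_total = 0.005 * 20.0 * 5e5 * 50
        se = np.sqrt(0.2 * 0.8 / n_total)
        assert abs(np.mean(fracs) - 0.2) < 3 * se

    def test_pure_host_population_is_single_metal(self, instrument, sensitivities):
        """Magnetite with no accessories: every ledger particle carries Fe
        only, i.e. an Fe fraction of detected metals of exactly 1."""
        pop = ParticlePopulation(
            "magnetite", number_concentration=2e5, size_median_nm=140,
            size_gsd=1.5, phase_density=5170.0, host_mass_fraction=0.7236,
        )
        cfg = SimulationConfig(
            populations=(pop,), sensitivities=sensitivities,
            instrument=instrument, seed=3,
        )
        _, ledger = simulate_run(cfg)
        masses = ledger.particles.filter(like="mass_")
        assert set(masses.columns) == {"mass_Fe_fg"}
        assert (masses["mass_Fe_fg"] > 0).all()

    def test_mass_balance_host_counts(self, sensitivities):
        """Total emitted Fe counts match the ledger's inverse-model means
        within Poisson error (no background, no thinning loss bookkeeping:
        compare against passed particles only)."""
        inst = InstrumentParams(duration=20.0, eta=0.05)
        pop = ParticlePopulation(
            "magnetite", number_concentration=5e5, size_median_nm=100,
            size_gsd=1.4, phase_density=5170.0,
        )
        cfg = SimulationConfig(
            populations=(pop,), sensitivities=sensitivities,
            instrument=inst, seed=9,
        )
        run, ledger = simulate_run(cfg)
        passed = ledger.detected_eligible
        counts_per_fg = sensitivities["Fe"] / (
            inst.eta * (0.3 / 60000.0) * inst.t_acq
        ) / 1e9
        expected = (passed["mass_Fe_fg"] * counts_per_fg).sum()
        total = run.series("Fe").sum()
        assert abs(total - expected) < 3 * np.sqrt(expected)

    def test_split_events_conserve_expected_counts(self, instrument, sensitivities):
        pop = ParticlePopulation(
            "magnetite", number_concentration=2e5, size_median_nm=140,
            size_gsd=1.5, phase_density=5170.0,
        )
        cfg = SimulationConfig(
            populations=(pop,), sensitivities=sensitivities,
            instrument=instrument, split_probability=0.5, seed=4, noise="none",
        )
        run, ledger = simulate_run(cfg)
        passed = ledger.detected_eligible
        assert (passed["acq_index_2"] >= 0).any()
        counts_per_fg = sensitivities["Fe"] / (
            instrument.eta * (0.3 / 60000.0) * instrument.t_acq
        ) / 1e9
        np.testing.assert_allclose(
            run.series("Fe").sum(),
            (passed["mass_Fe_fg"] * counts_per_fg).sum(),
            rtol=1e-9,
        )

    def test_inconsistent_panel_rejected(self, instrument):
        pop = ParticlePopulation(
            "magnetite", number_concentration=1e5, size_median_nm=140,
            size_gsd=1.5, phase_density=5170.0, host_element="Fe",
        )
        with pytest.raises(ValueError, match="missing from sensitivity panel"):
            SimulationConfig(
                populations=(pop,), sensitivities={"Al": 50.0}, instrument=instrument
            )


class TestDissolvedSeries:
    def test_noise_free_means_exact(self):
        levels, runs = simulate_dissolved_series(
            {"Fe": 100.0}, [0.0, 1.0], n_acquisitions=50, noise="none"
        )
        assert runs[1].counts[:, 0] == pytest.approx(100.0)

    def test_default_levels_are_the_seven_standards(self):
        levels, runs = simulate_dissolved_series({"Fe": 100.0}, n_acquisitions=10)
        assert levels == [0.0, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0]
        assert len(runs) == 7
        assert runs[0].label == "blank"

    def test_poisson_mean_within_se(self):
        _, runs = simulate_dissolved_series(
            {"Fe": 200.0}, [0.0, 5.0], n_acquisitions=10_000, seed=1
        )
        mean = runs[1].series("Fe").mean()
        assert abs(mean - 1000.0) < 3 * np.sqrt(1000.0 / 10_000)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            simulate_dissolved_series({"Fe": 100.0}, [0.0, -1.0])


class TestNpStandard:
    def test_sphere_mass_and_metadata(self, instrument):
        std = ReferenceParticleStandard(50.0, 19300.0, "Au", number_concentration=1e5)
        assert std.particle_mass_fg == pytest.approx(1.263, rel=1e-3)
        run, ledger = simulate_np_standard(std, {"Au": 100.0}, instrument, seed=0)
        assert run.meta["nominal_diameter_nm"] == 50.0
        passed = ledger.detected_eligible
        # monodisperse: every particle mass at the sphere mass
        np.testing.assert_allclose(
            passed["mass_Au_fg"], std.particle_mass_fg, rtol=2e-3
        )

    def test_identity_thinning_keeps_every_particle(self):
        inst = InstrumentParams(duration=10.0, eta=1.0)
        std = ReferenceParticleStandard(50.0, 19300.0, "Au", number_concentration=1e5)
        _, ledger = simulate_np_standard(std, {"Au": 100.0}, inst, seed=2)
        assert ledger.n_detected_eligible == len(ledger.particles)

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            ReferenceParticleStandard(50.0, 19300.0, "Au", number_concentration=0.0)


class TestCohortScenario:
    def _scenario(self, efs, sm=0.8, **kw):
        tissues = tuple(
            TissueScenario(
                tissue=name, control_concentration=5e4, enrichment_factor=ef,
                size_median_nm=med, single_metal_probability=sm,
            )
            for (name, ef, med) in efs
        )
        return CohortScenario(
            tissues=tissues,
            sensitivities={"Fe": 100.0, "Al": 120.0, "Si": 60.0, "Mg": 150.0,
                           "Mn": 180.0, "Ti": 90.0},
            instrument=InstrumentParams(duration=20.0, eta=0.05),
            n_replicates=2,
            **kw,
        )

    def test_unit_enrichment_means_identical_generative_concentration(self):
        sc = self._scenario([("lung", 1.0, 130.0)])
        samples = make_cohort_scenario(sc, seed=0)
        assert {s.group for s in samples} == {"exposed", "control"}
        by_group = {}
        for s in samples:
            by_group.setdefault(s.group, []).append(len(s.ledger.particles))
        # identical generative rate: totals agree within Poisson error
        ne, nc = sum(by_group["exposed"]), sum(by_group["control"])
        assert abs(ne - nc) < 4 * np.sqrt(ne + nc)

    def test_requested_size_ordering_reproduced(self):
        pattern = [("PM2.5", 1.0, 146.0), ("lung", 1.0, 137.0),
                   ("serum", 1.0, 124.0), ("heart", 1.0, 115.0)]
        samples = make_cohort_scenario(self._scenario(pattern), seed=1)
        medians = {}
        for s in samples:
            d = s.ledger.detected_eligible["diameter_nm"]
            medians.setdefault(s.tissue, []).extend(d.tolist())
        order = [np.median(medians[t]) for t, _, _ in pattern]
        assert order == sorted(order, reverse=True)

    def test_single_metal_proportion_within_binomial_se(self):
        sc = self._scenario([("heart", 1.0, 130.0)], sm=0.8)
        samples = make_cohort_scenario(sc, seed=5)
        pooled = pd.concat([s.ledger.detected_eligible for s in samples])
        acc_cols = [c for c in pooled.columns
                    if c.startswith("mass_") and c != "mass_Fe_fg"]
        single = (pooled[acc_cols].sum(axis=1) == 0).mean()
        n = len(pooled)
        assert n > 500
        assert abs(single - 0.8) < 3 * np.sqrt(0.8 * 0.2 / n)

    def test_missing_control_arm_impossible_by_construction(self):
        samples = make_cohort_scenario(self._scenario([("lung", 4.5, 130.0)]), seed=0)
        tissues_groups = {(s.tissue, s.group) for s in samples}
        assert ("lung", "control") in tissues_groups


class TestForwardInverse:
    def test_noise_free_chain_recovers_ledger_masses(self, sensitivities):
        """Full quantification with the true constants on noise-free output
        reproduces the ledger masses to 1e-9 relative (single-particle
        windows; same-window coincidences are unresolvable by design)."""
        inst = InstrumentParams(duration=30.0, eta=0.05)
        pop = ParticlePopulation(
            "magnetite", number_concentration=1e5, size_median_nm=140,
            size_gsd=1.5, phase_density=5170.0,
            accessories={"Al": AccessorySpec(prob=0.5, median_fraction=0.3)},
        )
        cfg = SimulationConfig(
            populations=(pop,), sensitivities=sensitivities,
            dissolved_background={"Fe": 0.05}, instrument=inst,
            split_probability=0.1, seed=8, noise="none",
        )
        run, ledger = simulate_run(cfg)
        events = detect_events(run, DetectionConfig())
        model = MassCalibrationModel(
            sensitivities=sensitivities, eta=inst.eta,
            q_sample=inst.q_sample, t_acq=inst.t_acq,
        )
        matches = match_events_to_ledger(events, ledger)
        solo = matches[matches["n_in_window"] == 1]
        assert len(solo) > 500
        for elem in ("Fe", "Al"):
            true = solo[f"true_mass_{elem}_fg"].to_numpy()
            got = np.array(
                [model.counts_to_mass(events[e].net_counts[elem], elem)
                 for e in solo["event"]]
            )
            mask = true > 0
            np.testing.assert_allclose(got[mask], true[mask], rtol=1e-9)
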