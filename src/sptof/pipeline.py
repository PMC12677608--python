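"""Pipeline orchestration: simulate -> detect -> calibrate -> quantify ->
summarize with stable text-file contracts.

A single YAML document configures every stage; all thresholds and tolerances
live there, none are hard-coded. Every output table carries the config hash
and seed in its header, per-stage counts are logged so filter attrition is
auditable, and a rerun with identical config and seed is bitwise-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import calibrate as cal
from . import cohort as coh
from . import composition as comp
from . import detect as det
from . import simulate as sim
from .io import write_acquisition_run, write_table

__all__ = ["validate_config", "run_pipeline", "PipelineResult", "load_config"]

log = logging.getLogger("sptof.pipeline")

REPORT_FILES = (
    "calibration_report.tsv",
    "particles.tsv",
    "cohort_summary.tsv",
    "enrichment_retention.tsv",
    "run_manifest.yaml",
)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    return doc


def config_hash(config: dict[str, Any]) -> str:
    """Stable SHA-256 over the canonical JSON form of the config."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def validate_config(config: dict[str, Any]) -> list[str]:
    """Check a pipeline config document; returns a list of violations
    (empty means valid). Never mutates its input."""
    v: list[str] = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]

    detection = config.get("detection", {})
    method = detection.get("method", "iterative-sigma")
    if method not in ("iterative-sigma", "poisson-quantile"):
        v.append(f"detection.method {method!r} not one of iterative-sigma/poisson-quantile")
    k = detection.get("k", 5.0)
    if not isinstance(k, (int, float)) or k <= 0:
        v.append("detection.k must be > 0")
    alpha = detection.get("alpha", 1e-6)
    if not isinstance(alpha, (int, float)) or not 0 < alpha < 0.5:
        v.append("detection.alpha must lie in (0, 0.5)")

    quant = config.get("quantify", {})
    thr = quant.get("fe_rich_threshold", 0.40)
    if not isinstance(thr, (int, float)) or not 0 <= thr <= 1:
        v.append(f"quantify.fe_rich_threshold {thr}: fraction out of [0,1]")
    phase = quant.get("phase", "magnetite")
    if phase not in comp.PHASES and not isinstance(phase, dict):
        v.append(f"quantify.phase {phase!r} unknown (magnetite/hematite or custom mapping)")

    inst = config.get("instrument", {})
    eta = inst.get("eta", 0.05)
    if not isinstance(eta, (int, float)) or not 0 < eta <= 1:
        v.append("instrument.eta must lie in (0, 1]")
    for key in ("q_sample", "t_acq", "duration"):
        val = inst.get(key)
        if val is not None and (not isinstance(val, (int, float)) or val <= 0):
            v.append(f"instrument.{key} must be > 0")

    scenario = config.get("scenario", {})
    sens = scenario.get("sensitivities", {})
    if scenario:
        if not sens:
            v.append("scenario.sensitivities missing")
        bg = scenario.get("dissolved_background", {})
        missing = sorted(set(bg) - set(sens))
        if missing:
            v.append(
                f"element panels mismatch: background elements {missing} absent "
                f"from sensitivity panel {sorted(sens)}"
            )
        tissues = scenario.get("tissues", [])
        if not tissues:
            v.append("scenario.tissues missing")
        for t in tissues:
            p = t.get("single_metal_probability", 0.7)
            if not 0 <= p <= 1:
                v.append(f"tissue {t.get('tissue')}: single_metal_probability out of [0,1]")
            if "matrix_unit" not in t and "matrix_quantity" in t:
                v.append(f"tissue {t.get('tissue')}: matrix_quantity given without matrix_unit")

    calib = config.get("calibration", {})
    levels = calib.get("levels_ug_l")
    if levels is not None:
        if 0 not in levels and 0.0 not in levels:
            v.append("calibration.levels_ug_l must include the 0 (blank) level")
        if sorted(levels) != list(levels):
            v.append("calibration.levels_ug_l must be increasing")
    lod_mult = calib.get("lod_multiplier", 3.0)
    if not isinstance(lod_mult, (int, float)) or lod_mult <= 0:
        v.append("calibration.lod_multiplier must be > 0")
    return v


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline produced."""

    calibration_report: pd.DataFrame
    eta: cal.TransportEfficiency
    model: cal.MassCalibrationModel
    samples: list[coh.CohortSample]
    ledgers: dict[tuple[str, str, int], sim.GroundTruthLedger]
    cohort_summary: pd.DataFrame
    enrichment_retention: pd.DataFrame
    manifest: dict[str, Any]


def _build_scenario(config: dict[str, Any]) -> sim.CohortScenario:
    sc = config["scenario"]
    inst = sim.InstrumentParams(**config.get("instrument", {}))
    accessories = {
        el: sim.AccessorySpec(**spec)
        for el, spec in sc.get("accessories", {}).items()
    } or dict(sim.DEFAULT_ACCESSORIES)
    tissues = tuple(sim.TissueScenario(**t) for t in sc["tissues"])
    return sim.CohortScenario(
        tissues=tissues,
        sensitivities={k: float(v) for k, v in sc["sensitivities"].items()},
        dissolved_background={
            k: float(v) for k, v in sc.get("dissolved_background", {}).items()
        },
        instrument=inst,
        accessories=accessories,
        n_replicates=int(sc.get("n_replicates", 3)),
        split_probability=float(sc.get("split_probability", 0.05)),
        noise=sc.get("noise", "poisson"),
    )


def calibrate_from_runs(
    levels: list[float],
    cal_runs: list,
    ref_run,
    standard: cal.ReferenceParticleStandard,
    detection: det.DetectionConfig,
    lod_multiplier: float = 3.0,
    eta_method: str = "frequency",
) -> tuple[list[cal.DissolvedCalibration], cal.TransportEfficiency, cal.MassCalibrationModel]:
    """Run the full calibration stage from raw calibration tables: fit every
    element's dissolved sensitivity, detect the reference-standard events,
    estimate transport efficiency (frequency method by default, signal-based
    size method as the alternative) and assemble the mass model with LODs."""
    elements = cal_runs[0].elements
    calibrations = []
    for elem in elements:
        try:
            calibrations.append(cal.fit_sensitivity(elem, levels, cal_runs))
        except ValueError:
            log.warning("element %s uncalibratable; skipped", elem)
    ref_events = det.detect_events(ref_run, detection)
    n_det = len(ref_events)
    eta_freq = cal.transport_efficiency_frequency(
        n_det, standard, ref_run.q_sample, ref_run.duration, ref_run.dilution_factor
    )
    if eta_method == "size":
        host = standard.host_element
        s_host = next(c.slope for c in calibrations if c.element == host)
        nets = np.array([ev.net_counts[host] for ev in ref_events])
        eta = cal.transport_efficiency_size(
            float(nets.mean()), standard, s_host, ref_run.q_sample, ref_run.t_acq,
            se_mean_counts=float(nets.std(ddof=1) / np.sqrt(nets.size)) if nets.size > 1 else 0.0,
        )
    else:
        eta = eta_freq
    model = cal.build_calibration_model(
        calibrations, eta, cal_runs[0].q_sample, cal_runs[0].t_acq, lod_multiplier
    )
    log.info("calibrated %d elements; eta=%.4f (%s) from %d reference events",
             len(model.elements), eta.eta, eta.method, n_det)
    return calibrations, eta, model


def run_pipeline(
    config: dict[str, Any] | str | Path,
    outdir: str | Path,
    seed: int | None = None,
) -> PipelineResult:
    """Execute the full chain on a simulated scenario and write the report
    bundle (calibration report, particle table, cohort summary,
    enrichment/retention report, run manifest) under ``outdir``."""
    if not isinstance(config, dict):
        config = load_config(config)
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid pipeline config: " + "; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    chash = config_hash({**config, "seed": seed})
    header = {"config_hash": chash, "seed": seed}
    counts_log: dict[str, int] = {}

    rng = np.random.default_rng(seed)
    detection = det.DetectionConfig(**config.get("detection", {}))
    inst = sim.InstrumentParams(**config.get("instrument", {}))
    scenario = _build_scenario(config)

    # --- stage 1: simulate calibration inputs and cohort runs -------------
    calib_cfg = config.get("calibration", {})
    levels = list(calib_cfg.get("levels_ug_l", cal.DEFAULT_CAL_LEVELS_UG_L))
    ref_cfg = calib_cfg.get("reference_standard", {})
    standard = cal.ReferenceParticleStandard(
        diameter_nm=float(ref_cfg.get("diameter_nm", 50.0)),
        density=float(ref_cfg.get("density", 19300.0)),
        host_element=ref_cfg.get("host_element", "Au"),
        number_concentration=float(ref_cfg.get("number_concentration", 2e5)),
    )
    sens_truth = dict(scenario.sensitivities)
    if standard.host_element not in sens_truth:
        sens_truth[standard.host_element] = float(
            ref_cfg.get("sensitivity", 100.0)
        )
    levels, cal_runs = sim.simulate_dissolved_series(
        sens_truth,
        levels,
        n_acquisitions=int(calib_cfg.get("n_acquisitions", 5000)),
        seed=int(rng.integers(0, 2**31 - 1)),
        instrument=inst,
        noise=scenario.noise,
        background_ug_l=float(calib_cfg.get("blank_background_ug_l", 0.0)),
    )
    # the standard is run at single-particle occupancy (and may use a longer
    # acquisition than the cohort samples) so the event frequency is clean
    ref_inst = inst
    if "duration" in ref_cfg:
        from dataclasses import replace as _dc_replace

        ref_inst = _dc_replace(inst, duration=float(ref_cfg["duration"]))
    ref_run, ref_ledger = sim.simulate_np_standard(
        standard, sens_truth, ref_inst, seed=int(rng.integers(0, 2**31 - 1)),
        noise=scenario.noise,
    )
    samples_in = sim.make_cohort_scenario(scenario, seed=int(rng.integers(0, 2**31 - 1)))
    counts_log["calibration_runs"] = len(cal_runs)
    counts_log["cohort_runs"] = len(samples_in)
    counts_log["acquisitions_read"] = sum(s.run.n_acquisitions for s in samples_in)

    # --- stage 2+3: calibrate --------------------------------------------
    calibrations, eta, model = calibrate_from_runs(
        levels, cal_runs, ref_run, standard, detection,
        lod_multiplier=float(calib_cfg.get("lod_multiplier", 3.0)),
        eta_method=calib_cfg.get("eta_method", "frequency"),
    )
    cal_report = pd.DataFrame(
        [
            {
                "element": c.element,
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "blank_sd": c.blank_sd,
                "mass_lod_fg": model.mass_lod_fg.get(c.element, float("nan")),
            }
            for c in calibrations
        ]
    )
    write_table(
        cal_report, outdir / "calibration_report.tsv",
        {**header, "eta": repr(eta.eta), "eta_method": eta.method, "eta_se": repr(eta.se)},
    )

    # --- stage 4: detect + quantify ---------------------------------------
    quant = config.get("quantify", {})
    phase_name = quant.get("phase", "magnetite")
    phase = comp.PHASES[phase_name] if isinstance(phase_name, str) else comp.MineralPhase(**phase_name)
    fe_rich = float(quant.get("fe_rich_threshold", 0.40))
    samples: list[coh.CohortSample] = []
    ledgers: dict[tuple[str, str, int], sim.GroundTruthLedger] = {}
    particle_frames = []
    n_events = 0
    for s in samples_in:
        events = det.detect_events(s.run, detection)
        n_events += len(events)
        table = comp.events_to_particle_table(events, model, phase, fe_rich)
        table.insert(0, "tissue", s.tissue)
        table.insert(1, "group", s.group)
        table.insert(2, "replicate", s.replicate)
        particle_frames.append(table)
        samples.append(
            coh.CohortSample(
                particles=table,
                tissue=s.tissue,
                group=s.group,
                replicate=s.replicate,
                matrix_quantity=s.matrix_quantity,
                matrix_unit=s.matrix_unit,
                dilution_factor=s.run.dilution_factor,
                q_sample=s.run.q_sample,
                duration=s.run.duration,
            )
        )
        ledgers[(s.tissue, s.group, s.replicate)] = s.ledger
    particles_all = pd.concat(particle_frames, ignore_index=True)
    counts_log["events_found"] = n_events
    counts_log["particles_quantified"] = int(len(particles_all))
    counts_log["records_filtered_at_lod"] = n_events - int(len(particles_all))
    write_table(particles_all, outdir / "particles.tsv", header)

    # --- stage 5: summarize ------------------------------------------------
    summary = coh.summarize_cohort(samples, eta)
    write_table(summary, outdir / "cohort_summary.tsv", header)

    er_rows = []
    tissues = sorted({s.tissue for s in samples})
    for tissue in tissues:
        for basis, metric in (("number", coh.number_concentration), ("mass", coh.mass_concentration)):
            exp_vals = [
                metric(s, eta) for s in samples if s.tissue == tissue and s.group == "exposed"
            ]
            ctl_vals = [
                metric(s, eta) for s in samples if s.tissue == tissue and s.group == "control"
            ]
            try:
                ef = coh.enrichment_factor(exp_vals, ctl_vals, tissue, basis)
                er_rows.append(
                    {"tissue": tissue, "metric": f"EF_{basis}", "value": ef.ef, "se": ef.se}
                )
            except ValueError as exc:
                log.warning("EF undefined for %s (%s): %s", tissue, basis, exc)

    dose_cfg = dict(config.get("dose") or {})
    if dose_cfg:
        basis = dose_cfg.pop("basis", "mass")
        dose = coh.DoseModel(**dose_cfg)
        for tissue in tissues:
            exposed = [s for s in samples if s.tissue == tissue and s.group == "exposed"]
            if not exposed:
                continue
            if basis == "mass":
                burdens = [
                    coh.mass_concentration(s, eta, per_matrix=True) * s.matrix_quantity
                    for s in exposed
                ]
            else:
                burdens = [
                    coh.number_concentration(s, eta, per_matrix=True) * s.matrix_quantity
                    for s in exposed
                ]
            ret = coh.retention_rate(float(np.mean(burdens)), dose, tissue, basis)
            er_rows.append(
                {"tissue": tissue, "metric": f"retention_{basis}_pct", "value": ret.percent,
                 "se": float("nan")}
            )
    er_report = pd.DataFrame(er_rows, columns=["tissue", "metric", "value", "se"])
    write_table(er_report, outdir / "enrichment_retention.tsv", header)

    # --- manifest -----------------------------------------------------------
    file_hashes = {}
    for name in REPORT_FILES[:-1]:
        p = outdir / name
        file_hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {
        "config_hash": chash,
        "seed": seed,
        "stage_counts": counts_log,
        "eta": float(eta.eta),
        "files": file_hashes,
    }
    with open(outdir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    log.info("pipeline complete: %s", counts_log)
    return PipelineResult(
        calibration_report=cal_report,
        eta=eta,
        model=model,
        samples=samples,
        ledgers=ledgers,
        cohort_summary=summary,
        enrichment_retention=er_report,
        manifest=manifest,
    )


def demo_config(seed: int = 0) -> dict[str, Any]:
    """A small, fast, self-contained demo scenario exercising every stage:
    four compartments with the enrichment/size/composition structure of an
    inhalation biodistribution study, scaled down for desk runtimes."""
    return {
        "seed": seed,
        "detection": {"method": "poisson-quantile", "alpha": 1e-6, "merge_gap": 0},
        "instrument": {
            "q_sample": 0.3, "t_acq": 1e-3, "duration": 60.0,
            "eta": 0.05, "dilution_factor": 1.0,
        },
        "calibration": {
            "levels_ug_l": [0.0, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0],
            "n_acquisitions": 2000,
            "blank_background_ug_l": 0.02,
            "lod_multiplier": 3.0,
            "eta_method": "frequency",
            "reference_standard": {
                "diameter_nm": 50.0, "density": 19300.0,
                "host_element": "Au", "number_concentration": 2e4,
                "sensitivity": 150.0, "duration": 200.0,
            },
        },
        "quantify": {"phase": "magnetite", "fe_rich_threshold": 0.40},
        "scenario": {
            "sensitivities": {
                "Fe": 100.0, "Al": 120.0, "Si": 60.0, "Mg": 150.0,
                "Mn": 180.0, "Ti": 90.0,
            },
            "dissolved_background": {"Fe": 0.02, "Al": 0.02, "Si": 0.05},
            "n_replicates": 3,
            "split_probability": 0.05,
            "tissues": [
                {"tissue": "PM2.5", "control_concentration": 5e4,
                 "enrichment_factor": 1.0, "size_median_nm": 146.0,
                 "single_metal_probability": 0.68,
                 "matrix_quantity": 1.0, "matrix_unit": "m3"},
                {"tissue": "lung", "control_concentration": 1e4,
                 "enrichment_factor": 4.5, "size_median_nm": 137.0,
                 "single_metal_probability": 0.62,
                 "matrix_quantity": 0.15, "matrix_unit": "g"},
                {"tissue": "serum", "control_concentration": 1e4,
                 "enrichment_factor": 3.6, "size_median_nm": 124.0,
                 "single_metal_probability": 0.76,
                 "matrix_quantity": 1.0, "matrix_unit": "mL"},
                {"tissue": "heart", "control_concentration": 1e4,
                 "enrichment_factor": 4.7, "size_median_nm": 115.0,
                 "single_metal_probability": 0.83,
                 "matrix_quantity": 0.12, "matrix_unit": "g"},
            ],
        },
        "dose": {"administered_dose": 1e9, "basis": "mass"},
    }
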