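"""Exposed/control biodistribution statistics on a synthetic cohort.

Generates a four-compartment scenario (PM2.5 extract, lung, serum, heart)
with generative number-basis enrichment factors {4.5, 3.6, 4.7}, decreasing
size medians (146 -> 115 nm) and rising single-metal proportions, then
recovers enrichment factors, size summaries, Fe-fraction proportions, a
retention rate against an explicit dose model, and a Welch exposed-vs-
control comparison.
"""

import numpy as np
import pandas as pd

from sptof import (
    CohortSample,
    CohortScenario,
    DetectionConfig,
    DoseModel,
    InstrumentParams,
    MassCalibrationModel,
    TissueScenario,
    detect_events,
    enrichment_factor,
    events_to_particle_table,
    fraction_bins,
    group_compare,
    make_cohort_scenario,
    number_concentration,
    retention_rate,
    size_summary,
)

EF = {"PM2.5": 1.0, "lung": 4.5, "serum": 3.6, "heart": 4.7}
SIZE = {"PM2.5": 146.0, "lung": 137.0, "serum": 124.0, "heart": 115.0}
SINGLE = {"PM2.5": 0.68, "lung": 0.62, "serum": 0.76, "heart": 0.83}

instrument = InstrumentParams(q_sample=0.3, t_acq=1e-3, duration=300.0, eta=0.05)
scenario = CohortScenario(
    tissues=tuple(
        TissueScenario(tissue=t, control_concentration=1e4, enrichment_factor=EF[t],
                       size_median_nm=SIZE[t], single_metal_probability=SINGLE[t])
        for t in EF
    ),
    sensitivities={"Fe": 100.0, "Al": 120.0, "Si": 60.0, "Mg": 150.0,
                   "Mn": 180.0, "Ti": 90.0},
    dissolved_background={"Fe": 0.02, "Al": 0.02},
    instrument=instrument,
    n_replicates=4,
)
samples = make_cohort_scenario(scenario, seed=20)
model = MassCalibrationModel(sensitivities=scenario.sensitivities, eta=0.05,
                             q_sample=0.3, t_acq=1e-3)
detection = DetectionConfig(method="poisson-quantile", alpha=1e-6)

cohort = []
for s in samples:
    table = events_to_particle_table(detect_events(s.run, detection), model)
    cohort.append(CohortSample(particles=table, tissue=s.tissue, group=s.group,
                               replicate=s.replicate, q_sample=0.3,
                               duration=instrument.duration))

print("tissue   EF_number (truth)   median_d  single-metal (truth)")
for tissue in EF:
    exp = [number_concentration(s, 0.05) for s in cohort
           if s.tissue == tissue and s.group == "exposed"]
    ctl = [number_concentration(s, 0.05) for s in cohort
           if s.tissue == tissue and s.group == "control"]
    r = enrichment_factor(exp, ctl, tissue)
    pooled = pd.concat([s.particles for s in cohort
                        if s.tissue == tissue and s.group == "exposed"])
    sz = size_summary(pooled["diameter_nm"].dropna())
    fb = fraction_bins(pooled["fe_fraction"].dropna())
    print(f"{tissue:8s} {r.ef:4.2f} +/- {r.se:4.2f} ({EF[tissue]:3.1f})"
          f"      {sz['median_nm']:5.0f} nm   {fb['single_metal_proportion']:.2f}"
          f" ({SINGLE[tissue]:.2f})")

# retention: lung Fe burden as percent of an explicitly declared dose
lung_burden_fg = np.mean(
    [s.particles["mass_Fe_fg"].sum() / 0.05 for s in cohort
     if s.tissue == "lung" and s.group == "exposed"]
)
dose = DoseModel(administered_dose=lung_burden_fg / 0.62)  # illustrative dose
ret = retention_rate(lung_burden_fg, dose, "lung", "mass")
print(f"\nlung retention: {ret.percent:.1f}% of administered Fe mass "
      f"(dose form: {ret.dose_form})")

exp = [number_concentration(s, 0.05) for s in cohort
       if s.tissue == "heart" and s.group == "exposed"]
ctl = [number_concentration(s, 0.05) for s in cohort
       if s.tissue == "heart" and s.group == "control"]
welch = group_compare(exp, ctl)
print(f"heart exposed vs control: t = {welch['t']:.1f}, p = {welch['p']:.2g}")

# Number-basis EFs track the generative map within replicate error; size
# medians fall monotonically along the PM2.5 -> heart route; the Welch test
# flags the exposed/control difference in particle number concentration.
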