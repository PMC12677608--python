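"""Cross-sample biodistribution statistics.

Turns per-particle tables into the quantities a nanoparticle biodistribution
study reports: particle number concentrations per matrix quantity,
exposed/control enrichment factors on mass or number basis, retention rates
against an explicit administered-dose model, size summaries, Fe-mass-fraction
bin proportions, bulk-element contribution shares, replicate aggregation and
Welch's exposed-vs-control comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import TransportEfficiency

__all__ = [
    "CohortSample",
    "DoseModel",
    "EnrichmentResult",
    "RetentionResult",
    "number_concentration",
    "enrichment_factor",
    "retention_rate",
    "element_contribution",
    "size_summary",
    "fraction_bins",
    "replicate_aggregate",
    "group_compare",
    "summarize_cohort",
]


@dataclass
class CohortSample:
    """One tissue x group x replicate particle table with the acquisition
    metadata required for concentration arithmetic.

    ``matrix_quantity`` is the amount of original matrix represented by the
    measured suspension (g tissue, mL serum, or m^3 air-equivalent) and
    ``suspension_volume_ml`` the undiluted suspension volume it was digested
    or extracted into; both are needed to report burdens per matrix unit.
    """

    particles: pd.DataFrame
    tissue: str
    group: str  # "exposed" | "control"
    replicate: int = 0
    matrix_quantity: float = 1.0
    matrix_unit: str = "g"
    suspension_volume_ml: float = 1.0
    dilution_factor: float = 1.0
    q_sample: float = 0.3  # mL min^-1
    duration: float = 100.0  # s

    def __post_init__(self) -> None:
        if self.matrix_quantity <= 0:
            raise ValueError("matrix quantity must be positive")
        if self.group not in ("exposed", "control"):
            raise ValueError("group must be 'exposed' or 'control'")
        if not self.matrix_unit:
            raise ValueError("matrix unit must be declared")


def number_concentration(
    sample: CohortSample,
    eta: TransportEfficiency | float,
    per_matrix: bool = False,
) -> float:
    """Particle number concentration from detected events.

    C_N = N_detected * dilution / (eta * q * duration), in particles per mL
    of the undiluted suspension (q in mL/s so q*duration is the aspirated
    volume). With ``per_matrix=True`` the suspension concentration is
    converted to particles per matrix unit via the suspension volume and
    matrix quantity. Linear in N_detected and in the dilution factor.
    """
    eta_val = eta.eta if isinstance(eta, TransportEfficiency) else float(eta)
    if not 0 < eta_val <= 1:
        raise ValueError("eta must be in (0, 1]")
    if sample.q_sample <= 0 or sample.duration <= 0:
        raise ValueError("missing instrument metadata (flow/duration)")
    n = len(sample.particles)
    q_ml_s = sample.q_sample / 60.0
    c_per_ml = n * sample.dilution_factor / (eta_val * q_ml_s * sample.duration)
    if not per_matrix:
        return c_per_ml
    return c_per_ml * sample.suspension_volume_ml / sample.matrix_quantity


def mass_concentration(
    sample: CohortSample,
    eta: TransportEfficiency | float,
    element: str = "Fe",
    per_matrix: bool = False,
) -> float:
    """Element mass concentration (fg per mL suspension, or per matrix unit)
    carried by detected particles, scaled by 1/eta and dilution like the
    number concentration."""
    eta_val = eta.eta if isinstance(eta, TransportEfficiency) else float(eta)
    col = f"mass_{element}_fg"
    total_fg = float(sample.particles[col].fillna(0.0).sum()) if col in sample.particles else 0.0
    q_ml_s = sample.q_sample / 60.0
    c = total_fg * sample.dilution_factor / (eta_val * q_ml_s * sample.duration)
    if not per_matrix:
        return c
    return c * sample.suspension_volume_ml / sample.matrix_quantity


@dataclass
class EnrichmentResult:
    """Exposed/control enrichment factor in one tissue."""

    tissue: str
    basis: str  # "mass" | "number"
    ef: float
    se: float
    n_exposed: int
    n_control: int


def enrichment_factor(
    exposed_values,
    control_values,
    tissue: str = "",
    basis: str = "number",
) -> EnrichmentResult:
    """Enrichment factor: the ratio of the exposed-group mean to the
    control-group mean of a concentration metric, with first-order
    (delta-method) propagation of the replicate standard errors:

        SE(EF) = EF * sqrt((SE_e/mean_e)^2 + (SE_c/mean_c)^2)
    """
    e = np.asarray(exposed_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if e.size == 0 or c.size == 0:
        raise ValueError("both groups must be present")
    mean_e, mean_c = e.mean(), c.mean()
    if mean_c <= 0:
        raise ValueError(f"control mean is {mean_c}; enrichment factor undefined")
    ef = mean_e / mean_c
    se_e = e.std(ddof=1) / sqrt(e.size) if e.size > 1 else 0.0
    se_c = c.std(ddof=1) / sqrt(c.size) if c.size > 1 else 0.0
    rel_e = se_e / mean_e if mean_e > 0 else 0.0
    se = ef * sqrt(rel_e**2 + (se_c / mean_c) ** 2)
    return EnrichmentResult(tissue, basis, float(ef), float(se), e.size, c.size)


@dataclass(frozen=True)
class DoseModel:
    """Administered (inhaled) dose for retention-rate denominators.

    Either supply ``administered_dose`` directly (Fe mass in the burden's
    units, or a particle number), or give the product-form inputs:
    air concentration x inhalation rate x exposure schedule x deposition
    fraction x magnetic-Fe mass fraction. The form actually used is
    reported so the denominator is always explicit.
    """

    administered_dose: float | None = None
    air_concentration_ug_m3: float | None = None
    inhalation_rate_ml_min: float | None = None
    hours_per_day: float | None = None
    days: float | None = None
    deposition_fraction: float = 1.0
    magnetic_fe_fraction: float = 1.0

    def __post_init__(self) -> None:
        for frac in (self.deposition_fraction, self.magnetic_fe_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")

    def dose(self) -> tuple[float, str]:
        """Return (administered dose, description of the form used)."""
        if self.administered_dose is not None:
            if self.administered_dose <= 0:
                raise ValueError("administered dose must be positive")
            return self.administered_dose, "direct"
        needed = (
            self.air_concentration_ug_m3,
            self.inhalation_rate_ml_min,
            self.hours_per_day,
            self.days,
        )
        if any(v is None for v in needed):
            raise ValueError(
                "dose model incomplete: supply administered_dose or all of "
                "air concentration, inhalation rate, hours/day and days"
            )
        inhaled_m3 = (
            self.inhalation_rate_ml_min * 60.0 * self.hours_per_day * self.days * 1e-6
        )
        dose_ug = (
            self.air_concentration_ug_m3
            * inhaled_m3
            * self.deposition_fraction
            * self.magnetic_fe_fraction
        )
        if dose_ug <= 0:
            raise ValueError("computed dose is nonpositive")
        return dose_ug, "air_conc x ventilation x schedule x deposition x magnetic-Fe"


@dataclass
class RetentionResult:
    """Percent of the administered dose recovered in one compartment."""

    compartment: str
    basis: str  # "mass" | "number"
    percent: float
    dose_form: str
    exceeds_dose: bool = False


def retention_rate(
    compartment_burden: float,
    dose: DoseModel,
    compartment: str = "",
    basis: str = "mass",
) -> RetentionResult:
    """Retention rate: 100 * compartment burden / administered dose, on a
    declared basis (Fe mass or particle number). The burden is the measured
    concentration times the total compartment quantity (organ mass, blood
    volume); values above 100% are flagged, not clipped."""
    if compartment_burden < 0:
        raise ValueError("burden must be nonnegative")
    d, form = dose.dose()
    pct = 100.0 * compartment_burden / d
    return RetentionResult(compartment, basis, pct, form, exceeds_dose=pct > 100.0)


def element_contribution(table: pd.Series | dict, element: str) -> float:
    """Share of one element in the summed panel of a bulk concentration
    table (e.g. Fe as a fraction of the 22-metal total)."""
    s = pd.Series(table, dtype=float)
    if (s < 0).any():
        raise ValueError("negative concentration in panel")
    total = float(s.sum())
    if total <= 0:
        raise ValueError("panel sums to zero; contribution undefined")
    return float(s[element]) / total


def size_summary(diameters_nm) -> dict[str, float]:
    """Arithmetic mean/SD, median and geometric SD of particle diameters."""
    d = np.asarray(diameters_nm, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no particles to summarize")
    gsd = float(np.exp(np.log(d).std(ddof=1))) if d.size > 1 else 1.0
    return {
        "mean_nm": float(d.mean()),
        "sd_nm": float(d.std(ddof=1)) if d.size > 1 else 0.0,
        "median_nm": float(np.median(d)),
        "gsd": gsd,
        "n": int(d.size),
    }


def fraction_bins(
    fe_fractions,
    edges=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
) -> dict[str, object]:
    """Number proportions of particles per Fe-mass-fraction bin.

    Bins are left-closed over ``edges`` (which must cover [0, 1]); the
    proportions sum to 1 and the particles at exactly 1.0 — Fe the only
    detected metal — are additionally reported as the single-metal
    proportion."""
    f = np.asarray(fe_fractions, dtype=float)
    f = f[np.isfinite(f)]
    if f.size == 0:
        raise ValueError("no particles to bin")
    edges = np.asarray(edges, dtype=float)
    if edges[0] > 0 or edges[-1] < 1:
        raise ValueError("bin edges must cover [0, 1]")
    hist, _ = np.histogram(f, bins=edges)
    props = hist / f.size
    return {
        "edges": list(map(float, edges)),
        "proportions": list(map(float, props)),
        "single_metal_proportion": float(np.mean(f >= 1.0)),
        "n": int(f.size),
    }


def replicate_aggregate(values_per_metric: dict[str, list[float]]) -> pd.DataFrame:
    """Mean +/- SD across replicates for each metric. With a single
    replicate the SD is NaN (flagged undefined), never zero."""
    rows = []
    for metric, vals in values_per_metric.items():
        v = np.asarray(vals, dtype=float)
        rows.append(
            {
                "metric": metric,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
                "n": int(v.size),
            }
        )
    return pd.DataFrame(rows)


def group_compare(exposed_values, control_values) -> dict[str, float]:
    """Welch's two-sample t-test (unequal variances) of exposed vs control
    replicate metrics; returns group means/SDs, the difference, t and the
    two-sided p. Degenerate zero-variance inputs with equal means give
    p = 1 by convention."""
    e = np.asarray(exposed_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if e.size < 2 or c.size < 2:
        raise ValueError("need >= 2 replicates per group")
    out = {
        "mean_exposed": float(e.mean()),
        "sd_exposed": float(e.std(ddof=1)),
        "mean_control": float(c.mean()),
        "sd_control": float(c.std(ddof=1)),
        "difference": float(e.mean() - c.mean()),
    }
    if out["sd_exposed"] == 0 and out["sd_control"] == 0:
        identical = out["difference"] == 0
        out["t"] = 0.0 if identical else float("inf")
        out["p"] = 1.0 if identical else 0.0
        return out
    t, p = stats.ttest_ind(e, c, equal_var=False)
    out["t"] = float(t)
    out["p"] = float(p)
    return out


def summarize_cohort(
    samples: list[CohortSample],
    eta: TransportEfficiency | float,
    fraction_edges=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
) -> pd.DataFrame:
    """Per tissue x group summary over replicates: number concentration and
    Fe mass concentration (mean +/- SD across replicates), size statistics
    and Fe-fraction proportions over the pooled particles."""
    rows = []
    keys = sorted({(s.tissue, s.group) for s in samples})
    for tissue, group in keys:
        group_samples = [s for s in samples if s.tissue == tissue and s.group == group]
        ncs = [number_concentration(s, eta) for s in group_samples]
        mcs = [mass_concentration(s, eta) for s in group_samples]
        pooled = pd.concat([s.particles for s in group_samples], ignore_index=True)
        diam = pooled["diameter_nm"].dropna().to_numpy()
        sz = size_summary(diam) if diam.size else {}
        fb = (
            fraction_bins(pooled["fe_fraction"].dropna().to_numpy(), fraction_edges)
            if len(pooled)
            else {}
        )
        nc = np.asarray(ncs)
        mc = np.asarray(mcs)
        rows.append(
            {
                "tissue": tissue,
                "group": group,
                "n_replicates": len(group_samples),
                "n_particles": int(len(pooled)),
                "number_conc_per_ml": float(nc.mean()),
                "number_conc_sd": float(nc.std(ddof=1)) if nc.size > 1 else float("nan"),
                "fe_mass_conc_fg_per_ml": float(mc.mean()),
                "fe_mass_conc_sd": float(mc.std(ddof=1)) if mc.size > 1 else float("nan"),
                "mean_diameter_nm": sz.get("mean_nm", float("nan")),
                "median_diameter_nm": sz.get("median_nm", float("nan")),
                "diameter_gsd": sz.get("gsd", float("nan")),
                "single_metal_proportion": fb.get("single_metal_proportion", float("nan")),
            }
        )
    return pd.DataFrame(rows)
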