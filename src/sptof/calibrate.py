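"""Counts-to-mass calibration: dissolved sensitivities, transport efficiency
from a nanoparticle reference standard, mass/size detection limits, and spike
recovery.

The mass conversion follows the standard single-particle ICP-MS relation

    m_X = I_net * eta * q * t_acq / S_X

where ``S_X`` is the dissolved sensitivity of element X (counts per
acquisition per ug/L), ``eta`` the transport efficiency, ``q`` the sample
flow and ``t_acq`` the acquisition time. With q in L/s and S against ug/L
the mass comes out in ug; results are reported in femtograms (1 ug = 1e9 fg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import pi, sqrt

import numpy as np
from scipy import stats

__all__ = [
    "DissolvedCalibration",
    "ReferenceParticleStandard",
    "TransportEfficiency",
    "MassCalibrationModel",
    "fit_sensitivity",
    "transport_efficiency_frequency",
    "transport_efficiency_size",
    "mass_lod",
    "spike_recovery",
    "ml_per_min_to_l_per_s",
]

FG_PER_UG = 1e9

#: The dissolved calibration series used throughout: seven levels in ug/L,
#: the zero level serving as the blank run.
DEFAULT_CAL_LEVELS_UG_L = (0.0, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0)


def ml_per_min_to_l_per_s(q_ml_min: float) -> float:
    """Convert a sample flow from mL min^-1 to L s^-1."""
    return q_ml_min * 1e-3 / 60.0


@dataclass
class DissolvedCalibration:
    """Fitted dissolved response of one element."""

    element: str
    levels_ug_l: list[float]
    mean_counts: list[float]  # per acquisition, one per level
    slope: float  # counts acq^-1 (ug/L)^-1
    intercept: float  # counts acq^-1
    r_squared: float
    blank_sd: float  # counts, from the 0 level
    calibratable: bool = True


@dataclass(frozen=True)
class ReferenceParticleStandard:
    """A monodisperse nanoparticle number-concentration standard (e.g. the
    50 nm Au standard used to determine transport efficiency)."""

    diameter_nm: float
    density: float  # kg m^-3
    host_element: str = "Au"
    host_mass_fraction: float = 1.0
    number_concentration: float = 1e5  # particles per mL of measured suspension

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0 or self.density <= 0:
            raise ValueError("diameter and density must be positive")
        if not 0 < self.host_mass_fraction <= 1:
            raise ValueError("host_mass_fraction must be in (0, 1]")
        if self.number_concentration <= 0:
            raise ValueError("number concentration must be positive")

    @property
    def particle_mass_fg(self) -> float:
        """Sphere mass (pi/6) d^3 rho, in fg."""
        d_m = self.diameter_nm * 1e-9
        return pi / 6.0 * d_m**3 * self.density * 1e18

    @property
    def host_mass_fg(self) -> float:
        return self.particle_mass_fg * self.host_mass_fraction


@dataclass
class TransportEfficiency:
    """Transport (transmission) efficiency estimate."""

    eta: float
    method: str  # "frequency" | "size"
    se: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.eta <= 1:
            raise ValueError(
                f"transport efficiency {self.eta:.4g} outside (0, 1]; "
                "inconsistent standard or instrument inputs"
            )


def fit_sensitivity(
    element: str,
    levels_ug_l,
    runs,
    weighted: bool = False,
) -> DissolvedCalibration:
    """Fit the dissolved sensitivity of one element by least squares of mean
    counts per acquisition against concentration.

    ``runs`` is one AcquisitionRun per level (the 0 level is the blank); the
    blank mean anchors the intercept (it is subtracted before the fit, and
    the reported intercept is relative to the blank level). At the study's
    sub-10 ug/L levels the averaged counts are near-homoscedastic, so the
    default is unweighted OLS; ``weighted=True`` applies 1/variance Poisson
    weights.
    """
    levels = np.asarray(levels_ug_l, dtype=float)
    if levels.size < 3:
        raise ValueError("need >= 3 concentration levels")
    if np.any(np.diff(levels) <= 0):
        raise ValueError("concentration levels must be strictly increasing")
    if np.any(levels < 0):
        raise ValueError("negative concentration level")
    if 0.0 not in levels:
        raise ValueError("levels must include a 0 (blank) level")
    if len(runs) != levels.size:
        raise ValueError("one run per concentration level required")

    means = np.array([float(r.series(element).mean()) for r in runs])
    blank_idx = int(np.flatnonzero(levels == 0.0)[0])
    blank_series = runs[blank_idx].series(element)
    blank_sd = float(blank_series.std(ddof=1)) if blank_series.size > 1 else 0.0
    y = means - means[blank_idx]

    if np.allclose(means, 0.0):
        return DissolvedCalibration(
            element, list(levels), list(means), 0.0, 0.0, 0.0, blank_sd,
            calibratable=False,
        )

    if weighted:
        # Poisson variance of a mean ~ mu / n_acq; guard zero with the blank
        var = np.maximum(means, 1.0) / np.array([r.n_acquisitions for r in runs])
        w = 1.0 / var
        W = np.diag(w)
        X = np.column_stack([np.ones_like(levels), levels])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        intercept, slope = float(beta[0]), float(beta[1])
        resid = y - X @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        fit = stats.linregress(levels, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue**2)

    if slope < 0:
        raise ValueError(
            f"negative fitted sensitivity for {element}: corrupt calibration input"
        )
    return DissolvedCalibration(
        element, list(levels), list(means), slope, intercept, r2, blank_sd
    )


def transport_efficiency_frequency(
    n_detected: int,
    standard: ReferenceParticleStandard,
    q_sample: float,
    duration: float,
    dilution_factor: float = 1.0,
) -> TransportEfficiency:
    """Transport efficiency from the detected event frequency of a reference
    standard of known number concentration:

        eta = N_detected / (q * duration * C_N / dilution)

    with q in mL s^-1 so q*duration is the aspirated volume in mL. The
    standard error reflects Poisson counting of N_detected.
    """
    if n_detected <= 0:
        raise ValueError("no particles detected in reference run; eta undefined")
    q_ml_s = q_sample / 60.0
    expected_aspirated = q_ml_s * duration * standard.number_concentration / dilution_factor
    eta = n_detected / expected_aspirated
    se = sqrt(n_detected) / expected_aspirated
    return TransportEfficiency(eta=eta, method="frequency", se=se)


def transport_efficiency_size(
    mean_net_counts: float,
    standard: ReferenceParticleStandard,
    sensitivity: float,
    q_sample: float,
    t_acq: float,
    se_mean_counts: float = 0.0,
) -> TransportEfficiency:
    """Transport efficiency from the reference particles' mean signal:

        eta = m_ref * S / (I_bar * q * t_acq)

    where ``m_ref`` is the known per-particle host-element mass of the
    standard. A cross-check of the frequency method that requires a fitted
    dissolved sensitivity ``S`` for the host element.
    """
    if mean_net_counts <= 0:
        raise ValueError("zero mean event intensity; eta undefined")
    if sensitivity <= 0:
        raise ValueError("host-element sensitivity must be positive")
    q_l_s = ml_per_min_to_l_per_s(q_sample)
    m_ref_ug = standard.host_mass_fg / FG_PER_UG
    eta = m_ref_ug * sensitivity / (mean_net_counts * q_l_s * t_acq)
    se = eta * (se_mean_counts / mean_net_counts) if se_mean_counts else 0.0
    return TransportEfficiency(eta=eta, method="size", se=se)


@dataclass
class MassCalibrationModel:
    """Per-element counts -> mass (fg) conversion.

    ``sensitivities`` maps element -> S in counts per acquisition per ug/L;
    ``eta`` is shared across elements; ``q_sample`` is in mL min^-1 and
    ``t_acq`` in seconds. The conversion factor per count is
    F = eta * q * t_acq / S (in fg per count after unit conversion), so
    mass is exactly linear in net counts and zero maps to zero.
    """

    sensitivities: dict[str, float]
    eta: float
    q_sample: float  # mL min^-1
    t_acq: float  # s
    mass_lod_fg: dict[str, float] = field(default_factory=dict)
    blank_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        if self.q_sample <= 0 or self.t_acq <= 0:
            raise ValueError("flow and acquisition time must be positive")
        for elem, s in self.sensitivities.items():
            if s <= 0:
                raise ValueError(f"nonpositive sensitivity for {elem}")

    @property
    def elements(self) -> list[str]:
        return list(self.sensitivities)

    def fg_per_count(self, element: str) -> float:
        if element not in self.sensitivities:
            raise KeyError(f"element {element!r} is not calibrated")
        q_l_s = ml_per_min_to_l_per_s(self.q_sample)
        return self.eta * q_l_s * self.t_acq / self.sensitivities[element] * FG_PER_UG

    def counts_to_mass(self, net_counts: float, element: str) -> float:
        """Mass in fg for the given net counts of ``element``."""
        return net_counts * self.fg_per_count(element)

    def mass_to_counts(self, mass_fg: float, element: str) -> float:
        """Inverse conversion (used by the forward simulator)."""
        return mass_fg / self.fg_per_count(element)


def mass_lod(
    blank_sd: float,
    model: MassCalibrationModel,
    element: str,
    multiplier: float = 3.0,
) -> float:
    """Mass detection limit (fg): ``multiplier * sigma_blank`` converted
    through the counts->mass factor (3-sigma criterion by default)."""
    if blank_sd < 0 or not np.isfinite(blank_sd):
        raise ValueError("blank sigma undefined")
    return multiplier * blank_sd * model.fg_per_count(element)


def size_lod(
    mass_lod_fg: float,
    phase,
) -> float:
    """Size detection limit (nm) for a declared mineral phase: the
    equivalent-sphere diameter at the host-element mass LOD."""
    from .composition import equivalent_diameter

    if mass_lod_fg <= 0:
        return 0.0
    return equivalent_diameter(mass_lod_fg, phase)


def spike_recovery(measured: float, nominal: float) -> float:
    """Percent recovery of a spiked quantity: 100 * measured / nominal."""
    if nominal <= 0:
        raise ValueError("nominal spike must be positive")
    return 100.0 * measured / nominal


def build_calibration_model(
    calibrations: list[DissolvedCalibration],
    eta: TransportEfficiency,
    q_sample: float,
    t_acq: float,
    lod_multiplier: float = 3.0,
) -> MassCalibrationModel:
    """Assemble the per-element mass-calibration model from fitted dissolved
    sensitivities and a transport-efficiency estimate, with 3-sigma mass LODs
    derived from each element's blank scatter."""
    sens = {c.element: c.slope for c in calibrations if c.calibratable and c.slope > 0}
    model = MassCalibrationModel(
        sensitivities=sens, eta=eta.eta, q_sample=q_sample, t_acq=t_acq
    )
    for c in calibrations:
        if c.element in sens:
            model.blank_sd[c.element] = c.blank_sd
            model.mass_lod_fg[c.element] = mass_lod(
                c.blank_sd, model, c.element, lod_multiplier
            )
    return model
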