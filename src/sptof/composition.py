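"""Per-particle element masses, Fe mass fractions, composition classes and
equivalent-sphere sizing under a declared mineral-phase model.

The sizing model assumes each particle is a homogeneous sphere of a single
mineral phase (magnetite Fe3O4 by default). The host-element mass measured by
the instrument is scaled up to total particle mass through the phase's host
mass fraction, and the equivalent spherical diameter follows from the phase
density. Oxygen is not measured by the instrument, so mass fractions are
always over the *detected metal* panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import MassCalibrationModel
from .detect import ParticleEvent

__all__ = [
    "ATOMIC_MASS",
    "MineralPhase",
    "MAGNETITE",
    "HEMATITE",
    "ParticleRecord",
    "stoichiometric_ratio",
    "equivalent_diameter",
    "element_masses",
    "fe_mass_fraction",
    "classify_particle",
    "events_to_particle_table",
]

# IUPAC 2021 standard atomic weights (g mol^-1), rounded to 3 decimals.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008, "O": 15.999, "Na": 22.990, "Mg": 24.305, "Al": 26.982,
    "Si": 28.085, "K": 39.098, "Ca": 40.078, "Ti": 47.867, "V": 50.942,
    "Cr": 51.996, "Mn": 54.938, "Fe": 55.845, "Co": 58.933, "Ni": 58.693,
    "Cu": 63.546, "Zn": 65.38, "As": 74.922, "Sr": 87.62, "Mo": 95.95,
    "Cd": 112.414, "Sn": 118.710, "Sb": 121.760, "Ba": 137.327,
    "Pb": 207.2, "Au": 196.967,
}


@dataclass(frozen=True)
class MineralPhase:
    """A stoichiometric mineral phase used for particle sizing.

    ``host_mass_fraction`` is derived from the stoichiometry and standard
    atomic masses; e.g. for magnetite Fe3O4 it is
    3*M(Fe) / (3*M(Fe) + 4*M(O)) ~= 0.7236.
    """

    name: str
    stoichiometry: dict[str, int]
    density: float  # kg m^-3
    host_element: str = "Fe"

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.host_element not in self.stoichiometry:
            raise ValueError(f"host element {self.host_element} absent from stoichiometry")
        for elem in self.stoichiometry:
            if elem not in ATOMIC_MASS:
                raise ValueError(f"no atomic mass for element {elem!r}")

    @property
    def host_mass_fraction(self) -> float:
        total = sum(n * ATOMIC_MASS[e] for e, n in self.stoichiometry.items())
        return self.stoichiometry[self.host_element] * ATOMIC_MASS[self.host_element] / total


#: Magnetite Fe3O4, the dominant Fe-bearing phase in combustion-derived
#: particles; density 5170 kg m^-3, atomic Fe/O = 3/4.
MAGNETITE = MineralPhase("magnetite", {"Fe": 3, "O": 4}, density=5170.0)

#: Hematite Fe2O3 (alternative sizing phase), density 5260 kg m^-3.
HEMATITE = MineralPhase("hematite", {"Fe": 2, "O": 3}, density=5260.0)

PHASES: dict[str, MineralPhase] = {"magnetite": MAGNETITE, "hematite": HEMATITE}


def stoichiometric_ratio(phase: MineralPhase, elem_a: str, elem_b: str) -> float:
    """Atomic ratio elem_a : elem_b in the phase formula unit.

    For magnetite, Fe/O = 3/4 = 0.75 — the lower edge of the Fe/O window
    diagnostic for magnetite in elemental microanalysis.
    """
    for e in (elem_a, elem_b):
        if e not in phase.stoichiometry:
            raise KeyError(f"element {e!r} absent from phase {phase.name}")
    return phase.stoichiometry[elem_a] / phase.stoichiometry[elem_b]


def equivalent_diameter(m_host_fg: float | np.ndarray, phase: MineralPhase = MAGNETITE):
    """Equivalent spherical diameter (nm) from host-element mass (fg).

    The particle mass is ``m_host / w_host`` and the diameter is that of a
    sphere of the phase density with this mass: d = (6 m_p / (pi rho))^(1/3).
    Strictly increasing in ``m_host``.
    """
    m = np.asarray(m_host_fg, dtype=float)
    if np.any(m <= 0):
        raise ValueError("host mass must be positive")
    m_particle_kg = m / phase.host_mass_fraction * 1e-18  # fg -> kg
    d_m = (6.0 * m_particle_kg / (np.pi * phase.density)) ** (1.0 / 3.0)
    d_nm = d_m * 1e9
    return float(d_nm) if np.isscalar(m_host_fg) else d_nm


def sphere_mass_fg(diameter_nm: float | np.ndarray, density: float) -> float | np.ndarray:
    """Mass (fg) of a sphere of given diameter (nm) and density (kg m^-3)."""
    d_m = np.asarray(diameter_nm, dtype=float) * 1e-9
    m_kg = np.pi / 6.0 * d_m**3 * density
    m_fg = m_kg * 1e18
    return float(m_fg) if np.isscalar(diameter_nm) else m_fg


@dataclass
class ParticleRecord:
    """One detected particle: calibrated element masses and derived metrics.

    ``masses`` holds only elements detected at or above their mass LOD (the
    below-LOD rule is strict: mass < LOD is masked). ``fe_fraction`` is the
    Fe share of the summed detected-metal mass; oxygen is unmeasured and
    never enters the denominator.
    """

    masses: dict[str, float]  # fg, detected elements only
    fe_fraction: float | None = None
    diameter_nm: float | None = None
    classes: frozenset[str] = field(default_factory=frozenset)
    window: tuple[int, int] | None = None

    @property
    def total_metal_mass(self) -> float:
        return float(sum(self.masses.values()))


def element_masses(
    event: ParticleEvent,
    model: MassCalibrationModel,
    lod_fg: dict[str, float] | None = None,
) -> ParticleRecord:
    """Convert a detected event's net counts into a per-element mass record.

    An element is attributed to the particle only if it was flagged above
    its detection threshold within the event window (sub-threshold net
    counts are background fluctuation, not particle mass) AND its converted
    mass reaches the element's mass LOD (the below-LOD rule is strict:
    mass < LOD is masked). Every flagged element must be calibrated.
    """
    lod = lod_fg if lod_fg is not None else model.mass_lod_fg
    masses: dict[str, float] = {}
    for elem, net in event.net_counts.items():
        if not event.above_threshold.get(elem, False) or net <= 0:
            continue
        m = model.counts_to_mass(net, elem)
        if lod and elem in lod and m < lod[elem]:
            continue  # below LOD: not detected
        masses[elem] = m
    return ParticleRecord(masses=masses, window=event.window)


def fe_mass_fraction(record: ParticleRecord, host_element: str = "Fe") -> float:
    """Host-element (Fe) share of the particle's detected metal mass."""
    total = record.total_metal_mass
    if total <= 0:
        raise ValueError("no detected metal mass; Fe fraction undefined")
    return record.masses.get(host_element, 0.0) / total


def classify_particle(
    record: ParticleRecord,
    fe_rich_threshold: float = 0.40,
    host_element: str = "Fe",
) -> frozenset[str]:
    """Assign composition class labels.

    - ``Fe-containing``: host element detected.
    - ``Fe-rich``: Fe mass fraction strictly greater than the threshold
      (default 0.40).
    - ``single-metal-Fe``: Fe is the only detected element (fraction 1.0).
    - ``multi-metal``: Fe plus at least one other detected metal.
    """
    labels: set[str] = set()
    if host_element in record.masses:
        labels.add("Fe-containing")
        frac = fe_mass_fraction(record, host_element)
        if frac > fe_rich_threshold:
            labels.add("Fe-rich")
        if len(record.masses) == 1:
            labels.add("single-metal-Fe")
        else:
            labels.add("multi-metal")
    elif record.masses:
        labels.add("multi-metal" if len(record.masses) > 1 else "other-single-metal")
    return frozenset(labels)


def events_to_particle_table(
    events: list[ParticleEvent],
    model: MassCalibrationModel,
    phase: MineralPhase = MAGNETITE,
    fe_rich_threshold: float = 0.40,
    host_element: str = "Fe",
) -> pd.DataFrame:
    """Quantify a list of events into a particle table (one row per particle).

    Columns: window start/end, per-element mass (fg; NaN when not detected),
    total detected metal mass, Fe mass fraction, equivalent diameter under
    ``phase`` (NaN when the host element is not detected), and boolean class
    columns. Events with no detected element above LOD are dropped.
    """
    rows = []
    for ev in events:
        rec = element_masses(ev, model)
        if not rec.masses:
            continue
        classes = classify_particle(rec, fe_rich_threshold, host_element)
        m_host = rec.masses.get(host_element, np.nan)
        row: dict[str, object] = {
            "start": ev.window[0],
            "end": ev.window[1],
            "total_metal_fg": rec.total_metal_mass,
            "fe_fraction": (
                fe_mass_fraction(rec, host_element) if rec.masses else np.nan
            ),
            "diameter_nm": (
                equivalent_diameter(m_host, phase) if m_host == m_host and m_host > 0 else np.nan
            ),
            "fe_containing": "Fe-containing" in classes,
            "fe_rich": "Fe-rich" in classes,
            "single_metal_fe": "single-metal-Fe" in classes,
            "multi_metal": "multi-metal" in classes,
        }
        for elem in model.elements:
            row[f"mass_{elem}_fg"] = rec.masses.get(elem, np.nan)
        rows.append(row)
    cols = [
        "start", "end", "total_metal_fg", "fe_fraction", "diameter_nm",
        "fe_containing", "fe_rich", "single_metal_fe", "multi_metal",
    ] + [f"mass_{e}_fg" for e in model.elements]
    return pd.DataFrame(rows, columns=cols)
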