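import numpy as np
import pytest

from sptof.calibrate import MassCalibrationModel, ReferenceParticleStandard
from sptof.io import AcquisitionRun
from sptof.simulate import InstrumentParams, ParticlePopulation, SimulationConfig


@pytest.fixture
def instrument():
    return InstrumentParams(q_sample=0.3, t_acq=1e-3, duration=60.0, eta=0.05)


@pytest.fixture
def sensitivities():
    return {"Fe": 100.0, "Al": 120.0, "Si": 60.0}


@pytest.fixture
def magnetite_population():
    return ParticlePopulation(
        phase_name="magnetite",
        number_concentration=2e5,
        size_median_nm=140.0,
        size_gsd=1.5,
        phase_density=5170.0,
        host_element="Fe",
        host_mass_fraction=0.7236,
    )


@pytest.fixture
def simple_config(instrument, sensitivities, magnetite_population):
    return SimulationConfig(
        populations=(magnetite_population,),
        sensitivities=sensitivities,
        dissolved_background={"Fe": 0.05},
        instrument=instrument,
        seed=42,
    )


@pytest.fixture
def unit_model():
    """Calibration model matching the worked unit example: eta=0.05,
    q=0.6 mL/min, t=1 ms, S=100 -> 5e-3 fg per count."""
    return MassCalibrationModel(
        sensitivities={"Fe": 100.0, "Al": 120.0, "Au": 100.0},
        eta=0.05,
        q_sample=0.6,
        t_acq=1e-3,
    )


@pytest.fixture
def au_standard():
    return ReferenceParticleStandard(
        diameter_nm=50.0, density=19300.0, host_element="Au",
        number_concentration=1e5,
    )


def make_run(counts, elements=("Fe",), t_acq=1e-3, q_sample=0.3, **kw):
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, None]
    return AcquisitionRun(
        counts=counts, elements=list(elements), t_acq=t_acq, q_sample=q_sample, **kw
    )


@pytest.fixture
def run_factory():
    return make_run
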