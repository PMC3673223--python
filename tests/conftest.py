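import numpy as np
import pytest

from hiertx.kinetics import CellKinetics, CellTimeSeries, ChangepointTranscription
from hiertx.simulate import PopulationSpec, make_benchmark

try:
    from hypothesis import settings, HealthCheck

    settings.register_profile(
        "ci", derandomize=True, deadline=None,
        suppress_health_check=[HealthCheck.too_slow])
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def basic_kinetics() -> CellKinetics:
    """A benchmark-scale cell: several mRNA, hundreds of protein molecules."""
    return CellKinetics(
        transcription=ChangepointTranscription(tau_off=0.2, tau_on=2.0, switch_time=10.0),
        alpha=2.0, delta_M=0.2, delta_P=0.05,
        copy_number=3.0, kappa=1.0, sigma_eps2=900.0)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Three groups of 3 cells each, 26 observations: fast fitting fixture."""
    spec = PopulationSpec(
        n_cells_per_group={"A": 3, "B": 3, "C": 3},
        obs_times=np.arange(0.0, 51.0, 2.0))
    return make_benchmark(spec, seed=42)
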