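import numpy as np
import pytest

from zincquant.core_model import CalibrationEndpoints, SensorParams


@pytest.fixture
def fluozin3() -> SensorParams:
    """Intensity dye: Kd 9.1 nM, single-site binding (n = 1)."""
    return SensorParams("FluoZin-3", kd_nM=9.1, hill_n=1.0)


@pytest.fixture
def fret_sensor() -> SensorParams:
    """Cytosolic FRET sensor with its in-vitro Kd of 5.3 nM; the Hill
    coefficient is not a published constant, so tests pick n = 1 explicitly."""
    return SensorParams("NES-ZapCV2", kd_nM=5.3, hill_n=1.0)


@pytest.fixture
def unit_endpoints() -> CalibrationEndpoints:
    return CalibrationEndpoints(f_min=1.0, f_max=3.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
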