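import numpy as np
import pytest

from pterosoar.bone_mechanics import MaterialParams
from pterosoar.flight_performance import GlidePolarParams, Planform


@pytest.fixture(scope="session")
def default_params() -> GlidePolarParams:
    return GlidePolarParams()


@pytest.fixture(scope="session")
def default_material() -> MaterialParams:
    return MaterialParams()


@pytest.fixture(scope="session")
def chatterjee_planform() -> Planform:
    """Narrow Quetzalcoatlus reconstruction: 70 kg, 10.39 m span, 9.55 m^2."""
    return Planform(span=10.39, area=9.55, mass=70.0, label="chatterjee")


@pytest.fixture(scope="session")
def witton_planform() -> Planform:
    """Broad, heavy Quetzalcoatlus reconstruction: 259.06 kg, 9.64 m, 11.36 m^2."""
    return Planform(span=9.64, area=11.36, mass=259.06, label="witton")


@pytest.fixture(scope="session")
def random_planforms() -> list[Planform]:
    """100 seeded random, aerodynamically valid planforms.

    Wing loading follows a mass allometry spanning shearwaters to giant
    azhdarchids; draws whose unconstrained minimum-sink speed would fall
    below the steady stall speed lie outside the glide polar's validity
    domain and are rejected.
    """
    from pterosoar.flight_performance import (
        GlidePolarParams,
        minimum_sink_speed,
        stall_speed,
    )

    params = GlidePolarParams()
    rng = np.random.default_rng(42)
    planforms: list[Planform] = []
    while len(planforms) < 100:
        mass = 10 ** rng.uniform(-0.5, 2.4)  # 0.3 - 250 kg
        loading = 10 ** (1.70 + 0.25 * np.log10(mass) + rng.normal(0, 0.12))
        ar = rng.uniform(6.0, 19.0)
        area = mass * 9.81 / loading
        span = float(np.sqrt(ar * area))
        pf = Planform(span=span, area=area, mass=mass, label=f"r{len(planforms)}")
        v_ms, _ = minimum_sink_speed(pf, params)
        if v_ms > stall_speed(pf, params, params.cl_max_steady):
            planforms.append(pf)
    return planforms
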