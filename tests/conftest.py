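import pytest

import epiland as el
from epiland.attractors import find_fixed_points, stable_points
from epiland.experiments import SweepSpec, run_basal_shift, run_hill_sweep
from epiland.landscape import GridSpec, align, build_trajectory_fan, interpolate_surface


@pytest.fixture(scope="session")
def bistable():
    return el.get_preset("bistable")


@pytest.fixture(scope="session")
def tristable():
    return el.get_preset("tristable")


@pytest.fixture(scope="session")
def bistable_fps(bistable):
    return find_fixed_points(bistable, seed=1)


@pytest.fixture(scope="session")
def tristable_fps(tristable):
    return find_fixed_points(tristable, seed=1)


@pytest.fixture(scope="session")
def bistable_stable(bistable_fps):
    return stable_points(bistable_fps)


@pytest.fixture(scope="session")
def tristable_stable(tristable_fps):
    return stable_points(tristable_fps)


def _make_landscape(params, fps, n=41):
    fan = build_trajectory_fan(params, GridSpec.for_params(params, n=n),
                               fixed_points=fps)
    aligned = align(fan)
    surface = interpolate_surface(aligned)
    return fan, aligned, surface


@pytest.fixture(scope="session")
def bistable_landscape(bistable, bistable_fps):
    return _make_landscape(bistable, bistable_fps)


@pytest.fixture(scope="session")
def tristable_landscape(tristable, tristable_fps):
    return _make_landscape(tristable, tristable_fps)


@pytest.fixture(scope="session")
def hill_sweep_table():
    """Hill-coefficient sweep at the scaled-down study conditions."""
    return run_hill_sweep(SweepSpec(seed=1))


@pytest.fixture(scope="session")
def basal_shift_table():
    """Basal-expression remodeling comparison (B_Y 0 -> 4 at n_H = 10)."""
    spec = SweepSpec(
        base=el.get_preset("tristable").replace(n_H=10.0),
        swept_field="B_Y", values=(0.0, 4.0), seed=1,
    )
    return run_basal_shift(spec)
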