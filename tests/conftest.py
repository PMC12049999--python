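import pytest

from cardiotag.anatomy import LVGeometry, voxelize_lv
from cardiotag.grids import GridSpec
from cardiotag.motion import MotionParams


@pytest.fixture(scope="session")
def grid128():
    return GridSpec((128, 128, 128), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def grid96():
    return GridSpec((96, 96, 96), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def geometry():
    """A mid-sized physiological LV that fits a 96 mm field of view."""
    return LVGeometry(
        endo_radius_eq=20.0,
        wall_thickness=8.0,
        long_axis_length=72.0,
        base_truncation_fraction=0.6,
    )


@pytest.fixture(scope="session")
def voxelized(geometry, grid96):
    labels, mesh = voxelize_lv(geometry, grid96)
    return labels, mesh


@pytest.fixture(scope="session")
def motion():
    return MotionParams(contraction=0.2, twist_deg=12.0, shortening=0.15)


@pytest.fixture(scope="session")
def scaled_learning_result():
    """The full desk-scale simulate-train-evaluate cycle (runs once)."""
    from cardiotag.experiments import run_scaled_learning

    return run_scaled_learning(seed=1)
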