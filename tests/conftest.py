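import numpy as np
import pytest

from qus_settingcal import PatchGridSpec, build_setting_calibrator
from qus_settingcal.simulator import (
    MISMATCH_PRESETS,
    SimConfig,
    make_calibration_stacks,
    preset_pair,
)

_PRESET_SEEDS = {"frequency": 101, "focus": 202, "power": 303}


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def grid() -> PatchGridSpec:
    return PatchGridSpec()


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Reduced geometry for cheap unit tests (still >= one full gate)."""
    return SimConfig(n_axial=600, n_lateral=64)


@pytest.fixture(scope="session")
def small_grid() -> PatchGridSpec:
    return PatchGridSpec(
        skip_axial=100,
        patch_axial=200,
        stride_axial=100,
        n_axial_lines=3,
        patch_lateral=26,
        stride_lateral=26,
        n_lateral_lines=2,
    )


@pytest.fixture(scope="session", params=sorted(MISMATCH_PRESETS))
def preset_calibration(request, sim_cfg, grid):
    """(name, train setting, test setting, stacks, calibrator) per mismatch."""
    name = request.param
    setting_a, setting_b = preset_pair(name)
    stack_a, stack_b = make_calibration_stacks(
        sim_cfg, setting_a, setting_b, n_repeats=10, seed=_PRESET_SEEDS[name]
    )
    cal = build_setting_calibrator(stack_a, stack_b, grid)
    return name, setting_a, setting_b, (stack_a, stack_b), cal


@pytest.fixture(scope="session")
def freq_calibration(sim_cfg, grid):
    """Frequency-mismatch stacks + calibrator (the hardest preset)."""
    setting_a, setting_b = preset_pair("frequency")
    stack_a, stack_b = make_calibration_stacks(
        sim_cfg, setting_a, setting_b, n_repeats=10, seed=_PRESET_SEEDS["frequency"]
    )
    cal = build_setting_calibrator(stack_a, stack_b, grid)
    return setting_a, setting_b, (stack_a, stack_b), cal


@pytest.fixture(scope="session")
def power_calibration(sim_cfg, grid):
    setting_a, setting_b = preset_pair("power")
    stack_a, stack_b = make_calibration_stacks(
        sim_cfg, setting_a, setting_b, n_repeats=10, seed=_PRESET_SEEDS["power"]
    )
    cal = build_setting_calibrator(stack_a, stack_b, grid)
    return setting_a, setting_b, (stack_a, stack_b), cal


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
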