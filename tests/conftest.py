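import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octshaper.source import CalibrationTable, default_calibration

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table():
    """Shipped default AOTF calibration (575-1040 nm)."""
    return default_calibration()


@pytest.fixture()
def flat_table():
    """Linear 2-node calibration with flat unit efficiency and 5 nm linewidth."""
    return CalibrationTable(
        voltage_nodes=[0.0, 10.0],
        wavelength_nodes=[1040.0, 575.0],
        linewidth_nodes=[5.0, 5.0],
        efficiency_nodes=[1.0, 1.0],
    )


def _make_table(linewidth, efficiency=None, n=12):
    """Linear calibration with prescribed linewidth/efficiency profiles."""
    v = np.linspace(0.0, 10.0, n)
    lam = 1040.0 + (575.0 - 1040.0) * v / 10.0
    if callable(linewidth):
        lw = linewidth(lam)
    else:
        lw = np.broadcast_to(np.asarray(linewidth, dtype=float), lam.shape)
    if efficiency is None:
        eff = np.ones_like(lam)
    elif callable(efficiency):
        eff = efficiency(lam)
    else:
        eff = np.broadcast_to(np.asarray(efficiency, dtype=float), lam.shape)
    return CalibrationTable(v, lam, lw, eff)


@pytest.fixture(scope="session")
def make_table():
    """Factory for linear calibrations with prescribed linewidth/efficiency."""
    return _make_table
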