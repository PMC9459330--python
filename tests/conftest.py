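import numpy as np
import pytest

from patchfeat import synthetic_data as sd


@pytest.fixture(scope="session")
def vi_protocol():
    """Seven-step −100…+50 pA family used for the V–I fit."""
    return sd.vi_step_protocol()


@pytest.fixture(scope="session")
def hyper_protocol():
    """The four hyperpolarizing steps −100…−25 pA."""
    return sd.default_step_protocol(hi_pA=-25.0)


@pytest.fixture(scope="session")
def full_protocol():
    return sd.default_step_protocol()


@pytest.fixture(scope="session")
def wt_passive():
    return sd.PassiveParams(R_in_MOhm=176.3, tau_m_ms=22.0, V_rest_mV=-69.3)


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort with short PSC traces (session-cached)."""
    return sd.simulate_cohort(n_cells_per_group=4, seed=11, psc_duration_s=10.0)


def make_flat_sweep(level, duration_s=0.5, rate_hz=20_000.0, mode="current_clamp",
                    command_level=0.0):
    n = int(duration_s * rate_hz)
    t = np.arange(n) / rate_hz
    from patchfeat.trace_model import Sweep

    return Sweep(t, np.full(n, float(level)), np.full(n, float(command_level)), rate_hz, mode)
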