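import pytest

from adexfit import (
    AdExParameters,
    FeatureConfig,
    SimulationConfig,
    build_sinusoid_protocol,
    build_step_protocol,
)


def lif_limit_params(C_m=5.0, g_L=0.05, E_L=-70.0, V_T=-40.0, V_r=-70.0):
    """AdEx degenerate to a leaky integrate-and-fire neuron: no adaptation
    (a = b = 0), minimal slope factor, reset triggered right at threshold."""
    return AdExParameters(
        C_m=C_m, g_L=g_L, E_L=E_L, V_T=V_T, Delta_T=1.0,
        V_peak=V_T, V_r=V_r, a=0.0, b=0.0, tau_w=100.0,
    )


@pytest.fixture
def lif_params():
    return lif_limit_params()


@pytest.fixture
def spiking_params():
    """A well-behaved regular-spiking configuration used across tests."""
    return AdExParameters(
        C_m=4.226, g_L=0.333, E_L=-79.225, V_T=-20.446, Delta_T=55.881,
        V_peak=-19.981, V_r=-76.638, a=0.123, b=-0.999, tau_w=7.138,
    )


@pytest.fixture
def reduced_suite():
    """Short protocol suite: 0.5-s steps, 2.5-s theta-band sinusoids."""
    steps = [build_step_protocol(a, 0.5) for a in (10.0, 16.0, 22.0)]
    sines = [
        build_sinusoid_protocol(a, 12.0, f, 2.5)
        for a in (6.0, 8.0)
        for f in (4.0, 6.0, 8.0)
    ]
    return steps + sines


@pytest.fixture
def tiny_suite():
    """Very short suite for fast end-to-end runs (4 analyzed cycles)."""
    steps = [build_step_protocol(a, 0.2) for a in (10.0, 22.0)]
    sines = [build_sinusoid_protocol(6.0, 12.0, f, 1.0) for f in (4.0, 8.0)]
    return steps + sines


@pytest.fixture
def tiny_feature_config():
    return FeatureConfig(n_cycles=4)


@pytest.fixture
def sim_config():
    return SimulationConfig(dt_ms=0.1)
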