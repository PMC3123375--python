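"""Gating kinetics, channel currents and calcium-pool dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hstheta.channels import (
    CalciumPool,
    ChannelSpec,
    CompartmentState,
    ConfigurationError,
    GateKinetics,
    RateFunction,
    V_RANGE,
    calcium_pool_step,
    channel_current,
    gate_steady_state_and_tau,
)
from hstheta.params import build_gate_kinetics


# independent scalar re-implementations of the default kinetics, coded
# directly from the rate formulas (not via RateFunction/GateKinetics)
def _na_m_inf_tau(v, phi=20.0):
    a = 0.1 * (v + 35.0) / (1.0 - math.exp(-(v + 35.0) / 10.0))
    b = 4.0 * math.exp(-(v + 60.0) / 18.0)
    return a / (a + b), 1.0 / (phi * (a + b))


def _na_h_inf_tau(v, phi=5.0):
    a = 0.07 * math.exp(-(v + 58.0) / 20.0)
    b = 1.0 / (1.0 + math.exp(-(v + 28.0) / 10.0))
    return a / (a + b), 1.0 / (phi * (a + b))


def _k_n_inf_tau(v, phi=5.0):
    a = 0.01 * (v + 34.0) / (1.0 - math.exp(-(v + 34.0) / 10.0))
    b = 0.125 * math.exp(-(v + 44.0) / 80.0)
    return a / (a + b), 1.0 / (phi * (a + b))


class TestGateKinetics:
    @pytest.mark.parametrize(
        "gate,oracle",
        [("na_m", _na_m_inf_tau), ("na_h", _na_h_inf_tau), ("k_n", _k_n_inf_tau)],
    )
    @pytest.mark.parametrize("v", [-80.0, -60.0, -40.0, -20.0, 0.0])
    def test_alpha_beta_matches_independent_evaluation(self, params, gate, oracle, v):
        gk = build_gate_kinetics(params, gate)
        x_inf, tau = gate_steady_state_and_tau(gk, v)
        x_ref, tau_ref = oracle(v)
        assert x_inf == pytest.approx(x_ref, rel=1e-12)
        assert tau == pytest.approx(tau_ref, rel=1e-12)

    def test_equal_rates_give_half_activation(self):
        # alpha(V) == beta(V) implies x_inf = 1/2 by symmetry
        gk = GateKinetics(
            gate_name="g", form="alpha_beta",
            alpha=RateFunction("exponential", 1.0, -50.0, 20.0),
            beta=RateFunction("exponential", 1.0, -50.0, 20.0),
        )
        x_inf, _ = gate_steady_state_and_tau(gk, -50.0)
        assert x_inf == pytest.approx(0.5)

    def test_sigmoidal_activation_saturates(self, params):
        gk = build_gate_kinetics(params, "ca_m")
        assert gk.steady_state(60.0) > 0.999
        assert gk.steady_state(-120.0) < 1e-6

    def test_linoid_removable_singularity(self):
        rf = RateFunction("linoid", 0.1, -35.0, 10.0)
        # continuous through V == vh, limit a*k
        assert rf(-35.0) == pytest.approx(1.0, rel=1e-9)
        assert rf(-35.0 + 1e-9) == pytest.approx(rf(-35.0 - 1e-9), rel=1e-6)

    @pytest.mark.parametrize(
        "gate",
        ["na_m", "na_h", "k_n", "ca_m", "h_r", "a_a", "a_b", "bk_m", "ks_p", "ks_q"],
    )
    def test_bounds_over_physiological_range(self, params, gate):
        gk = build_gate_kinetics(params, gate)
        v = np.linspace(V_RANGE[0], V_RANGE[1], 721)
        x_inf, tau = gate_steady_state_and_tau(gk, v)
        assert np.all((x_inf >= 0.0) & (x_inf <= 1.0))
        assert np.all(tau > 0.0)


class TestChannelCurrent:
    def _state(self, v, gates=None, pools=None):
        return CompartmentState(v=v, gate_values=gates or {}, pools=pools or {})

    def test_zero_conductance_zero_current(self):
        spec = ChannelSpec("k", 0.0, -80.0)
        assert channel_current(spec, self._state(30.0)) == 0.0

    def test_zero_driving_force(self):
        spec = ChannelSpec("leak", 0.3, -65.0)
        assert channel_current(spec, self._state(-65.0)) == 0.0

    def test_leak_magnitude(self):
        # 0.1 mS/cm2 * 10 mV = 1.0 uA/cm2
        spec = ChannelSpec("leak", 0.1, -65.0)
        assert channel_current(spec, self._state(-55.0)) == pytest.approx(1.0)

    def test_gate_product_with_exponents(self):
        gk = GateKinetics("m", "inf_tau", exponent=3, vh=-40.0, k=5.0)
        spec = ChannelSpec("na", 10.0, 55.0, gates=(gk,))
        st_ = self._state(-55.0, gates={"m": 0.5})
        assert channel_current(spec, st_) == pytest.approx(10.0 * 0.125 * (-110.0))

    def test_calcium_gated_channel_uses_pool(self):
        spec = ChannelSpec("ahp", 2.0, -80.0, ca_pool="ahp", ca_kd=1.0)
        pool = CalciumPool("ahp", conc=1.0)
        st_ = self._state(-60.0, pools={"ahp": pool})
        assert channel_current(spec, st_) == pytest.approx(2.0 * 0.5 * 20.0)

    def test_missing_gate_is_configuration_error(self):
        gk = GateKinetics("m", "inf_tau", vh=-40.0, k=5.0)
        spec = ChannelSpec("na", 10.0, 55.0, gates=(gk,))
        with pytest.raises(ConfigurationError):
            channel_current(spec, self._state(-55.0))

    def test_missing_pool_is_configuration_error(self):
        spec = ChannelSpec("ct", 1.0, -80.0, ca_pool="ct")
        with pytest.raises(ConfigurationError):
            channel_current(spec, self._state(-55.0))


class TestCalciumPool:
    def test_blocked_influx_stays_zero(self):
        pool = CalciumPool("ct", b=0.0, tau_ca=8.0, conc=0.0)
        for _ in range(100):
            pool = calcium_pool_step(pool, -50.0, 0.1)
        assert pool.conc == 0.0

    def test_free_decay_is_exact_exponential(self):
        pool = CalciumPool("ahp", b=1.0, tau_ca=80.0, conc=3.0)
        for _ in range(200):
            pool = calcium_pool_step(pool, 0.0, 0.5)
        assert pool.conc == pytest.approx(3.0 * math.exp(-100.0 / 80.0), rel=1e-12)

    def test_constant_current_fixed_point(self):
        # analytic steady state B*k*|I_Ca|*tau, cross-checked against a
        # fine-step explicit Euler integration of the same ODE
        b, k, tau, i_ca = 1.0, 0.13, 40.0, -5.0
        target = b * k * abs(i_ca) * tau
        pool = CalciumPool("ahp", b=b, tau_ca=tau, k_unit=k)
        for _ in range(10_000):
            pool = calcium_pool_step(pool, i_ca, 0.1)
        assert pool.conc == pytest.approx(target, rel=1e-6)
        conc, dt = 0.0, 0.001
        for _ in range(400_000):
            conc += dt * (-b * k * i_ca - conc / tau)
        assert pool.conc == pytest.approx(conc, rel=1e-3)

    @given(st.floats(0.0, 5.0), st.floats(-20.0, 0.0))
    @settings(max_examples=50, deadline=None)
    def test_concentration_never_negative(self, conc0, i_ca):
        pool = CalciumPool("ct", b=1.0, tau_ca=8.0, conc=conc0)
        for _ in range(20):
            pool = calcium_pool_step(pool, i_ca, 0.5)
            assert pool.conc >= 0.0
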