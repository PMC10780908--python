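"""Tests for the reduced musculoskeletal model, assistance and energy."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import exofatigue as xf
from exofatigue.biomech import GRAVITY, JointState, MtgModel


def _static_state(theta_deg, n=50, duration=5.0):
    t = np.linspace(0.0, duration, n)
    z = np.zeros_like(t)
    return JointState(t, np.full_like(t, theta_deg), z, z)


def _bare_model(**kw):
    defaults = dict(
        subject_id="X",
        sex="male",
        tau0_pos=80.0,
        tau0_neg=56.0,
        arm_mass=2.5,
        arm_length=0.6,
        com_length=0.4,
        inertia=2.5 * 0.6**2 / 3,
    )
    defaults.update(kw)
    return MtgModel(**defaults)


# ------------------------------------------------------------- scaling


def test_scale_model_deterministic_and_linear_in_mass(subject_m):
    m1, m2 = xf.scale_model(subject_m), xf.scale_model(subject_m)
    assert m1 == m2
    heavier = xf.SubjectProfile("M02", "male", 27.0, 2 * 74.0, 1.78, "right", 1.0)
    assert xf.scale_model(heavier).tau0_pos == pytest.approx(2 * m1.tau0_pos)


def test_scale_model_female_smaller_and_weaker(subject_f, subject_m):
    f, m = xf.scale_model(subject_f), xf.scale_model(subject_m)
    assert f.arm_length < m.arm_length
    assert f.tau0_pos < m.tau0_pos


def test_scale_model_rejects_nonpositive_anthropometry():
    with pytest.raises(ValueError):
        xf.SubjectProfile("X", "male", 30.0, -1.0, 1.8, "right", 1.0)


# ------------------------------------------------ gravitational torque


def test_gravitational_torque_hand_value():
    # m_arm*l_com = 1.0 kg*m, 2.268 kg load on a 0.6 m lever at 90 deg.
    model = _bare_model(arm_mass=2.5, com_length=0.4, arm_length=0.6)
    tau = xf.gravitational_torque(model, np.pi / 2, 2.268)
    assert tau == pytest.approx((1.0 + 2.268 * 0.6) * GRAVITY, abs=1e-9)
    assert xf.gravitational_torque(model, 0.0, 2.268) == 0.0


@given(theta=st.floats(0.0, np.pi))
def test_gravitational_torque_sine_symmetry(theta):
    model = _bare_model()
    assert xf.gravitational_torque(model, theta, 2.0) == pytest.approx(
        xf.gravitational_torque(model, np.pi - theta, 2.0), abs=1e-9
    )


# ------------------------------------------------------ inverse dynamics


def test_inverse_dynamics_static_limit():
    model = _bare_model()
    state = _static_state(60.0)
    tau = xf.inverse_dynamics(model, state, None, 2.268)
    expected = xf.gravitational_torque(model, np.deg2rad(60.0), 2.268)
    assert np.allclose(tau, expected, atol=1e-9)
    # perfect assistance cancels the demand entirely
    assist = np.full(state.time.size, expected)
    assert np.allclose(xf.inverse_dynamics(model, state, assist, 2.268), 0.0, atol=1e-9)


def test_inverse_dynamics_static_random_postures_and_loads():
    rng = np.random.default_rng(11)
    model = _bare_model()
    for _ in range(100):
        theta = rng.uniform(0.05, 3.0)
        load = rng.uniform(0.0, 5.0)
        state = _static_state(np.rad2deg(theta), n=5)
        tau = xf.inverse_dynamics(model, state, None, load)
        assert np.all(
            np.abs(tau - xf.gravitational_torque(model, theta, load)) <= 1e-9
        )


def test_inverse_dynamics_pendulum_matches_analytic_torque():
    # theta(t) = A sin(w t): tau = -I_eff A w^2 sin(w t) + lever g sin(theta).
    model = _bare_model()
    load = 2.268
    A, w = np.deg2rad(40.0), 2.0 * np.pi * 0.5
    t = np.linspace(0.0, 4.0, 4001)
    theta = A * np.sin(w * t) + np.deg2rad(50.0)
    omega = A * w * np.cos(w * t)
    alpha = -A * w**2 * np.sin(w * t)
    state = JointState(t, np.rad2deg(theta), np.rad2deg(omega), np.rad2deg(alpha))
    tau = xf.inverse_dynamics(model, state, None, load)
    lever = model.arm_mass * model.com_length + load * model.arm_length
    oracle = model.effective_inertia(load) * alpha + lever * GRAVITY * np.sin(theta)
    assert np.max(np.abs(tau - oracle)) <= 1e-6 * np.max(np.abs(oracle))


def test_inverse_dynamics_rejects_misaligned_assistance():
    model = _bare_model()
    state = _static_state(45.0)
    with pytest.raises(ValueError):
        xf.inverse_dynamics(model, state, np.zeros(state.time.size - 1), 1.0)


# ----------------------------------------------------- MTG activation


def test_mtg_activation_passive_only_torque_gives_zero():
    model = _bare_model()
    state = _static_state(35.0)
    tau_p = model.tau_passive(state.theta, state.omega)
    a, sat = xf.mtg_activation(model, tau_p, state)
    assert np.allclose(a, 0.0, atol=1e-12) and sat == 0.0


def test_mtg_activation_definitional_inversion_at_peak_posture():
    # At the torque-angle peak, isometric: tau_net - tau_p = 0.5 tau0 -> a = 0.5.
    model = _bare_model()
    theta_peak_deg = np.rad2deg(model.scaling.theta_peak)
    state = _static_state(theta_peak_deg)
    tau_net = model.tau_passive(state.theta, state.omega) + 0.5 * model.tau0_pos
    a, sat = xf.mtg_activation(model, tau_net, state)
    assert np.allclose(a, 0.5, atol=1e-12)


def test_mtg_activation_saturation_reported():
    model = _bare_model()
    state = _static_state(np.rad2deg(model.scaling.theta_peak))
    a, sat = xf.mtg_activation(model, np.full(state.time.size, 2.5 * model.tau0_pos), state)
    assert np.allclose(a, 1.0) and sat == 1.0


@given(
    a_true=st.floats(-0.95, 0.95),
    theta=st.floats(0.3, 1.7),
    omega=st.floats(-2.0, 2.0),
)
def test_mtg_forward_inverse_round_trip(a_true, theta, omega):
    model = _bare_model()
    t = np.array([0.0, 1.0])
    state = JointState(
        t,
        np.full(2, np.rad2deg(theta)),
        np.full(2, np.rad2deg(omega)),
        np.zeros(2),
    )
    tau = xf.mtg_torque(model, np.full(2, a_true), state)
    a, _ = xf.mtg_activation(model, tau, state)
    assert np.allclose(a, a_true, atol=1e-6)


def test_mtg_scaling_function_invariants():
    model = _bare_model()
    omegas = np.linspace(-6, 10, 200)
    tw = model.tau_omega(omegas)
    assert np.all((tw >= 0) & (tw <= 1))
    assert model.tau_omega(0.0) == pytest.approx(1.0)
    assert model.tau_passive(model.scaling.theta_neutral, 0.0) == pytest.approx(0.0)
    assert model.tau_theta(model.scaling.theta_peak) == pytest.approx(1.0)


# -------------------------------------------------------- assistance


def test_assist_modes():
    theta = np.linspace(0.0, np.pi, 50)
    intent = np.full_like(theta, 20.0)
    ie = xf.assist_torque(xf.AssistanceModel.for_mode("IE"), theta, intent)
    assert np.all(ie == 0.0)
    fp = xf.assist_torque(xf.AssistanceModel.for_mode("FP"), theta, None)
    fa = xf.assist_torque(xf.AssistanceModel.for_mode("FA"), theta, intent)
    ap = xf.assist_torque(xf.AssistanceModel.for_mode("AP"), theta, intent)
    assert np.allclose(ap, fp + fa, atol=1e-12)
    # 0.40 gain * 20 N*m intent = 8 N*m; a 50 N*m intent saturates at 9 N*m
    assert np.allclose(fa, 8.0)
    fa_sat = xf.assist_torque(
        xf.AssistanceModel.for_mode("FA"), theta, np.full_like(theta, 50.0)
    )
    assert np.allclose(fa_sat, 9.0)


def test_assist_requires_intent_for_active_modes():
    with pytest.raises(ValueError):
        xf.assist_torque(xf.AssistanceModel.for_mode("FA"), np.array([1.0]), None)


def test_assist_spring_support_levels_scale():
    theta = np.array([np.pi / 2])
    lo = xf.assist_torque(xf.AssistanceModel.for_mode("FP", support_level=1), theta)
    hi = xf.assist_torque(xf.AssistanceModel.for_mode("FP", support_level=3), theta)
    assert hi[0] > lo[0] > 0


# ------------------------------------------------------------- MMEE


def test_mmee_zero_torque_zero_energy():
    t = np.linspace(0.0, 5.0, 100)
    assert xf.mmee(np.zeros_like(t), np.ones_like(t), t) == 0.0


def test_mmee_isometric_closed_form():
    # omega = 0, omega_max from a motion phase: E = h_m * omega_max * c * T.
    t = np.linspace(0.0, 5.0, 501)
    params = xf.MmeeParams(omega_max=2.0)
    E = xf.mmee(np.full_like(t, 10.0), np.zeros_like(t), t, params)
    assert E == pytest.approx(0.054 * 2.0 * 10.0 * 5.0, rel=1e-9)


def test_mmee_constant_positive_power_closed_form():
    # tau = 10, omega = 0.3 (power 3 W) for 4 s, omega_max = 0.3:
    # E = (h_m*0.3*10 + (h_sl_pos + 1)*3) * 4
    t = np.linspace(0.0, 4.0, 401)
    E = xf.mmee(np.full_like(t, 10.0), np.full_like(t, 0.3), t)
    expected = (0.054 * 0.3 * 10.0 + 1.283 * 3.0) * 4.0
    assert E == pytest.approx(expected, rel=1e-9)


def test_mmee_lengthening_heat_exceeds_shortening():
    t = np.linspace(0.0, 4.0, 401)
    pos = xf.mmee(np.full_like(t, 10.0), np.full_like(t, 0.3), t)
    neg = xf.mmee(np.full_like(t, 10.0), np.full_like(t, -0.3), t)
    # negative power: no mechanical-work term but a larger heat coefficient
    assert neg == pytest.approx((0.054 * 0.3 * 10.0 + 1.423 * 3.0) * 4.0, rel=1e-9)
    assert pos > neg - 3.0 * 4.0  # consistency of the decomposition


@given(seed=st.integers(0, 1000))
def test_mmee_at_least_mechanical_work(seed):
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 3.0, 120)
    tau = rng.normal(0, 10, t.size)
    omega = rng.normal(0, 1, t.size)
    work = np.trapezoid(np.clip(tau * omega, 0.0, None), t)
    assert xf.mmee(tau, omega, t) >= work - 1e-9


def test_mmee_rejects_bad_params():
    with pytest.raises(ValueError):
        xf.MmeeParams(h_m=-0.1)
    with pytest.raises(ValueError):
        xf.MmeeParams(h_sl_pos=1.5, h_sl_neg=1.0)


# ------------------------------------------------- activation dynamics


def test_activation_dynamics_step_matches_closed_form():
    t = np.linspace(0.0, 2.0, 2001)
    u = np.ones_like(t)
    a = xf.activation_dynamics(u, t, tau_act=0.05, a0=0.0)
    assert np.max(np.abs(a[1:] - (1 - np.exp(-t[1:] / 0.05)))) < 1e-4


def test_activation_dynamics_fixed_point_and_zero():
    t = np.linspace(0.0, 1.0, 500)
    assert np.allclose(xf.activation_dynamics(np.zeros_like(t), t, 0.05), 0.0)
    a = xf.activation_dynamics(np.full_like(t, 0.7), t, 0.02)
    assert a[-1] == pytest.approx(0.7, abs=1e-6)


def test_activation_dynamics_rejects_bad_time_constant():
    t = np.linspace(0.0, 1.0, 10)
    with pytest.raises(ValueError):
        xf.activation_dynamics(np.zeros_like(t), t, 0.0)
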