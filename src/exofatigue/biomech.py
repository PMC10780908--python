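"""Reduced sagittal musculoskeletal model with muscle torque generators.

The lift-and-hold task is planar and dominated by shoulder elevation, so the
full-body coordinate set is reduced to a single sagittal shoulder-elevation
degree of freedom: the straight arm (plus hand-held load) is a rigid pendulum
actuated by a muscle torque generator (MTG).

The MTG expresses the net human joint torque as

    tau = a * tau_omega(omega) * tau_theta(theta) * tau0(+/-)  +  tau_p(theta, omega)

with a in [-1, 1] the signed activation, tau0 the peak isometric strength for
the agonist (+, elevation) or antagonist (-, lowering) direction, tau_theta a
raised-cosine torque-angle scaling (peak 1), tau_omega a Hill-type
torque-velocity scaling (1 at omega = 0), and tau_p a passive term combining
nonlinear stiffness about the neutral pose and viscous damping.

Metabolic cost follows a joint-space muscle metabolic energy expenditure
(MMEE) model: maintenance/activation heat proportional to |tau_a| times the
motion's peak angular velocity, sign-dependent shortening/lengthening heat
proportional to |tau_a * omega|, plus positive mechanical work.

Conventions: angles in radians internally (0 = arm hanging, pi/2 =
horizontal); degrees only at the I/O dataclass boundary; torques N*m,
g = 9.81 m/s^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import integrate

from .synth_types import SubjectProfile

log = logging.getLogger(__name__)

GRAVITY = 9.81  # m/s^2

MODES = ("IE", "FP", "FA", "AP")


@dataclass(frozen=True)
class ScalingConfig:
    """Anthropometric and strength scaling table.

    Segment fractions follow standard whole-arm anthropometry for an extended
    arm lifting a hand-held load: arm mass 5% of body mass, shoulder-to-grip
    lever 40% of stature, centre of mass at 45% of that lever, slender-rod
    inertia about the shoulder. Peak isometric shoulder-elevation strength
    scales linearly with body mass with a sex-specific coefficient
    (N*m per kg); the lowering (antagonist) direction is weaker.
    """

    arm_mass_frac: float = 0.050
    arm_length_frac: float = 0.40
    com_frac: float = 0.45
    strength_per_kg: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.85, "male": 1.10}
    )
    tau0_neg_frac: float = 0.70
    # torque-angle bell (radians)
    theta_peak: float = np.deg2rad(70.0)
    theta_width: float = np.deg2rad(100.0)
    # torque-velocity hyperbola
    omega_max: float = 8.0  # rad/s, concentric cutoff
    hill_k: float = 0.25
    # passive torque: k1*sinh(k2*(neutral - theta)) - damping*omega
    passive_k1: float = 0.20  # N*m
    passive_k2: float = 1.50  # 1/rad
    passive_damping: float = 0.15  # N*m*s/rad
    theta_neutral: float = 0.0


@dataclass(frozen=True)
class MtgModel:
    """Subject-scaled muscle torque generator + segment parameters."""

    subject_id: str
    sex: str
    tau0_pos: float
    tau0_neg: float
    arm_mass: float
    arm_length: float
    com_length: float
    inertia: float  # about the shoulder, arm only (kg m^2)
    scaling: ScalingConfig = ScalingConfig()

    def __post_init__(self) -> None:
        if self.tau0_pos <= 0 or self.tau0_neg <= 0:
            raise ValueError("peak isometric strengths must be positive")

    def tau_theta(self, theta: np.ndarray) -> np.ndarray:
        """Active torque-angle scaling: raised-cosine bell, peak 1."""
        s = self.scaling
        u = np.clip((np.asarray(theta, float) - s.theta_peak) / s.theta_width, -1, 1)
        return 0.5 * (1.0 + np.cos(np.pi * u))

    def tau_omega(self, omega: np.ndarray) -> np.ndarray:
        """Active torque-velocity scaling in [0, 1], = 1 at omega = 0.

        Concentric (shortening): Hill hyperbola falling to 0 at omega_max.
        Eccentric: capped at 1 (plateau).
        """
        s = self.scaling
        w = np.asarray(omega, dtype=float)
        conc = np.clip(
            (1.0 - w / s.omega_max) / (1.0 + w / (s.hill_k * s.omega_max)), 0.0, 1.0
        )
        return np.where(w > 0, conc, 1.0)

    def tau_passive(self, theta: np.ndarray, omega: np.ndarray) -> np.ndarray:
        """Passive torque: nonlinear stiffness toward neutral + viscous damping."""
        s = self.scaling
        th = np.asarray(theta, dtype=float)
        return s.passive_k1 * np.sinh(
            s.passive_k2 * (s.theta_neutral - th)
        ) - s.passive_damping * np.asarray(omega, dtype=float)

    def effective_inertia(self, load_mass: float) -> float:
        return self.inertia + load_mass * self.arm_length**2


@dataclass
class JointState:
    """Shoulder-elevation kinematics. Degrees at the interface; radian
    views are provided for the dynamics routines."""

    time: np.ndarray
    theta_deg: np.ndarray
    omega_deg_s: np.ndarray
    alpha_deg_s2: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.theta_deg = np.asarray(self.theta_deg, dtype=float).ravel()
        self.omega_deg_s = np.asarray(self.omega_deg_s, dtype=float).ravel()
        self.alpha_deg_s2 = np.asarray(self.alpha_deg_s2, dtype=float).ravel()
        n = self.time.size
        if not (self.theta_deg.size == self.omega_deg_s.size == self.alpha_deg_s2.size == n):
            raise ValueError("kinematic traces are misaligned")

    @property
    def theta(self) -> np.ndarray:
        return np.deg2rad(self.theta_deg)

    @property
    def omega(self) -> np.ndarray:
        return np.deg2rad(self.omega_deg_s)

    @property
    def alpha(self) -> np.ndarray:
        return np.deg2rad(self.alpha_deg_s2)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class MmeeParams:
    """Heat-rate coefficients of the joint-space metabolic energy model.

    h_m: dimensionless activation/maintenance heat rate (0.054);
    h_sl_pos / h_sl_neg: shortening (0.283) and lengthening (1.423) heat
    rates applied to |tau_a * omega| by the sign of the instantaneous power;
    omega_max: peak |angular velocity| over the whole motion (rad/s), taken
    from the trace when not supplied.
    """

    h_m: float = 0.054
    h_sl_pos: float = 0.283
    h_sl_neg: float = 1.423
    omega_max: float | None = None

    def __post_init__(self) -> None:
        if min(self.h_m, self.h_sl_pos, self.h_sl_neg) < 0:
            raise ValueError("MMEE heat rates must be non-negative")
        if self.h_sl_neg <= self.h_sl_pos:
            raise ValueError("lengthening heat rate must exceed shortening rate")


@dataclass(frozen=True)
class AssistanceModel:
    """Exoskeleton assistance torque for one of the four modes.

    IE: inactive, zero torque. FP: passive spring, piecewise-linear
    torque-angle profile peaking at 90 deg elevation, three discrete support
    levels. FA: motor torque = gain * estimated task-demand (intent) torque,
    saturated at the 9 N*m motor rating. AP: sum of FP and FA.
    """

    mode: str
    spring_peak: float = 7.5  # N*m at 90 deg, support level 2
    support_level: int = 2
    level_scales: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 1.0, 3: 1.3}
    )
    gain: float = 0.40
    saturation: float = 9.0  # N*m motor rating
    gear_ratio: float = 9.0  # metadata only

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown assistance mode {self.mode!r}")
        if self.support_level not in self.level_scales:
            raise ValueError(f"unknown support level {self.support_level}")

    @classmethod
    def for_mode(cls, mode: str, **kwargs) -> "AssistanceModel":
        return cls(mode=mode, **kwargs)

    def spring_torque(self, theta: np.ndarray) -> np.ndarray:
        th = np.asarray(theta, dtype=float)
        peak = self.spring_peak * self.level_scales[self.support_level]
        half = np.pi / 2.0
        profile = np.where(th <= half, th / half, 2.0 - th / half)
        return peak * np.clip(profile, 0.0, 1.0)

    def motor_torque(self, intent: np.ndarray) -> np.ndarray:
        return np.clip(
            self.gain * np.asarray(intent, dtype=float),
            -self.saturation,
            self.saturation,
        )


def assist_torque(
    assist: AssistanceModel,
    theta: np.ndarray,
    intent_torque_estimate: np.ndarray | None = None,
) -> np.ndarray:
    """Assistance torque trace (N*m) for the given mode at angle theta (rad).

    FA and AP require an intent (task-demand) torque estimate; the active
    contribution saturates at the motor's 9 N*m rating.
    """
    th = np.asarray(theta, dtype=float)
    if assist.mode == "IE":
        return np.zeros_like(th)
    if assist.mode == "FP":
        return assist.spring_torque(th)
    if intent_torque_estimate is None:
        raise ValueError(f"mode {assist.mode} requires an intent torque estimate")
    active = assist.motor_torque(intent_torque_estimate)
    if assist.mode == "FA":
        return active * np.ones_like(th)
    return assist.spring_torque(th) + active  # AP


# ---------------------------------------------------------------------------


def scale_model(
    beta: SubjectProfile, config: ScalingConfig = ScalingConfig()
) -> MtgModel:
    """Scale the MTG/segment model to a subject's anthropometry (beta).

    Deterministic: identical profiles yield identical models. Strength is
    proportional to body mass (sex-specific coefficient), segment mass to
    body mass, lever length to stature.
    """
    if beta.body_mass <= 0 or beta.height <= 0:
        raise ValueError("body mass and height must be positive")
    if beta.sex not in config.strength_per_kg:
        raise ValueError(f"no strength coefficient for sex {beta.sex!r}")
    arm_mass = config.arm_mass_frac * beta.body_mass
    arm_length = config.arm_length_frac * beta.height
    tau0 = config.strength_per_kg[beta.sex] * beta.body_mass
    return MtgModel(
        subject_id=beta.id,
        sex=beta.sex,
        tau0_pos=tau0,
        tau0_neg=config.tau0_neg_frac * tau0,
        arm_mass=arm_mass,
        arm_length=arm_length,
        com_length=config.com_frac * arm_length,
        inertia=arm_mass * arm_length**2 / 3.0,
        scaling=config,
    )


def gravitational_torque(
    model: MtgModel, theta: np.ndarray, load_mass: float
) -> np.ndarray:
    """Gravity demand (m_arm*l_com + m_load*l_arm) * g * sin(theta), N*m.

    theta in radians from the arm-down pose, so demand peaks at 90 deg.
    """
    lever = model.arm_mass * model.com_length + load_mass * model.arm_length
    return lever * GRAVITY * np.sin(np.asarray(theta, dtype=float))


def inverse_dynamics(
    model: MtgModel,
    state: JointState,
    external: np.ndarray | None = None,
    load_mass: float = 0.0,
) -> np.ndarray:
    """Net human joint torque tau_ht = I_eff*alpha + tau_g(theta) - tau_exo.

    ``external`` is the exoskeleton assistance torque on the same time base
    (None = unassisted). In the static limit (omega = alpha = 0) this reduces
    to gravitational demand minus assistance.
    """
    tau = model.effective_inertia(load_mass) * state.alpha + gravitational_torque(
        model, state.theta, load_mass
    )
    if external is not None:
        external = np.asarray(external, dtype=float).ravel()
        if external.size != state.time.size:
            raise ValueError("assistance trace misaligned with kinematics")
        tau = tau - external
    return tau


def mtg_activation(
    model: MtgModel,
    tau_net: np.ndarray,
    state: JointState,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Invert the MTG torque law for the signed activation trace.

    a = (tau_net - tau_p(theta, omega)) / (tau_omega * tau_theta * tau0_branch)
    with the +/- strength branch chosen by the sign of the numerator, clipped
    to [-1, 1]. Returns (activation, saturated-sample fraction); samples where
    the scaling functions vanish (unreachable posture/velocity) are NaN.
    """
    tau_net = np.asarray(tau_net, dtype=float).ravel()
    if tau_net.size != state.time.size:
        raise ValueError("torque trace misaligned with kinematics")
    num = tau_net - model.tau_passive(state.theta, state.omega)
    scale = model.tau_omega(state.omega) * model.tau_theta(state.theta)
    tau0 = np.where(num >= 0, model.tau0_pos, model.tau0_neg)
    denom = scale * tau0
    bad = denom < tol * np.maximum(model.tau0_pos, model.tau0_neg)
    if np.any(bad):
        log.warning(
            "mtg_activation: %d sample(s) outside the force-generating range",
            int(bad.sum()),
        )
    raw = np.where(bad, np.nan, num / np.where(bad, np.nan, denom))
    a = np.clip(raw, -1.0, 1.0)
    finite = np.isfinite(raw)
    saturation = float(np.mean(np.abs(raw[finite]) > 1.0)) if finite.any() else 0.0
    return a, saturation


def mtg_torque(model: MtgModel, a: np.ndarray, state: JointState) -> np.ndarray:
    """Forward MTG torque law (inverse of :func:`mtg_activation`)."""
    a = np.asarray(a, dtype=float)
    tau0 = np.where(a >= 0, model.tau0_pos, model.tau0_neg)
    return a * model.tau_omega(state.omega) * model.tau_theta(
        state.theta
    ) * tau0 + model.tau_passive(state.theta, state.omega)


def activation_dynamics(
    u: np.ndarray, time: np.ndarray, tau_act: float, a0: float = 0.0
) -> np.ndarray:
    """First-order excitation-to-activation ODE a' = (u - a)/tau_act.

    Integrated exactly per step (exponential integrator with zero-order hold
    on u), so a step input follows 1 - exp(-t/tau_act) to machine precision
    on the grid and a -> u at steady state.
    """
    if tau_act <= 0:
        raise ValueError("activation time constant must be positive")
    u = np.asarray(u, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    if u.size != time.size:
        raise ValueError("excitation and time traces are misaligned")
    a = np.empty_like(u)
    a[0] = a0
    decay = np.exp(-np.diff(time) / tau_act)
    for i in range(1, u.size):
        a[i] = u[i] + (a[i - 1] - u[i]) * decay[i - 1]
    return a


def mmee(
    tau_a: np.ndarray,
    omega: np.ndarray,
    time: np.ndarray,
    params: MmeeParams = MmeeParams(),
) -> float:
    """Muscle metabolic energy expenditure (J) over the motion.

    E = integral of [ h_m * omega_max * |tau_a|
                      + h_sl(sign(tau_a*omega)) * |tau_a*omega|
                      + max(tau_a*omega, 0) ] dt

    i.e. maintenance/activation heat, sign-dependent shortening/lengthening
    heat, and positive (concentric) mechanical work; trapezoidal integration.
    Non-negative, and zero iff tau_a is identically zero.
    """
    tau_a = np.asarray(tau_a, dtype=float).ravel()
    omega = np.asarray(omega, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    if not (tau_a.size == omega.size == time.size):
        raise ValueError("traces are misaligned")
    w_max = params.omega_max
    if w_max is None:
        w_max = float(np.max(np.abs(omega))) if omega.size else 0.0
    power = tau_a * omega
    h_sl = np.where(power >= 0, params.h_sl_pos, params.h_sl_neg)
    rate = (
        params.h_m * w_max * np.abs(tau_a)
        + h_sl * np.abs(power)
        + np.clip(power, 0.0, None)
    )
    if time.size < 2:
        return 0.0
    return float(integrate.trapezoid(rate, time))
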