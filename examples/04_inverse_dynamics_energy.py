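"""Inverse dynamics, MTG activation and metabolic cost across modes.

The reduced sagittal model treats the extended arm + kettlebell as a rigid
pendulum: net human torque = inertia * alpha + gravity demand - exoskeleton
assistance. Inverting the muscle-torque-generator law gives the activation
the muscles must produce; the metabolic model converts active torque and
motion into energy expenditure. More assistance -> lower activation and a
lower metabolic rate.
"""

from dataclasses import replace

import numpy as np

import exofatigue as xf

subject = xf.SubjectProfile("F02", "female", 24.0, 59.0, 1.65, "right", 3.0)
mtg = xf.scale_model(subject)
load = 2.268  # kg

theta90 = np.pi / 2
print(
    f"gravity demand at 90 deg: "
    f"{xf.gravitational_torque(mtg, theta90, load):.1f} N*m "
    f"(peak strength {mtg.tau0_pos:.1f} N*m)"
)

cfg = xf.TrialConfig()
print("\nmode  mean net torque  mean |a|  MMEE rate")
for mode in xf.MODES:
    assist_model = xf.AssistanceModel.for_mode(mode)
    trial = xf.simulate_trial(subject, replace(cfg, mode=mode), mtg, assist_model, seed=5)
    kin = trial.kin
    task = xf.gravitational_torque(mtg, kin.theta, load)
    exo = xf.assist_torque(assist_model, kin.theta, task)
    tau_ht = xf.inverse_dynamics(mtg, kin, exo, load)
    a, saturated = xf.mtg_activation(mtg, tau_ht, kin)
    tau_active = tau_ht - mtg.tau_passive(kin.theta, kin.omega)
    rate = xf.mmee(tau_active, kin.omega, kin.time) / kin.duration
    print(
        f"{mode:4s}  {np.mean(tau_ht):12.1f} N*m"
        f"  {np.nanmean(np.abs(a)):8.3f}  {rate:6.2f} W"
    )

# excitation-to-activation dynamics: a first-order lag toward the excitation
t = np.linspace(0.0, 0.5, 500)
a = xf.activation_dynamics(np.ones_like(t), t, tau_act=0.05)
print(f"\nactivation reaches {100 * a[-1]:.1f}% of a step excitation in 0.5 s")
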