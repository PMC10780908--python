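"""Decode shoulder torque from EMG: the MuscleNET-style intent estimator.

A subject-specific ridge decoder maps activation envelopes + angular
velocity to net shoulder-elevation torque. It is trained on the protocol's
data-gathering trials (free motion, an unassisted hold and a passive-spring
hold) and then estimates torque and joint power on unseen assisted trials.
"""

from dataclasses import replace

import numpy as np

import exofatigue as xf

subject = xf.SubjectProfile("M03", "male", 29.0, 78.0, 1.80, "right", 2.0)
mtg = xf.scale_model(subject)
cfg = xf.TrialConfig()

training = [
    xf.simulate_trial(subject, replace(cfg, protocol="free"), mtg, seed=1),
    xf.simulate_trial(subject, replace(cfg, mode="IE"), mtg, seed=2),
    xf.simulate_trial(
        subject, replace(cfg, mode="FP"), mtg, xf.AssistanceModel.for_mode("FP"), seed=3
    ),
]
model = xf.fit_intent_model(training, seed=0)
print(f"decoder held-out R^2 = {model.r2_holdout:.3f}")
print(f"features: {model.feature_names}")

trial = xf.simulate_trial(
    subject, replace(cfg, mode="FA"), mtg, xf.AssistanceModel.for_mode("FA"), seed=4
)
tau_hat = xf.estimate_torque(model, trial)
tau_true = trial.truth.net_torque
rmse = np.sqrt(np.mean((tau_hat - tau_true) ** 2))
print(
    f"\nunseen FA trial: torque RMSE {rmse:.2f} N*m "
    f"({100 * rmse / np.mean(np.abs(tau_true)):.1f}% of the mean demand)"
)

p_intent = xf.joint_power(tau_hat, trial.kin.omega)
p_inverse = xf.joint_power(tau_true, trial.kin.omega)
agree = np.sqrt(np.mean((p_intent - p_inverse) ** 2)) / np.sqrt(np.mean(p_inverse**2))
print(
    f"joint power: peak {np.max(np.abs(p_intent)):.1f} W, "
    f"EMG-decoded vs inverse-dynamics power RMSE {100 * agree:.1f}%"
)
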