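"""EMG-driven shoulder torque estimation (intent decoding).

A subject-specific machine-learning mapping from sEMG + kinematics to
shoulder-elevation torque provides two efficiency measures: the estimated
joint torque itself and the joint power (torque times measured angular
velocity). The published network behind the original study is not
reproducible, so this module ships a documented ridge-regression stand-in
with the same I/O contract: features are the per-channel activation
envelopes resampled to the kinematic time base plus angular velocity (an
optional sin(angle) column is off by default — trained on unassisted data
it simply memorizes the gravity demand and fails to transfer to assisted
modes); the target is the net human joint torque (generator truth on
synthetic data, inverse-dynamics torque otherwise). The estimator is
deliberately pluggable — anything honouring :class:`IntentModel`'s
``predict`` contract can be substituted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .emg_metrics import FilterConfig, preprocess_emg
from .synthgen import TrialRecord


@dataclass(frozen=True)
class IntentConfig:
    """Ridge stand-in settings: regularization strength (applied to
    standardized features), held-out sample fraction for goodness-of-fit,
    and the EMG preprocessing chain used to build envelope features."""

    alpha: float = 1e-2
    holdout_frac: float = 0.25
    filter_config: FilterConfig = FilterConfig()
    #: sin(theta) encodes the *unassisted* gravity demand when training on
    #: unassisted trials only, so it does not transfer across assistance
    #: modes; off by default, available for experiments.
    include_angle: bool = False
    include_velocity: bool = True


@dataclass
class IntentModel:
    """Fitted linear intent decoder.

    ``coef``/``intercept`` act on standardized features (stored mean/scale);
    ``r2_holdout`` is the goodness-of-fit on the held-out sample split
    recorded at training time.
    """

    feature_names: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    r2_holdout: float
    subject_id: str | None = None
    config: IntentConfig = field(default_factory=IntentConfig)

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        Z = (X - self.feature_mean) / self.feature_scale
        return Z @ self.coef + self.intercept

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "feature_names": list(self.feature_names),
                    "coef": self.coef.tolist(),
                    "intercept": self.intercept,
                    "feature_mean": self.feature_mean.tolist(),
                    "feature_scale": self.feature_scale.tolist(),
                    "r2_holdout": self.r2_holdout,
                    "subject_id": self.subject_id,
                    "alpha": self.config.alpha,
                }
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "IntentModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(d["feature_names"]),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            feature_mean=np.asarray(d["feature_mean"], dtype=float),
            feature_scale=np.asarray(d["feature_scale"], dtype=float),
            r2_holdout=float(d["r2_holdout"]),
            subject_id=d.get("subject_id"),
            config=IntentConfig(alpha=float(d.get("alpha", 1e-2))),
        )


def trial_features(
    trial: TrialRecord, config: IntentConfig = IntentConfig()
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Feature matrix on the kinematic time base.

    Columns: one activation envelope per EMG channel (band-pass, rectify,
    low-pass, MVIC-normalize, then linear resampling from the EMG grid to
    the kinematic grid), then angular velocity (rad/s) and, when enabled,
    sin(theta).
    """
    if trial.emg is None:
        raise ValueError(f"trial {trial.trial_id} carries no EMG recording")
    acts = preprocess_emg(trial.emg, trial.mvic_envelopes, config.filter_config)
    t_kin = trial.kin.time
    cols = [
        np.interp(t_kin, acts.times, acts.data[i])
        for i in range(len(acts.channels))
    ]
    names = list(acts.channels)
    if config.include_velocity:
        cols.append(trial.kin.omega)
        names.append("omega")
    if config.include_angle:
        cols.append(np.sin(trial.kin.theta))
        names.append("sin_theta")
    return np.column_stack(cols), tuple(names)


def fit_ridge(
    X: np.ndarray, y: np.ndarray, alpha: float
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Closed-form ridge on standardized features with unpenalized intercept.

    Returns (coef, intercept, feature mean, feature scale). Near-constant
    features get unit scale so they simply drop out of the fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    Z = (X - mean) / scale
    y_mean = y.mean()
    A = Z.T @ Z + alpha * np.eye(Z.shape[1])
    coef = np.linalg.solve(A, Z.T @ (y - y_mean))
    return coef, float(y_mean), mean, scale


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if np.allclose(y, yhat) else -np.inf
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def fit_intent_model(
    training_trials: list[TrialRecord],
    config: IntentConfig = IntentConfig(),
    seed: int = 0,
) -> IntentModel:
    """Fit the subject-specific intent decoder on training trials.

    Labels are the generator-truth net torque traces (synthetic trials) —
    on real data the inverse-dynamics torque plays that role. A random
    ``holdout_frac`` of samples is withheld to record held-out R^2.
    """
    if len(training_trials) < 2:
        raise ValueError("need at least 2 training trials")
    Xs, ys = [], []
    names: tuple[str, ...] | None = None
    for trial in training_trials:
        if trial.truth is None:
            raise ValueError(
                f"trial {trial.trial_id} has no torque labels (truth missing)"
            )
        X, nm = trial_features(trial, config)
        names = nm if names is None else names
        if nm != names:
            raise ValueError("inconsistent feature sets across training trials")
        Xs.append(X)
        ys.append(np.asarray(trial.truth.net_torque, dtype=float))
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    if X.shape[0] != y.size:
        raise ValueError("feature/label misalignment across training trials")
    informative = X.std(axis=0) > 1e-12
    if informative.sum() < 2:
        raise ValueError("degenerate features: fewer than 2 informative columns")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    n_hold = int(round(config.holdout_frac * n))
    perm = rng.permutation(n)
    hold, train = perm[:n_hold], perm[n_hold:]
    if train.size < X.shape[1] + 1:
        raise ValueError("too few samples to fit the decoder")
    coef, intercept, mean, scale = fit_ridge(X[train], y[train], config.alpha)
    model = IntentModel(
        feature_names=names,
        coef=coef,
        intercept=intercept,
        feature_mean=mean,
        feature_scale=scale,
        r2_holdout=np.nan,
        subject_id=training_trials[0].subject.id,
        config=config,
    )
    r2 = _r2(y[hold], model.predict(X[hold])) if n_hold else np.nan
    model.r2_holdout = float(r2)
    return model


def estimate_torque(model: IntentModel, trial: TrialRecord) -> np.ndarray:
    """Estimated shoulder-elevation torque trace (N*m) on the kinematic
    time base of ``trial``."""
    X, names = trial_features(trial, model.config)
    if names != model.feature_names:
        raise ValueError("trial features do not match the fitted model")
    return model.predict(X)


def joint_power(torque: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Instantaneous joint power (W): torque (N*m) times angular velocity
    (rad/s), pointwise; negative values mark eccentric (absorbing) phases."""
    torque = np.asarray(torque, dtype=float).ravel()
    omega = np.asarray(omega, dtype=float).ravel()
    if torque.size != omega.size:
        raise ValueError("torque and angular-velocity traces are misaligned")
    return torque * omega
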