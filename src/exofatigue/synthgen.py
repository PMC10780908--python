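"""Synthetic cohorts and fatiguing weight-lifting trials.

The generator emulates the statistical structure the downstream analysis
assumes, so the full 12-measure pipeline can be exercised end-to-end without
the (unavailable) laboratory recordings:

* a crossed cohort design — ``n_per_sex`` females and males with
  sex-specific anthropometry drawn from truncated normals matching the
  study population moments;
* a lift-and-hold task per assistance mode (IE, FP, FA, AP): the arm ramps
  from rest to a 90 deg elevation target, holds with small postural jitter
  until an endurance time implied by the subject's net torque demand, then
  drops;
* a Rohmert-type endurance law T = a * max(d - floor, eps)^(-b) on the net
  relative demand d = (gravity demand - assistance) / peak strength, so
  mode-dependent hold times (AP about twice FP) *emerge* from the assistance
  calibration rather than being injected;
* surface EMG per channel: band-pass-filtered Gaussian noise whose
  instantaneous amplitude tracks net muscle demand and grows with
  accumulated fatigue, and whose spectrum compresses toward low frequencies
  as fatigue accumulates (time-warped carrier). The brachioradialis (BRD)
  channel drives elbow flexion, is untouched by a shoulder exoskeleton, and
  is therefore synthesized fatigue-free;
* a post-trial survey whose comfort score decreases with accumulated
  fatigue and is highest for the AP mode.

Every trial carries a ``truth`` block (exact endurance time, net torque
trace) for recovery tests. Fixed seeds give bit-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from . import biomech
from .biomech import AssistanceModel, JointState, MtgModel, assist_torque, scale_model
from .emg_metrics import CHANNELS, EmgRecording
from .synth_types import (
    SEXES,
    AttributeDist,
    CohortConfig,
    SubjectProfile,
    SurveyResponse,
)

log = logging.getLogger(__name__)

#: Per-channel synthesis parameters: demand weight (fraction of net demand
#: expressed at that site), fatigue amplitude-growth multiplier (relative to
#: ``TrialConfig.amp_growth``; distinct across sites so a linear decoder can
#: separate demand from fatigue drift), and MVIC-level RMS amplitude in mV.
CHANNEL_PARAMS: Mapping[str, tuple[float, float, float]] = {
    "UTRA": (0.55, 1.30, 0.35),
    "MTRA": (0.45, 1.15, 0.30),
    "MDEL": (1.00, 1.00, 0.55),
    "PDEL": (0.65, 0.85, 0.40),
    "ADEL": (0.85, 0.70, 0.50),
    "BRD": (0.15, 0.00, 0.45),  # weight here is a constant baseline level
}

#: mean |x| / rms for a Gaussian carrier; converts MVIC RMS to envelope level
_GAUSS_RECT_MEAN = float(np.sqrt(2.0 / np.pi))


@dataclass(frozen=True)
class EnduranceLaw:
    """Rohmert-type endurance law T = scale * max(d - floor, eps)^(-exponent).

    ``exponent`` and the assistance sizing are jointly calibrated once so the
    cohort-mean AP/FP hold-time ratio is about 2; ``scale`` sets absolute
    hold times (unassisted holds ~25-35 s).
    """

    scale_s: float = 12.0
    exponent: float = 0.97
    floor: float = 0.0
    eps: float = 1e-3
    t_max_s: float = 600.0


@dataclass(frozen=True)
class SurveyConfig:
    """Comfort-score generator: mode baseline minus a fatigue penalty plus
    Gaussian noise, rounded and clipped to the 1-10 scale."""

    baselines: Mapping[str, float] = field(
        default_factory=lambda: {"IE": 5.0, "FP": 6.0, "FA": 7.0, "AP": 8.0}
    )
    fatigue_penalty: float = 1.5
    sd: float = 1.0


@dataclass(frozen=True)
class TrialConfig:
    """Task, sampling, noise and endurance-law parameters for one trial."""

    mode: str = "IE"
    protocol: str = "hold"  # "hold" (to exhaustion) or "free" (training motion)
    load_mass: float = 2.268  # kg (5 lb at 0.45359 kg/lb)
    target_angle_deg: float = 90.0
    hold_threshold_frac: float = 0.8
    sample_rate_emg: float = 2000.0
    sample_rate_kin: float = 100.0
    rise_time_s: float | None = None  # None -> sex default (females faster)
    rise_time_by_sex: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.9, "male": 1.3}
    )
    angle_jitter_deg: float = 0.8
    emg_band_hz: tuple[float, float] = (20.0, 450.0)
    emg_noise_floor_mv: float = 0.01
    amp_growth: float = 0.35  # fractional amplitude rise at full fatigue
    mf_compression: float = 0.30  # fractional median-frequency drop
    endurance: EnduranceLaw = EnduranceLaw()
    demand_floor: float = 0.02  # net-demand clamp (never negative)
    endurance_jitter_sd: float = 0.05  # lognormal within-subject variability
    pre_s: float = 0.5
    drop_s: float = 1.0
    tail_s: float = 1.5
    rest_angle_deg: float = 12.0
    free_duration_s: float = 30.0
    survey: SurveyConfig = SurveyConfig()

    def __post_init__(self) -> None:
        if self.mode not in biomech.MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.protocol not in ("hold", "free"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if not 0 < self.hold_threshold_frac < 1:
            raise ValueError("hold_threshold_frac must lie in (0, 1)")
        if self.sample_rate_emg <= 0 or self.sample_rate_kin <= 0:
            raise ValueError("sample rates must be positive")
        if self.load_mass <= 0:
            raise ValueError("load mass must be positive")


@dataclass
class TrialTruth:
    """Hidden generator state for recovery tests (synthetic trials only)."""

    endurance_s: float | None
    hold_start_s: float | None
    relative_demand: float | None
    net_torque: np.ndarray  # N*m on the kinematic time base
    assist_torque: np.ndarray


@dataclass
class TrialRecord:
    """One subject x mode trial: sEMG, kinematics, survey and metadata."""

    trial_id: str
    subject: SubjectProfile
    mode: str
    emg: EmgRecording | None
    kin: JointState
    load_mass: float
    mvic_envelopes: dict[str, float]
    survey: SurveyResponse | None = None
    truth: TrialTruth | None = None

    def __post_init__(self) -> None:
        if self.emg is not None:
            span_e = self.emg.duration
            span_k = self.kin.duration
            if abs(span_e - span_k) > 0.1:
                raise ValueError("EMG and kinematics must cover the same span")


# ---------------------------------------------------------------------------
# Cohort generation


def _draw(rng: np.random.Generator, dist: AttributeDist, n: int) -> np.ndarray:
    if dist.sd == 0:
        return np.full(n, dist.mean)
    a = (dist.lo - dist.mean) / dist.sd
    b = (dist.hi - dist.mean) / dist.sd
    return stats.truncnorm.rvs(
        a, b, loc=dist.mean, scale=dist.sd, size=n, random_state=rng
    )


def generate_cohort(config: CohortConfig = CohortConfig()) -> list[SubjectProfile]:
    """Draw ``n_per_sex`` subjects per sex from the configured truncated
    normals. Reproducible under a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    cohort: list[SubjectProfile] = []
    for sex in SEXES:
        dists = config.distributions[sex]
        n = config.n_per_sex
        age = _draw(rng, dists["age"], n)
        mass = _draw(rng, dists["body_mass"], n)
        height = _draw(rng, dists["height"], n)
        activity = _draw(rng, dists["activity"], n)
        right = rng.random(n) < config.right_handed_frac
        prefix = sex[0].upper()
        for i in range(n):
            cohort.append(
                SubjectProfile(
                    id=f"{prefix}{i + 1:02d}",
                    sex=sex,
                    age=float(age[i]),
                    body_mass=float(mass[i]),
                    height=float(height[i]),
                    dominant_side="right" if right[i] else "left",
                    activity=float(activity[i]),
                )
            )
    return cohort


# ---------------------------------------------------------------------------
# Endurance law


def endurance_time(
    relative_demand: float, law: EnduranceLaw = EnduranceLaw()
) -> float:
    """Endurance time (s) at a given fraction of torque capacity.

    Strictly decreasing in demand, finite and positive; capped at
    ``law.t_max_s`` for very low demands.
    """
    if relative_demand <= 0:
        raise ValueError("relative demand must be positive")
    base = max(relative_demand - law.floor, law.eps)
    return float(min(law.scale_s * base ** (-law.exponent), law.t_max_s))


# ---------------------------------------------------------------------------
# Trial synthesis


def _smoothstep(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    s = np.clip((t - t0) / max(width, 1e-9), 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _postural_jitter(
    rng: np.random.Generator, n: int, fs: float, rms_deg: float
) -> np.ndarray:
    """Slow postural sway: low-pass-filtered noise scaled to a target RMS."""
    if rms_deg <= 0 or n < 20:
        return np.zeros(n)
    sos = signal.butter(2, 0.8, btype="lowpass", fs=fs, output="sos")
    raw = signal.sosfiltfilt(sos, rng.standard_normal(n))
    r = float(np.sqrt(np.mean(raw**2)))
    return raw * (rms_deg / r) if r > 0 else np.zeros(n)


def _hold_kinematics(
    rng: np.random.Generator,
    cfg: TrialConfig,
    sex: str,
    t_end: float,
) -> tuple[JointState, float]:
    rise = cfg.rise_time_s
    if rise is None:
        rise = cfg.rise_time_by_sex[sex] * float(np.exp(rng.normal(0.0, 0.05)))
    dt = 1.0 / cfg.sample_rate_kin
    hold_start = cfg.pre_s + rise
    total = hold_start + t_end + cfg.drop_s + cfg.tail_s
    t = np.arange(0.0, total, dt)
    up = _smoothstep(t, cfg.pre_s, rise)
    down = _smoothstep(t, hold_start + t_end, cfg.drop_s)
    theta = cfg.target_angle_deg * up - (cfg.target_angle_deg - cfg.rest_angle_deg) * down
    theta = theta + _postural_jitter(rng, t.size, cfg.sample_rate_kin, cfg.angle_jitter_deg) * up * (1.0 - down)
    omega = np.gradient(theta, dt)
    alpha = np.gradient(omega, dt)
    return JointState(t, theta, omega, alpha), hold_start


def _free_kinematics(rng: np.random.Generator, cfg: TrialConfig) -> JointState:
    """Training motion: smooth multi-frequency reaching between ~5 and 95 deg."""
    dt = 1.0 / cfg.sample_rate_kin
    t = np.arange(0.0, cfg.free_duration_s, dt)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    env = _smoothstep(t, 0.0, 2.0) * (1.0 - _smoothstep(t, t[-1] - 2.0, 2.0))
    theta = 50.0 + env * (
        35.0 * np.sin(2 * np.pi * 0.20 * t + phase[0])
        + 10.0 * np.sin(2 * np.pi * 0.07 * t + phase[1])
    )
    omega = np.gradient(theta, dt)
    alpha = np.gradient(omega, dt)
    return JointState(t, theta, omega, alpha)


def _synthesize_emg(
    rng: np.random.Generator,
    cfg: TrialConfig,
    kin: JointState,
    demand_kin: np.ndarray,
    fatigue_kin: np.ndarray,
) -> tuple[EmgRecording, dict[str, float]]:
    fs = cfg.sample_rate_emg
    n = int(round(kin.time[-1] * fs)) + 1
    t_emg = np.arange(n) / fs
    demand = np.interp(t_emg, kin.time, demand_kin)
    fatigue = np.interp(t_emg, kin.time, fatigue_kin)
    lo, hi = cfg.emg_band_hz
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    sample_idx = np.arange(n, dtype=float)
    data = np.empty((len(CHANNELS), n))
    envelopes: dict[str, float] = {}
    for row, ch in enumerate(CHANNELS):
        weight, growth_rel, mvic_mv = CHANNEL_PARAMS[ch]
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= float(np.sqrt(np.mean(carrier**2)))
        if ch == "BRD":
            sigma = np.full(n, weight)  # elbow muscle: demand-decoupled, no fatigue
            warped = carrier
        else:
            sigma = np.clip(
                weight * demand * (1.0 + cfg.amp_growth * growth_rel * fatigue),
                0.0,
                1.2,
            )
            rate = 1.0 - cfg.mf_compression * fatigue  # spectral warp factor
            phase = np.concatenate(([0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]))))
            warped = np.interp(phase, sample_idx, carrier)
        data[row] = mvic_mv * sigma * warped + cfg.emg_noise_floor_mv * rng.standard_normal(n)
        envelopes[ch] = mvic_mv * _GAUSS_RECT_MEAN
    return EmgRecording(CHANNELS, data, fs), envelopes


def simulate_survey(
    subject: SubjectProfile,
    mode: str,
    accumulated_fatigue: float,
    seed: int | np.random.Generator = 0,
    config: SurveyConfig = SurveyConfig(),
) -> SurveyResponse:
    """Draw a post-trial survey response.

    Comfort is the mode baseline (highest for AP) minus a penalty growing
    with accumulated fatigue, plus Gaussian noise, rounded and clipped to
    [1, 10]. With zero fatigue and zero noise it equals the baseline.
    """
    if accumulated_fatigue < 0:
        raise ValueError("accumulated fatigue must be non-negative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    f = min(float(accumulated_fatigue), 1.0)
    raw = config.baselines[mode] - config.fatigue_penalty * f + rng.normal(0.0, config.sd)
    comfort = int(np.clip(round(raw), 1, 10))
    levels = tuple(int(np.clip(round(1 + 4 * f * frac), 1, 5)) for frac in (0.25, 0.5, 0.75, 1.0))
    sites = []
    for site, p in (("deltoid", 0.8 * f), ("upper trapezius", 0.6 * f), ("forearm", 0.2)):
        if rng.random() < p:
            sites.append(site)
    return SurveyResponse(comfort=comfort, fatigue_level=levels, fatigue_sites=tuple(sites))


def simulate_trial(
    subject: SubjectProfile,
    trial_config: TrialConfig = TrialConfig(),
    mtg: MtgModel | None = None,
    assist: AssistanceModel | None = None,
    seed: int = 0,
    trial_id: str | None = None,
) -> TrialRecord:
    """Simulate one lift-and-hold (or free-motion training) trial.

    The hold duration follows the endurance law applied to the net relative
    demand at the hold posture: gravitational demand minus assistance torque,
    normalized by the subject's peak isometric strength. Assistance exceeding
    gravity clamps the demand at the configured floor with a logged warning.
    """
    cfg = trial_config
    if mtg is None:
        mtg = scale_model(subject)
    if assist is None:
        assist = AssistanceModel.for_mode(cfg.mode)
    if assist.mode != cfg.mode:
        raise ValueError(
            f"assistance model mode {assist.mode!r} does not match trial mode {cfg.mode!r}"
        )
    rng = np.random.default_rng(seed)
    theta_hold = np.deg2rad(cfg.target_angle_deg)
    tau_g_hold = float(biomech.gravitational_torque(mtg, theta_hold, cfg.load_mass))
    assist_hold = float(
        np.asarray(assist_torque(assist, np.array([theta_hold]), np.array([tau_g_hold])))[0]
    )
    net_hold = tau_g_hold - assist_hold
    if net_hold < 0:
        log.warning(
            "trial %s: assistance (%.2f N*m) exceeds gravitational demand "
            "(%.2f N*m); clamping net demand at the floor",
            trial_id or subject.id,
            assist_hold,
            tau_g_hold,
        )
    demand = float(np.clip(net_hold / mtg.tau0_pos, cfg.demand_floor, 1.0))

    if cfg.protocol == "hold":
        t_end = endurance_time(demand, cfg.endurance)
        if cfg.endurance_jitter_sd > 0:
            t_end = min(
                t_end * float(np.exp(rng.normal(0.0, cfg.endurance_jitter_sd))),
                cfg.endurance.t_max_s,
            )
        kin, hold_start = _hold_kinematics(rng, cfg, subject.sex, t_end)
        fatigue_kin = np.clip((kin.time - hold_start) / t_end, 0.0, 1.0)
    else:
        t_end, hold_start = None, None
        kin = _free_kinematics(rng, cfg)
        fatigue_kin = np.zeros_like(kin.time)

    task = biomech.gravitational_torque(mtg, kin.theta, cfg.load_mass)
    assist_trace = assist_torque(assist, kin.theta, task)
    tau_ht = (
        mtg.effective_inertia(cfg.load_mass) * kin.alpha + task - assist_trace
    )
    demand_kin = np.clip(np.abs(tau_ht) / mtg.tau0_pos, cfg.demand_floor, 1.0)
    emg, envelopes = _synthesize_emg(rng, cfg, kin, demand_kin, fatigue_kin)
    survey = simulate_survey(
        subject,
        cfg.mode,
        float(fatigue_kin[-1]),
        rng,
        cfg.survey,
    )
    tid = trial_id or f"{subject.id}_{cfg.mode}"
    return TrialRecord(
        trial_id=tid,
        subject=subject,
        mode=cfg.mode,
        emg=emg,
        kin=kin,
        load_mass=cfg.load_mass,
        mvic_envelopes=envelopes,
        survey=survey,
        truth=TrialTruth(
            endurance_s=t_end,
            hold_start_s=hold_start,
            relative_demand=demand,
            net_torque=tau_ht,
            assist_torque=assist_trace,
        ),
    )


# ---------------------------------------------------------------------------
# Trial I/O: CSV traces + JSON sidecar


def write_trial(record: TrialRecord, directory: str | Path) -> dict[str, Path]:
    """Write ``<id>_emg.csv``, ``<id>_kin.csv`` and ``<id>_meta.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tid = record.trial_id
    paths: dict[str, Path] = {}
    if record.emg is not None:
        df = pd.DataFrame({"time_s": record.emg.times})
        for ch in record.emg.channels:
            df[ch] = record.emg.channel(ch)
        paths["emg"] = directory / f"{tid}_emg.csv"
        df.to_csv(paths["emg"], index=False, float_format="%.10g")
    kin_df = pd.DataFrame(
        {
            "time_s": record.kin.time,
            "theta_deg": record.kin.theta_deg,
            "omega_deg_s": record.kin.omega_deg_s,
            "alpha_deg_s2": record.kin.alpha_deg_s2,
        }
    )
    paths["kin"] = directory / f"{tid}_kin.csv"
    kin_df.to_csv(paths["kin"], index=False, float_format="%.10g")
    meta = {
        "trial_id": tid,
        "mode": record.mode,
        "load_mass_kg": record.load_mass,
        "subject": {
            "id": record.subject.id,
            "sex": record.subject.sex,
            "age": record.subject.age,
            "body_mass": record.subject.body_mass,
            "height": record.subject.height,
            "dominant_side": record.subject.dominant_side,
            "activity": record.subject.activity,
        },
        "mvic_envelopes": record.mvic_envelopes,
        "sample_rate_emg": None if record.emg is None else record.emg.sample_rate,
    }
    if record.survey is not None:
        meta["survey"] = {
            "comfort": record.survey.comfort,
            "fatigue_level": list(record.survey.fatigue_level),
            "fatigue_sites": list(record.survey.fatigue_sites),
        }
    if record.truth is not None:
        meta["truth"] = {
            "endurance_s": record.truth.endurance_s,
            "hold_start_s": record.truth.hold_start_s,
            "relative_demand": record.truth.relative_demand,
            "net_torque": record.truth.net_torque.tolist(),
            "assist_torque": record.truth.assist_torque.tolist(),
        }
    paths["meta"] = directory / f"{tid}_meta.json"
    paths["meta"].write_text(json.dumps(meta))
    return paths


def _read_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # malformed/truncated rows
        raise ValueError(f"parse error in {path.name}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    bad = df[list(required)].isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after the header line
        raise ValueError(f"parse error in {path.name}: truncated data at row {row}")
    return df


def read_trial(directory: str | Path, trial_id: str) -> TrialRecord:
    """Read a trial written by :func:`write_trial` (round-trip identity on
    all numeric traces to serialization precision)."""
    directory = Path(directory)
    meta_path = directory / f"{trial_id}_meta.json"
    try:
        meta = json.loads(meta_path.read_text())
    except FileNotFoundError:
        raise ValueError(f"missing metadata file {meta_path.name}") from None
    except json.JSONDecodeError as exc:
        raise ValueError(f"parse error in {meta_path.name}: {exc}") from exc

    def need(mapping: Mapping, key: str, where: str):
        if key not in mapping:
            raise ValueError(f"{meta_path.name}: missing field {where}.{key}")
        return mapping[key]

    subj_d = need(meta, "subject", "meta")
    subject = SubjectProfile(
        id=need(subj_d, "id", "subject"),
        sex=need(subj_d, "sex", "subject"),
        age=need(subj_d, "age", "subject"),
        body_mass=need(subj_d, "body_mass", "subject"),
        height=need(subj_d, "height", "subject"),
        dominant_side=need(subj_d, "dominant_side", "subject"),
        activity=need(subj_d, "activity", "subject"),
    )
    kin_df = _read_csv(
        directory / f"{trial_id}_kin.csv",
        ["time_s", "theta_deg", "omega_deg_s", "alpha_deg_s2"],
    )
    kin = JointState(
        kin_df["time_s"].to_numpy(),
        kin_df["theta_deg"].to_numpy(),
        kin_df["omega_deg_s"].to_numpy(),
        kin_df["alpha_deg_s2"].to_numpy(),
    )
    emg = None
    emg_path = directory / f"{trial_id}_emg.csv"
    if emg_path.exists():
        emg_df = _read_csv(emg_path, ["time_s", *CHANNELS])
        emg = EmgRecording(
            CHANNELS,
            emg_df[list(CHANNELS)].to_numpy().T,
            float(need(meta, "sample_rate_emg", "meta")),
        )
    survey = None
    if "survey" in meta:
        s = meta["survey"]
        survey = SurveyResponse(
            comfort=need(s, "comfort", "survey"),
            fatigue_level=tuple(s.get("fatigue_level", ())),
            fatigue_sites=tuple(s.get("fatigue_sites", ())),
        )
    truth = None
    if "truth" in meta:
        tr = meta["truth"]
        truth = TrialTruth(
            endurance_s=tr.get("endurance_s"),
            hold_start_s=tr.get("hold_start_s"),
            relative_demand=tr.get("relative_demand"),
            net_torque=np.asarray(need(tr, "net_torque", "truth"), dtype=float),
            assist_torque=np.asarray(need(tr, "assist_torque", "truth"), dtype=float),
        )
    return TrialRecord(
        trial_id=need(meta, "trial_id", "meta"),
        subject=subject,
        mode=need(meta, "mode", "meta"),
        emg=emg,
        kin=kin,
        load_mass=need(meta, "load_mass_kg", "meta"),
        mvic_envelopes=dict(need(meta, "mvic_envelopes", "meta")),
        survey=survey,
        truth=truth,
    )
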