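"""Per-trial computation of the twelve efficiency measures and cohort table.

Measures, by data source:

==  ===========================================================  =========
id  quantity                                                     units
==  ===========================================================  =========
1   sEMG mean absolute value (per channel)                       mV
2   trial-mean instantaneous median frequency (per channel)      Hz
3   median-power final/initial ratio (per channel)               --
4   accumulated squared EMG activation, per unit time            1/s
5   EMG-decoded (intent) shoulder torque, trial mean             N*m
6   intent joint power, trial mean magnitude                     W
7   MTG-activation fatigue from inverse dynamics, per unit time  1/s
8   inverse-dynamics net human torque, trial mean                N*m
9   inverse-dynamics joint power, trial mean magnitude           W
10  muscle metabolic energy expenditure, per unit time           W
11  load tolerance duration (angle above 80% of trial max)       s
12  survey comfort score                                         1-10
==  ===========================================================  =========

Measures 4, 7 and 10 divide the accumulated integral by the trace duration:
trials end at exhaustion, so hold times differ by about 2x across assistance
modes and raw accumulated integrals would mechanically reward the *least*
supportive mode. The per-time rates compare fatigue/energy intensity across
modes on equal footing; the underlying integral operations are available
unchanged in :mod:`exofatigue.emg_metrics` and :mod:`exofatigue.biomech`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import biomech
from .biomech import (
    AssistanceModel,
    JointState,
    MmeeParams,
    MtgModel,
    assist_torque,
    gravitational_torque,
    inverse_dynamics,
    mmee,
    mtg_activation,
    scale_model,
)
from .emg_metrics import (
    CHANNELS,
    FilterConfig,
    MeasureResult,
    fatigue_accumulation,
    imdf,
    mav,
    median_power,
    preprocess_emg,
    spectral_trend,
    time_dependent_psd,
)
from .intent_torque import IntentConfig, IntentModel, estimate_torque, fit_intent_model, joint_power
from .synth_types import CohortConfig, SurveyResponse
from .synthgen import TrialConfig, TrialRecord, generate_cohort, simulate_trial

log = logging.getLogger(__name__)

MEASURE_UNITS = {
    1: "mV", 2: "Hz", 3: "ratio", 4: "1/s", 5: "N*m", 6: "W",
    7: "1/s", 8: "N*m", 9: "W", 10: "W", 11: "s", 12: "score",
}
PER_CHANNEL_MEASURES = (1, 2, 3)
EMG_MEASURES = (1, 2, 3, 4, 5, 6)

TABLE_COLUMNS = (
    "trial_id", "subject", "sex", "mode", "measure_id", "channel",
    "value", "units", "note",
)


# ---------------------------------------------------------------------------
# Measure 11


def load_tolerance_duration(
    theta: np.ndarray,
    time: np.ndarray,
    threshold_frac: float = 0.8,
    reference: str = "trial_max",
    target_angle: float = 90.0,
) -> float:
    """Total time (s) the elevation angle exceeds ``threshold_frac`` of its
    reference (per-trial maximum by default, or the nominal target angle),
    with linear interpolation at threshold crossings."""
    theta = np.asarray(theta, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    if theta.size == 0 or theta.size != time.size:
        raise ValueError("empty or misaligned angle trace")
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must lie in (0, 1)")
    ref = float(np.max(theta)) if reference == "trial_max" else float(target_angle)
    thr = threshold_frac * ref
    above = theta > thr
    if not above.any():
        return 0.0
    total = 0.0
    d = theta - thr
    for i in range(time.size - 1):
        t0, t1 = time[i], time[i + 1]
        if above[i] and above[i + 1]:
            total += t1 - t0
        elif above[i] != above[i + 1] and d[i + 1] != d[i]:
            frac = d[i] / (d[i] - d[i + 1])  # crossing position in [0, 1]
            total += (1.0 - frac) * (t1 - t0) if above[i + 1] else frac * (t1 - t0)
    return float(total)


# ---------------------------------------------------------------------------
# Measure 12


def aggregate_survey(
    responses: Sequence[SurveyResponse], modes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-mode comfort summary (mean, median, STD) and fatigue-site counts.

    ``modes`` pairs each response with its assistance mode; if omitted all
    responses are pooled under mode ``'all'``.
    """
    if len(responses) == 0:
        raise ValueError("no survey responses to aggregate")
    if modes is None:
        modes = ["all"] * len(responses)
    if len(modes) != len(responses):
        raise ValueError("responses and modes are misaligned")
    rows = []
    for r, m in zip(responses, modes):
        if not 1 <= r.comfort <= 10:
            raise ValueError(f"comfort {r.comfort} outside [1, 10]")
        rows.append({"mode": m, "comfort": r.comfort, "sites": r.fatigue_sites})
    df = pd.DataFrame(rows)
    out = (
        df.groupby("mode")["comfort"]
        .agg(mean="mean", median="median", std=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="count")
        .reset_index()
    )
    site_counts: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        d = site_counts.setdefault(row["mode"], {})
        for s in row["sites"]:
            d[s] = d.get(s, 0) + 1
    out["site_counts"] = out["mode"].map(lambda m: dict(sorted(site_counts.get(m, {}).items())))
    return out


# ---------------------------------------------------------------------------
# Trial evaluation


@dataclass
class ModelsBundle:
    """Everything needed to evaluate one subject's trials: the scaled MTG
    model, per-mode assistance models, the fitted intent decoder, metabolic
    parameters and signal-processing settings."""

    mtg: MtgModel
    intent: IntentModel | None = None
    assist_models: Mapping[str, AssistanceModel] = field(
        default_factory=lambda: {m: AssistanceModel.for_mode(m) for m in biomech.MODES}
    )
    mmee_params: MmeeParams = MmeeParams()
    filter_config: FilterConfig = FilterConfig()
    psd_window_s: float = 0.5
    psd_overlap: float = 0.5
    trend_k: int = 3
    hold_threshold_frac: float = 0.8
    tolerance_reference: str = "trial_max"


def _missing(measure_id: int, reason: str, channel: str | None = None) -> MeasureResult:
    return MeasureResult(
        measure_id, np.nan, MEASURE_UNITS[measure_id], channel, {"missing": reason}
    )


def evaluate_trial(trial: TrialRecord, bundle: ModelsBundle) -> list[MeasureResult]:
    """Compute all applicable measures for one trial.

    Deterministic given inputs. Missing inputs degrade gracefully: without
    an EMG recording Measures 1-6 are flagged missing while the kinematic
    measures 7-11 are still computed; without a fitted intent decoder only
    5-6 are flagged.
    """
    results: list[MeasureResult] = []
    kin = trial.kin
    duration = kin.duration
    prov = {"window_s": bundle.psd_window_s, "overlap": bundle.psd_overlap}

    if trial.emg is None:
        for mid in (1, 2, 3):
            results.extend(_missing(mid, "no EMG recording", ch) for ch in CHANNELS)
        results.extend(_missing(mid, "no EMG recording") for mid in (4, 5, 6))
    else:
        acts = preprocess_emg(trial.emg, trial.mvic_envelopes, bundle.filter_config)
        for ch in trial.emg.channels:
            results.append(
                MeasureResult(1, mav(trial.emg.channel(ch)), "mV", ch, dict(prov))
            )
            spec = time_dependent_psd(
                trial.emg.channel(ch),
                trial.emg.sample_rate,
                bundle.psd_window_s,
                bundle.psd_overlap,
            )
            med_freq = imdf(spec)
            results.append(
                MeasureResult(2, float(np.nanmean(med_freq)), "Hz", ch, dict(prov))
            )
            trend = spectral_trend(median_power(spec), spec.times, bundle.trend_k)
            results.append(MeasureResult(3, trend.ratio, "ratio", ch, dict(prov)))
        results.append(
            MeasureResult(
                4,
                fatigue_accumulation(acts) / duration,
                "1/s",
                None,
                {"normalized_by": "trace duration"},
            )
        )
        if bundle.intent is None:
            results.extend(_missing(mid, "no intent model") for mid in (5, 6))
        else:
            tau_hat = estimate_torque(bundle.intent, trial)
            results.append(
                MeasureResult(5, float(np.mean(tau_hat)), "N*m", None, {})
            )
            p_hat = joint_power(tau_hat, kin.omega)
            results.append(
                MeasureResult(6, float(np.mean(np.abs(p_hat))), "W", None, {})
            )

    mtg = bundle.mtg
    assist_model = bundle.assist_models[trial.mode]
    task = gravitational_torque(mtg, kin.theta, trial.load_mass)
    exo = assist_torque(assist_model, kin.theta, task)
    tau_ht = inverse_dynamics(mtg, kin, exo, trial.load_mass)
    a, saturation = mtg_activation(mtg, tau_ht, kin)
    finite = np.isfinite(a)
    results.append(
        MeasureResult(
            7,
            fatigue_accumulation(a[np.newaxis, finite], kin.time[finite]) / duration,
            "1/s",
            None,
            {"saturation_frac": saturation, "normalized_by": "trace duration"},
        )
    )
    results.append(MeasureResult(8, float(np.mean(tau_ht)), "N*m", None, {}))
    results.append(
        MeasureResult(
            9, float(np.mean(np.abs(joint_power(tau_ht, kin.omega)))), "W", None, {}
        )
    )
    tau_active = tau_ht - mtg.tau_passive(kin.theta, kin.omega)
    results.append(
        MeasureResult(
            10,
            mmee(tau_active, kin.omega, kin.time, bundle.mmee_params) / duration,
            "W",
            None,
            {"normalized_by": "trace duration"},
        )
    )
    results.append(
        MeasureResult(
            11,
            load_tolerance_duration(
                kin.theta_deg,
                kin.time,
                bundle.hold_threshold_frac,
                bundle.tolerance_reference,
            ),
            "s",
            None,
            {"reference": bundle.tolerance_reference},
        )
    )
    if trial.survey is None:
        results.append(_missing(12, "no survey response"))
    else:
        results.append(MeasureResult(12, float(trial.survey.comfort), "score", None, {}))
    return results


# ---------------------------------------------------------------------------
# Cohort measure table


@dataclass
class MeasureTable:
    """Tidy long-format table: one row per (trial, measure, channel)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"measure table missing column(s) {missing}")
        key = self.df[["trial_id", "measure_id", "channel"]].astype(str)
        dup = key.duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate (trial, measure, channel) rows: {key[dup].values[:3]}"
            )

    def values(
        self, measure_id: int, channel: str | None = None, shoulder_mean: bool = True
    ) -> pd.DataFrame:
        """Scalar value per trial for one measure.

        Per-channel measures are averaged over the shoulder channels when
        ``channel`` is None (BRD excluded: it is not a shoulder-elevation
        muscle), matching how per-channel metrics are summarized per trial.
        """
        sub = self.df[self.df["measure_id"] == measure_id].copy()
        if channel is not None:
            sub = sub[sub["channel"] == channel]
        elif measure_id in PER_CHANNEL_MEASURES and shoulder_mean:
            sub = sub[sub["channel"] != "BRD"]
        grouped = (
            sub.groupby(["trial_id", "subject", "sex", "mode"], sort=True)["value"]
            .mean()
            .reset_index()
        )
        return grouped

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.df.to_csv(path, index=False, float_format="%.10g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasureTable":
        df = pd.read_csv(path)
        df["channel"] = df["channel"].where(pd.notna(df["channel"]), None)
        df["note"] = df["note"].where(pd.notna(df["note"]), "")
        return cls(df)


def build_measure_table(
    evaluated: Iterable[tuple[TrialRecord, Sequence[MeasureResult]]],
) -> MeasureTable:
    """Assemble evaluated trials into the cohort-level tidy table."""
    rows = []
    for trial, results in evaluated:
        for r in results:
            rows.append(
                {
                    "trial_id": trial.trial_id,
                    "subject": trial.subject.id,
                    "sex": trial.subject.sex,
                    "mode": trial.mode,
                    "measure_id": r.measure_id,
                    "channel": r.channel,
                    "value": r.value,
                    "units": r.units,
                    "note": r.provenance.get("missing", ""),
                }
            )
    if not rows:
        raise ValueError("no evaluated trials to tabulate")
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    df = df.sort_values(
        ["subject", "mode", "measure_id", "channel"], kind="stable", na_position="first"
    ).reset_index(drop=True)
    return MeasureTable(df)


# ---------------------------------------------------------------------------
# End-to-end pipeline


def run_pipeline(
    cohort_config: CohortConfig = CohortConfig(),
    trial_config: TrialConfig = TrialConfig(),
    seed: int = 0,
    modes: Sequence[str] = biomech.MODES,
    assist_models: Mapping[str, AssistanceModel] | None = None,
    mmee_params: MmeeParams = MmeeParams(),
    intent_config: IntentConfig = IntentConfig(),
) -> MeasureTable:
    """Simulate and evaluate a full cohort: for every subject, fit the
    intent decoder on a training set of one free-motion trial, one
    unassisted (IE) hold and one passive-spring (FP) hold — the protocol's
    data-gathering phase; the FP hold needs no decoder to run and breaks
    the collinearity between kinematics and torque in unassisted data —
    then run and evaluate one lift-and-hold trial per assistance mode.

    Trials are processed one at a time and discarded, so memory stays flat;
    ``seed`` drives every random draw through spawned child seeds.
    """
    if assist_models is None:
        assist_models = {m: AssistanceModel.for_mode(m) for m in biomech.MODES}
    cohort = generate_cohort(replace(cohort_config, seed=seed))
    root = np.random.SeedSequence(seed)
    evaluated: list[tuple[TrialRecord, list[MeasureResult]]] = []
    for subj, subj_seq in zip(cohort, root.spawn(len(cohort))):
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in subj_seq.spawn(4 + len(modes))]
        mtg = scale_model(subj)
        train_free = simulate_trial(
            subj, replace(trial_config, protocol="free", mode="IE"),
            mtg, assist_models["IE"], seed=seeds[0],
            trial_id=f"{subj.id}_train_free",
        )
        train_ie = simulate_trial(
            subj, replace(trial_config, mode="IE"),
            mtg, assist_models["IE"], seed=seeds[1],
            trial_id=f"{subj.id}_train_ie",
        )
        train_fp = simulate_trial(
            subj, replace(trial_config, mode="FP"),
            mtg, assist_models["FP"], seed=seeds[2],
            trial_id=f"{subj.id}_train_fp",
        )
        intent = fit_intent_model(
            [train_free, train_ie, train_fp], intent_config, seed=seeds[3]
        )
        bundle = ModelsBundle(
            mtg=mtg,
            intent=intent,
            assist_models=assist_models,
            mmee_params=mmee_params,
            hold_threshold_frac=trial_config.hold_threshold_frac,
        )
        for k, mode in enumerate(modes):
            trial = simulate_trial(
                subj, replace(trial_config, mode=mode),
                mtg, assist_models[mode], seed=seeds[4 + k],
            )
            results = evaluate_trial(trial, bundle)
            trial.emg = None  # drop the heavy trace; measures are computed
            evaluated.append((trial, results))
        log.info("evaluated subject %s (%s)", subj.id, subj.sex)
    return build_measure_table(evaluated)
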