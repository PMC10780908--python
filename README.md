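# exofatigue

Quantitative evaluation of shoulder-exoskeleton efficiency during fatiguing
weight-lifting holds — for biomechanists and wearable-robotics engineers who
want a tested, reproducible version of the standard 12-measure analysis
(surface-EMG fatigue metrics, inverse dynamics with muscle torque
generators, metabolic energy, endurance, survey) across four assistance
modes: inactive (IE), fully passive spring (FP), fully active motor (FA)
and active–passive (AP).

Because raw human-subject recordings from such studies are rarely shareable,
the package includes a first-class synthetic-cohort generator: fatiguing
holds whose endurance follows a Rohmert-type law on net relative demand,
with EMG amplitude growth and spectral compression as fatigue accumulates.
Mode differences (AP holding ~2× longer than FP, the efficiency ordering
AP > FA > FP > IE) *emerge* from the simulated mechanics and calibrated
assistance, so every claim the analysis makes can be checked end-to-end.

## The model in brief

* **Endurance:** T = a·d^(−b), with net relative demand
  d = (τ_gravity − τ_exo)/τ₀ at the 90° hold posture.
* **Muscle torque generator:** τ = a·τ_ω(ω)·τ_θ(θ)·τ₀^± + τ_p(θ, ω);
  inverse dynamics on a sagittal arm+load pendulum gives the net human
  torque; inverting the MTG law gives the required activation.
* **Metabolic energy (MMEE):**
  E = ∫ h_M·ω_max·|τ_a| + h_SL·|τ_a·ω| + max(τ_a·ω, 0) dt,
  h_M = 0.054, h_SL = 0.283 (shortening) / 1.423 (lengthening).
* **EMG measures:** MAV, instantaneous median frequency (IMDF), median-power
  trend, and FAT = Σ_m ∫ σ_m² dt on MVIC-normalized envelopes.
* **Statistics:** per-measure mixed model `value ~ mode + mode:sex` with a
  random subject intercept; Tukey HSD connecting letters on the eight
  mode × sex least-squares means (Q = q(α, k, df)/√2).

See `docs/methods.md` for assumptions, calibration and limitations.

## Worked example

```python
import exofatigue as xf

table = xf.run_pipeline(
    cohort_config=xf.CohortConfig(n_per_sex=4),
    trial_config=xf.TrialConfig(sample_rate_emg=1000.0, emg_band_hz=(20.0, 400.0)),
    seed=2,
)
endurance = table.values(11).groupby("mode")["value"].mean()
print(endurance.round(1))
print(f"AP/FP ratio: {endurance['AP']/endurance['FP']:.2f}")

fit = xf.fit_measure_model(table, 11)
print(xf.tukey_hsd(fit).table())
```

prints (seed 2):

```
mode
AP    85.2
FA    47.3
FP    42.7
IE    31.8
AP/FP ratio: 2.00
mode    sex letters   ls_mean
  AP   male       A 86.696282
  AP female       A 83.631981
  FA   male       B 54.149911
  FP   male      BC 48.344073
  FA female      CD 40.495842
  FP female       D 37.014511
  IE   male       D 37.009594
  IE female       E 26.647173
```

Mean load-tolerance duration (seconds the elevation angle stays above 80%
of its per-trial maximum) rises monotonically with assistance, the
active–passive mode doubles the passive hold time, and groups sharing a
Tukey letter are statistically indistinguishable at α = 0.05 — e.g. both
sexes benefit equally from AP (shared letter A), while unassisted females
fatigue fastest (letter E alone).

The `examples/` directory walks each capability: cohort/trial simulation
and CSV+JSON round-tripping (`01`), EMG fatigue signatures (`02`), the
EMG-to-torque intent decoder (`03`), inverse dynamics and metabolic cost
(`04`), and the full statistics layer (`05`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch — simulates a cohort,
evaluates all twelve measures per trial, fits the mixed models and Tukey
comparisons — prints the per-mode endurance summary, and writes the results
JSON for the run.
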