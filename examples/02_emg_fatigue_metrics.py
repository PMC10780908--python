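"""Surface-EMG fatigue signatures on a fatiguing hold.

During a sustained contraction the EMG amplitude (MAV) grows while the
spectrum compresses toward low frequencies (IMDF falls): the two classic
myoelectric fatigue signatures. The forearm channel (BRD) drives the elbow,
is unaffected by a shoulder hold, and shows neither trend.
"""

import numpy as np

import exofatigue as xf

subject = xf.SubjectProfile("F05", "female", 26.0, 61.0, 1.66, "right", 3.0)
trial = xf.simulate_trial(subject, xf.TrialConfig(mode="IE"), seed=11)
fs = trial.emg.sample_rate
t0 = trial.truth.hold_start_s + 0.3
t1 = trial.truth.hold_start_s + trial.truth.endurance_s - 0.3
window = slice(int(t0 * fs), int(t1 * fs))
print(f"hold duration {t1 - t0:.1f} s at 90 deg elevation\n")

print("channel  MAV slope (mV/s)  IMDF slope (Hz/s)  mean IMDF (Hz)")
for ch in trial.emg.channels:
    x = trial.emg.channel(ch)[window]
    times, vals = xf.mav_trend(x, fs, window_s=1.0)
    mav_slope = xf.spectral_trend(vals, times).slope
    spec = xf.time_dependent_psd(x, fs, window_s=0.5)
    freq_trace = xf.imdf(spec)
    imdf_slope = xf.spectral_trend(freq_trace, spec.times).slope
    tag = "(elbow muscle, fatigue-exempt)" if ch == "BRD" else ""
    print(
        f"{ch:7s}  {mav_slope:+16.2e}  {imdf_slope:+17.3f}"
        f"  {np.nanmean(freq_trace):13.1f}  {tag}"
    )

acts = xf.preprocess_emg(trial.emg, trial.mvic_envelopes)
fat = xf.fatigue_accumulation(acts)
print(
    f"\naccumulated squared activation FAT = {fat:.1f} "
    f"({fat / trial.kin.duration:.3f} per second)"
)
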