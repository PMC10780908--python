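# Methods

`exofatigue` evaluates how much a shoulder exoskeleton helps during
fatiguing weight-lifting holds, across four assistance modes — inactive
(IE), fully passive spring (FP), fully active motor (FA), and active–passive
(AP = spring + motor) — using twelve quantitative measures spanning surface
EMG, kinematics/inverse dynamics, metabolic energy and a user survey. The
raw laboratory recordings such a study produces are typically not shareable,
so the package pairs the analysis pipeline with a synthetic-cohort generator
that reproduces the statistical structure the analysis assumes; every stage
is testable end-to-end, and the headline claims (mode ordering, the ~2×
AP-vs-FP endurance gain) *emerge* from the simulated physics rather than
being injected.

## The synthetic world

**Cohort.** `n_per_sex` subjects per sex with anthropometry drawn from
truncated normals matching the study population: females 24 ± 3.0 y,
59 ± 10.6 kg, 1.65 ± 0.07 m, 3.0 ± 1.9 workouts/wk; males 27 ± 3.1 y,
74 ± 11.7 kg, 1.78 ± 0.06 m, 1.0 ± 1.7 workouts/wk; ages truncated to
[20, 50]; 9 of 10 right-dominant.

**Task.** Lift a 2.268 kg (5 lb) kettlebell with the extended arm to a
90° elevation target (smoothstep ramp; females ramp faster, 0.9 s vs 1.3 s
mean rise, reflecting the faster female lifting pace), hold with ~0.8° RMS
postural jitter until exhaustion, then lower. The endurance time follows a
Rohmert-type law on the net relative demand d = (gravity demand − assistance)
/ peak isometric strength:

    T = a · max(d − floor, ε)^(−b),  capped at T_max

with defaults a = 12 s, b = 0.97, floor = 0 (demand is separately clamped
at 0.02 so over-assistance never produces negative demand). The paper-side
literature reports no hold durations, so `a` was set to give realistic
unassisted holds of ~25–35 s; `b` was calibrated **once, analytically, at
cohort-mean anthropometry** so the AP/FP endurance ratio is ≈ 2 (the
stated headline), and frozen. Within-subject endurance variability is
lognormal with σ = 0.05.

**Assistance calibration.** FP: piecewise-linear spring profile peaking at
7.5 N·m at 90° (three support levels ×0.7/1.0/1.3). FA: motor torque =
0.40 × estimated task-demand torque, saturated at the motor's 9 N·m rating
(9:1 gearing kept as metadata). AP is their sum. The spring peak sits just
*below* the motor rating deliberately: the reported mode ordering
(AP > FA > FP > IE) requires the active mode to out-assist the spring for
every subject. The "intent" signal driving FA/AP in both generation and
evaluation is the model-estimated gravitational task demand — a feedforward
on the task — which keeps the controller reconstruction identical on both
sides and avoids a circular dependency on the EMG decoder.

**EMG synthesis.** Per channel (UTRA, MTRA, MDEL, PDEL, ADEL, BRD), a
band-pass-filtered (20–450 Hz) Gaussian carrier is amplitude-modulated by
σ(t) = w_ch · d(t) · (1 + k_ch · f(t)), where d is the instantaneous net
demand, f ∈ [0, 1] is the fraction of the endurance time elapsed, and the
per-channel fatigue gains k_ch (0.35 base, site multipliers 0.7–1.3) are
deliberately heterogeneous so a linear decoder can separate demand from
fatigue drift. Spectral compression toward low frequencies is implemented
by time-warped resampling of the carrier (local warp rate 1 − 0.30·f, i.e.
a 30% median-frequency drop at exhaustion). The BRD (brachioradialis,
elbow) channel is decoupled from shoulder demand and carries no fatigue
modulation. MVIC-level RMS amplitudes (0.30–0.55 mV) set the scale; the
stored per-channel MVIC *envelope* equals RMS × √(2/π), the rectified mean
of a Gaussian carrier. Sample rates default to 2000 Hz (EMG) and 100 Hz
(kinematics) — unstated in the source literature, exposed in config.

What the generator does **not** emulate: motor-unit physiology, conduction
artifacts, electrode lift, 3-D kinematics, co-contraction, or real survey
psychology. A green test therefore establishes that the *pipeline* computes
what it claims on data with the assumed structure — not that the
physiological assumptions themselves are true.

## The measures

1–4 (EMG): mean absolute value; trial-mean instantaneous median frequency
(cumulative-spectrum inversion with linear interpolation; zero-power windows
dropped and counted); per-window "median power" trend, defaulting to total
spectral power per window (the literature's wording is ambiguous between a
frequency and a power statistic — both are implemented, the choice is a
config switch, and the default is the one consistent with "a decline in
median frequency and a rise in median power" under fatigue); accumulated
squared activation FAT = Σ_m ∫ σ_m² dt. Preprocessing is a 4th-order
zero-phase Butterworth band-pass (20–450 Hz), rectification, 6 Hz low-pass
envelope, MVIC normalization; the spectrogram uses 0.5 s Hann windows with
50% overlap (none of these are specified upstream; all are config).

5–6 (intent): a ridge-regression stand-in for the subject-specific neural
network decoder, mapping activation envelopes + angular velocity to net
shoulder torque, and joint power = torque × measured angular velocity.
The sin(angle) feature listed in the original feature set is **off by
default**: trained on unassisted data the torque label is an exact function
of kinematics, so the regression loads on the angle feature and fails to
transfer to assisted modes; for the same reason the per-subject training
set is free motion + an IE hold + an FP hold (the spring mode runs without
a decoder, and the contrast forces the fit to credit the EMG). Holdout
fraction 25%, α = 0.01 on standardized features; models persist as JSON.

7–10 (inverse dynamics / energy): the arm + load is a sagittal rigid
pendulum (arm mass 5% of body mass, shoulder–grip lever 40% of stature,
COM at 45% of the lever, rod inertia; peak strength 0.85/1.10 N·m·kg⁻¹ of
body mass for females/males, lowering strength 70% of lifting). Net human
torque τ_ht = I_eff·ω̇ + (m_arm l_com + m_load l_arm) g sin θ − τ_exo.
The MTG law τ = a·τ_ω(ω)·τ_θ(θ)·τ₀^± + τ_p is inverted pointwise for the
signed activation (branch by numerator sign, clipped to [−1, 1] with the
saturated fraction reported). τ_θ is a raised-cosine bell (centre 70°,
half-width 100°); τ_ω is a Hill hyperbola (ω_max 8 rad/s, shape 0.25) with
the eccentric branch capped at 1 to keep τ_ω ∈ [0, 1]; τ_p combines sinh
stiffness about the neutral pose (0.20 N·m, 1.5 rad⁻¹) with 0.15 N·m·s/rad
viscous damping. Metabolic cost follows the joint-space MMEE model

    E = ∫ [ h_M ω_max |τ_a| + h_SL(sign τ_a ω) |τ_a ω| + max(τ_a ω, 0) ] dt

with h_M = 0.054, h_SL = 0.283 (shortening) / 1.423 (lengthening); the
printed form of this integrand is typographically ambiguous about absolute
values and work rectification, and the interpretation above (maintenance
heat + sign-dependent sliding heat + positive mechanical work) is fixed
explicitly and oracle-tested. The excitation-to-activation first-order ODE
uses an exact exponential integrator.

11–12: load-tolerance duration = time the elevation angle exceeds 80% of
its per-trial maximum (linear interpolation at crossings; a fixed-90°
reference is available since the upstream definition is ambiguous), and
the survey comfort score (mode baseline − fatigue penalty + noise, on
1–10; baselines IE 5 < FP 6 < FA 7 < AP 8).

**Rate normalization (a deliberate interpretation).** Measures 4, 7 and 10
are reported per unit time (integral ÷ trace duration). Trials end at
exhaustion, so hold times differ ~2× across modes; raw accumulated
integrals would mechanically reward the *least* supportive mode and cannot
jointly reproduce the reported mode ordering and the 2× endurance ratio
under any monotone endurance law (E_total ∝ d·T(d) is non-monotone in d
when the endurance ratio tracks the demand ratio). The rate form compares
fatigue/energy intensity on equal footing and lands on the magnitude of
the published least-squares means (~0.5–1.5 for MMEE with
h_M·ω_max·τ_a ≈ 1 W). The integral operations themselves are unchanged.

## Statistics

Each measure: linear mixed model `value ~ mode + mode:sex` with a random
subject intercept (sex is not separately estimable — each subject has one
sex — so between-subject sex variance loads on the intercept; hence the
"subject Wald p-value"). Fitting uses REML via statsmodels; a singular or
degenerate fit (e.g. noiseless data) falls back to OLS cell means with a
warning, which leaves cell means and R² valid but no variance component.
Reported per measure: normalized RMSE (RMS residual / grand mean × 100),
R² = 1 − SS_res/SS_tot with fitted values including the subject BLUPs, and
the Wald p (variance estimate / asymptotic SE, two-sided normal). Two known
pathologies of that Wald test are documented rather than hidden: under the
null the variance sits on its parameter-space boundary, making the p-value
conservative (non-uniform); and for extreme variance ratios or very few
subjects the asymptotic SE degenerates and power collapses — at the study's
design size (20 subjects × 4 modes) with moderate heterogeneity it detects
reliably.

Tukey HSD on the eight mode × sex least-squares means: a pair differs when
|mean_i − mean_j| / SE_ij > Q with Q = q(α, k, df)/√2 from the studentized
range; SE_ij comes from the fixed-effect covariance of the cell means.
The denominator df is configurable because the original analysis software's
method is not published: `residual` (default) uses N − p_fixed −
(n_subjects − 1) = 53 for the 20 × 4 design, giving Q = 3.1551;
`containment` uses N − n_subjects = 60, giving Q = 3.1403 — both within
0.5% of the reported 3.14619. Connecting letters use the insert-and-absorb
algorithm, which provably yields the maximal cliques of the
non-significance graph (tested against a brute-force clique oracle);
letter assignment is canonicalized by descending best-member mean, making
the output invariant to input row order. One-way ANOVA (used for the
sex-balance checks) is the classical fixed-effects F, which equals the
squared pooled t for two groups.

## Numerical conventions and edge cases

Radians/seconds/N·m internally, degrees at the I/O boundary; g = 9.81 m/s².
Zero-power spectrogram windows → NaN, dropped from trends with a count.
MTG inversion outside the force-generating range → NaN samples, flagged.
Over-assistance clamps net demand at the floor with a logged warning.
Trial CSVs round-trip at 10 significant digits; truncated or malformed
rows raise parse errors naming file and row. All randomness flows from
integer seeds through `numpy.random.Generator` (spawned per subject/trial
in the pipeline), so fixed seeds give bit-identical traces.

## Interface note

The package is a library: the importable API plus `examples/` scripts are
the interface (simulation, evaluation, reporting are one-call functions),
so no command-line wrapper is shipped.

## Known limitations

Single sagittal degree of freedom (no scapulothoracic or 3-D motion); the
intent decoder is linear and subject-specific (a pluggable interface allows
a network substitute); the spring's true torque–angle curve is not public,
so the piecewise-linear profile is an assumption; survey generation is a
toy model adequate only for exercising the aggregation/statistics path;
REML machinery is limited to the random-intercept model.
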