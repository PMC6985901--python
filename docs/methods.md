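# Methods

`betadyn` analyses movement-related beta-band (15–30 Hz) dynamics in a cued
isometric grip-force paradigm: contractions of 2, 5 or 10 s at 30 % of
maximum voluntary force (MVF), 15 trials per duration per run in
pseudo-random order, separated by 30-s rests, with the visual target
appearing 2 s before each contraction. Because no real recordings ship with
the package, a first-class synthetic-session generator produces multichannel
sensor data with the statistical structure this analysis assumes, together
with ground-truth annotations that every downstream stage can be scored
against.

## Synthetic sessions

**Burst model.** Sensorimotor beta activity is generated as transient bursts
(~100 ms, 21.5-Hz carrier under a Tukey window, random phase, lognormal
amplitude) rather than a sustained oscillation, following the burst account
of sensorimotor beta: task phases modulate the *probability* of a burst, not
its amplitude. Burst trains are drawn from an inhomogeneous renewal process
with a refractory period equal to the burst duration plus a 20-ms gap, so
bursts are disjoint by construction. The waiting hazard is dead-time
compensated, `lambda' = lambda / (1 - lambda * dbar)` with `dbar` the mean
burst-plus-gap length, which makes the configured `lambda(t)` the
*unconditional* burst rate: the expected burst count over any window equals
the integral of the rate. Configurations whose peak rate violates
`lambda * dbar < 0.85` are rejected as unable to keep bursts disjoint.

**Rate profile.** The task source rests at 1.8 bursts/s, is suppressed to
0.3 bursts/s from the visual cue (2 s before contraction) to contraction
offset (the movement-related beta decrease, MRBD), and receives a
post-offset surplus shaped as a Weibull density — the same parametric family
the rebound fit uses, which is what makes parameter-recovery tests sharp.
Defaults per condition: surplus mass 8 / 5 / 2.5 bursts per trial and
Weibull scale 2.0 / 2.75 / 3.5 s (shape 1.8) for the 2 / 5 / 10-s tasks.
These values were fixed once, by a power analysis of the ordering contrasts
at the default trial counts, to produce the qualitative pattern the analysis
is designed to detect: post-movement rebound (PMBR) amplitude decreasing,
and its latency increasing, with task duration, at constant burst amplitude.
Background sources are organised into three *networks* that burst as units
(shared event times at a stationary 1.2 bursts/s per network, independent
carrier phases, mild amplitude jitter across members) — ongoing activity in
real recordings is network-structured, and this is exactly the mutually
exclusive state organisation the envelope HMM downstream assumes; fully
independent per-source bursts would make the state decomposition
unidentifiable.

**Sensors.** MEG-like data are a lead-field projection of the sources plus
spatially white Gaussian noise (SD 0.05) and per-channel 1/f background
(amplitude 0.10), at 600 Hz. The default lead field has random orthonormal
columns (seeded QR), which keeps localization well-conditioned without
pretending to model anatomy; a crude single-sphere dipole option exists for
geometry-flavoured experiments. Desk-scale defaults are 24 channels and 10
sources/parcels; 78 parcels are supported through configuration. EMG is
modelled as baseline Gaussian noise whose SD is multiplied by 10 (extensor)
and 6 (flexor) during contractions, so the 3×SD detection rule operates at a
known contrast. Force is written directly in %MVF: 30 % plateaus with
per-condition trial-to-trial SD (1.0 / 0.8 / 0.6 %MVF — harder, shorter
tasks vary more), 0.3-s ramps, measurement noise, and two 3-s 100 %MVF
probes before and after the trial block for fatigue monitoring. Contraction
onsets/offsets are jittered (SD 80 ms, clipped at ±0.4 s) around the cued
times and recorded as ground truth.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: anatomical forward models and head movement,
sensor-noise covariance structure of a real gradiometer array, ocular and
cardiac artifacts, physiological EMG waveforms, fatigue drift, and
between-subject variability. Recovery results here demonstrate correctness
of the algorithms under the stated generative assumptions, not field
performance.

## Event detection and behaviour

EMG is band-pass filtered 1–150 Hz (zero-phase 4th-order Butterworth — used
everywhere a band is named) and rectified. The noise threshold is
`k_sd`(= 3) × the SD of the rectified signal over baseline windows 13–23 s
after each offset cue, pooled over all trials of the session, per channel.
Onset is the first supra-threshold sample within ±0.5 s of the contraction
cue; offset the last within ±0.5 s of the end cue. A raw 3×SD comparison on
rectified Gaussian noise is exceeded ~7 % of the time, so the raw search is
gated by a sustained excursion of a 25-ms moving average (run length ≥ one
smoothing window): the gate locates the contraction edge robustly, the first
raw supra-threshold sample after it gives a sample-exact onset on clean
steps. Trials failing either search are rejected (`no_onset`/`no_offset`);
trials with supra-threshold activity ≥ 50 ms on *both* channels during rest
are rejected as `rest_movement`; an automated broadband-power z-score
(> 5 SD across trials) replaces visual inspection for MEG artifacts
(`artifact`). Filtering is skippable (`filter_band=None`) for
already-conditioned fixtures. Behavioural summaries exclude the first and
last 0.5 s of each contraction; MVF is the peak 200-ms sliding mean minus
the final 400-ms baseline of the probe trace.

## Beamforming

A scalar LCMV beamformer with unit-gain constraint,
`w = C⁻¹l / (lᵀC⁻¹l)`. Windows (relative to detected events): MRBD active =
[onset, onset + duration], control starting 24 s after onset with matching
length; PMBR active = [offset, offset + 8 s], control = [offset + 16 s,
offset + 24 s]. Covariances are second-moment matrices of beta-filtered data
concatenated over all kept trials of all three durations (and pooled
sample-weighted across runs); MRBD and PMBR get separate covariance sets and
weights. Weights use the Tikhonov-regularised combined covariance
(`C + 0.05·λ_max·I`; the same 5 % rule the wide-band parcel beamformer
states); power terms use the unregularised window covariances. The contrast
is the Vrba–Robinson pseudo-T, `(P_a − P_c) / (2·ε·wᵀw)` with ε the smallest
eigenvalue of the unregularised combined covariance as the sensor-noise
proxy — chosen because it is standard practice and scale-invariant; the map
is invariant to global amplitude rescaling by construction. The peak is the
maximum (PMBR) or minimum (MRBD) of the map. Parcel ("virtual electrode")
timecourses use one representative source per parcel, a 1–150 Hz covariance
over the whole experiment, and are leakage-corrected by iterative Löwdin
symmetric orthogonalization with per-row magnitude regression (closest
orthogonal matrix; relative SSR change < 1e-6, ≤ 50 iterations;
deterministic; rank-deficient input is an error naming the collinear rows).

## Spectral analysis

Time-frequency spectrograms use 31 overlapping bands — centres linearly
spaced 2–148 Hz, 8 Hz wide, lower edges clipped at 0.5 Hz — a layout chosen
to span the 1–150 Hz analysis range with >50 % overlap; it is configurable.
Band envelopes are Hilbert magnitudes computed on the continuous timecourse
(so epoch edges carry no transform transients), epoched offset-aligned
(31/34/39-s epochs starting 5/8/13 s before offset for 2/5/10 s) or
onset-aligned (from 3 s before onset), averaged over same-condition trials,
then baseline-corrected: subtract and divide by the mean over the window
2–10 s before the end of the trial (averaging precedes correction). The
beta timecourse keeps absolute units (baseline subtracted only) so the
Weibull amplitude has source units; its TFS counterpart is a relative
measure and scale-invariant.

## Response quantification

**PMBR.** The rebound start t0 is the first zero up-crossing of the trial-
averaged envelope, lightly smoothed (200-ms moving average used for t0
detection only), searched from the movement offset — anchoring there makes
t0 immune to brief positive wobbles inside long movement periods. The curve
`β · f(t − t0; a, b)` with the Weibull density
`f(t) = (b/a)(t/a)^{b−1} e^{−(t/a)^b}` is fitted by, for each candidate
(a, b), solving β by ordinary least squares and minimising the SSR over
(log a, log b) with Nelder–Mead from a 3×3 log-spaced multi-start grid over
a ∈ [0.1, 20] s, b ∈ [0.5, 10] (the SSR surface is multimodal); a soft box
penalty keeps iterates inside those ranges. Derived metrics: time-to-peak
`t0 + a((b−1)/b)^{1/b}` (the density mode, b > 1), peak amplitude `β·f` at
that time, and return-to-baseline: the first time after the post-peak point
of steepest descent where |d(βf)/dt| < 1e-4 (units: source units per second;
the threshold is configurable — the bare number is conventional). The
steepest-descent anchor matters because the gradient is exactly zero at the
peak itself.

**MRBD.** A trapezoid (0→h over [t1,t2], h over [t2,t3], h→0 over [t3,t4],
h < 0) is fitted to the onset-aligned envelope from 3 s before onset to the
rebound start, with vertex ordering enforced by optimising (t1, log Δ1,
log Δ2, log Δ3, h) — positive increments by construction — with multi-start
Nelder–Mead seeded from half-depth crossing heuristics. Amplitude |h|,
duration t3 − t2, integral |h|((t4−t1)+(t3−t2))/2. Fits with |h| below 0.1 %
of the data scale are flagged degenerate rather than erroring.

## Envelope HMM

Parcel timecourses are decimated to 100 Hz (FIR, zero-phase), filtered
1–40 Hz, Hilbert-enveloped, standardised per parcel (zero mean, unit
variance — prevents high-power parcels dominating the observation model),
and concatenated across runs with recorded boundaries so chain recursions
never bridge runs. The model: K mutually exclusive states, each a
multivariate normal over parcels; a Markovian state sequence. Inference is
structured variational Bayes with conjugate posteriors — Dirichlet rows on
the transition matrix (pseudo-counts 10 on the diagonal, 1 off — a mild
persistence prior), Dirichlet initial distribution, Normal–Wishart
observation parameters (empirical-mean centring, β0 = 1, ν0 = P + 2, scale
matrix set so the prior expected precision equals the inverse empirical
covariance) — and an exact forward–backward chain posterior computed with
the expected-log parameters. The free energy −ELBO = −ln Z̃ + Σ KL is
evaluated after every E-step; it is mathematically non-increasing and
asserted so (relative tolerance 1e-8) in the tests. Each fit runs `n_inits`
(default 10) restarts from seeded random perturbations of a k-means
partition (init index added to the base seed); the lowest-free-energy run is
returned with all trajectories logged. Decoding is log-domain Viterbi under
posterior-mean parameters (inner loops numba-compiled, as is
forward–backward). Model order: the pipeline fits the selected K = 8 by
default; `scan_states` fits K ∈ {4, 6, 8, 10} and identifies the
sensorimotor-like state by spatial correlation of state means with a
template (the synthetic truth loading in tests and the pipeline).

**State metrics.** Per state, epoch and condition, over windows relative to
each trial's detected offset — post-movement 1–5 s, movement −4–0 s, rest
20–24 s (for 2-s trials the movement window reaches before the contraction;
this is reproduced as defined and flagged by the window metadata): fractional
occupancy; occurrences (visits whose *onset* falls in the window — a visit
belongs to the window containing its onset); mean lifetime of those visits,
unclipped at window edges (unbiased); mean interval between consecutive
in-window visits; and mean beta amplitude — the conventional beta envelope
masked by the binary state timecourse, the path sample-and-held up to the
envelope grid. Lifetimes/intervals with no qualifying visits are reported
absent (NaN), never zero. Metrics average over trials, then (if several)
sessions.

## Statistics

Paired two-sided Student's t (identical pairs degrade to p = 1 with a
warning), one-way repeated-measures ANOVA `F = MS_levels/MS_error` with
df (L−1, (L−1)(S−1)) — sphericity assumed by default, Greenhouse–Geisser
behind a flag — and Benjamini–Hochberg step-up FDR correction (via
statsmodels) applied per metric family. The pipeline, which analyses one
synthetic subject, forms within-"subject" tables by pairing trials across
conditions by within-condition rank — a pragmatic stand-in for the
across-subject pairing a cohort would provide, documented in the stats
output. Null calibration (5000-rep simulation) and the F = t² identity are
asserted in the acceptance tests.

## Pipeline, seeding and problem sizes

`run_pipeline` executes simulate → events → behaviour → beamformer →
spectral → fits → HMM → stats → report from one `PipelineConfig`. Every
random stage draws from a `SeedSequence` keyed by (master seed, stage
counter, item), so stages are independently reproducible; identical
config+seed produces identical output checksums, and re-running a completed
output directory is a checksum-gated no-op. The default analysis set is one
synthetic subject × two runs of 45 trials (the acquisition the paradigm
prescribes), 24 channels, 10 parcels, K = 8, 10 VB restarts — sizes chosen
so the full pipeline, including the HMM, completes in a few minutes on one
CPU while leaving every ordering contrast well-powered. The component
benchmarks in `scripts/acceptance.py` use 1e5 samples (HMM recovery), 50
noise seeds (curve fits), 20 sessions (localization) and 5000 replicates
(ANOVA calibration).

## Known limitations

- The generator's Weibull-shaped rate surplus makes generator and fit share
  a family; it validates the estimator, not the biological shape of real
  rebounds.
- Single-subject synthetic "cohorts": group-level inference is exercised
  with trial-rank pairing, not true between-subject variance.
- The envelope HMM is the amplitude-only variant; spectrally resolved or
  time-delay-embedded state models are out of scope.
- Free-energy comparisons are valid within a dataset only; the scan reports
  per-K free energies without a penalised model-selection rule.
- The orthonormal lead field makes localization easier than a realistic,
  highly correlated forward model would be.
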