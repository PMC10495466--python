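# Methods

This note documents the models, parameter choices and numerical decisions
behind `corticalstate`, in the order data flows through the pipeline.

## Trial epoch and tasks

A trial epoch is 1500 ms at 1000 Hz: 100 ms pre-cue, a 400 ms
cue-to-stimulus interval (the **pre-stimulus window** used for state
estimation is the 400 ms immediately before the first stimulus onset),
200 ms first stimulus (target), 200 ms delay, 200 ms second stimulus
(test; discrimination only) and a 400 ms response window. Detection
trials present one near-threshold stimulus; discrimination trials present
a target and a slightly rotated test grating. Each trial carries a task
label, a correct/incorrect outcome, and a reaction time on correct trials.

## Synthetic session generator

The generator produces sessions with a known latent state so that every
pipeline stage can be tested against ground truth. It is a statistical
emulator, not a biophysical model: no dipole/forward modelling, no
inter-trial temporal dynamics, no auditory cue response.

**Latent state.** For trial *t*, a global standard-normal latent g_t is
drawn; electrode *e*'s standardized latent is
z_te = √s·g_t + √(1−s)·ε_te with private noise ε, so each electrode's
log PR = μ + σ·z_te is marginally Normal(μ, σ²) and a fraction
`state_sharing = s` of its variance is shared. Defaults: σ = 0.8 (a
typical log-scale spread for band-power ratios) and μ = ln(10.62) − σ²/2,
so the log-normal mean PR is 10.62, matching the pooled mean reported for
this kind of temporal-lobe data. s = 0.14 was set by inverting the
bivariate-normal orthant probability: the correlation between z_e and the
mean of the other 49 electrodes' latents is ρ = s/√(s + (1−s)/49) ≈ 0.35,
and the probability that two median-split labels agree is
1/2 + arcsin(ρ)/π ≈ 0.61, the same-state probability the analysis should
recover. Trials are i.i.d. in session order, so the PR autocorrelation is
flat by construction.

**Traces.** Each electrode's background is
`background_rms_uv`·(√PR·L + H), where L and H are Gaussian noise
filtered into 2.5–12 Hz and 12–80 Hz by the *analysis pipeline's own*
band filters (generator and analysis agree on band definitions by
construction) and normalized to unit RMS in the pre-stimulus window. The
normalizer is floored at 60% of the epoch-wide RMS: the low band has only
~8 degrees of freedom in 400 ms, and dividing by an unluckily small
realized window RMS would otherwise scale entire trials up severalfold,
producing spurious high-amplitude trials. With the floor, the measured
log PR still tracks the latent at r ≈ 0.93 per electrode (r ≈ 0.99
without it), and the pooled measured PR mean stays within a few percent
of 10.62. The latent state scales the whole epoch, not only the
pre-stimulus window, so evoked-window coupling holds by construction.

**Outcomes.** P(correct) = logistic(logit(base) + c·g_t), with
detection c = +0.6 (base 0.64) and discrimination c = −0.7 (base 0.56).
The couplings were derived, before any acceptance checks were run, from
the performance splits such data show (≈58% vs ≈71% for detection,
≈65% vs ≈47% for discrimination): a median split on a logistic model
gives a split difference of roughly 1.6·σ′(logit(base))·c, and the
defaults land in that range while giving reliable single-session sign
recovery at 120 trials per task (the split difference is ≈2.3 binomial
standard errors at 60 trials per bin). Couplings with |c| > 5 are
rejected at configuration time as degenerate.

**Evoked responses.** Each stimulus window receives a Tukey-tapered
broad-band transient whose power is
P₀·exp(`evoked_gain`·z_te + `evoked_noise_sd`·η), with P₀ = 2000 µV²
(roughly twice the background window power), gain 0.3 and noise 0.9 —
yielding a per-electrode Pearson correlation between log PR and evoked
dB of ~0.4–0.5 once the state-coupled background adds its share. For
discrimination, the test transient's power is the target's times
10^((0.2·(−g_t) + 0.5·ν)/10): the (test − target) difference in dB
declines with the synchronized state at 0.2 dB per SD, giving a
low-vs-high state split of ≈ +0.1 / −0.1 dB. Reaction time on correct
trials is `rt_base` − `rt_slope`·sign(c)·g_t + noise (600 − 15·sign·g ±
150 ms), giving small negative PR-RT correlations for detection and
positive for discrimination; at the default slope a single session often
cannot resolve the sign — the tests that assert the sign use a steeper
slope explicitly.

**Artifacts.** `inject_artifacts` adds, on every electrode of a randomly
selected trial subset, a run of biphasic sharp waves: a square spike
train at 8 Hz with a 70% duty cycle and amplitude `amplitude_factor`
times the electrode's background SD. The waveform shape is load-bearing.
The rejection threshold TH = mean + 3·std of |x| is computed on the
contaminated signal and therefore *inflates with contamination*; a
sinusoidal burst's graded samples then straddle TH, whereas a two-level
waveform keeps its active samples clearly above it. Even so, at very
high contamination (e.g., every trial carrying a long burst) TH rises
toward the burst amplitude itself and the rule loses sensitivity — this
is a property of the published rule, not of the implementation, and the
test suite treats the brute-force recount of the rule as the oracle in
that regime. Ground-truth flags are stored per trial.

**Determinism.** One `numpy.random.Generator` seeded from `config.seed`
is threaded through all draws; identical configs give bit-identical
sessions. Voltages are stored float32 (µV); statistics are computed in
float64.

## Preprocessing

**Referencing.** Common-average reference over all non-ictal electrodes,
the referenced electrode included in the mean. In synthetic sessions all
electrodes not flagged by ground truth count as non-ictal; for real data
the caller supplies the list (clinically defined).

**Filters.** All filters are Chebyshev type II with 60 dB stopband
attenuation and cutoff (stopband-edge) frequencies 0.3 Hz outside the
nominal band: 2.2/12.3 Hz and 11.7/80.3 Hz for the two analysis bands,
59.4–60.6 Hz for the line-noise notch. A minimal-order design with a
0.6 Hz transition is attempted first; for the analysis bands that order
is impractically high (21 and 57 for a bandpass at 1000 Hz), so the
design falls back to a fixed order (8 for bandpass; the notch meets the
criterion at order 7) with the cutoffs kept at the stated stopband
edges, and the relaxation is recorded on the returned `FilterSpec` and
warned once. The fixed-order low-band filter passes 8 Hz at gain 0.9997
and attenuates ≥60 dB beyond the cutoffs.

**Zero-phase application.** Forward–backward filtering has net transfer
|H(f)|² and zero phase. The default implementation applies that squared
magnitude response in the frequency domain after odd (point-symmetric,
slope-preserving) reflection padding of ~0.7 epoch lengths, nudged so the
FFT length factorizes well. Odd reflection matters for short epochs: the
low-band filter rings for hundreds of milliseconds, and the boundary kink
of even reflection leaks measurable low-frequency energy into a
pre-stimulus window that starts 100 ms into the epoch (with even padding
a two-tone PR is biased ~10%; with odd padding the bias is <1%).
`sosfiltfilt` remains available via `method="sos"` and agrees on interior
samples; the FFT route is an order of magnitude faster on
trials×electrodes batches.

**Epileptiform trial rejection.** Per electrode and task,
TH = mean + 3·std of the absolute raw signal concatenated across trials
(moments of |x|, as the rule is stated); a trial is rejected when |x|
strictly exceeds TH for ≥5% of its samples (strict inequality so a
constant signal rejects nothing), and an electrode is excluded when
fewer than 50 clean trials survive in either task. For population
analyses, which need one common trial set, the pipeline drops trials
rejected on ≥50% of electrodes — epileptiform discharges are spatially
widespread, while isolated single-electrode exceedances are usually
large evoked responses; the full per-electrode report remains available.

**z-transform.** Per-channel z-scoring over all retained samples is
applied only when pooling channels into population statistics. PR is a
within-channel power ratio and is scale-invariant, so it is computed on
the unnormalized (referenced, notched) traces.

## Spectral estimation

Per-trial spectra use a DPSS multitaper estimator (time-bandwidth 3,
5 tapers) on the 400 ms window — standard settings for short ECoG
windows; spectrograms slide a 200 ms window in 50 ms steps. All settings
are keyword-exposed. Power is z-scored along the trial dimension at each
(electrode, frequency[, time]) point, so condition means obey
Σ_c n_c·mean_c = 0 exactly (mirror symmetry for two equal groups);
zero-variance grid points (judged relative to the mean, to absorb
floating-point rounding on identical trials) return 0 with a degeneracy
flag rather than NaN. PR itself is computed in the time domain as the
ratio of band-passed mean squared voltages — the FFT band-integration
appears only as an independent oracle in tests. The PR autocorrelation
uses the biased normalized estimator with mean removal; population
per-lag inference uses the one-sample Wilcoxon signed-rank against zero,
Bonferroni-corrected over the 20 default lags.

## State analyses

Median splits label a trial "high" when its PR strictly exceeds the
median (ties, measure-zero for continuous PR, go to "low"). The
population state for electrode e is the median split of the mean
min-max-normalized PR of the *other* electrodes; `global_labels` keeps
all electrodes. Note only the per-electrode labels are invariant under
arbitrary monotone PR transforms; the normalized population average is
invariant under affine maps only. The same-state probability's null
permutes the electrode's label sequence (≥1000 permutations); with
balanced labels its expectation is exactly 0.5. Performance-by-state
uses two median-split bins by default and "three equal-size bins" read
as equal-width over the PR range (equal-count offered as an option);
empty bins raise rather than merge. Between-bin differences use a
within-group bootstrap (default 10⁴ iterations, 10⁶ supported) with
(k+1)/(B+1)-smoothed two-sided p-values. The correct-vs-incorrect
contrast reports 100·(mean PR_c − mean PR_i)/mean PR_i per electrode on
raw PR (the incorrect-trial mean is the denominator) while the
population signed-rank tests operate on per-electrode mean log-PR
differences. Evoked power is the broad-band mean voltage-squared over
each 200 ms stimulus window in dB relative to the electrode's
session-mean pre-stimulus power — a fixed reference that cancels in
(test − target) differences. The quartile comparison ranks electrodes by
same-state probability with a stable sort and compares Q1 vs Q4 with the
unpaired rank-sum (the groups are disjoint electrode sets).

## Decoding

The Fisher discriminant w = S_w⁻¹(m₁ − m₀) is computed from the
within-class scatter with a ridge λI, λ = 10⁻³·trace(S_w)/d, added when
the training count is within 2 of the dimension or the condition number
exceeds 10⁸; classification thresholds the projection at the midpoint of
the projected class means (equal priors, since training draws are
balanced). Cross-validation is stratified 5-fold; subsampling draws
min(class counts) trials per class without replacement each iteration.
The empirical p-value is the fraction of iterations below 0.5. Features
default to the per-electrode log-PR vector; passing a single column
reproduces the single-site variant. Under a true null the mean CV
accuracy is 0.5 exactly in expectation, but one session's estimate
fluctuates with SD ≈ 0.025 at 200 trials because all iterations resample
the same finite trial set — chance-level checks therefore pool several
independent sessions.

## Statistical machinery

Wilcoxon signed-rank and rank-sum tests wrap scipy with explicit
sidedness and pairing; exact nulls are used for n < 25 (signed-rank,
no ties) and min(n) ≤ 10 (rank-sum; tied small samples fall back to full
permutation enumeration), otherwise the normal approximation with
continuity correction. Bonferroni correction is min(1, p·m). At n = 97
the one-sided signed-rank's type-I error calibrates to 0.05 ± 0.01 over
10⁴ null simulations.

## Test-suite problem sizes and what passing shows

Most unit tests run sessions of 4–12 electrodes and 60–120 trials;
replicate analyses use 100 sessions of 50 electrodes × 120 trials per
task, and chance-level checks pool 5–8 sessions — sizes chosen so the
full suite exercises the complete pipeline at single-desktop scale.
Artifact-equivalence fixtures use narrower state spread
(`logpr_sd = 0.4`) and subdued evoked variability so that injected
bursts are the only above-threshold events; with the default spread, a
few percent of clean trials on single electrodes exceed the amplitude
rule through ordinary heteroscedasticity, exactly as on real recordings.
Passing tests show the pipeline recovers the structure the generator put
in; they cannot certify behavior under features the generator omits —
1/f background shape, nonstationary states with temporal structure,
correlated line noise, or volume-conducted artifact topographies.
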