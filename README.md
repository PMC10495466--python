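# corticalstate

Analysis pipeline for studying how the **cortical state** of ongoing neural
population activity shapes perception, using trial-epoched intracranial
field potentials (ECoG). The package implements the full chain — synthetic
session generation, preprocessing, state estimation, state-conditioned
behavioral analysis, and trial-outcome decoding — for a two-task visual
paradigm (contrast **detection** vs orientation **discrimination**).

## The problem and the statistic

Neocortical population activity wanders along a continuum between
*synchronized* states (strong low-frequency fluctuations) and
*desynchronized* states (flatter spectra, relatively more high-frequency
power). The pipeline operationalizes the state of each trial by the
**power ratio**

&nbsp;&nbsp;&nbsp;&nbsp;PR = P(2.5–12 Hz) / P(12–80 Hz),

the mean voltage-squared power of the zero-phase band-passed trace in the
low over the high band, measured in the 400 ms window preceding the first
stimulus. PR is log-normal across trials, so statistics operate on log PR;
a trial is "high PR" (synchronized) when its PR exceeds the median across
trials. Downstream analyses ask, per electrode and per session:

- how strongly single recording sites share the population state
  (**same-state probability**, with a trial-shuffle null at 0.5);
- whether high-PR trials are answered correctly more often than low-PR
  trials (and how this reverses between detection and discrimination);
- how stimulus-evoked broad-band power and reaction times covary with the
  pre-stimulus state;
- whether the trial outcome can be decoded from the per-electrode log-PR
  vector with a cross-validated **Fisher linear discriminant** under
  balanced subsampling, with the empirical p-value given by the fraction
  of iterations below 50% accuracy.

Because the human recordings such analyses are built for cannot be
redistributed, the package ships a **synthetic session generator** whose
latent per-trial state reproduces the statistical structure the analysis
assumes: log-normal PR with a controllable fraction of variance shared
across electrodes, logistic state-outcome coupling of opposite sign for
the two tasks, state-coupled evoked transients, reaction-time coupling,
and optional epileptiform bursts for testing artifact rejection. Every
downstream stage is validated against this ground truth.

## Worked example

```bash
python analysis/01_simulate_session.py   # 50 electrodes x 120 trials/task
python analysis/02_preprocess_qc.py
python analysis/03_state_estimation.py
python analysis/04_state_and_behavior.py
python analysis/05_evoked_responses.py
python analysis/06_decode_outcome.py
```

On the default session (seed 7), `04_state_and_behavior.py` prints:

```
detection: same-state probability 0.599 +/- 0.007 (shuffle null 0.500)
  performance low/high PR: 46.7% / 65.0% (bootstrap p=0.0454)
  PR percent difference (correct-incorrect): +12.57 +/- 2.57% (one-sided p=3.01e-07)
discrimination: same-state probability 0.592 +/- 0.007 (shuffle null 0.500)
  performance low/high PR: 58.3% / 38.3% (bootstrap p=0.0306)
  PR percent difference (correct-incorrect): -20.28 +/- 1.97% (one-sided p=2.32e-09)
```

Individual electrodes share the population state on ~60% of trials
(chance 0.5), and the state-performance coupling reverses between tasks:
synchronized (high-PR) trials are answered better in detection and worse
in discrimination, with the correct-vs-incorrect PR contrast positive for
detection and negative for discrimination. `05_evoked_responses.py` shows
evoked power rising with pre-stimulus PR (mean Pearson r ≈ 0.43) and a
larger (test − target) evoked difference on desynchronized trials
(+0.12 dB vs −0.07 dB); `06_decode_outcome.py` decodes the discrimination
outcome at 59.3% (p = 0.006) while a zero-coupling control session stays
at chance. Expect session-to-session variability at this size — single
sessions are deliberately noisy.

The library surface mirrors the pipeline: `generate_session`,
`inject_artifacts`, `common_average_reference`, `remove_line_noise`,
`bandpass`, `detect_spiking_trials`, `compute_power_ratio`,
`zscored_spectrum`/`zscored_spectrogram`, `pr_autocorrelation`,
`label_states`, `same_state_probability`, `performance_by_state`,
`pr_outcome_contrast`, `evoked_analysis`, `rt_state_correlation`,
`quartile_comparison`, `flda_fit_predict`, `decode_outcome`, plus the
Wilcoxon/bootstrap machinery in `corticalstate.stats`. See
`docs/methods.md` for models, parameters and numerical choices.

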