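"""Synthetic multi-electrode trial-epoched session generator.

The generator produces sessions with a controllable latent cortical state so
that every downstream stage of the pipeline can be checked against ground
truth. The statistical structure it emulates:

* trial-wise pre-stimulus power ratio (PR) is log-normal, with a fraction
  ``state_sharing`` of the log-PR variance shared across electrodes through
  a single global latent per trial (this controls the same-state
  probability between an electrode and the rest of the population);
* trial outcome is Bernoulli with a logistic dependence on the standardized
  global latent, with opposite-sign couplings for the detection and
  discrimination tasks;
* stimulus-evoked broad-band power increases log-linearly with the latent
  state, and the (test - target) evoked difference in dB decreases with it;
* reaction time on correct trials is linear in the latent with a
  task-dependent sign;
* optional epileptiform high-amplitude bursts for rejection testing.

Trials are i.i.d. across the session (the measured PR autocorrelation is
flat) and every draw flows from a single seeded generator, so identical
configs give bit-identical sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal.windows import tukey

from .preprocess import HIGH_BAND, LOW_BAND, design_filter, zero_phase_filter
from .session import DETECTION, DISCRIMINATION, EpochLayout, SessionData

__all__ = ["GeneratorConfig", "generate_session", "inject_artifacts", "draw_latents"]

#: session-pooled mean power ratio the defaults aim for (lognormal mean
#: exp(mu + sigma^2/2) with sigma = 0.8)
DEFAULT_PR_MEAN = 10.62
DEFAULT_LOGPR_SD = 0.8


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic session generator.

    The defaults describe a single recording session of the two-task
    experiment: 50 temporal electrodes, 120 trials per task at 1000 Hz,
    log-normal trial state calibrated to a pooled mean PR of ~10.6, enough
    state sharing for a same-state probability near 0.61, and opposite-sign
    state-outcome couplings (synchronized state helps detection, hurts
    discrimination).
    """

    n_electrodes: int = 50
    n_trials: int = 120  # per task
    fs: float = 1000.0
    epoch: EpochLayout = field(default_factory=EpochLayout)
    tasks: tuple = (DETECTION, DISCRIMINATION)

    # latent log-PR distribution (natural-log scale)
    logpr_mean: float = math.log(DEFAULT_PR_MEAN) - DEFAULT_LOGPR_SD**2 / 2
    logpr_sd: float = DEFAULT_LOGPR_SD
    state_sharing: float = 0.14  # shared fraction of log-PR variance

    # outcome model: P(correct) = logistic(logit(base_rate) + coupling * g)
    detection_coupling: float = 0.6
    discrimination_coupling: float = -0.7
    detection_base_rate: float = 0.64
    discrimination_base_rate: float = 0.56

    # evoked-response model (dB / natural-log couplings to the latent state)
    evoked_gain: float = 0.3
    evoked_noise_sd: float = 0.9
    evoked_base_power_uv2: float = 2000.0
    testminus_target_slope_db: float = 0.2
    test_target_noise_db: float = 0.5

    # reaction-time model (correct trials only)
    rt_base_ms: float = 600.0
    rt_slope_ms: float = 15.0
    rt_noise_ms: float = 150.0

    background_rms_uv: float = 10.0  # high-band component RMS in the window

    # epileptiform burst injection
    artifact_rate: float = 0.0
    artifact_amplitude_factor: float = 6.0
    artifact_duration_frac: float = 0.10
    artifact_freq_hz: float = 8.0

    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.state_sharing <= 1.0:
            raise ValueError("state_sharing must lie in [0, 1]")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must lie in [0, 1)")
        if self.fs <= 2 * HIGH_BAND[1]:
            raise ValueError(f"fs must exceed 2 x {HIGH_BAND[1]} Hz")
        if self.n_electrodes < 1 or self.n_trials < 1:
            raise ValueError("n_electrodes and n_trials must be positive")
        if self.logpr_sd <= 0:
            raise ValueError("logpr_sd must be > 0")
        for name in ("detection_base_rate", "discrimination_base_rate"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("detection_coupling", "discrimination_coupling"):
            c = getattr(self, name)
            # at |g| = 3 the logistic argument should stay in a sane range;
            # larger couplings signal misconfiguration, not a stronger effect
            if abs(c) > 5.0:
                raise ValueError(f"|{name}| > 5 drives outcome probabilities degenerate")
        if self.rt_noise_ms <= 0 or self.rt_base_ms <= 0:
            raise ValueError("reaction-time parameters must be positive")

    def base_rate(self, task: str) -> float:
        return (
            self.detection_base_rate if task == DETECTION else self.discrimination_base_rate
        )

    def coupling(self, task: str) -> float:
        return (
            self.detection_coupling if task == DETECTION else self.discrimination_coupling
        )


def draw_latents(config: GeneratorConfig, rng: np.random.Generator, n_trials: int):
    """Draw the per-trial latent state structure.

    Returns ``(g, z, log_pr)`` where ``g`` (n_trials,) is the standardized
    global latent, ``z`` (n_trials, n_electrodes) the standardized
    per-electrode latents with ``corr(z_e, g) = sqrt(state_sharing)``, and
    ``log_pr = logpr_mean + logpr_sd * z``. Marginally each electrode's
    log-PR is Normal(logpr_mean, logpr_sd^2).
    """
    s = config.state_sharing
    g = rng.standard_normal(n_trials)
    eps = rng.standard_normal((n_trials, config.n_electrodes))
    z = math.sqrt(s) * g[:, None] + math.sqrt(1.0 - s) * eps
    log_pr = config.logpr_mean + config.logpr_sd * z
    return g, z, log_pr


def _band_component(white: np.ndarray, band, fs: float, window: slice) -> np.ndarray:
    """Filter white noise into a band and normalize toward unit RMS in ``window``.

    The normalizer is the realized window RMS floored at 60% of the
    epoch-wide RMS. The low band has only ~8 degrees of freedom in 400 ms,
    so dividing by the raw window RMS would occasionally scale the whole
    trial up severalfold, producing spurious high-amplitude trials; the
    floor bounds the amplification at ~1.7x while leaving the window power
    exact for the vast majority of draws.
    """
    comp = zero_phase_filter(white, design_filter("bandpass", band, fs))
    w = np.sqrt((comp[..., window] ** 2).mean(axis=-1, keepdims=True))
    u = np.sqrt((comp**2).mean(axis=-1, keepdims=True))
    return comp / np.maximum(w, 0.6 * u)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_session(config: GeneratorConfig) -> SessionData:
    """Generate a full synthetic session (all tasks, traces, behavior).

    Each electrode's background is a mixture of 2.5-12 Hz and 12-80 Hz
    band-limited Gaussian noise, produced with the analysis pipeline's own
    band filters and mixed so that the low/high power ratio in the
    pre-stimulus window matches the trial's latent PR. The latent state
    applies to the whole epoch, so evoked-window coupling holds by
    construction. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    epoch = config.epoch
    n_samp = epoch.n_samples(fs)
    markers = epoch.markers(fs)
    prestim = slice(markers["stim1_on"] - int(round(400 * fs / 1000)), markers["stim1_on"])

    blocks = []
    for task in config.tasks:
        n = config.n_trials
        g, z, log_pr = draw_latents(config, rng, n)
        pr = np.exp(log_pr)

        # background: state-mixed band-limited noise
        white_lo = rng.standard_normal((n, config.n_electrodes, n_samp), dtype=np.float32)
        white_hi = rng.standard_normal((n, config.n_electrodes, n_samp), dtype=np.float32)
        low = _band_component(white_lo, LOW_BAND, fs, prestim)
        high = _band_component(white_hi, HIGH_BAND, fs, prestim)
        volts = config.background_rms_uv * (
            np.sqrt(pr)[:, :, None].astype(np.float32) * low + high
        )
        del white_lo, white_hi, low, high

        # stimulus-evoked broad-band transients
        eta = rng.standard_normal((n, config.n_electrodes))
        log_p1 = (
            math.log(config.evoked_base_power_uv2)
            + config.evoked_gain * z
            + config.evoked_noise_sd * eta
        )
        _add_transient(volts, rng, markers["stim1_on"], markers["stim1_off"], np.exp(log_p1))
        if task == DISCRIMINATION:
            nu = rng.standard_normal(n)
            diff_db = config.testminus_target_slope_db * (-g) + config.test_target_noise_db * nu
            p2 = np.exp(log_p1) * 10.0 ** (diff_db[:, None] / 10.0)
            _add_transient(volts, rng, markers["stim2_on"], markers["stim2_off"], p2)

        # behavior
        b = math.log(config.base_rate(task) / (1 - config.base_rate(task)))
        p_correct = _logistic(b + config.coupling(task) * g)
        outcome = rng.random(n) < p_correct
        sign = 1.0 if config.coupling(task) >= 0 else -1.0
        rt = (
            config.rt_base_ms
            - config.rt_slope_ms * sign * g
            + config.rt_noise_ms * rng.standard_normal(n)
        )
        rt = np.maximum(rt, 150.0)
        rt[~outcome] = np.nan

        blocks.append(
            dict(volts=volts, task=task, outcome=outcome, rt=rt, g=g, log_pr=log_pr)
        )

    session = SessionData(
        voltages=np.concatenate([b["volts"] for b in blocks], axis=0),
        fs=fs,
        task=np.concatenate(
            [np.full(config.n_trials, b["task"], dtype=object) for b in blocks]
        ),
        outcome=np.concatenate([b["outcome"] for b in blocks]),
        reaction_time_ms=np.concatenate([b["rt"] for b in blocks]),
        markers=markers,
        ground_truth={
            "log_pr": np.concatenate([b["log_pr"] for b in blocks], axis=0),
            "global_latent": np.concatenate([b["g"] for b in blocks]),
            "artifact": np.zeros(len(config.tasks) * config.n_trials, dtype=bool),
        },
    )
    if config.artifact_rate > 0:
        session = inject_artifacts(
            session,
            rate=config.artifact_rate,
            amplitude_factor=config.artifact_amplitude_factor,
            duration_frac=config.artifact_duration_frac,
            burst_freq_hz=config.artifact_freq_hz,
            seed=rng,
        )
    return session


def _add_transient(volts, rng, on, off, power_uv2):
    """Add a tapered broad-band transient with exact mean-square power."""
    n, n_el = power_uv2.shape
    width = off - on
    taper = tukey(width, 0.25).astype(np.float32)
    seg = rng.standard_normal((n, n_el, width)).astype(np.float32) * taper
    ms = (seg**2).mean(axis=-1, keepdims=True)
    seg *= np.sqrt(power_uv2[:, :, None] / ms).astype(np.float32)
    volts[:, :, on:off] += seg


def inject_artifacts(
    session: SessionData,
    rate: float,
    amplitude_factor: float = 6.0,
    duration_frac: float = 0.10,
    burst_freq_hz: float = 8.0,
    seed=None,
) -> SessionData:
    """Return a copy of the session with epileptiform bursts on random trials.

    Each selected trial receives, on every electrode, an additive run of
    biphasic sharp waves: a square spike train at ``burst_freq_hz`` with a
    70% duty cycle, whose amplitude is ``amplitude_factor`` times that
    electrode's background standard deviation, lasting ``duration_frac`` of
    the trial. The duty cycle matters: the rejection threshold
    (mean + 3*std of |x|) inflates with contamination, and a waveform whose
    samples are either at full amplitude or near zero keeps the active
    samples above the inflated threshold even when every trial carries a
    burst, while a sinusoid's graded samples would straddle it.

    Flags are recorded in ``ground_truth['artifact']``.
    """
    if amplitude_factor <= 3.0:
        raise ValueError("amplitude_factor must exceed the 3*std rejection rule")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if not 0.0 < duration_frac < 1.0:
        raise ValueError("duration_frac must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    volts = np.array(session.voltages, copy=True)
    n_trials, n_el, n_samp = volts.shape
    flagged = rng.random(n_trials) < rate
    if flagged.any():
        width = int(round(duration_frac * n_samp))
        bg_std = volts.std(axis=(0, 2))  # per-electrode background scale
        t = np.arange(width) / session.fs
        duty = 0.7
        gate_level = np.cos(duty * np.pi / 2)  # |sin| above this <=> active
        for tr in np.flatnonzero(flagged):
            start = int(rng.integers(0, n_samp - width + 1))
            phase = rng.uniform(0, 2 * np.pi)
            carrier = np.sin(2 * np.pi * burst_freq_hz * t + phase)
            wave = np.sign(carrier) * (np.abs(carrier) >= gate_level)
            burst = (amplitude_factor * bg_std)[:, None] * wave[None, :]
            volts[tr, :, start : start + width] += burst.astype(volts.dtype)
    gt = dict(session.ground_truth or {})
    prev = gt.get("artifact", np.zeros(n_trials, dtype=bool))
    gt["artifact"] = np.asarray(prev, dtype=bool) | flagged
    return replace(session, voltages=volts, ground_truth=gt)
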