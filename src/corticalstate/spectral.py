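"""Power-ratio computation, multitaper spectra/spectrograms, and PR autocorrelation.

The power ratio (PR) — mean voltage-squared power in the 2.5-12 Hz band
divided by that in the 12-80 Hz band over the 400 ms pre-stimulus window —
is the scalar summary of cortical state used throughout the pipeline. High
PR marks the synchronized state, low PR the desynchronized state. PR values
are log-normal across trials, so statistics downstream operate on log PR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

from .preprocess import HIGH_BAND, LOW_BAND, design_filter, zero_phase_filter
from .session import SessionData
from .stats import TestResult, wilcoxon_signed_rank

__all__ = [
    "PowerRatioTable",
    "SpectralEstimate",
    "compute_power_ratio",
    "multitaper_psd",
    "zscored_spectrum",
    "zscored_spectrogram",
    "pr_autocorrelation",
]

DEFAULT_WINDOW_MS = (-400.0, 0.0)


@dataclass
class PowerRatioTable:
    """Trials x electrodes pre-stimulus power ratios.

    ``pr`` holds the raw ratio (positive), ``log_pr`` its natural log.
    ``valid`` flags trials whose high-band power was numerically nonzero.
    """

    pr: np.ndarray
    window_ms: tuple
    low_band: tuple = LOW_BAND
    high_band: tuple = HIGH_BAND
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.pr = np.asarray(self.pr, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.pr) & (self.pr > 0)

    @property
    def log_pr(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log(self.pr)

    @property
    def n_trials(self) -> int:
        return self.pr.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.pr.shape[1]

    def population_mean_normalized(self, exclude: int | None = None) -> np.ndarray:
        """Across-electrode mean of min-max normalized PR per trial.

        ``exclude`` drops one electrode (leave-one-out population state).
        """
        rng_ = self.pr.max(axis=0) - self.pr.min(axis=0)
        rng_ = np.where(rng_ == 0, 1.0, rng_)
        norm = (self.pr - self.pr.min(axis=0)) / rng_
        if exclude is not None:
            keep = np.arange(self.n_electrodes) != exclude
            norm = norm[:, keep]
        return norm.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        t, e = np.meshgrid(
            np.arange(self.n_trials), np.arange(self.n_electrodes), indexing="ij"
        )
        return pd.DataFrame(
            {
                "trial": t.ravel(),
                "electrode": e.ravel(),
                "pr": self.pr.ravel(),
                "log_pr": self.log_pr.ravel(),
            }
        )


def compute_power_ratio(
    session: SessionData,
    window_ms: tuple = DEFAULT_WINDOW_MS,
    low_band: tuple = LOW_BAND,
    high_band: tuple = HIGH_BAND,
) -> PowerRatioTable:
    """Compute the pre-stimulus power ratio per trial and electrode.

    Each band's power is the mean voltage-squared of the zero-phase
    band-passed trace within ``window_ms`` (relative to the first stimulus
    onset); PR is their ratio. Trials with numerically zero high-band power
    are flagged invalid (PR = NaN) rather than propagated.
    """
    win = session.prestim_slice(window_ms)
    v = session.voltages
    fs = session.fs
    lo = zero_phase_filter(v, design_filter("bandpass", tuple(low_band), fs))
    hi = zero_phase_filter(v, design_filter("bandpass", tuple(high_band), fs))
    p_lo = (np.asarray(lo[..., win], dtype=np.float64) ** 2).mean(axis=-1)
    p_hi = (np.asarray(hi[..., win], dtype=np.float64) ** 2).mean(axis=-1)
    tiny = np.finfo(np.float64).tiny
    valid = p_hi > tiny * 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        pr = np.where(valid, p_lo / np.where(valid, p_hi, 1.0), np.nan)
    return PowerRatioTable(pr=pr, window_ms=tuple(window_ms), low_band=tuple(low_band),
                           high_band=tuple(high_band), valid=valid)


@dataclass
class SpectralEstimate:
    """Per-condition mean z-scored power on a frequency (x time) grid.

    ``condition_means`` maps condition label -> array of shape
    (n_electrodes, n_freqs) for spectra or (n_electrodes, n_times, n_freqs)
    for spectrograms. ``degenerate`` flags grid points with zero variance
    across trials (their z-scores are defined as 0).
    """

    freqs: np.ndarray
    condition_means: dict
    condition_counts: dict
    degenerate: np.ndarray
    times_ms: np.ndarray | None = None
    zscores: np.ndarray | None = field(default=None, repr=False)


def multitaper_psd(x: np.ndarray, fs: float, nw: float = 3.0, n_tapers: int = 5):
    """DPSS multitaper power spectral density along the last axis.

    Averages ``n_tapers`` Slepian-tapered periodograms (time-bandwidth
    product ``nw``) — the standard estimator for short trial windows.
    Returns ``(freqs, psd)`` with psd in units^2/Hz.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    tapers = dpss(n, nw, Kmax=n_tapers)  # (K, n), unit energy
    xt = x[..., None, :] * tapers  # (..., K, n)
    spec = np.fft.rfft(xt, axis=-1)
    psd = (spec.real**2 + spec.imag**2).mean(axis=-2) / fs
    # one-sided correction (all bins except DC and Nyquist appear twice)
    psd[..., 1:] *= 2.0
    if n % 2 == 0:
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, psd


def _zscore_trials(power: np.ndarray):
    """z-score along the trial axis (axis 0); zero-variance points -> 0.

    Variance is judged relative to the mean so that identical trials whose
    moments differ only by floating rounding still count as degenerate.
    """
    mean = power.mean(axis=0, keepdims=True)
    sd = power.std(axis=0, keepdims=True)
    degenerate = sd <= 1e-10 * (np.abs(mean) + np.finfo(power.dtype).tiny)
    z = (power - mean) / np.where(degenerate, 1.0, sd)
    z[np.broadcast_to(degenerate, z.shape)] = 0.0
    return z, degenerate[0]


def zscored_spectrum(
    session: SessionData,
    condition_labels,
    window_ms: tuple = DEFAULT_WINDOW_MS,
    fmax: float = 100.0,
    nw: float = 3.0,
    n_tapers: int = 5,
) -> SpectralEstimate:
    """Per-condition mean of trial-z-scored multitaper spectra.

    The per-trial spectrum is z-scored across all trials at each
    (electrode, frequency) point, so condition means obey the weighted-sum
    identity sum_c n_c * mean_c(f) = 0 — with two equal-sized conditions the
    means are mirror images.
    """
    labels = np.asarray(condition_labels)
    if labels.shape[0] != session.n_trials:
        raise ValueError("condition_labels must have one entry per trial")
    win = session.prestim_slice(window_ms)
    freqs, psd = multitaper_psd(
        np.asarray(session.voltages[..., win], dtype=np.float64), session.fs, nw, n_tapers
    )
    keep = freqs <= fmax
    freqs, psd = freqs[keep], psd[..., keep]
    z, degenerate = _zscore_trials(psd)
    means, counts = {}, {}
    for c in np.unique(labels):
        sel = labels == c
        if sel.sum() < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 trials")
        means[c] = z[sel].mean(axis=0)
        counts[c] = int(sel.sum())
    return SpectralEstimate(
        freqs=freqs,
        condition_means=means,
        condition_counts=counts,
        degenerate=degenerate,
        zscores=z,
    )


def zscored_spectrogram(
    session: SessionData,
    condition_labels,
    window_ms: float = 200.0,
    step_ms: float = 50.0,
    fmax: float = 100.0,
    nw: float = 3.0,
    n_tapers: int = 5,
) -> SpectralEstimate:
    """Sliding-window variant of :func:`zscored_spectrum` over the epoch.

    Each (time, frequency) point is z-scored along the trial dimension.
    Window centers are reported in ms relative to the first stimulus onset.
    """
    labels = np.asarray(condition_labels)
    fs = session.fs
    nwin = int(round(window_ms * fs / 1000.0))
    step = int(round(step_ms * fs / 1000.0))
    n = session.n_samples
    starts = np.arange(0, n - nwin + 1, step)
    v = np.asarray(session.voltages, dtype=np.float64)
    segs = np.stack([v[..., s : s + nwin] for s in starts], axis=2)
    freqs, psd = multitaper_psd(segs, fs, nw, n_tapers)  # (T, E, nt, F)
    keep = freqs <= fmax
    freqs, psd = freqs[keep], psd[..., keep]
    z, degenerate = _zscore_trials(psd)
    means, counts = {}, {}
    for c in np.unique(labels):
        sel = labels == c
        if sel.sum() < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 trials")
        means[c] = z[sel].mean(axis=0)
        counts[c] = int(sel.sum())
    centers = (starts + nwin / 2) / fs * 1000.0 - session.markers["stim1_on"] / fs * 1000.0
    return SpectralEstimate(
        freqs=freqs,
        condition_means=means,
        condition_counts=counts,
        degenerate=degenerate,
        times_ms=centers,
        zscores=z,
    )


def _acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized autocorrelation of a 1-D series at lags 0..max_lag."""
    x = np.asarray(x, dtype=float)
    d = x - x.mean()
    denom = np.dot(d, d)
    if denom == 0:
        raise ValueError("constant series: autocorrelation undefined")
    return np.array([np.dot(d[: len(d) - k], d[k:]) / denom for k in range(max_lag + 1)])


def pr_autocorrelation(
    pr: np.ndarray, max_lag: int = 20, alpha: float = 0.05
) -> pd.DataFrame:
    """Trial-order autocorrelation of PR per electrode with population tests.

    ``pr`` is (n_trials, n_electrodes) in trial order. For each lag
    1..max_lag, per-electrode coefficients are tested against zero
    (one-sample Wilcoxon signed-rank, two-sided) with Bonferroni correction
    over the ``max_lag`` lags. Returns a tidy frame with the mean
    coefficient, raw and corrected p per lag (lag 0 is 1 by definition and
    untested).
    """
    pr = np.atleast_2d(np.asarray(pr, dtype=float))
    if pr.ndim == 2 and pr.shape[0] < pr.shape[1] and pr.shape[0] < max_lag + 10:
        raise ValueError("need at least max_lag + 10 trials")
    n_trials, n_el = pr.shape
    if n_trials < max_lag + 10:
        raise ValueError("need at least max_lag + 10 trials")
    coefs = np.stack([_acf(pr[:, e], max_lag) for e in range(n_el)], axis=1)
    rows = [dict(lag=0, mean_acf=1.0, pvalue=np.nan, pvalue_corrected=np.nan,
                 significant=False)]
    for k in range(1, max_lag + 1):
        if n_el >= 6:
            res: TestResult = wilcoxon_signed_rank(coefs[k], sidedness="two")
            p = res.pvalue
        else:
            p = np.nan
        rows.append(dict(lag=k, mean_acf=float(coefs[k].mean()), pvalue=p,
                         pvalue_corrected=min(1.0, p * max_lag) if np.isfinite(p) else np.nan,
                         significant=bool(np.isfinite(p) and p * max_lag < alpha)))
    return pd.DataFrame(rows)
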