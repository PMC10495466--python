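"""Core containers for trial-epoched multi-electrode recordings."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EpochLayout", "SessionData", "DETECTION", "DISCRIMINATION"]

DETECTION = "detection"
DISCRIMINATION = "discrimination"


@dataclass(frozen=True)
class EpochLayout:
    """Durations (ms) of the consecutive windows making up one trial epoch.

    The trial runs pre-cue silence, a 400 ms cue-to-stimulus (pre-stimulus)
    interval, a 200 ms first stimulus (target), a 200 ms delay, a 200 ms
    second stimulus (test; discrimination task only), and a response window.
    The pre-stimulus window used for cortical-state estimation is the 400 ms
    immediately preceding the first stimulus onset.
    """

    pre_cue_ms: float = 100.0
    pre_stim_ms: float = 400.0
    stim_ms: float = 200.0
    delay_ms: float = 200.0
    test_ms: float = 200.0
    response_ms: float = 400.0

    def __post_init__(self):
        for name in (
            "pre_cue_ms",
            "pre_stim_ms",
            "stim_ms",
            "delay_ms",
            "test_ms",
            "response_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def total_ms(self) -> float:
        return (
            self.pre_cue_ms
            + self.pre_stim_ms
            + self.stim_ms
            + self.delay_ms
            + self.test_ms
            + self.response_ms
        )

    def n_samples(self, fs: float) -> int:
        return int(round(self.total_ms * fs / 1000.0))

    def markers(self, fs: float) -> dict[str, int]:
        """Sample indices of the trial events (monotone within the epoch)."""
        ms = np.cumsum(
            [
                self.pre_cue_ms,
                self.pre_stim_ms,
                self.stim_ms,
                self.delay_ms,
                self.test_ms,
            ]
        )
        idx = [int(round(m * fs / 1000.0)) for m in ms]
        return {
            "cue": int(round(self.pre_cue_ms * fs / 1000.0)),
            "stim1_on": idx[1],
            "stim1_off": idx[2],
            "stim2_on": idx[3],
            "stim2_off": idx[4],
        }


@dataclass
class SessionData:
    """Trial-epoched multi-electrode voltage data with behavioral metadata.

    Attributes
    ----------
    voltages : ndarray, shape (n_trials, n_electrodes, n_samples)
        Voltage traces in microvolts (float32).
    fs : float
        Sampling rate in Hz.
    task : ndarray of str, shape (n_trials,)
        ``"detection"`` or ``"discrimination"`` per trial.
    outcome : ndarray of bool, shape (n_trials,)
        True for correct trials.
    reaction_time_ms : ndarray of float, shape (n_trials,)
        Reaction time for correct (responded) trials; NaN otherwise.
    markers : dict
        Sample indices of cue, stim1_on/off, stim2_on/off (shared layout).
    ground_truth : dict or None
        Synthetic sessions only: ``log_pr`` (trials x electrodes latent
        log power ratio), ``global_latent`` (trials,), ``artifact``
        (trials,) bool flags.
    """

    voltages: np.ndarray
    fs: float
    task: np.ndarray
    outcome: np.ndarray
    reaction_time_ms: np.ndarray
    markers: dict
    ground_truth: dict | None = None

    def __post_init__(self):
        v = self.voltages
        if v.ndim != 3:
            raise ValueError("voltages must be (n_trials, n_electrodes, n_samples)")
        n = v.shape[0]
        for name in ("task", "outcome", "reaction_time_ms"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must equal n_trials")
        m = self.markers
        order = [m["cue"], m["stim1_on"], m["stim1_off"], m["stim2_on"], m["stim2_off"]]
        if any(b <= a for a, b in zip(order, order[1:])):
            raise ValueError("markers must be strictly increasing within the epoch")
        if m["stim2_off"] > v.shape[2]:
            raise ValueError("markers exceed epoch length")
        rt_on_incorrect = np.isfinite(self.reaction_time_ms) & ~np.asarray(self.outcome)
        if np.any(rt_on_incorrect):
            raise ValueError("reaction time must be NaN for incorrect trials")

    @property
    def n_trials(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.voltages.shape[1]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[2]

    def task_index(self, task: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.task) == task)

    def prestim_slice(self, window_ms: tuple[float, float] = (-400.0, 0.0)) -> slice:
        """Sample slice for a window given in ms relative to stim1 onset."""
        on = self.markers["stim1_on"]
        a = on + int(round(window_ms[0] * self.fs / 1000.0))
        b = on + int(round(window_ms[1] * self.fs / 1000.0))
        if a < 0 or b > self.n_samples or a >= b:
            raise ValueError(f"window {window_ms} ms does not fit inside the epoch")
        return slice(a, b)

    def with_voltages(self, voltages: np.ndarray) -> "SessionData":
        """Copy of the session with replaced voltage array (metadata shared)."""
        return replace(self, voltages=voltages)

    def subset_trials(self, idx: np.ndarray) -> "SessionData":
        gt = None
        if self.ground_truth is not None:
            gt = {
                k: (np.asarray(v)[idx] if np.ndim(v) >= 1 else v)
                for k, v in self.ground_truth.items()
            }
        return SessionData(
            voltages=self.voltages[idx],
            fs=self.fs,
            task=np.asarray(self.task)[idx],
            outcome=np.asarray(self.outcome)[idx],
            reaction_time_ms=np.asarray(self.reaction_time_ms)[idx],
            markers=dict(self.markers),
            ground_truth=gt,
        )
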