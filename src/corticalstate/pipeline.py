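"""End-to-end recipes combining the pipeline stages.

These are the entry points the analysis drivers and the acceptance checks
use: preprocess a session, compute state tables per task, and summarize the
task-dependent state-behavior relationships of a single session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import detect_spiking_trials, preprocess_session
from .session import DETECTION, DISCRIMINATION, SessionData
from .spectral import PowerRatioTable, compute_power_ratio
from .state import (
    StateLabelTable,
    label_states,
    performance_by_state,
    pr_outcome_contrast,
)

__all__ = ["TaskStateTables", "prepare_task", "session_sign_pattern"]


@dataclass
class TaskStateTables:
    """Per-task cleaned session with its PR and state-label tables."""

    task: str
    session: SessionData
    pr_table: PowerRatioTable
    labels: StateLabelTable
    clean_trials: np.ndarray  # indices into the original session


def prepare_task(
    session: SessionData,
    task: str,
    notch: bool = True,
    reject: bool = True,
    reject_electrode_fraction: float = 0.5,
) -> TaskStateTables:
    """Run the standard pipeline for one task of a session.

    Epileptiform trial rejection operates on the raw traces; the surviving
    trials are re-referenced to the non-ictal common average, notch
    filtered, and summarized into the power-ratio and state-label tables.
    Population analyses need one common trial set, so a trial is dropped
    when at least ``reject_electrode_fraction`` of the electrodes reject it
    (epileptiform discharges are spatially widespread, while an isolated
    single-electrode exceedance is usually a large evoked response); the
    per-electrode rejection sets remain available via
    :func:`corticalstate.detect_spiking_trials`.
    """
    idx = session.task_index(task)
    if reject:
        report = detect_spiking_trials(session, task)
        bad = report.rejected.mean(axis=1) >= reject_electrode_fraction
        idx = idx[~bad]
    sub = session.subset_trials(idx)
    pre = preprocess_session(sub, notch=notch)
    pr = compute_power_ratio(pre)
    return TaskStateTables(
        task=task, session=pre, pr_table=pr, labels=label_states(pr), clean_trials=idx
    )


def session_sign_pattern(
    session: SessionData, n_bootstrap: int = 200, seed=None, notch: bool = False
) -> dict:
    """Qualitative state-behavior signature of one two-task session.

    Returns the four signs the task-dependence result rests on: whether
    high-PR trials outperform low-PR trials in detection, whether low-PR
    trials outperform high-PR trials in discrimination, and whether the
    correct-vs-incorrect PR percent difference is positive for detection
    and negative for discrimination. Splits use the global population state
    label (the session-average PR against its median).
    """
    out = {}
    for task, direction in ((DETECTION, "positive"), (DISCRIMINATION, "negative")):
        tables = prepare_task(session, task, notch=notch)
        outcomes = np.asarray(tables.session.outcome, dtype=bool)
        perf = performance_by_state(
            tables.labels.global_labels, outcomes, n_bins=2,
            n_bootstrap=n_bootstrap, seed=seed,
        )
        contrast = pr_outcome_contrast(tables.pr_table, outcomes, direction=direction)
        median_pct = float(np.nanmedian(contrast.percent_difference))
        high_minus_low = float(perf.percent_correct[1] - perf.percent_correct[0])
        out[task] = {
            "high_minus_low_percent": high_minus_low,
            "median_percent_difference": median_pct,
        }
    out["signs_match"] = bool(
        out[DETECTION]["high_minus_low_percent"] > 0
        and out[DISCRIMINATION]["high_minus_low_percent"] < 0
        and out[DETECTION]["median_percent_difference"] > 0
        and out[DISCRIMINATION]["median_percent_difference"] < 0
    )
    return out
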