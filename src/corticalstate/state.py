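"""State labelling, same-state probability, state-conditioned behavior, and
evoked-response analyses.

Trials are labelled "low" or "high" state by a median split of the
pre-stimulus power ratio — per electrode, and at the population level from
the across-electrode mean of min-max-normalized PR (leaving out the
electrode under study). The same-state probability is the fraction of
trials in which an electrode's label matches the rest-of-population label;
its chance level, obtained by shuffling the electrode's trial labels, is
0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import DETECTION, SessionData
from .spectral import PowerRatioTable
from .stats import (
    BootstrapResult,
    TestResult,
    bootstrap_diff,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)

__all__ = [
    "StateLabelTable",
    "EvokedTable",
    "label_states",
    "same_state_probability",
    "performance_by_state",
    "pr_outcome_contrast",
    "evoked_analysis",
    "rt_state_correlation",
    "quartile_comparison",
]


@dataclass
class StateLabelTable:
    """Binary low/high state labels from median splits of PR.

    ``electrode_labels[t, e]`` is True when trial t's PR at electrode e is
    strictly above that electrode's median. ``population_labels[t, e]`` is
    the label of the rest of the population (all electrodes but e) from the
    median split of their mean normalized PR. ``global_labels[t]`` uses all
    electrodes. Median splits are invariant under monotone transforms of PR.
    """

    electrode_labels: np.ndarray
    population_labels: np.ndarray
    global_labels: np.ndarray
    normalized_pr: np.ndarray
    degenerate: np.ndarray  # per-electrode flag: all-equal PR

    @property
    def n_trials(self) -> int:
        return self.electrode_labels.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.electrode_labels.shape[1]


def _median_split(x: np.ndarray) -> np.ndarray:
    """High iff strictly above the median (ties -> low)."""
    return x > np.median(x, axis=0, keepdims=True)


def label_states(pr_table: PowerRatioTable) -> StateLabelTable:
    """Median-split state labels per electrode and for the population.

    The population label for electrode e is computed from the mean
    min-max-normalized PR of all *other* electrodes (leave-one-out), as when
    asking whether e shares the population's state; ``global_labels`` keeps
    every electrode in the average.
    """
    pr = pr_table.pr
    if pr.shape[0] < 2:
        raise ValueError("need at least 2 trials for a median split")
    degenerate = pr.max(axis=0) == pr.min(axis=0)
    electrode_labels = _median_split(pr)
    n_el = pr.shape[1]
    pop = np.empty_like(electrode_labels)
    for e in range(n_el):
        series = pr_table.population_mean_normalized(exclude=e if n_el > 1 else None)
        pop[:, e] = series > np.median(series)
    global_series = pr_table.population_mean_normalized()
    rng_ = pr.max(axis=0) - pr.min(axis=0)
    rng_ = np.where(rng_ == 0, 1.0, rng_)
    normalized = (pr - pr.min(axis=0)) / rng_
    return StateLabelTable(
        electrode_labels=electrode_labels,
        population_labels=pop,
        global_labels=global_series > np.median(global_series),
        normalized_pr=normalized,
        degenerate=degenerate,
    )


@dataclass
class SameStateResult:
    """Same-state probability of one electrode with a shuffle null."""

    electrode: int
    probability: float
    null_probabilities: np.ndarray = field(repr=False)
    n_trials: int
    n_permutations: int

    @property
    def null_mean(self) -> float:
        return float(self.null_probabilities.mean())


def same_state_probability(
    labels: StateLabelTable,
    electrode: int,
    population_subset=None,
    n_permutations: int = 1000,
    seed=None,
) -> SameStateResult:
    """Probability that an electrode shares the population's state label.

    The population label comes from the leave-one-out split stored in
    ``labels`` unless ``population_subset`` names an explicit electrode set
    (which must exclude ``electrode``). The null distribution permutes the
    electrode's trial labels, destroying any trial-wise coupling while
    preserving the label counts; its expectation is 0.5.
    """
    el = labels.electrode_labels[:, electrode]
    if population_subset is not None:
        subset = np.asarray(population_subset, dtype=int)
        if electrode in subset:
            raise ValueError("electrode must not belong to population_subset")
        series = labels.normalized_pr[:, subset].mean(axis=1)
        pop = series > np.median(series)
    else:
        pop = labels.population_labels[:, electrode]
    n = el.size
    if n < 20:
        raise ValueError("need at least 20 trials")
    if el.all() or (~el).any() is False or labels.degenerate[electrode]:
        pass  # degenerate labels still yield a defined match fraction
    prob = float((el == pop).mean())
    rng = np.random.default_rng(seed)
    # vectorized permutations: row-wise shuffles of the electrode labels
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    null = (el[order] == pop[None, :]).mean(axis=1)
    return SameStateResult(
        electrode=int(electrode),
        probability=prob,
        null_probabilities=null,
        n_trials=n,
        n_permutations=n_permutations,
    )


@dataclass
class PerformanceByState:
    """Percent correct per state bin with a bootstrap bin comparison."""

    percent_correct: np.ndarray  # per bin, low state first
    n_trials: np.ndarray
    n_bins: int
    binning: str  # "median" | "equal-width" | "equal-count"
    comparison: BootstrapResult  # highest bin minus lowest bin


def performance_by_state(
    state,
    outcomes,
    n_bins: int = 2,
    binning: str = "equal-width",
    n_bootstrap: int = 10_000,
    seed=None,
) -> PerformanceByState:
    """Perceptual performance (percent correct) per pre-stimulus state bin.

    ``state`` is either a boolean high-state label vector (used directly
    when ``n_bins == 2``) or a continuous PR vector binned by a median
    split (2 bins) or into ``n_bins`` bins over the PR range
    (``equal-width``, as in dividing the range of PR values into three
    equal-size bins; ``equal-count`` quantile bins are the config
    alternative). The bin comparison resamples trials with replacement
    within the lowest and highest bins and reports the two-sided empirical
    p for their performance difference.
    """
    state = np.asarray(state)
    outcomes = np.asarray(outcomes, dtype=bool)
    if state.shape[0] != outcomes.shape[0]:
        raise ValueError("state and outcomes must align")
    if state.dtype == bool:
        if n_bins != 2:
            raise ValueError("boolean labels imply 2 bins")
        bin_idx = state.astype(int)
        binning = "median"
    elif n_bins == 2:
        bin_idx = (state > np.median(state)).astype(int)
        binning = "median"
    elif binning == "equal-width":
        edges = np.linspace(state.min(), state.max(), n_bins + 1)
        bin_idx = np.clip(np.digitize(state, edges[1:-1]), 0, n_bins - 1)
    elif binning == "equal-count":
        edges = np.quantile(state, np.linspace(0, 1, n_bins + 1))
        bin_idx = np.clip(np.digitize(state, edges[1:-1]), 0, n_bins - 1)
    else:
        raise ValueError(f"unknown binning {binning!r}")
    counts = np.bincount(bin_idx, minlength=n_bins)
    if np.any(counts == 0):
        raise ValueError(
            f"empty state bin(s) {np.flatnonzero(counts == 0).tolist()}; "
            "bins are not merged — rebin explicitly"
        )
    perf = np.array(
        [100.0 * outcomes[bin_idx == b].mean() for b in range(n_bins)]
    )
    comparison = bootstrap_diff(
        outcomes[bin_idx == n_bins - 1].astype(float),
        outcomes[bin_idx == 0].astype(float),
        n_iterations=n_bootstrap,
        seed=seed,
    )
    return PerformanceByState(
        percent_correct=perf,
        n_trials=counts,
        n_bins=n_bins,
        binning=binning,
        comparison=comparison,
    )


@dataclass
class OutcomeContrast:
    """Correct-vs-incorrect PR contrast per electrode with population tests."""

    percent_difference: np.ndarray  # per electrode, on raw PR
    delta_log_pr: np.ndarray  # per electrode mean log-PR difference
    skipped: np.ndarray  # electrodes lacking one outcome condition
    test_two_sided: TestResult
    test_one_sided: TestResult
    direction: str

    @property
    def mean_percent_difference(self) -> float:
        return float(np.nanmean(self.percent_difference))

    @property
    def sem_percent_difference(self) -> float:
        v = self.percent_difference[np.isfinite(self.percent_difference)]
        return float(v.std(ddof=1) / np.sqrt(v.size))


def pr_outcome_contrast(
    pr_table: PowerRatioTable, outcomes, direction: str = "positive"
) -> OutcomeContrast:
    """Percentage PR difference between correct and incorrect trials.

    Per electrode: 100 * (mean PR_correct - mean PR_incorrect) /
    mean PR_incorrect on raw PR (the effect size as displayed), while the
    population-level Wilcoxon signed-rank tests operate on per-electrode
    mean log-PR differences (all statistics on log PR). ``direction`` sets
    the one-sided alternative ("positive" for detection-style effects,
    "negative" for discrimination).
    """
    outcomes = np.asarray(outcomes, dtype=bool)
    pr = pr_table.pr
    if outcomes.all() or not outcomes.any():
        raise ValueError("need at least one correct and one incorrect trial")
    mean_c = pr[outcomes].mean(axis=0)
    mean_i = pr[~outcomes].mean(axis=0)
    pct = 100.0 * (mean_c - mean_i) / mean_i
    dlog = pr_table.log_pr[outcomes].mean(axis=0) - pr_table.log_pr[~outcomes].mean(axis=0)
    skipped = ~np.isfinite(pct)
    vals = dlog[~skipped]
    return OutcomeContrast(
        percent_difference=pct,
        delta_log_pr=dlog,
        skipped=skipped,
        test_two_sided=wilcoxon_signed_rank(vals, sidedness="two"),
        test_one_sided=wilcoxon_signed_rank(vals, sidedness="one", direction=direction),
        direction=direction,
    )


@dataclass
class EvokedTable:
    """Broad-band evoked power (dB re per-electrode pre-stimulus mean)."""

    target_db: np.ndarray  # (n_trials, n_electrodes)
    test_db: np.ndarray | None  # None for detection
    reference_power: np.ndarray  # per electrode, uV^2

    @property
    def diff_db(self) -> np.ndarray:
        """(test - target) evoked difference; discrimination trials only."""
        if self.test_db is None:
            raise ValueError("no second stimulus: difference undefined for detection")
        return self.test_db - self.target_db


@dataclass
class EvokedResult:
    table: EvokedTable
    pearson_r: np.ndarray  # per electrode r(log PR, target dB)
    r_test: TestResult  # one-sided signed-rank for positive median r
    diff_low_db: np.ndarray | None  # per-electrode mean (test-target), low-PR trials
    diff_high_db: np.ndarray | None
    diff_test: TestResult | None  # two-sided signed-rank low vs high


def _window_power(session: SessionData, on: int, off: int) -> np.ndarray:
    v = np.asarray(session.voltages[..., on:off], dtype=np.float64)
    return (v**2).mean(axis=-1)


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of two (n, m) arrays."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc * yc).sum(axis=0) / denom


def evoked_analysis(
    session: SessionData,
    pr_table: PowerRatioTable,
    labels: StateLabelTable | None = None,
) -> EvokedResult:
    """Relate stimulus-evoked broad-band power to the pre-stimulus state.

    Evoked power is the mean voltage-squared of the (broad-band,
    preprocessed) trace over each 200 ms stimulus window, in dB relative to
    the electrode's session-wide mean pre-stimulus power (a fixed reference
    that cancels in test-target differences). Reports the per-electrode
    Pearson correlation between log PR and target-evoked dB with a
    one-sided signed-rank test for a positive population median; for
    discrimination sessions, also the (test - target) dB difference of
    low- vs high-PR trial groups split by the global population state.
    """
    m = session.markers
    ref = _window_power(session, session.prestim_slice().start, session.prestim_slice().stop)
    ref_e = ref.mean(axis=0)  # per electrode
    target_db = 10.0 * np.log10(_window_power(session, m["stim1_on"], m["stim1_off"]) / ref_e)
    is_discrimination = bool(np.all(np.asarray(session.task) != DETECTION))
    test_db = None
    if is_discrimination:
        test_db = 10.0 * np.log10(
            _window_power(session, m["stim2_on"], m["stim2_off"]) / ref_e
        )
    table = EvokedTable(target_db=target_db, test_db=test_db, reference_power=ref_e)

    r = _pearson_columns(pr_table.log_pr, target_db)
    r_test = wilcoxon_signed_rank(r[np.isfinite(r)], sidedness="one", direction="positive")

    diff_low = diff_high = diff_test = None
    if is_discrimination:
        if labels is None:
            raise ValueError("labels required for the test-target state split")
        high = labels.global_labels
        diff = table.diff_db
        diff_low = diff[~high].mean(axis=0)
        diff_high = diff[high].mean(axis=0)
        diff_test = wilcoxon_signed_rank(diff_low - diff_high, sidedness="two")
    return EvokedResult(
        table=table,
        pearson_r=r,
        r_test=r_test,
        diff_low_db=diff_low,
        diff_high_db=diff_high,
        diff_test=diff_test,
    )


@dataclass
class RTCorrelation:
    pearson_r: np.ndarray  # per electrode r(log PR, RT), correct trials
    n_trials: int
    r_test: TestResult
    direction: str


def rt_state_correlation(
    pr_table: PowerRatioTable, reaction_time_ms, direction: str
) -> RTCorrelation:
    """Correlation between pre-stimulus log PR and reaction time.

    Only correct (responded) trials carry a reaction time. ``direction`` is
    the one-sided alternative for the population median r: "negative" for
    detection (synchronized state -> faster), "positive" for discrimination.
    """
    rt = np.asarray(reaction_time_ms, dtype=float)
    ok = np.isfinite(rt)
    if ok.sum() < 10:
        raise ValueError("need at least 10 correct trials with reaction times")
    r = _pearson_columns(pr_table.log_pr[ok], np.repeat(rt[ok, None], pr_table.n_electrodes, axis=1))
    return RTCorrelation(
        pearson_r=r,
        n_trials=int(ok.sum()),
        r_test=wilcoxon_signed_rank(r[np.isfinite(r)], sidedness="one", direction=direction),
        direction=direction,
    )


@dataclass
class QuartileComparison:
    quartile_of: np.ndarray  # per-electrode quartile index 0..3
    q1_values: np.ndarray
    q4_values: np.ndarray
    test: TestResult


def quartile_comparison(same_state_probs, electrode_values) -> QuartileComparison:
    """Compare an electrode-level quantity between same-state-probability quartiles.

    Electrodes are ranked by same-state probability (stable order resolves
    ties), cut into four near-equal groups, and the first vs fourth
    quartile's values compared with a two-sided rank-sum test (the groups
    are disjoint electrode sets, hence unpaired).
    """
    p = np.asarray(same_state_probs, dtype=float)
    v = np.asarray(electrode_values, dtype=float)
    if p.size != v.size:
        raise ValueError("inputs must align")
    if p.size < 8:
        raise ValueError("need at least 8 electrodes")
    order = np.argsort(p, kind="stable")
    quart = np.empty(p.size, dtype=int)
    quart[order] = (np.arange(p.size) * 4) // p.size
    q1, q4 = v[quart == 0], v[quart == 3]
    return QuartileComparison(
        quartile_of=quart,
        q1_values=q1,
        q4_values=q4,
        test=wilcoxon_rank_sum(q1, q4, sidedness="two"),
    )
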