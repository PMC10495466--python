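"""Shared statistical machinery: Wilcoxon tests, bootstrap comparisons, Bonferroni.

Every test used by the analysis modules goes through this module so that
sidedness, pairing, exact-vs-asymptotic null handling, and multiplicity
correction are explicit and serializable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "BootstrapResult",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "bootstrap_diff",
    "bonferroni",
]

# sample-size crossover between exact enumeration and the normal approximation
EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_MIN_N = 10


@dataclass
class TestResult:
    """Outcome of a rank test with its full context.

    Attributes
    ----------
    statistic : float
        The test statistic (signed-rank W+ or Mann-Whitney U).
    pvalue : float
        The p-value at the requested sidedness.
    sidedness : str
        ``"one"`` or ``"two"``.
    pairing : str
        ``"signed-rank"`` (one-sample / paired) or ``"rank-sum"`` (two-sample).
    n : int
        Effective sample size (non-zero differences for signed-rank,
        total for rank-sum).
    method : str
        ``"exact"`` or ``"approx"`` null distribution.
    correction : str
        Multiplicity correction applied (``"none"`` or ``"bonferroni"``).
    family_size : int
        Family size of the correction (1 when uncorrected).
    """

    statistic: float
    pvalue: float
    sidedness: str
    pairing: str
    n: int
    method: str = "approx"
    correction: str = "none"
    family_size: int = 1

    def corrected(self, family_size: int) -> "TestResult":
        """Return a Bonferroni-corrected copy: p -> min(1, p * family_size)."""
        return TestResult(
            statistic=self.statistic,
            pvalue=min(1.0, self.pvalue * family_size),
            sidedness=self.sidedness,
            pairing=self.pairing,
            n=self.n,
            method=self.method,
            correction="bonferroni",
            family_size=family_size,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def wilcoxon_signed_rank(
    x,
    sidedness: str = "two",
    direction: str = "positive",
    exact_max_n: int = EXACT_SIGNED_RANK_MAX_N,
) -> TestResult:
    """One-sample Wilcoxon signed-rank test against a zero median.

    Parameters
    ----------
    x : array-like
        Sample (or paired differences).
    sidedness : {"one", "two"}
    direction : {"positive", "negative"}
        For a one-sided test, the direction of the alternative median.
    exact_max_n : int
        Use the exact null for n below this bound (ties force the
        normal approximation, which scipy applies automatically).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    nz = x[x != 0]
    if nz.size == 0:
        raise ValueError("all differences are zero; signed-rank test undefined")
    if sidedness == "two":
        alternative = "two-sided"
    elif sidedness == "one":
        alternative = "greater" if direction == "positive" else "less"
    else:
        raise ValueError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    has_ties = np.unique(np.abs(nz)).size < nz.size
    use_exact = nz.size < exact_max_n and not has_ties
    method = "exact" if use_exact else "approx"
    res = sps.wilcoxon(
        nz,
        alternative=alternative,
        method=method,
        correction=(method == "approx"),
    )
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(min(1.0, res.pvalue)),
        sidedness=sidedness,
        pairing="signed-rank",
        n=int(nz.size),
        method=method,
    )


def wilcoxon_rank_sum(
    x,
    y,
    sidedness: str = "two",
    direction: str = "positive",
    exact_max_min_n: int = EXACT_RANK_SUM_MAX_MIN_N,
) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U) test.

    For small samples (min(n, m) <= ``exact_max_min_n``) the exact null is
    used; with ties this is obtained by full permutation enumeration.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if sidedness == "two":
        alternative = "two-sided"
    elif sidedness == "one":
        alternative = "greater" if direction == "positive" else "less"
    else:
        raise ValueError(f"sidedness must be 'one' or 'two', got {sidedness!r}")

    small = min(x.size, y.size) <= exact_max_min_n
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if small and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="exact")
        stat, p, method = float(res.statistic), float(res.pvalue), "exact"
    elif small and math.comb(x.size + y.size, x.size) <= 200_000:
        # tied small samples: exact permutation null of the U statistic
        def _u(a, b, axis=-1):
            return sps.mannwhitneyu(a, b, alternative="two-sided", axis=axis).statistic

        perm = sps.permutation_test(
            (x, y),
            _u,
            permutation_type="independent",
            alternative=alternative,
            n_resamples=np.inf,
        )
        stat, p, method = float(perm.statistic), float(perm.pvalue), "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative=alternative, method="asymptotic", use_continuity=True
        )
        stat, p, method = float(res.statistic), float(res.pvalue), "approx"
    return TestResult(
        statistic=stat,
        pvalue=float(min(1.0, p)),
        sidedness=sidedness,
        pairing="rank-sum",
        n=int(x.size + y.size),
        method=method,
    )


@dataclass
class BootstrapResult:
    """Bootstrap comparison of a statistic between two groups."""

    observed_diff: float
    pvalue: float
    ci_low: float
    ci_high: float
    n_iterations: int
    boot_diffs: np.ndarray = field(repr=False)


def bootstrap_diff(
    group_a,
    group_b,
    statistic=np.mean,
    n_iterations: int = 10_000,
    seed=None,
    ci: float = 0.95,
) -> BootstrapResult:
    """Bootstrap test for a difference in a statistic between two groups.

    Trials are resampled with replacement within each group; the two-sided
    empirical p-value uses (k+1)/(B+1) smoothing on the fraction of bootstrap
    differences on either side of zero, so p is never exactly 0 and has a
    floor of 2/(B+1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    obs = float(statistic(a) - statistic(b))

    if statistic is np.mean:
        # vectorized fast path for the common case
        ia = rng.integers(0, a.size, size=(n_iterations, a.size))
        ib = rng.integers(0, b.size, size=(n_iterations, b.size))
        diffs = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    else:
        diffs = np.empty(n_iterations)
        for i in range(n_iterations):
            diffs[i] = statistic(a[rng.integers(0, a.size, a.size)]) - statistic(
                b[rng.integers(0, b.size, b.size)]
            )
    if np.ptp(diffs) == 0 and diffs[0] == obs:
        # degenerate statistic: no resampling variability
        p_lo = p_hi = (n_iterations + 1.0) / (n_iterations + 1.0)
    else:
        p_lo = (np.sum(diffs <= 0) + 1.0) / (n_iterations + 1.0)
        p_hi = (np.sum(diffs >= 0) + 1.0) / (n_iterations + 1.0)
    pvalue = min(1.0, 2.0 * min(p_lo, p_hi))
    alpha = 1.0 - ci
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    return BootstrapResult(
        observed_diff=obs,
        pvalue=float(pvalue),
        ci_low=float(lo),
        ci_high=float(hi),
        n_iterations=n_iterations,
        boot_diffs=diffs,
    )


def bonferroni(pvals, family_size: int | None = None):
    """Bonferroni correction: elementwise min(1, p * family_size)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = family_size if family_size is not None else p.size
    return np.minimum(1.0, p * m)
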