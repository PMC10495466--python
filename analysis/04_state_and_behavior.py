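#!/usr/bin/env python
"""Relate cortical state to behavior: same-state probability, performance
splits, correct-vs-incorrect PR contrast, and reaction-time correlations.

Writes results/same_state.csv and results/state_behavior.csv and prints the
task-dependent signature: high-PR (synchronized) trials help detection and
hurt discrimination.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from corticalstate import (
    load_session,
    performance_by_state,
    pr_outcome_contrast,
    prepare_task,
    rt_state_correlation,
    same_state_probability,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    warnings.filterwarnings("ignore", message="minimal-order Chebyshev-II")
    session = load_session(OUT / "session.h5")

    rows, ss_rows = [], []
    for task, direction in (("detection", "positive"), ("discrimination", "negative")):
        tables = prepare_task(session, task)
        outcomes = np.asarray(tables.session.outcome, bool)

        probs = []
        for e in range(tables.labels.n_electrodes):
            res = same_state_probability(tables.labels, e, n_permutations=1000, seed=e)
            probs.append(res.probability)
            ss_rows.append(dict(task=task, electrode=e, probability=res.probability,
                                null_mean=res.null_mean))
        print(f"{task}: same-state probability {np.mean(probs):.3f} +/- "
              f"{np.std(probs) / np.sqrt(len(probs)):.3f} (shuffle null "
              f"{np.mean([r['null_mean'] for r in ss_rows if r['task'] == task]):.3f})")

        perf = performance_by_state(tables.labels.global_labels, outcomes,
                                    n_bootstrap=10_000, seed=1)
        tert = performance_by_state(tables.pr_table.population_mean_normalized(),
                                    outcomes, n_bins=3, n_bootstrap=10_000, seed=2)
        contrast = pr_outcome_contrast(tables.pr_table, outcomes, direction=direction)
        rt = rt_state_correlation(tables.pr_table, tables.session.reaction_time_ms,
                                  "negative" if task == "detection" else "positive")
        print(f"  performance low/high PR: {perf.percent_correct[0]:.1f}% / "
              f"{perf.percent_correct[1]:.1f}% (bootstrap p={perf.comparison.pvalue:.4f})")
        print(f"  tertile performances: "
              + " / ".join(f"{p:.1f}%" for p in tert.percent_correct))
        print(f"  PR percent difference (correct-incorrect): "
              f"{contrast.mean_percent_difference:+.2f} +/- "
              f"{contrast.sem_percent_difference:.2f}% "
              f"(one-sided p={contrast.test_one_sided.pvalue:.2e})")
        print(f"  RT vs log-PR: median r {np.median(rt.pearson_r):+.3f} "
              f"(one-sided p={rt.r_test.pvalue:.3f})")
        rows.append(dict(
            task=task,
            perf_low=perf.percent_correct[0], perf_high=perf.percent_correct[1],
            perf_p=perf.comparison.pvalue,
            pct_diff_mean=contrast.mean_percent_difference,
            pct_diff_sem=contrast.sem_percent_difference,
            pct_diff_p=contrast.test_one_sided.pvalue,
            rt_r_median=float(np.median(rt.pearson_r)), rt_p=rt.r_test.pvalue,
        ))

    pd.DataFrame(ss_rows).to_csv(OUT / "same_state.csv", index=False)
    pd.DataFrame(rows).to_csv(OUT / "state_behavior.csv", index=False)
    print("wrote same_state.csv and state_behavior.csv")


if __name__ == "__main__":
    main()
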