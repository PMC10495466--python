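#!/usr/bin/env python
"""Relate stimulus-evoked responses to pre-stimulus state.

Computes the per-electrode correlation between pre-stimulus log PR and the
broad-band evoked power of the first stimulus, the (test - target) evoked
difference split by population state for discrimination, and the
same-state-probability quartile comparison of evoked responses. Writes
results/evoked.csv and a figure results/figures/evoked.png.
"""

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from corticalstate import (
    evoked_analysis,
    load_session,
    prepare_task,
    quartile_comparison,
    same_state_probability,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    warnings.filterwarnings("ignore", message="minimal-order Chebyshev-II")
    session = load_session(OUT / "session.h5")
    (OUT / "figures").mkdir(parents=True, exist_ok=True)

    rows = []
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for task in ("detection", "discrimination"):
        tables = prepare_task(session, task)
        res = evoked_analysis(tables.session, tables.pr_table, tables.labels)
        print(f"{task}: evoked-response vs log-PR Pearson r = "
              f"{np.nanmean(res.pearson_r):.3f} +/- "
              f"{np.nanstd(res.pearson_r) / np.sqrt(res.pearson_r.size):.3f} "
              f"(one-sided p={res.r_test.pvalue:.2e})")
        row = dict(task=task, evoked_r_mean=float(np.nanmean(res.pearson_r)),
                   evoked_r_p=res.r_test.pvalue)
        if task == "discrimination":
            print(f"  (test - target) difference: low PR "
                  f"{res.diff_low_db.mean():+.3f} dB vs high PR "
                  f"{res.diff_high_db.mean():+.3f} dB "
                  f"(two-sided p={res.diff_test.pvalue:.4f})")
            row.update(diff_low_db=float(res.diff_low_db.mean()),
                       diff_high_db=float(res.diff_high_db.mean()),
                       diff_p=res.diff_test.pvalue)

        probs = np.array([
            same_state_probability(tables.labels, e, n_permutations=10, seed=e).probability
            for e in range(tables.labels.n_electrodes)
        ])
        quart = quartile_comparison(probs, np.nanmean(res.table.target_db, axis=0))
        print(f"  evoked power, Q1 vs Q4 same-state electrodes: "
              f"{quart.q1_values.mean():+.3f} vs {quart.q4_values.mean():+.3f} dB "
              f"(p={quart.test.pvalue:.3f})")
        row.update(quartile_p=quart.test.pvalue)
        rows.append(row)

        ax = axes[0] if task == "detection" else axes[1]
        ax.scatter(tables.pr_table.log_pr[:, 0], res.table.target_db[:, 0], s=8)
        ax.set(xlabel="log PR (electrode 0)", ylabel="evoked power (dB)", title=task)

    fig.tight_layout()
    fig.savefig(OUT / "figures" / "evoked.png", dpi=120)
    pd.DataFrame(rows).to_csv(OUT / "evoked.csv", index=False)
    print("wrote evoked.csv and figures/evoked.png")


if __name__ == "__main__":
    main()
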