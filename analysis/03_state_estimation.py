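#!/usr/bin/env python
"""Estimate pre-stimulus cortical state: PR distribution, spectra, autocorrelation.

Runs the preprocessing + power-ratio pipeline per task, checks the
log-normality of the measured PR distribution, verifies the absence of
trial-order structure, and contrasts low- vs high-PR trial spectra.
Writes results/pr_table.csv, results/pr_autocorrelation.csv and a summary
figure results/figures/state_estimation.png.
"""

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as sps

from corticalstate import load_session, pr_autocorrelation, prepare_task, zscored_spectrum

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    warnings.filterwarnings("ignore", message="minimal-order Chebyshev-II")
    session = load_session(OUT / "session.h5")
    (OUT / "figures").mkdir(parents=True, exist_ok=True)

    frames, acfs = [], []
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    for task in ("detection", "discrimination"):
        tables = prepare_task(session, task)
        pr = tables.pr_table
        df = pr.to_frame()
        df["task"] = task
        frames.append(df)

        normal_p = np.array(
            [sps.normaltest(pr.log_pr[:, e]).pvalue for e in range(pr.n_electrodes)]
        )
        print(f"{task}: PR mean {pr.pr.mean():.2f}, log-PR normality rejected on "
              f"{(normal_p < 0.01).sum()}/{pr.n_electrodes} electrodes (alpha=0.01)")

        acf = pr_autocorrelation(pr.pr, max_lag=20)
        acf["task"] = task
        acfs.append(acf)
        print(f"  trial-order autocorrelation: "
              f"{acf.significant.sum()} significant lags (Bonferroni)")

        # low vs high PR state spectra for one electrode
        labels = np.where(tables.labels.electrode_labels[:, 0], "high", "low")
        est = zscored_spectrum(tables.session, labels)
        if task == "detection":
            for state, color in (("low", "tab:blue"), ("high", "tab:red")):
                axes[1].plot(est.freqs, est.condition_means[state][0], color=color,
                             label=f"{state} PR")
            axes[1].set(xlabel="frequency (Hz)", ylabel="z-scored power",
                        title="electrode 0, detection")
            axes[1].legend(frameon=False)

    all_pr = pd.concat(frames)
    axes[0].hist(all_pr.pr, bins=60, color="gray")
    axes[0].set(xlabel="power ratio", ylabel="trials", title="PR distribution")
    acf_all = pd.concat(acfs)
    mean_acf = acf_all.groupby("lag").mean_acf.mean()
    axes[2].stem(mean_acf.index, mean_acf.values)
    axes[2].set(xlabel="lag (trials)", ylabel="autocorrelation", ylim=(-0.2, 1.05))
    fig.tight_layout()
    fig.savefig(OUT / "figures" / "state_estimation.png", dpi=120)

    all_pr.to_csv(OUT / "pr_table.csv", index=False)
    acf_all.to_csv(OUT / "pr_autocorrelation.csv", index=False)
    print(f"wrote pr_table.csv, pr_autocorrelation.csv and figures/state_estimation.png")


if __name__ == "__main__":
    main()
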