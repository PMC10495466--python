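#!/usr/bin/env python
"""Preprocessing quality control: filter designs and epileptiform rejection.

Loads results/session.h5, reports the Chebyshev-II filter designs in use,
runs the amplitude-threshold trial rejection per task, and writes the
per-trial rejection report to results/rejection_report.csv.
"""

import warnings
from pathlib import Path

import pandas as pd

from corticalstate import (
    HIGH_BAND,
    LOW_BAND,
    design_filter,
    detect_spiking_trials,
    load_session,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    warnings.filterwarnings("ignore", message="minimal-order Chebyshev-II")
    session = load_session(OUT / "session.h5")

    print("filter designs (60 dB Chebyshev-II, zero-phase):")
    for kind, band in [("bandpass", LOW_BAND), ("bandpass", HIGH_BAND),
                       ("bandstop", (59.4, 60.6))]:
        spec = design_filter(kind, band, session.fs)
        note = " (fixed-order fallback)" if spec.relaxed else ""
        print(f"  {kind} {band} Hz -> order {spec.order}, cutoffs {spec.cutoffs}{note}")

    frames = []
    for task in ("detection", "discrimination"):
        report = detect_spiking_trials(session, task)
        frames.append(report.to_frame())
        n_any = report.rejected.any(axis=1).sum()
        n_major = (report.rejected.mean(axis=1) >= 0.5).sum()
        print(f"{task}: {n_any}/{report.trial_ids.size} trials exceed threshold on "
              f">=1 electrode (isolated large evoked responses), {n_major} on a "
              f"majority of electrodes (dropped as epileptiform); "
              f"{report.electrode_excluded.sum()} electrodes excluded "
              f"(<{report.min_trials} clean trials)")
    pd.concat(frames).to_csv(OUT / "rejection_report.csv", index=False)
    print(f"wrote {OUT / 'rejection_report.csv'}")


if __name__ == "__main__":
    main()
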