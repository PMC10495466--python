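#!/usr/bin/env python
"""Simulate one two-task recording session with the default study conditions.

Generates 50 electrodes x 120 trials per task (detection + discrimination)
at 1000 Hz with the default latent-state structure, writes the session to
results/session.h5 and the behavioral table to results/behavior.csv, and
prints a summary of what was simulated.
"""

import sys
import warnings
from pathlib import Path

import numpy as np

from corticalstate import GeneratorConfig, export_behavior_csv, generate_session, save_session

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 7) -> None:
    warnings.filterwarnings("ignore", message="minimal-order Chebyshev-II")
    cfg = GeneratorConfig(seed=seed)
    session = generate_session(cfg)
    OUT.mkdir(exist_ok=True)
    save_session(OUT / "session.h5", session)
    export_behavior_csv(OUT / "behavior.csv", session)

    task = np.asarray(session.task)
    print(f"session: {session.n_trials} trials x {session.n_electrodes} electrodes "
          f"x {session.n_samples} samples at {session.fs:.0f} Hz")
    for t in ("detection", "discrimination"):
        sel = task == t
        correct = session.outcome[sel].mean()
        rt = np.nanmean(session.reaction_time_ms[sel])
        print(f"  {t:15s}: {sel.sum()} trials, {100 * correct:.1f}% correct, "
              f"mean RT {rt:.0f} ms")
    gt = session.ground_truth
    print(f"  latent PR: mean {np.exp(gt['log_pr']).mean():.2f} "
          f"(target log-normal mean {np.exp(cfg.logpr_mean + cfg.logpr_sd ** 2 / 2):.2f}), "
          f"state sharing {cfg.state_sharing}")
    print(f"wrote {OUT / 'session.h5'} and {OUT / 'behavior.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
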