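import numpy as np
import pytest

from corticalstate import (
    EpochLayout,
    GeneratorConfig,
    SessionData,
    generate_session,
    prepare_task,
)

FS = 1000.0


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_electrodes=8, n_trials=60, seed=11)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def det_tables(small_session):
    return prepare_task(small_session, "detection", notch=False)


@pytest.fixture(scope="session")
def dis_tables(small_session):
    return prepare_task(small_session, "discrimination", notch=False)


@pytest.fixture(scope="session")
def tame_config():
    """Generator settings with subdued evoked and state variability, so the
    only above-threshold amplitude events are deliberately injected bursts
    (large trial-to-trial PR spread makes the whole-trial variance itself
    heterogeneous, which blurs the 5%-of-samples rule)."""
    return GeneratorConfig(
        n_electrodes=6,
        n_trials=80,
        seed=21,
        evoked_base_power_uv2=300.0,
        evoked_noise_sd=0.3,
        logpr_sd=0.4,
        tasks=("detection",),
    )


def build_session(voltages, fs=FS, task="detection", outcome=None, rt=None):
    """Assemble a SessionData around given voltage traces (default epoch)."""
    voltages = np.asarray(voltages, dtype=np.float32)
    n = voltages.shape[0]
    outcome = np.ones(n, dtype=bool) if outcome is None else np.asarray(outcome, bool)
    if rt is None:
        rt = np.where(outcome, 500.0, np.nan)
    return SessionData(
        voltages=voltages,
        fs=fs,
        task=np.full(n, task, dtype=object),
        outcome=outcome,
        reaction_time_ms=np.asarray(rt, dtype=float),
        markers=EpochLayout().markers(fs),
    )


@pytest.fixture
def make_session():
    return build_session
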