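import numpy as np
import pytest

from ramptime.preprocess import SessionData, TrialRecord
from ramptime.synthdata import (
    LatencyModel,
    NeuronModel,
    TaskConfig,
    generate_population,
    generate_session,
)


def make_session(
    spikes_fn,
    *,
    n_per_cell: int = 8,
    latency: float = 550.0,
    structure: str = "striatum",
    conditions=("short", "medium", "long"),
    directions=("contra", "ipsi"),
    cue_on: float = 1100.0,
) -> SessionData:
    """Deterministic hand-built session; spikes_fn(trial) -> spike array."""
    trials, spikes = [], {}
    tid = 0
    for cond in conditions:
        for direction in directions:
            for _ in range(n_per_cell):
                tr = TrialRecord(
                    trial_id=tid,
                    condition=cond,
                    direction=direction,
                    fp_on_ms=400.0,
                    cue_on_ms=cue_on,
                    saccade_ms=cue_on + latency,
                )
                trials.append(tr)
                spikes[tid] = np.asarray(spikes_fn(tr), dtype=float)
                tid += 1
    return SessionData(
        neuron_id="handmade", structure=structure, trials=trials, spikes=spikes
    )


@pytest.fixture(scope="session")
def small_task():
    return TaskConfig(trials_per_condition=10)


@pytest.fixture(scope="session")
def tracker_session(small_task):
    model = NeuronModel(archetype="tracker", baseline_rate=20, peak_rate=70)
    return generate_session(model, small_task, LatencyModel(), seed=11)


@pytest.fixture(scope="session")
def trigger_session(small_task):
    model = NeuronModel(
        archetype="trigger", baseline_rate=30, peak_rate=80, d_ms=500
    )
    return generate_session(
        model, small_task, LatencyModel(), seed=12, structure="cerebellum"
    )


@pytest.fixture(scope="session")
def small_tracker_population(small_task):
    return generate_population("tracker", 12, seed=31, task=small_task)


@pytest.fixture(scope="session")
def small_trigger_population(small_task):
    return generate_population("trigger", 12, seed=32, task=small_task)
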