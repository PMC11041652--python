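import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lhbpipe as lp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedules():
    """One habituation and one conditioning schedule, fixed seeds."""
    return (
        lp.generate_task_schedule(lp.Phase.HABITUATION, 101),
        lp.generate_task_schedule(lp.Phase.CONDITIONING, 102),
    )


@pytest.fixture(scope="session")
def small_spike_cohort():
    recs, truth = lp.generate_spike_cohort(
        lp.SpikeCohortParams(n_neurons=30, seed=7, duration_s=120.0)
    )
    return recs, truth


def make_trace_set(
    values: np.ndarray,
    cues=None,
    rate: float = 5.0,
    phase=lp.Phase.CONDITIONING,
    neuron_id: str = "n0",
) -> lp.NeuronTraceSet:
    values = np.atleast_2d(values)
    cues = cues or [lp.Cue.CS_PLUS] * values.shape[0]
    return lp.NeuronTraceSet(
        neuron_id=neuron_id,
        session_id="s0",
        phase=phase,
        window=lp.TrialTraceWindow(sample_rate_hz=rate),
        cue_per_trial=cues,
        raw_f=values,
    )
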