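import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mazerecall as mr

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_session(spike_times, trial_specs, track_end=None, dt_track=1 / 30):
    """Hand-built session.

    spike_times: list of per-neuron spike-time arrays.
    trial_specs: list of (t_start, t_end, arm, cue, outcome, rule) tuples.
    Tracking is a stationary point sampled at 30 Hz to `track_end`.
    """
    trains = [mr.SpikeTrain(i, np.asarray(t, float)) for i, t in enumerate(spike_times)]
    trials = [
        mr.Trial(i + 1, *spec) for i, spec in enumerate(trial_specs)
    ]
    end = track_end if track_end is not None else trials[-1].t_end + 10.0
    times = np.round(np.arange(0.0, end, dt_track), 4)
    tracking = mr.Tracking(times, np.zeros(times.size), np.full(times.size, -85.0))
    return mr.Session(trains, trials, tracking)


@pytest.fixture(scope="session")
def small_coupled_session():
    """12 neurons, 10 trials, gated ensemble coupling; short ITIs for speed."""
    cfg = mr.SynthConfig(
        n_neurons=12,
        n_trials=10,
        ensemble_members=(0, 1, 2, 3, 4),
        coupling=0.8,
        mean_iti_correct_s=25.0,
        mean_iti_error_s=15.0,
        seed=11,
    )
    return mr.generate_session(cfg)


@pytest.fixture(scope="session")
def small_null_session():
    """No gated ensemble; short ITIs for speed."""
    cfg = mr.SynthConfig(
        n_neurons=10,
        n_trials=8,
        mean_iti_correct_s=20.0,
        mean_iti_error_s=12.0,
        seed=5,
    )
    return mr.generate_session(cfg)


# ---------------------------------------------------------------------------
# independent brute-force oracles used across test modules
# ---------------------------------------------------------------------------

def pearson_oracle(u, v):
    """Textbook Pearson correlation, plain Python loops."""
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    num = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    du = sum((a - mu) ** 2 for a in u) ** 0.5
    dv = sum((b - mv) ** 2 for b in v) ** 0.5
    return num / (du * dv)


def gauss_density_oracle(spikes, grid_times, sigma):
    """Full Gaussian-kernel sum, no truncation."""
    out = np.zeros(len(grid_times))
    for s in spikes:
        out += np.exp(-((grid_times - s) ** 2) / (2 * sigma**2))
    return out / (sigma * np.sqrt(2 * np.pi))


def ks_stat_oracle(a, b):
    """Max |ECDF difference| by direct sweep over all sample points."""
    best = 0.0
    for x in list(a) + list(b):
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best
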