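"""Does the ITI ensemble pattern replay the preceding trial's pattern?

For each trial/ITI pair the similarity R_within between the trial's and
the ITI's pairwise-similarity matrices is compared with the similarity
R*_within expected between independently firing neurons, obtained by
ISI-shuffling the ITI spike trains (50 shuffles by default). The session
statistic is a one-tailed sign test that Delta_within = R_within -
mean(R*_within) is greater than zero.

The core population here is the joint one: neurons active in every trial
AND every ITI (trials are short, ~4 s, so this is a subset of the
ITI-only core population).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .recall import (
    _grid,
    _gauss_density,
    _recall_from_vectors,
    _pair_vectors_shuffled,
    core_population,
    recall_value,
    similarity_matrix,
)
from .session_model import Interval, Session


@dataclass
class TrialITIResult:
    pair_indices: np.ndarray  # trial/ITI index per pair
    r_within: np.ndarray
    r_within_shuffled: np.ndarray  # mean over shuffles, per pair
    delta_within: np.ndarray
    sign_test_p: float
    core_neurons: np.ndarray


def joint_core_population(session: Session) -> np.ndarray:
    """Neurons with at least one spike in every trial and every ITI."""
    trial_ivs = [Interval(t.index, t.t_start, t.t_end) for t in session.trials]
    return core_population(session, list(session.itis) + trial_ivs)


def trial_iti_similarity(
    session: Session,
    sigma: float = 0.1,
    dt: float = 0.01,
    n_shuffles: int = 50,
    seed=None,
) -> TrialITIResult:
    """Per trial/ITI pair: R_within, its shuffle null, and Delta_within,
    plus the session-level one-tailed sign test (Delta_within > 0)."""
    rng = np.random.default_rng(seed)
    core = joint_core_population(session)
    if core.size < 3:
        raise ValueError("joint core population must have >= 3 neurons")

    pairs = [
        (session.trials[iti.index - 1], iti)
        for iti in session.itis
    ]
    r_within = np.empty(len(pairs))
    r_shuf = np.empty(len(pairs))
    idx = np.empty(len(pairs), dtype=int)
    for i, (trial, iti) in enumerate(pairs):
        idx[i] = iti.index
        s_trial = _similarity_for(session, core, trial.t_start, trial.t_end, sigma, dt)
        s_iti = _similarity_for(session, core, iti.t_start, iti.t_end, sigma, dt)
        r_within[i] = recall_value(s_trial, s_iti)

        # null: ISI-shuffled ITI trains against the observed trial pattern
        iti_spikes = [
            [session.spike_trains[k].in_interval(iti.t_start, iti.t_end) for k in core]
        ]
        V = _pair_vectors_shuffled([iti_spikes[0]], [iti], sigma, dt, n_shuffles, rng)
        iu = np.triu_indices(core.size, k=1)
        v_trial = s_trial[iu]
        vals = np.empty(n_shuffles)
        for s in range(n_shuffles):
            vals[s] = _rectified_corr(v_trial, V[s, 0])
        r_shuf[i] = vals.mean()

    delta = r_within - r_shuf
    nonzero = delta[delta != 0]
    k = int((nonzero > 0).sum())
    p = (
        stats.binomtest(k, nonzero.size, 0.5, alternative="greater").pvalue
        if nonzero.size
        else 1.0
    )
    return TrialITIResult(idx, r_within, r_shuf, delta, float(p), core)


def _similarity_for(session, core, t0, t1, sigma, dt):
    iv = Interval(1, t0, t1)
    g0, n = _grid(iv, dt)
    D = np.vstack(
        [
            _gauss_density(
                session.spike_trains[k].in_interval(t0, t1), g0, n, dt, sigma
            )
            for k in core
        ]
    )
    return similarity_matrix(D)


def _rectified_corr(v, w):
    if np.ptp(v) == 0 or np.ptp(w) == 0:
        return 0.0
    return float(min(max(np.corrcoef(v, w)[0, 1], 0.0), 1.0))
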