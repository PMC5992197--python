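"""Synthetic Y-maze sessions with known ground truth.

The generator emulates the statistical structure the analyses assume:

* sessions of ~20-60 trials with an optional abrupt behavioural
  transition at a configured learning trial;
* inter-trial intervals drawn from a gamma distribution whose mean
  depends on the prior outcome (longer after correct trials, where the
  animal lingers at the reward site);
* 30 Hz tracking along the maze skeleton: trial run to the chosen goal
  arm, reward-site dwell, then a self-paced return to the start arm;
* inhomogeneous-Poisson spike trains in which a configurable ensemble
  shares a common latent rate modulation (Ornstein-Uhlenbeck, ~100 ms
  correlation time) only during ITIs that follow correct trials and fall
  within a configurable trial window — the reinforcement-gated
  co-activity the recall analysis is built to detect;
* optional position-dependent rate tuning to retrospective or
  prospective task features, for the decoding analyses.

Everything is drawn from a single seeded generator, with deterministic
per-component streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import maze
from .session_model import Interval, Session, SpikeTrain, Tracking, Trial, build_itis

FEATURES = (
    "prior_outcome",
    "prior_arm",
    "prior_cue",
    "next_outcome",
    "next_arm",
    "next_cue",
)


class SynthConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TuningRule:
    """Multiply some neurons' rates in given maze sections during ITIs
    whose (retrospective or prospective) task feature takes `value`."""

    feature: str
    value: str
    sections: tuple = (1, 2, 3, 4, 5)
    neurons: tuple | None = None  # None = all neurons
    gain: float = 1.0

    def __post_init__(self):
        if self.feature not in FEATURES:
            raise SynthConfigError(f"unknown tuning feature {self.feature!r}")
        if self.gain <= 0:
            raise SynthConfigError("tuning gain must be positive")


@dataclass(frozen=True)
class SynthConfig:
    n_neurons: int = 30
    n_trials: int = 40
    learning_trial: int | None = None
    p_correct_before: float = 0.5
    p_correct_after: float = 0.5
    mean_iti_correct_s: float = 79.1
    mean_iti_error_s: float = 48.4
    iti_gamma_shape: float = 4.0
    min_iti_s: float = 5.0
    rule: str = "go_cued"
    trial_duration_s: float = 4.0
    base_rates_hz: tuple | None = None  # None: lognormal, median 1.5 Hz
    ensemble_members: tuple = ()
    coupling: float = 0.0
    latent_tau_s: float = 0.1
    ensemble_window: tuple | None = None  # (onset_trial, offset_trial)
    #: weak session-wide co-fluctuation shared by ALL neurons at ALL times,
    #: independent of outcome — emulates the ubiquitous noise correlations
    #: of cortical populations (pairwise density correlations ~0.01-0.05
    #: at the default). This, not the gated ensemble, is what makes longer
    #: intervals yield more reliable similarity estimates (the duration
    #: bias the residual recall correction targets).
    background_coupling: float = 0.4
    tuning: tuple = ()
    reward_dwell_frac_correct: float = 0.5
    reward_dwell_frac_error: float = 0.25
    path_jitter_cm: float = 0.0
    stationary: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons < 1 or self.n_trials < 1:
            raise SynthConfigError("need at least one neuron and one trial")
        for p in (self.p_correct_before, self.p_correct_after):
            if not 0.0 <= p <= 1.0:
                raise SynthConfigError("probabilities must be in [0, 1]")
        if self.learning_trial is not None and not (
            1 <= self.learning_trial <= self.n_trials
        ):
            raise SynthConfigError("learning_trial outside [1, n_trials]")
        if self.mean_iti_correct_s <= 0 or self.mean_iti_error_s <= 0:
            raise SynthConfigError("ITI means must be positive")
        if self.coupling < 0 or self.background_coupling < 0:
            raise SynthConfigError("couplings must be >= 0")
        if self.coupling > 0 and not self.ensemble_members:
            raise SynthConfigError("coupling > 0 requires ensemble_members")
        if any(not 0 <= m < self.n_neurons for m in self.ensemble_members):
            raise SynthConfigError("ensemble member index out of range")
        if self.base_rates_hz is not None:
            if len(self.base_rates_hz) != self.n_neurons:
                raise SynthConfigError("base_rates_hz length != n_neurons")
            if any(r <= 0 for r in self.base_rates_hz):
                raise SynthConfigError("rates must be positive")
        w = self.ensemble_window
        if w is not None and not (1 <= w[0] <= w[1] <= self.n_trials):
            raise SynthConfigError(
                "ensemble_window must satisfy 1 <= onset <= offset <= n_trials"
            )

    def window(self) -> tuple:
        return self.ensemble_window or (1, self.n_trials)


def _correct_arm(rule: str, cue: str) -> str:
    if rule == "go_right":
        return "right"
    if rule == "go_left":
        return "left"
    if rule == "go_cued":
        return cue
    return "left" if cue == "right" else "right"


def _other(arm: str) -> str:
    return "left" if arm == "right" else "right"


def _q(t):
    """Quantise seconds to the 0.1 ms recording resolution."""
    return np.round(t, 4)


def generate_behaviour(config: SynthConfig, rng: np.random.Generator):
    """Draw the trial table.

    Returns (trials, iti_durations): `trials` is a list of Trial laid out
    on the session timeline, `iti_durations` the drawn ITI duration after
    each trial (the gaps between consecutive trials, plus the final
    return).
    """
    n = config.n_trials
    L = config.learning_trial
    idx = np.arange(1, n + 1)
    p = np.where(
        idx < (L if L is not None else n + 1),
        config.p_correct_before,
        config.p_correct_after,
    )
    correct = rng.random(n) < p
    cues = np.where(rng.random(n) < 0.5, "left", "right")

    shape = config.iti_gamma_shape
    means = np.where(correct, config.mean_iti_correct_s, config.mean_iti_error_s)
    itis = rng.gamma(shape, means / shape)
    itis = _q(np.maximum(itis, config.min_iti_s))

    trials = []
    t = 0.0
    for i in range(n):
        cue = str(cues[i])
        outcome = "correct" if correct[i] else "error"
        good = _correct_arm(config.rule, cue)
        arm = good if correct[i] else _other(good)
        dur = _q(config.trial_duration_s + rng.uniform(-0.5, 0.5))
        trials.append(
            Trial(i + 1, _q(t), _q(t + dur), arm, cue, outcome, config.rule)
        )
        t = _q(t + dur + itis[i])
    return trials, itis


def generate_tracking(
    config: SynthConfig, trials, iti_durations, rng: np.random.Generator
) -> Tracking:
    """30 Hz positions along the maze skeleton.

    Trials run start arm -> chosen goal arm; each ITI dwells at the
    reward site for a fixed fraction of its duration, then returns to the
    start arm at constant speed. `path_jitter_cm` adds isotropic Gaussian
    position noise to the return trip (zero keeps the travelled path
    length exactly equal to the 170 cm skeleton return path).
    """
    t_end = trials[-1].t_end + iti_durations[-1]
    n_samp = int(np.floor(t_end * 30.0)) + 1
    times = _q(np.arange(n_samp) / 30.0)
    xy = np.tile(maze.START_END, (n_samp, 1))

    if not config.stationary:
        for tr, iti_dur in zip(trials, iti_durations):
            # outward run during the trial (start end -> goal end)
            m = (times >= tr.t_start) & (times < tr.t_end)
            frac = (times[m] - tr.t_start) / (tr.t_end - tr.t_start)
            d_out = (1.0 - frac) * maze.RETURN_PATH_LENGTH_CM
            xy[m] = maze.point_on_return_path(tr.arm, d_out)

            # ITI: dwell at the reward site, then return to the start
            iti_start = tr.t_end
            iti_end = tr.t_end + iti_dur
            dwell = (
                config.reward_dwell_frac_correct
                if tr.outcome == "correct"
                else config.reward_dwell_frac_error
            ) * iti_dur
            m = (times >= iti_start) & (times < iti_end)
            tau = times[m] - iti_start
            d = np.zeros(tau.size)
            moving = tau >= dwell
            ret_dur = max(iti_dur - dwell, 1e-9)
            d[moving] = (
                (tau[moving] - dwell) / ret_dur * maze.RETURN_PATH_LENGTH_CM
            )
            pos = maze.point_on_return_path(tr.arm, d)
            if config.path_jitter_cm > 0:
                pos = pos + rng.normal(
                    0.0, config.path_jitter_cm, size=pos.shape
                ) * moving[:, None]
            xy[m] = pos

    xy = np.round(xy, 3)
    return Tracking(times, xy[:, 0], xy[:, 1])


def _feature_labels(trials, feature):
    """Per-ITI label of a task feature (ITI t sits after trial t)."""
    attr = {"outcome": "outcome", "arm": "arm", "cue": "cue"}[feature.split("_")[1]]
    vals = [getattr(t, attr) for t in trials]
    if feature.startswith("prior"):
        return vals
    return vals[1:] + [None]  # next_*: last ITI has no following trial


def generate_spikes(
    config: SynthConfig, trials, itis, tracking, rng: np.random.Generator
) -> list[SpikeTrain]:
    """Inhomogeneous-Poisson spike trains on a 10 ms simulation grid.

    Ensemble members share exp(c*z(t) - c^2/2) rate gain, z an OU process
    with `latent_tau_s` correlation time and unit stationary variance,
    applied only in ITIs following a correct trial inside the ensemble
    window. Tuning rules multiply rates by `gain` in the configured maze
    sections of ITIs whose feature matches.
    """
    dt = 0.01
    t_end = itis[-1].t_end if itis else trials[-1].t_end
    n_bins = int(np.ceil(t_end / dt))
    bin_t = (np.arange(n_bins) + 0.5) * dt

    if config.base_rates_hz is not None:
        base = np.asarray(config.base_rates_hz, dtype=float)
    else:
        # lognormal rate distribution typical of cortical populations
        base = np.clip(
            np.exp(rng.normal(np.log(1.5), 0.8, size=config.n_neurons)), 0.4, 10.0
        )

    log_rate = np.log(base)[:, None] * np.ones((1, n_bins))

    def _ou(tau):
        a = np.exp(-dt / tau)
        sq = np.sqrt(1.0 - a * a)
        eps = rng.normal(0.0, 1.0, size=n_bins)
        z = np.empty(n_bins)
        z[0] = eps[0]
        for i in range(1, n_bins):
            z[i] = a * z[i - 1] + sq * eps[i]
        return z

    # weak outcome-independent co-fluctuation across the whole population
    if config.background_coupling > 0:
        w = config.background_coupling * rng.uniform(0.2, 1.0, config.n_neurons)
        log_rate += w[:, None] * _ou(config.latent_tau_s)[None, :] - 0.5 * (
            w**2
        )[:, None]

    # shared latent in reinforcement-gated ITIs
    c = config.coupling
    if c > 0:
        z = _ou(config.latent_tau_s)
        lo, hi = config.window()
        gate = np.zeros(n_bins, dtype=bool)
        for iti, tr in zip(itis, trials):
            if tr.outcome == "correct" and lo <= tr.index <= hi:
                gate |= (bin_t >= iti.t_start) & (bin_t < iti.t_end)
        members = list(config.ensemble_members)
        log_rate[members] += np.where(gate, c * z - 0.5 * c * c, 0.0)

    # position/feature dependent tuning during ITIs
    if config.tuning:
        samp_idx = np.clip(
            np.searchsorted(tracking.times, bin_t) - 1, 0, len(tracking) - 1
        )
        for rule in config.tuning:
            labels = _feature_labels(trials, rule.feature)
            neurons = (
                list(rule.neurons)
                if rule.neurons is not None
                else list(range(config.n_neurons))
            )
            mask = np.zeros(n_bins, dtype=bool)
            for iti, tr, lab in zip(itis, trials, labels):
                if lab != rule.value:
                    continue
                m = (bin_t >= iti.t_start) & (bin_t < iti.t_end)
                if not m.any():
                    continue
                arc, _ = maze.project_to_return_path(
                    tr.arm,
                    tracking.x[samp_idx[m]],
                    tracking.y[samp_idx[m]],
                )
                sec = maze.section_of_arc(arc)
                mm = np.zeros(n_bins, dtype=bool)
                mm[np.nonzero(m)[0][np.isin(sec, rule.sections)]] = True
                mask |= mm
            log_rate[neurons] += np.where(mask, np.log(rule.gain), 0.0)

    counts = rng.poisson(np.exp(log_rate) * dt)
    trains = []
    for k in range(config.n_neurons):
        nz = np.nonzero(counts[k])[0]
        reps = counts[k][nz]
        starts = np.repeat(nz * dt, reps)
        t = _q(starts + rng.random(starts.size) * dt)
        t = np.unique(t)  # 0.1 ms quantisation can collide; keep strict order
        trains.append(SpikeTrain(k, t))
    return trains


def generate_session(config: SynthConfig, seed: int | None = None) -> Session:
    """Generate a full synthetic session (behaviour, tracking, spikes)."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    r_beh, r_trk, r_spk = (np.random.default_rng(s) for s in root.spawn(3))
    trials, iti_durs = generate_behaviour(config, r_beh)
    tracking = generate_tracking(config, trials, iti_durs, r_trk)
    itis = build_itis(trials, tracking)
    trains = generate_spikes(config, trials, itis, tracking, r_spk)
    return Session(trains, trials, tracking, itis)


def learning_session_config(seed: int = 0, **overrides) -> SynthConfig:
    """Convenience: a session with an abrupt behavioural transition."""
    base = dict(
        n_trials=40,
        learning_trial=20,
        p_correct_before=0.2,
        p_correct_after=0.9,
        seed=seed,
    )
    base.update(overrides)
    return SynthConfig(**base)
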