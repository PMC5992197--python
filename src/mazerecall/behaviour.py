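"""Behavioural analysis: learning-trial identification and path lengths.

Two learning-trial definitions are supported:

* the original criterion — the first of three consecutive correct trials
  after which performance is at least 80% correct for the remainder of
  the session;
* the steepest-change criterion — the trial at which a piecewise robust
  fit of the cumulative reward curve shows the largest increase in
  slope, with at least `min_side` trials on each side.

Two slope estimators are provided. Reported slopes default to
iteratively-reweighted least squares with a Huber loss (statsmodels
RLM), the field's standard robust fit. The split *search* defaults to
plain least squares: a cumulative count curve has bounded increments
and no outliers, and resistant estimators defeat the search — when a
candidate split mis-assigns part of the steep segment, a robust slope
simply downweights the minority segment, so the slope-increase
objective plateaus over a range of splits instead of peaking strictly
at the true change point (a median-based Theil-Sen slope is worst, but
Huber shows the same plateau over +-2 trials).

Sessions are classified as "learning" (original criterion met),
"minor_learning" (some admissible split has a positive slope increase),
or "other".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .session_model import Interval, Tracking, Trial


@dataclass(frozen=True)
class PiecewiseFit:
    split_trial: int
    r_before: float  # reward-accumulation rate (slope) before the split
    r_after: float

    @property
    def delta_slope(self) -> float:
        return self.r_after - self.r_before


@dataclass(frozen=True)
class SessionClassification:
    label: str  # learning | minor_learning | other
    learning_trial: int | None
    steepest_trial: int | None
    fit: PiecewiseFit | None = None


def _outcome_array(trials) -> np.ndarray:
    if trials and isinstance(trials[0], Trial):
        return np.array([t.outcome == "correct" for t in trials], dtype=bool)
    return np.asarray(
        [t == "correct" if isinstance(t, str) else bool(t) for t in trials],
        dtype=bool,
    )


def cumulative_reward(trials) -> np.ndarray:
    """Per-trial cumulative count of correct trials."""
    correct = _outcome_array(trials)
    if correct.size == 0:
        raise ValueError("no trials")
    return np.cumsum(correct.astype(int))


def find_learning_trial_original(trials, threshold: float = 0.8) -> int | None:
    """First of three consecutive correct trials after which performance is
    at least `threshold` correct for the remainder of the session.

    The threshold window includes the three consecutive correct trials
    themselves (trials i..end). Returns a 1-based trial index, or None.
    """
    correct = _outcome_array(trials)
    n = correct.size
    if n < 3:
        raise ValueError("need at least 3 trials")
    tail = np.cumsum(correct[::-1])[::-1]  # corrects from i..end
    for i in range(n - 2):
        if correct[i] and correct[i + 1] and correct[i + 2]:
            if tail[i] / (n - i) >= threshold:
                return i + 1
    return None


def _slope(x, y, method: str) -> float:
    """Regression slope; 'huber' IRLS falls back to the exact OLS solution
    on noiseless (collinear) input, where the scale estimate degenerates."""
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    if method == "ols":
        return float(ols.params[1])
    if method != "huber":
        raise ValueError("method must be 'huber' or 'ols'")
    resid = y - X @ ols.params
    if np.max(np.abs(resid)) < 1e-9 * max(1.0, np.max(np.abs(y))):
        return float(ols.params[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-scale convergence chatter
        return float(sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit().params[1])


def fit_piecewise(
    cumreward, split_trial: int, min_side: int = 5, method: str = "huber"
) -> PiecewiseFit:
    """Slopes of the cumulative reward curve before and after a split:
    before = trials 1..split-1, after = trials split..n.
    """
    y = np.asarray(cumreward, dtype=float)
    n = y.size
    n_before = split_trial - 1
    n_after = n - split_trial + 1
    if n_before < min_side:
        raise ValueError(
            f"split {split_trial}: only {n_before} trials before (need {min_side})"
        )
    if n_after < min_side:
        raise ValueError(
            f"split {split_trial}: only {n_after} trials after (need {min_side})"
        )
    x = np.arange(1, n + 1, dtype=float)
    r_before = _slope(x[:n_before], y[:n_before], method)
    r_after = _slope(x[n_before:], y[n_before:], method)
    return PiecewiseFit(split_trial, float(r_before), float(r_after))


def find_steepest_trial(cumreward, min_side: int = 5, method: str = "ols"):
    """Split maximising the slope increase of the piecewise fit.

    Returns (1-based trial index, delta_slope); ties go to the earliest
    trial. On a noiseless two-slope curve the returned trial is the kink
    trial (the last point shared by both line segments).
    """
    y = np.asarray(cumreward, dtype=float)
    n = y.size
    if n < 2 * min_side + 1:
        raise ValueError(f"need at least {2 * min_side + 1} trials")
    best = None
    for s in range(min_side + 1, n - min_side + 2):
        fit = fit_piecewise(y, s, min_side=min_side, method=method)
        if best is None or fit.delta_slope > best.delta_slope:
            best = fit
    return best.split_trial, best.delta_slope


def classify_session(
    trials, min_side: int = 5, threshold: float = 0.8, method: str = "ols"
) -> SessionClassification:
    """Label a session as learning / minor_learning / other.

    "learning" if the original criterion finds a learning trial;
    otherwise "minor_learning" if any admissible piecewise split has a
    positive slope increase; otherwise "other". (Rule-change status is an
    experimental annotation, not derivable from the trial table.)
    """
    learning_trial = find_learning_trial_original(trials, threshold=threshold)
    cum = cumulative_reward(trials)
    steepest, delta = (None, None)
    if cum.size >= 2 * min_side + 1:
        steepest, delta = find_steepest_trial(cum, min_side=min_side, method=method)
    if learning_trial is not None:
        label = "learning"
    elif delta is not None and delta > 0:
        label = "minor_learning"
    else:
        label = "other"
    fit = (
        fit_piecewise(cum, steepest, min_side, method=method)
        if steepest is not None
        else None
    )
    return SessionClassification(label, learning_trial, steepest, fit)


def path_length(tracking: Tracking, interval: Interval | tuple) -> float:
    """Distance travelled (cm) within [start, end): sum of frame-to-frame
    Euclidean steps."""
    if isinstance(interval, Interval):
        t0, t1 = interval.t_start, interval.t_end
    else:
        t0, t1 = interval
    sub = tracking.slice(t0, t1)
    if len(sub) < 2:
        raise ValueError("need at least 2 tracking samples in interval")
    return float(np.sum(np.hypot(np.diff(sub.x), np.diff(sub.y))))


def path_lengths(session) -> np.ndarray:
    """Path length of every ITI in a session."""
    return np.array([path_length(session.tracking, iti) for iti in session.itis])
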