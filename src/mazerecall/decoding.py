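"""Position-dependent decoding of task features from ITI firing rates.

The ITI return path (chosen goal-arm end -> choice point -> start arm)
is linearised into five equal-length sections. For each section p, every
ITI contributes the core population's firing-rate vector there; a linear
decoder is scored by leave-one-out cross-validation on the binary task
feature (prior or next outcome / arm / cue). Chance level is the same
LOOCV run on label-shuffled data (50 shuffles by default), and the
relative accuracy is accuracy minus the shuffled mean — this absorbs
class imbalance from the animal's own behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import maze
from .session_model import Session, Tracking

FEATURES = (
    "prior_outcome",
    "prior_arm",
    "prior_cue",
    "next_outcome",
    "next_arm",
    "next_cue",
)
DECODERS = ("logistic", "lda", "svm_linear", "nearest_neighbour")

OFF_PATH_TOL_CM = 15.0


def _make_decoder(name: str):
    # mild ridge penalty on the logistic keeps weights finite on
    # separable data; all four are deterministic fits
    if name == "logistic":
        return LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "svm_linear":
        return SVC(kernel="linear", C=1.0)
    if name == "nearest_neighbour":
        return KNeighborsClassifier(n_neighbors=1)
    raise ValueError(f"unknown decoder {name!r}; choose from {DECODERS}")


# ---------------------------------------------------------------------------
# linearisation and rate vectors
# ---------------------------------------------------------------------------

def linearise(
    tracking: Tracking, arm: str, off_path_tol_cm: float = OFF_PATH_TOL_CM
) -> np.ndarray:
    """Section id (1..5) per tracking sample along the return path for the
    given chosen arm; 0 marks samples off the skeleton beyond tolerance."""
    if len(tracking) == 0:
        return np.zeros(0, dtype=int)
    arc, perp = maze.project_to_return_path(arm, tracking.x, tracking.y)
    sec = maze.section_of_arc(arc)
    sec[perp > off_path_tol_cm] = 0
    return sec


def rate_vectors(session: Session, core) -> dict:
    """Firing-rate vectors per (ITI, maze section).

    Returns {section id: (rates array (n_itis, n_core), occupancy array,
    iti indices)}; ITIs with zero occupancy of a section carry NaN rates
    there and are excluded from that section's decoding.

    A section's occupancy in an ITI is the union of 30 Hz tracking-frame
    intervals whose sample falls in the section; each core neuron's rate
    is its spike count within those frames divided by the occupancy.
    """
    core = np.asarray(core)
    n_iti = len(session.itis)
    rates = {p: np.full((n_iti, core.size), np.nan) for p in range(1, 6)}
    occ = {p: np.zeros(n_iti) for p in range(1, 6)}
    for i, iti in enumerate(session.itis):
        trial = session.trials[iti.index - 1]
        trk = session.tracking.slice(iti.t_start, iti.t_end)
        if len(trk) == 0:
            continue
        sec = linearise(trk, trial.arm)
        # frame k covers [t_k, t_{k+1}), last frame to the ITI end
        edges = np.append(trk.times, iti.t_end)
        durations = np.diff(edges)
        for p in range(1, 6):
            m = sec == p
            total = durations[m].sum()
            occ[p][i] = total
            if total <= 0:
                continue
            counts = np.zeros(core.size)
            for j, k in enumerate(core):
                spikes = session.spike_trains[k].in_interval(
                    iti.t_start, iti.t_end
                )
                frame = np.searchsorted(trk.times, spikes, side="right") - 1
                frame = frame[frame >= 0]  # spikes before the first sample
                counts[j] = m[frame].sum()
            rates[p][i] = counts / total
    return {
        p: {"rates": rates[p], "occupancy": occ[p],
            "iti_index": np.array([iv.index for iv in session.itis])}
        for p in range(1, 6)
    }


def feature_labels(session: Session, feature: str) -> list:
    """Per-ITI binary label of a task feature (None = no label: the last
    ITI has no following trial for next_* features)."""
    if feature not in FEATURES:
        raise ValueError(f"feature must be one of {FEATURES}")
    attr = {"outcome": "outcome", "arm": "arm", "cue": "cue"}[feature.split("_")[1]]
    vals = [getattr(t, attr) for t in session.trials]
    if feature.startswith("prior"):
        return [vals[iti.index - 1] for iti in session.itis]
    return [
        vals[iti.index] if iti.index < len(vals) else None
        for iti in session.itis
    ]


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def loocv_predictions(X: np.ndarray, y: np.ndarray, decoder: str) -> np.ndarray:
    """Leave-one-out predictions of the chosen linear decoder."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    preds = np.empty(n, dtype=y.dtype)
    for i in range(n):
        m = np.ones(n, dtype=bool)
        m[i] = False
        clf = _make_decoder(decoder)
        clf.fit(X[m], y[m])
        preds[i] = clf.predict(X[i : i + 1])[0]
    return preds


def decode_feature(X, y, decoder: str = "logistic") -> float:
    """LOOCV accuracy of a linear decoder on firing-rate vectors.

    Requires two classes with at least 2 examples each (one session in
    the source data had to be excluded because the animal always chose
    the same arm, leaving a single class).
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class; cannot decode")
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 examples")
    return float((loocv_predictions(X, y, decoder) == y).mean())


def chance_distribution(
    X, y, decoder: str = "logistic", n_shuffles: int = 50, rng=None
) -> np.ndarray:
    """LOOCV accuracies with labels shuffled across ITIs."""
    rng = np.random.default_rng(rng)
    y = np.asarray(y)
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        out[s] = decode_feature(X, rng.permutation(y), decoder)
    return out


@dataclass
class SectionDecoding:
    section: int
    n_examples: int
    accuracy: float
    chance: np.ndarray
    relative: float


@dataclass
class DecodingResult:
    feature: str
    decoder: str
    sections: dict = field(default_factory=dict)  # section id -> SectionDecoding


def decode_session(
    session: Session,
    core,
    feature: str,
    decoder: str = "logistic",
    n_shuffles: int = 50,
    seed=None,
    rates=None,
) -> DecodingResult:
    """Per-section LOOCV decoding of one task feature with shuffled-label
    chance. `rates` (from rate_vectors) may be passed to reuse across
    features and decoders."""
    rng = np.random.default_rng(seed)
    if rates is None:
        rates = rate_vectors(session, core)
    labels = feature_labels(session, feature)
    result = DecodingResult(feature, decoder)
    for p, entry in rates.items():
        valid = np.array(
            [
                lab is not None and np.isfinite(entry["rates"][i]).all()
                for i, lab in enumerate(labels)
            ]
        )
        y = np.array([l for l, v in zip(labels, valid) if v])
        X = entry["rates"][valid]
        classes, counts = (
            np.unique(y, return_counts=True) if y.size else (np.array([]), np.array([]))
        )
        if classes.size < 2 or counts.min() < 2:
            warnings.warn(
                f"section {p}: feature {feature!r} degenerate; skipped",
                stacklevel=2,
            )
            continue
        acc = decode_feature(X, y, decoder)
        chance = chance_distribution(X, y, decoder, n_shuffles, rng)
        result.sections[p] = SectionDecoding(
            p, int(valid.sum()), acc, chance, acc - float(chance.mean())
        )
    return result


def single_neuron_tuning(rates, labels, alpha: float = 0.05):
    """Per-neuron KS test of rate differences between the two label groups
    at one maze position; tuned iff p < alpha. Neurons that cannot be
    tested (a group with < 2 rates) are skipped with a warning."""
    rates = np.asarray(rates, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("need exactly two label groups")
    g1 = labels == groups[0]
    tuned = np.zeros(rates.shape[1], dtype=bool)
    pvals = np.ones(rates.shape[1])
    for j in range(rates.shape[1]):
        a, b = rates[g1, j], rates[~g1, j]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if min(a.size, b.size) < 2:
            warnings.warn(f"neuron column {j}: degenerate groups; skipped",
                          stacklevel=2)
            continue
        pvals[j] = stats.ks_2samp(a, b).pvalue
        tuned[j] = pvals[j] < alpha
    return tuned, pvals
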