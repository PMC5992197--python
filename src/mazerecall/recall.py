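"""Ensemble co-activity recall analysis.

The pipeline, per session:

1. select the core population — neurons active in every inter-trial
   interval (ITI);
2. convolve each spike train with a Gaussian (sigma = 100 ms by default)
   to obtain spike-density functions, z-scored over all ITIs;
3. per ITI t, compute the pairwise similarity matrix S_t: the rectified
   Pearson correlation between neurons' densities (negatives set to 0);
4. per ITI pair (t, u), the recall value R(t, u): the rectified Pearson
   correlation between the upper-triangle vectors of S_t and S_u —
   collected into the recall matrix R;
5. the expected recall matrix is the mean of many recall matrices
   computed from inter-spike-interval-shuffled trains; the shuffle keeps
   each train's spike count and duration, so it isolates the bias that
   unequal ITI durations induce in similarity estimates;
6. the residual recall matrix (R minus expected) is what all group
   comparisons use: block means, their difference Delta_R, and a
   two-sample KS test between the blocks' value distributions.

A note on normalisation: the Pearson correlation within an interval is
invariant to any per-neuron affine transform, so the session-wide
z-scoring of densities cannot change a similarity matrix. The engine
therefore correlates raw densities directly; `zscore_over_itis` is
provided (and tested) as the explicit normalisation step for density
inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import maze
from .behaviour import path_lengths
from .session_model import Interval, Session, SpikeTrain

GROUPINGS = ("prior_outcome", "prior_arm", "prior_cue", "next_outcome", "path_length")

_SQRT2PI = np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# core population and spike densities
# ---------------------------------------------------------------------------

def core_population(
    session: Session, intervals=None, min_spikes: int = 1
) -> np.ndarray:
    """Indices (into session.spike_trains) of neurons with at least
    `min_spikes` spikes in every interval (default: every ITI)."""
    intervals = session.itis if intervals is None else intervals
    keep = []
    for i, st in enumerate(session.spike_trains):
        if all(
            st.in_interval(iv.t_start, iv.t_end).size >= min_spikes
            for iv in intervals
        ):
            keep.append(i)
    if not keep:
        warnings.warn("core population is empty", stacklevel=2)
    return np.array(keep, dtype=int)


def _grid(interval, dt: float):
    """Uniform sample grid for an interval: t_start + k*dt, k=0..n-1."""
    n = int(np.floor((interval.t_end - interval.t_start) / dt))
    return interval.t_start, n


try:  # jitted hot loop; the numpy path below is the reference fallback
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _accumulate_kernels_numpy(out, rel, dt, sigma, half, n_grid):
    S, n_sp = rel.shape
    m = np.floor(rel).astype(np.int64)
    offs = np.arange(-half, half + 1, dtype=np.int64)
    idx = m[:, :, None] + offs  # (S, n_sp, w)
    dev = (idx - rel[:, :, None]) * dt
    val = np.exp(-(dev * dev) / (2.0 * sigma * sigma))
    valid = (idx >= 0) & (idx < n_grid)
    flat = (np.arange(S)[:, None, None] * n_grid + idx)[valid]
    out += np.bincount(
        flat, weights=val[valid], minlength=S * n_grid
    ).reshape(S, n_grid)


if _njit is not None:

    @_njit(cache=False, fastmath=True)
    def _accumulate_kernels(out, rel, dt, sigma, half, n_grid):  # pragma: no cover
        inv = 1.0 / (2.0 * sigma * sigma)
        for s in range(rel.shape[0]):
            for p in range(rel.shape[1]):
                r = rel[s, p]
                m = int(np.floor(r))
                lo = m - half if m - half > 0 else 0
                hi = m + half if m + half < n_grid - 1 else n_grid - 1
                for j in range(lo, hi + 1):
                    d = (j - r) * dt
                    out[s, j] += np.exp(-d * d * inv)

else:  # pragma: no cover
    _accumulate_kernels = _accumulate_kernels_numpy


def _gauss_density(spike_times, t0, n_grid, dt, sigma, cutoff=6.0):
    """Sum of Gaussian kernels centred on spikes, on the interval grid.

    `spike_times` is (n_spikes,) or (n_shuffles, n_spikes); returns
    (n_grid,) or (n_shuffles, n_grid). Kernels are truncated at
    `cutoff` standard deviations (relative error < 2e-8 at the default).
    """
    t = np.atleast_2d(np.asarray(spike_times, dtype=float))
    S, n_sp = t.shape
    out = np.zeros((S, n_grid))
    if n_sp:
        half = int(np.ceil(cutoff * sigma / dt))
        rel = np.ascontiguousarray((t - t0) / dt)  # spike pos in grid units
        _accumulate_kernels(out, rel, dt, sigma, half, n_grid)
        out /= sigma * _SQRT2PI
    return out if np.ndim(spike_times) == 2 else out[0]


@dataclass
class SpikeDensity:
    """A neuron's Gaussian spike-density function on one interval grid."""

    neuron_id: int
    sample_times: np.ndarray
    values: np.ndarray
    sigma: float


def spike_density(
    train: SpikeTrain, interval: Interval, sigma: float, dt: float
) -> SpikeDensity:
    """Gaussian spike-density function of one neuron within an interval
    (pre-normalisation). Requires dt <= sigma/5 for adequate sampling."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if dt > sigma / 5:
        raise ValueError("dt must be <= sigma/5")
    t0, n = _grid(interval, dt)
    spikes = train.in_interval(interval.t_start, interval.t_end)
    values = _gauss_density(spikes, t0, n, dt, sigma)
    return SpikeDensity(train.neuron_id, t0 + dt * np.arange(n), values, sigma)


def zscore_over_itis(per_neuron: dict) -> dict:
    """Z-score each neuron's densities with mean/SD pooled over all ITIs.

    `per_neuron` maps neuron id -> sequence of SpikeDensity (one per
    ITI). Raises if a neuron's pooled variance is zero.
    """
    out = {}
    for nid, dens in per_neuron.items():
        pooled = np.concatenate([d.values for d in dens])
        mu = pooled.mean()
        sd = pooled.std()
        if sd == 0:
            raise ValueError(f"neuron {nid}: zero pooled variance across ITIs")
        out[nid] = [
            SpikeDensity(d.neuron_id, d.sample_times, (d.values - mu) / sd, d.sigma)
            for d in dens
        ]
    return out


# ---------------------------------------------------------------------------
# similarity and recall
# ---------------------------------------------------------------------------

def similarity_matrix(densities) -> np.ndarray:
    """Rectified pairwise Pearson correlation between neurons' density
    functions within one interval.

    `densities` is (N, n_samples) (rows may be SpikeDensity values).
    Entries for neurons constant within the interval are set to 0,
    keeping the matrix dimension constant across intervals.
    """
    if isinstance(densities, (list, tuple)) and isinstance(
        densities[0], SpikeDensity
    ):
        densities = np.vstack([d.values for d in densities])
    D = np.asarray(densities, dtype=float)
    if D.ndim != 2 or D.shape[0] < 2:
        raise ValueError("need >= 2 neurons")
    if D.shape[1] < 2:
        raise ValueError("need >= 2 grid samples")
    return _similarity_batch(D[None])[0]


def _similarity_batch(D: np.ndarray) -> np.ndarray:
    """Rectified correlation matrices for a (S, N, G) density stack."""
    Dc = D - D.mean(axis=2, keepdims=True)
    cov = np.einsum("sng,smg->snm", Dc, Dc, optimize=True)
    norm = np.sqrt(np.einsum("snn->sn", cov))
    denom = norm[:, :, None] * norm[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    C = np.clip(C, 0.0, 1.0)  # rectify; clip fp overshoot above 1
    # diagonal: 1 where the neuron varies within the interval, else 0
    S, N, _ = C.shape
    diag = (norm > 0).astype(float)
    C[:, np.arange(N), np.arange(N)] = diag
    return C


def recall_value(S_t: np.ndarray, S_u: np.ndarray) -> float:
    """Rectified Pearson correlation between the upper-triangle vectors
    of two similarity matrices. Constant vectors give 0 with a warning."""
    S_t = np.asarray(S_t, dtype=float)
    S_u = np.asarray(S_u, dtype=float)
    if S_t.shape != S_u.shape:
        raise ValueError("similarity matrices differ in shape")
    n = S_t.shape[0]
    if n < 3:
        raise ValueError("need >= 3 neurons (>= 3 upper-triangle entries)")
    iu = np.triu_indices(n, k=1)
    v, w = S_t[iu], S_u[iu]
    if np.ptp(v) == 0 or np.ptp(w) == 0:
        warnings.warn("constant upper-triangle vector; recall set to 0",
                      stacklevel=2)
        return 0.0
    r = np.corrcoef(v, w)[0, 1]
    return float(min(max(r, 0.0), 1.0))


def _recall_from_vectors(V: np.ndarray) -> np.ndarray:
    """Recall matrices from upper-triangle vectors, batched.

    V is (S, T, P): S shuffle replicates, T intervals, P pair entries.
    Returns (S, T, T) rectified correlation matrices with unit diagonal
    (0 where a vector is constant).
    """
    Vc = V - V.mean(axis=2, keepdims=True)
    norm = np.linalg.norm(Vc, axis=2)
    cov = np.einsum("stp,sup->stu", Vc, Vc, optimize=True)
    denom = norm[:, :, None] * norm[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    R = np.clip(R, 0.0, 1.0)
    T = R.shape[1]
    R[:, np.arange(T), np.arange(T)] = (norm > 0).astype(float)
    return R


def _interval_spikes(session, intervals, core):
    """Spike-time arrays per (interval, core neuron)."""
    return [
        [session.spike_trains[k].in_interval(iv.t_start, iv.t_end) for k in core]
        for iv in intervals
    ]


def _pair_vectors_data(spikes_per_iv, intervals, sigma, dt):
    """Upper-triangle similarity vectors for the recorded spike trains."""
    vecs = []
    for iv, spikes in zip(intervals, spikes_per_iv):
        t0, n = _grid(iv, dt)
        D = np.vstack([_gauss_density(s, t0, n, dt, sigma) for s in spikes])
        S = _similarity_batch(D[None])[0]
        iu = np.triu_indices(len(spikes), k=1)
        vecs.append(S[iu])
    return np.asarray(vecs)


def recall_matrix(
    session: Session,
    sigma: float = 0.1,
    dt: float = 0.01,
    intervals=None,
    core=None,
) -> np.ndarray:
    """The raw recall matrix R over all interval pairs (default: ITIs)."""
    intervals = session.itis if intervals is None else intervals
    core = core_population(session, intervals) if core is None else np.asarray(core)
    if core.size < 3:
        raise ValueError("core population must have >= 3 neurons")
    spikes = _interval_spikes(session, intervals, core)
    V = _pair_vectors_data(spikes, intervals, sigma, dt)
    return _recall_from_vectors(V[None])[0]


def shuffle_isi(times, interval: Interval, rng: np.random.Generator) -> np.ndarray:
    """ISI-shuffle the spikes of one train within an interval.

    The first spike keeps its offset from the interval start and the
    inter-spike intervals are permuted uniformly, so spike count and
    span are preserved and all spikes stay inside the interval.
    """
    if isinstance(times, SpikeTrain):
        times = times.in_interval(interval.t_start, interval.t_end)
    times = np.asarray(times, dtype=float)
    if times.size <= 2:
        return times.copy()
    isis = np.diff(times)
    return times[0] + np.concatenate(([0.0], np.cumsum(rng.permutation(isis))))


def _shuffled_spike_stack(times, n_shuffles, rng):
    """(n_shuffles, n_spikes) ISI-shuffled copies of one train."""
    times = np.asarray(times, dtype=float)
    if times.size <= 2:
        return np.tile(times, (n_shuffles, 1))
    isis = np.tile(np.diff(times), (n_shuffles, 1))
    isis = rng.permuted(isis, axis=1)
    out = np.empty((n_shuffles, times.size))
    out[:, 0] = times[0]
    np.cumsum(isis, axis=1, out=isis)
    out[:, 1:] = times[0] + isis
    return out


_CHUNK_ELEMS = 4_000_000  # cap on the (shuffles x spikes x kernel) workspace


def _pair_vectors_shuffled(spikes_per_iv, intervals, sigma, dt, n_shuffles, rng):
    """Upper-triangle vectors for ISI-shuffled trains: (S, T, P)."""
    cutoff = 6.0
    w = 2 * int(np.ceil(cutoff * sigma / dt)) + 1
    T = len(intervals)
    N = len(spikes_per_iv[0])
    iu = np.triu_indices(N, k=1)
    V = np.empty((n_shuffles, T, len(iu[0])))
    for t, (iv, spikes) in enumerate(zip(intervals, spikes_per_iv)):
        t0, n = _grid(iv, dt)
        D = np.empty((n_shuffles, N, n))
        for k, s in enumerate(spikes):
            stack = _shuffled_spike_stack(s, n_shuffles, rng)
            chunk = max(1, int(_CHUNK_ELEMS / max(1, s.size * w)))
            for i0 in range(0, n_shuffles, chunk):
                D[i0 : i0 + chunk, k] = _gauss_density(
                    stack[i0 : i0 + chunk], t0, n, dt, sigma, cutoff
                )
        Smats = _similarity_batch(D)
        V[:, t, :] = Smats[:, iu[0], iu[1]]
    return V


def expected_recall_matrix(
    session: Session,
    sigma: float = 0.1,
    dt: float = 0.01,
    n_shuffles: int = 1000,
    rng=None,
    intervals=None,
    core=None,
) -> np.ndarray:
    """Mean recall matrix over `n_shuffles` ISI-shuffled surrogates —
    the duration-only null for the recall matrix."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(rng)
    intervals = session.itis if intervals is None else intervals
    core = core_population(session, intervals) if core is None else np.asarray(core)
    if core.size < 3:
        raise ValueError("core population must have >= 3 neurons")
    spikes = _interval_spikes(session, intervals, core)
    V = _pair_vectors_shuffled(spikes, intervals, sigma, dt, n_shuffles, rng)
    return _recall_from_vectors(V).mean(axis=0)


def residual_recall(raw: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Residual recall matrix: raw minus shuffle-expected, in [-1, 1]."""
    raw = np.asarray(raw, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if raw.shape != expected.shape:
        raise ValueError("matrix shapes differ")
    return raw - expected


@dataclass
class RecallResult:
    raw: np.ndarray
    expected: np.ndarray
    residual: np.ndarray
    core_neurons: np.ndarray
    interval_indices: np.ndarray
    sigma: float
    dt: float
    n_shuffles: int


def recall_analysis(
    session: Session,
    sigma: float = 0.1,
    dt: float = 0.01,
    n_shuffles: int = 1000,
    seed=None,
    intervals=None,
) -> RecallResult:
    """Raw, expected, and residual recall matrices for a session."""
    intervals = session.itis if intervals is None else intervals
    core = core_population(session, intervals)
    raw = recall_matrix(session, sigma, dt, intervals, core)
    exp = expected_recall_matrix(
        session, sigma, dt, n_shuffles, np.random.default_rng(seed), intervals, core
    )
    return RecallResult(
        raw,
        exp,
        residual_recall(raw, exp),
        core,
        np.array([iv.index for iv in intervals]),
        sigma,
        dt,
        n_shuffles,
    )


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class BlockComparison:
    grouping: str
    block1: str
    block2: str
    mean_block1: float
    mean_block2: float
    ks_stat: float
    ks_p: float
    n1: int
    n2: int

    @property
    def delta(self) -> float:
        return self.mean_block1 - self.mean_block2


#: block1 (minuend) per grouping, so Delta_R has a canonical sign
_BLOCK1 = {
    "prior_outcome": "correct",
    "next_outcome": "correct",
    "prior_arm": "left",
    "prior_cue": "left",
    "path_length": "short",
}


def label_itis(session: Session, grouping: str):
    """Per-ITI group labels (None = excluded from the grouping).

    prior_* labels come from trial t, next_* from trial t+1 (last ITI
    excluded); path_length splits ITIs at the session median path length
    (group sizes differ by at most one).
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    n = len(session.itis)
    if grouping == "path_length":
        pl = path_lengths(session)
        order = np.argsort(pl, kind="stable")
        labels = np.empty(n, dtype=object)
        half = n // 2
        labels[order[:half]] = "short"
        labels[order[half:]] = "long"
        labels = list(labels)
    else:
        attr = grouping.split("_")[1]
        vals = [getattr(t, {"outcome": "outcome", "arm": "arm", "cue": "cue"}[attr])
                for t in session.trials]
        if grouping.startswith("prior"):
            labels = [vals[iti.index - 1] for iti in session.itis]
        else:
            labels = [
                vals[iti.index] if iti.index < len(vals) else None
                for iti in session.itis
            ]
    # NOTE: a degenerate labelling (one group) is legal here — e.g. the
    # next_outcome labels of a short all-correct stretch; block_compare
    # raises when asked to compare fewer than two groups.
    return labels


def _block_values(residual, idx, pair_counting):
    block = residual[np.ix_(idx, idx)]
    if pair_counting == "full":
        return block.ravel()
    iu = np.triu_indices(len(idx), k=1)
    return block[iu]


def block_compare(
    residual: np.ndarray,
    labels,
    grouping: str = "custom",
    block1: str | None = None,
    pair_counting: str = "offdiag",
) -> BlockComparison:
    """Compare residual recall between two groups of ITIs.

    Block values are the within-group interval pairs — by default the
    off-diagonal upper triangle of each group's block; `pair_counting=
    "full"` uses the complete block including the diagonal. Returns the
    block means, Delta_R (block1 - block2), and a two-sample KS test.
    """
    if pair_counting not in ("offdiag", "full"):
        raise ValueError("pair_counting must be 'offdiag' or 'full'")
    labels = list(labels)
    groups = sorted({l for l in labels if l is not None})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if block1 is None:
        block1 = _BLOCK1.get(grouping, groups[0])
    block2 = next(g for g in groups if g != block1)
    idx1 = [i for i, l in enumerate(labels) if l == block1]
    idx2 = [i for i, l in enumerate(labels) if l == block2]
    if min(len(idx1), len(idx2)) < 2:
        raise ValueError("each group needs >= 2 ITIs")
    v1 = _block_values(np.asarray(residual, float), idx1, pair_counting)
    v2 = _block_values(np.asarray(residual, float), idx2, pair_counting)
    ks = stats.ks_2samp(v1, v2, method="asymp")
    return BlockComparison(
        grouping,
        block1,
        block2,
        float(v1.mean()),
        float(v2.mean()),
        float(ks.statistic),
        float(ks.pvalue),
        len(v1),
        len(v2),
    )


def compare_groups(
    result_or_residual,
    session: Session,
    grouping: str,
    pair_counting: str = "offdiag",
) -> BlockComparison:
    """label_itis + block_compare in one call."""
    residual = (
        result_or_residual.residual
        if isinstance(result_or_residual, RecallResult)
        else result_or_residual
    )
    return block_compare(
        residual, label_itis(session, grouping), grouping, None, pair_counting
    )


def session_permutation_test(
    deltas, target_ids, n_perm: int = 10_000, rng=None
) -> float:
    """Chance of drawing a subset (the size of `target_ids`) of sessions,
    without replacement, in which every drawn session has Delta_R > 0.

    Returns the Monte-Carlo probability (analytically C(k, m)/C(n, m)
    with k positive sessions out of n and draw size m).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    deltas = np.asarray(deltas, dtype=float)
    m = len(np.atleast_1d(target_ids))
    if m > deltas.size:
        raise ValueError("draw size exceeds number of sessions")
    pos = deltas > 0
    keys = rng.random((n_perm, deltas.size))
    draws = np.argpartition(keys, m - 1, axis=1)[:, :m]
    return float(np.all(pos[draws], axis=1).mean())


# ---------------------------------------------------------------------------
# reward-site vs return-trip split
# ---------------------------------------------------------------------------

def split_iti_activity(
    session: Session, mode: str, zone_radius_cm: float = 10.0
) -> list[Interval]:
    """Clip each ITI to the reward-site dwell or the return trip.

    The reward site is a disc of `zone_radius_cm` around the chosen
    goal-arm end. The reward-site sub-period runs from the ITI start to
    the first tracked exit from the zone; the return trip covers the
    remainder. ITIs with an empty sub-period are dropped with a warning.
    """
    if mode not in ("reward_site", "return_trip"):
        raise ValueError("mode must be 'reward_site' or 'return_trip'")
    out = []
    for iti in session.itis:
        trial = session.trials[iti.index - 1]
        goal = maze.ARM_ENDS[trial.arm]
        trk = session.tracking.slice(iti.t_start, iti.t_end)
        if len(trk) == 0:
            warnings.warn(f"ITI {iti.index}: no tracking samples; dropped",
                          stacklevel=2)
            continue
        inside = np.hypot(trk.x - goal[0], trk.y - goal[1]) < zone_radius_cm
        if not inside.any():
            if mode == "reward_site":
                warnings.warn(
                    f"ITI {iti.index}: empty reward-site period; dropped",
                    stacklevel=2,
                )
                continue
            out.append(iti)  # whole ITI is return trip
            continue
        first_in = int(np.argmax(inside))
        after = np.nonzero(~inside[first_in:])[0]
        t_exit = trk.times[first_in + after[0]] if after.size else iti.t_end
        if mode == "reward_site":
            if t_exit > iti.t_start:
                out.append(Interval(iti.index, iti.t_start, t_exit))
            else:
                warnings.warn(
                    f"ITI {iti.index}: empty reward-site period; dropped",
                    stacklevel=2,
                )
        else:
            if t_exit < iti.t_end:
                out.append(Interval(iti.index, t_exit, iti.t_end))
            else:
                warnings.warn(
                    f"ITI {iti.index}: empty return-trip period; dropped",
                    stacklevel=2,
                )
    return out
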