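"""Domain types and delimited-file I/O for Y-maze recording sessions.

A session is the unit of analysis: a set of spike trains, a trial table,
the inter-trial intervals (ITIs) derived from consecutive trial boundaries,
and 30 Hz position tracking. Times are seconds; all intervals are half-open
[start, end) so boundary spikes are never double-counted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ARMS = ("left", "right")
OUTCOMES = ("correct", "error")
RULES = ("go_right", "go_cued", "go_left", "go_uncued")

#: rules rewarding a fixed arm vs. rules rewarding relative to the light cue
DIRECTION_RULES = ("go_right", "go_left")
CUE_RULES = ("go_cued", "go_uncued")

TIME_DECIMALS = 4  # 0.1 ms resolution


class SessionValidationError(ValueError):
    """A session (or one of its files) violates a structural invariant."""


@dataclass
class SpikeTrain:
    """One neuron's spike times, in seconds, strictly increasing."""

    neuron_id: int
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise SessionValidationError(
                f"neuron {self.neuron_id}: spike times must be a 1-d sequence"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise SessionValidationError(
                f"neuron {self.neuron_id}: spike times not strictly increasing"
            )
        if self.times.size and self.times[0] < 0:
            raise SessionValidationError(
                f"neuron {self.neuron_id}: negative spike time"
            )

    def in_interval(self, t_start: float, t_end: float) -> np.ndarray:
        """Spike times within the half-open window [t_start, t_end)."""
        i0, i1 = np.searchsorted(self.times, [t_start, t_end], side="left")
        return self.times[i0:i1]

    def __eq__(self, other):
        return (
            isinstance(other, SpikeTrain)
            and self.neuron_id == other.neuron_id
            and self.times.shape == other.times.shape
            and np.array_equal(self.times, other.times)
        )


@dataclass(frozen=True)
class Trial:
    """One maze traversal from departure-arm start to chosen goal-arm end."""

    index: int  # 1-based
    t_start: float
    t_end: float
    arm: str
    cue: str
    outcome: str
    rule: str

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise SessionValidationError(
                f"trial {self.index}: t_start must be < t_end"
            )
        for name, value, allowed in (
            ("arm", self.arm, ARMS),
            ("cue", self.cue, ARMS),
            ("outcome", self.outcome, OUTCOMES),
            ("rule", self.rule, RULES),
        ):
            if value not in allowed:
                raise SessionValidationError(
                    f"trial {self.index}: {name}={value!r} not in {allowed}"
                )


@dataclass(frozen=True)
class Interval:
    """A half-open analysis window [t_start, t_end), 1-based index.

    ITI t runs from the end of trial t to the start of trial t+1 (the last
    ITI runs to the final tracked timestamp).
    """

    index: int
    t_start: float
    t_end: float

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise SessionValidationError(
                f"interval {self.index}: non-positive duration"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class Tracking:
    """Position samples at a nominal 30 Hz: timestamps (s), x, y (cm)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.times.shape == self.x.shape == self.y.shape):
            raise SessionValidationError("tracking vectors differ in length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise SessionValidationError("tracking timestamps not increasing")

    def slice(self, t_start: float, t_end: float) -> "Tracking":
        """Samples with t_start <= time < t_end."""
        m = (self.times >= t_start) & (self.times < t_end)
        return Tracking(self.times[m], self.x[m], self.y[m])

    def __len__(self):
        return self.times.size

    def __eq__(self, other):
        return (
            isinstance(other, Tracking)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )


@dataclass
class Session:
    """One recording session: spikes, trials, derived ITIs, and tracking."""

    spike_trains: list[SpikeTrain]
    trials: list[Trial]
    tracking: Tracking
    itis: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        if not self.spike_trains:
            raise SessionValidationError("session has no neurons")
        if not self.trials:
            raise SessionValidationError("session has no trials")
        ids = [st.neuron_id for st in self.spike_trains]
        if len(set(ids)) != len(ids):
            raise SessionValidationError("duplicate neuron ids")
        for a, b in zip(self.trials[:-1], self.trials[1:]):
            if b.t_start < a.t_end:
                raise SessionValidationError(
                    f"trials {a.index} and {b.index} overlap"
                )
        if not self.itis:
            self.itis = build_itis(self.trials, self.tracking)

    # -- convenience ------------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return len(self.spike_trains)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def rule_type(self) -> str:
        """'direction' or 'cue', from the (session-constant) rule."""
        return "direction" if self.trials[0].rule in DIRECTION_RULES else "cue"

    def outcomes(self) -> np.ndarray:
        return np.array([t.outcome for t in self.trials])

    def __eq__(self, other):
        return (
            isinstance(other, Session)
            and self.spike_trains == other.spike_trains
            and self.trials == other.trials
            and self.tracking == other.tracking
            and self.itis == other.itis
        )


def build_itis(trials: list[Trial], tracking: Tracking) -> list[Interval]:
    """ITIs between consecutive trial boundaries.

    ITI t spans [end of trial t, start of trial t+1); the last ITI runs to
    the final tracked timestamp (the recording continues through the return
    to the start arm). If tracking does not extend past the last trial, the
    last ITI is omitted.
    """
    itis = []
    for t, (a, b) in enumerate(zip(trials[:-1], trials[1:]), start=1):
        itis.append(Interval(t, a.t_end, b.t_start))
    last = trials[-1]
    if len(tracking) and tracking.times[-1] > last.t_end:
        itis.append(Interval(len(trials), last.t_end, tracking.times[-1]))
    return itis


# ---------------------------------------------------------------------------
# Delimited-file schema
#
#   spikes.csv:   neuron_id,time_s
#   events.csv:   trial,t_start_s,t_end_s,arm,cue,outcome,rule
#   tracking.csv: time_s,x_cm,y_cm
# ---------------------------------------------------------------------------

SPIKES_FILE = "spikes.csv"
EVENTS_FILE = "events.csv"
TRACKING_FILE = "tracking.csv"


def _read_table(path, columns, numeric):
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise SessionValidationError(f"{path}: cannot parse ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SessionValidationError(f"{path}: missing columns {missing}")
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if df[col].isna().any():
            bad = np.union1d(bad, np.nonzero(df[col].isna().to_numpy())[0])
        if bad.size:
            # +2: header line plus 1-based numbering
            raise SessionValidationError(
                f"{path}: malformed value in column {col!r} at line {bad[0] + 2}"
            )
        df[col] = vals
    return df


def read_session(spikes_path, events_path, tracking_path) -> Session:
    """Read and validate a session from its three delimited files."""
    sp = _read_table(spikes_path, ["neuron_id", "time_s"], ["neuron_id", "time_s"])
    ev = _read_table(
        events_path,
        ["trial", "t_start_s", "t_end_s", "arm", "cue", "outcome", "rule"],
        ["trial", "t_start_s", "t_end_s"],
    )
    tr = _read_table(
        tracking_path, ["time_s", "x_cm", "y_cm"], ["time_s", "x_cm", "y_cm"]
    )

    trains = []
    for nid, grp in sp.groupby("neuron_id", sort=True):
        times = grp["time_s"].to_numpy()
        if times.size > 1 and np.any(np.diff(times) <= 0):
            j = int(np.nonzero(np.diff(times) <= 0)[0][0])
            line = int(grp.index[j + 1]) + 2
            raise SessionValidationError(
                f"{spikes_path}: spike times for neuron {int(nid)} "
                f"not strictly increasing at line {line}"
            )
        trains.append(SpikeTrain(int(nid), times))

    ev = ev.sort_values("trial")
    trials = [
        Trial(
            int(r.trial),
            float(r.t_start_s),
            float(r.t_end_s),
            str(r.arm),
            str(r.cue),
            str(r.outcome),
            str(r.rule),
        )
        for r in ev.itertuples()
    ]
    tracking = Tracking(
        tr["time_s"].to_numpy(), tr["x_cm"].to_numpy(), tr["y_cm"].to_numpy()
    )
    return Session(trains, trials, tracking)


def read_session_dir(session_dir) -> Session:
    d = str(session_dir)
    return read_session(
        os.path.join(d, SPIKES_FILE),
        os.path.join(d, EVENTS_FILE),
        os.path.join(d, TRACKING_FILE),
    )


def write_session(session: Session, out_dir) -> dict:
    """Write a session to its three delimited files (0.1 ms time precision).

    Returns the mapping of file roles to paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "spikes": os.path.join(out_dir, SPIKES_FILE),
        "events": os.path.join(out_dir, EVENTS_FILE),
        "tracking": os.path.join(out_dir, TRACKING_FILE),
    }
    with open(paths["spikes"], "w") as fh:
        fh.write("neuron_id,time_s\n")
        for st in session.spike_trains:
            for t in st.times:
                fh.write(f"{st.neuron_id},{t:.4f}\n")
    with open(paths["events"], "w") as fh:
        fh.write("trial,t_start_s,t_end_s,arm,cue,outcome,rule\n")
        for t in session.trials:
            fh.write(
                f"{t.index},{t.t_start:.4f},{t.t_end:.4f},"
                f"{t.arm},{t.cue},{t.outcome},{t.rule}\n"
            )
    with open(paths["tracking"], "w") as fh:
        fh.write("time_s,x_cm,y_cm\n")
        trk = session.tracking
        for t, x, y in zip(trk.times, trk.x, trk.y):
            fh.write(f"{t:.4f},{x:.3f},{y:.3f}\n")
    return paths
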