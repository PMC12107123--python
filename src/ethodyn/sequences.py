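"""Core data model for discrete behavioral sequences.

A behavioral sequence is a uniform time-windowed series of categorical state
labels for one individual (e.g. ``foraging``/``vigilance``/``running`` at 1 s
resolution). Bouts are maximal runs of a single state; their durations are the
survival times analyzed by the hazard and distribution-fitting modules.
Recording gaps (e.g. daily 3 h collar-on blocks) are represented as segment
breaks: bouts and transition pairs never span a break, so gaps cannot create
fictitious long bouts or spurious transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BehavioralSequence",
    "Bout",
    "TransitionModel",
    "read_sequence",
    "extract_bouts",
    "fit_transitions",
    "generate_pseudosequence",
]


@dataclass
class BehavioralSequence:
    """Uniform time-windowed categorical state series for one individual.

    Parameters
    ----------
    individual_id : str
        Identifier of the animal/agent.
    window_seconds : float
        Duration of one time window in seconds (1 s or 3 s in typical
        collar deployments).
    states : ndarray of object/str
        One state label per window.
    alphabet : tuple of str
        Permitted labels. Defaults to the sorted set of observed labels.
    segment_breaks : tuple of int
        Sorted window indices where a recording gap *begins*; the window at
        each break index starts a new contiguous segment. All indices lie in
        ``[1, len)``.
    """

    individual_id: str
    window_seconds: float
    states: np.ndarray
    alphabet: tuple = ()
    segment_breaks: tuple = ()

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=object)
        if self.states.size < 1:
            raise ValueError("sequence must contain at least one window")
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if not self.alphabet:
            self.alphabet = tuple(sorted(set(self.states.tolist())))
        else:
            self.alphabet = tuple(self.alphabet)
        unknown = set(self.states.tolist()) - set(self.alphabet)
        if unknown:
            raise ValueError(f"states outside alphabet: {sorted(unknown)}")
        br = tuple(int(b) for b in self.segment_breaks)
        if any(b2 <= b1 for b1, b2 in zip(br, br[1:])):
            raise ValueError("segment_breaks must be strictly increasing")
        if br and (br[0] < 1 or br[-1] >= len(self.states)):
            raise ValueError("segment_breaks must lie in [1, len)")
        self.segment_breaks = br

    def __len__(self) -> int:
        return len(self.states)

    @property
    def segments(self) -> list[tuple[int, int]]:
        """Half-open ``[start, stop)`` window ranges of contiguous recording."""
        edges = [0, *self.segment_breaks, len(self.states)]
        return [(a, b) for a, b in zip(edges[:-1], edges[1:])]

    def state_codes(self) -> np.ndarray:
        """Integer-coded states (alphabet order), for fast numerics."""
        lut = {s: i for i, s in enumerate(self.alphabet)}
        return np.fromiter((lut[s] for s in self.states), dtype=np.int64,
                           count=len(self.states))


@dataclass(frozen=True)
class Bout:
    """One maximal run of a single state.

    ``duration`` counts windows; the run occupies the half-open window
    interval ``[start_index, start_index + duration)`` and never crosses a
    segment break. ``boundary_truncated`` marks runs abutting a sequence end
    or a recording gap, whose true duration is right-censored.
    """

    state: str
    start_index: int
    duration: int
    boundary_truncated: bool = False

    def __post_init__(self):
        if self.duration < 1:
            raise ValueError("duration must be >= 1")


@dataclass
class TransitionModel:
    """First-order transition counts and row-stochastic probabilities."""

    alphabet: tuple
    counts: np.ndarray
    probabilities: np.ndarray = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        rows = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            p = self.counts / rows
        p[rows[:, 0] == 0] = 0.0
        self.probabilities = p


def read_sequence(path, window_seconds: float,
                  individual_id: str | None = None) -> BehavioralSequence:
    """Read a behavioral sequence from a two-column CSV.

    Accepted layouts: header ``time,state`` (ISO timestamps or numeric
    seconds) or ``index,state`` (integer window index). Any time gap larger
    than ``window_seconds`` (or an index jump larger than 1) inserts a
    segment break.
    """
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"empty sequence file: {path}")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "state" not in cols or not ({"time", "index"} & set(cols)):
        raise ValueError(
            f"unknown column layout {cols!r}; expected (time|index, state)")
    states = df["state"].astype(str).to_numpy()
    if "time" in cols:
        t = df["time"]
        if t.dtype == object:
            t = pd.to_datetime(t)
            dt = t.diff().dt.total_seconds().to_numpy()
        else:
            dt = t.diff().to_numpy(dtype=float)
        gap = window_seconds
    else:
        dt = df["index"].diff().to_numpy(dtype=float)
        gap = 1.0
    if np.any(dt[1:] <= 0):
        raise ValueError("time/index column must be strictly increasing")
    # a step of more than one window means recording stopped in between
    breaks = tuple(np.nonzero(dt[1:] > gap * 1.5)[0] + 1)
    return BehavioralSequence(
        individual_id=individual_id or str(path),
        window_seconds=window_seconds,
        states=states,
        segment_breaks=breaks,
    )


def _runs(codes: np.ndarray, start: int, stop: int):
    """Yield (code, run_start, run_len) over maximal runs of codes[start:stop]."""
    seg = codes[start:stop]
    if seg.size == 0:
        return
    change = np.nonzero(seg[1:] != seg[:-1])[0] + 1
    edges = np.concatenate([[0], change, [seg.size]])
    for a, b in zip(edges[:-1], edges[1:]):
        yield seg[a], start + a, b - a


def extract_bouts(seq: BehavioralSequence, min_duration: int = 2,
                  include_truncated: bool = True) -> dict[str, list[Bout]]:
    """Extract maximal same-state runs per state.

    Runs shorter than ``min_duration`` are discarded from the output (they
    still occupy the timeline). Runs touching a sequence end or a segment
    break are flagged ``boundary_truncated`` and kept unless
    ``include_truncated=False``.
    """
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    codes = seq.state_codes()
    out: dict[str, list[Bout]] = {s: [] for s in seq.alphabet}
    for a, b in seq.segments:
        for code, start, dur in _runs(codes, a, b):
            trunc = (start == a) or (start + dur == b)
            if dur < min_duration:
                continue
            if trunc and not include_truncated:
                continue
            out[seq.alphabet[code]].append(
                Bout(seq.alphabet[code], int(start), int(dur), trunc))
    return out


def bout_durations(seq: BehavioralSequence, state: str | None = None,
                   min_duration: int = 2) -> np.ndarray:
    """Convenience: integer durations of extracted bouts (one state or all)."""
    bouts = extract_bouts(seq, min_duration=min_duration)
    if state is not None:
        return np.array([b.duration for b in bouts[state]], dtype=np.int64)
    return np.array([b.duration for bs in bouts.values() for b in bs],
                    dtype=np.int64)


def fit_transitions(seq: BehavioralSequence) -> TransitionModel:
    """Tally first-order transitions within segments and row-normalize."""
    codes = seq.state_codes()
    k = len(seq.alphabet)
    counts = np.zeros((k, k), dtype=np.int64)
    npairs = 0
    for a, b in seq.segments:
        if b - a < 2:
            continue
        src, dst = codes[a:b - 1], codes[a + 1:b]
        np.add.at(counts, (src, dst), 1)
        npairs += b - a - 1
    if npairs == 0:
        raise ValueError("no transitions observable (all segments singleton)")
    return TransitionModel(seq.alphabet, counts)


def generate_pseudosequence(seq: BehavioralSequence, n_replicates: int = 30,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None,
                            ) -> list[BehavioralSequence]:
    """Markov surrogate sequences from the empirical transition structure.

    Each replicate preserves the length and segment structure of ``seq`` and
    starts each segment with the true segment's first state; every subsequent
    state is a categorical draw from the empirical successor distribution of
    the current state. Surrogates preserve instant-to-instant dynamics but
    destroy longer-timescale memory, making them null models with the same
    finite-size effects as the data.

    If a state with no observed successor is reached (possible only for the
    terminal state of the data), generation falls back to the successor pool
    of the most recent state that has successors, and logs the event.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tm = fit_transitions(seq)
    codes = seq.state_codes()
    k = len(seq.alphabet)
    has_succ = tm.counts.sum(axis=1) > 0
    # per-state inverse-CDF tables for O(1) categorical draws
    cdfs = np.cumsum(tm.probabilities, axis=1)
    reps = []
    for r in range(n_replicates):
        out = np.empty(len(seq), dtype=np.int64)
        for a, b in seq.segments:
            out[a] = codes[a]
            cur = codes[a]
            last_ok = cur if has_succ[cur] else None
            u = rng.random(b - a - 1)
            for i in range(a + 1, b):
                if not has_succ[cur]:
                    logger.warning(
                        "state %r has no observed successor; restarting draw "
                        "from successor pool of %r",
                        seq.alphabet[cur],
                        None if last_ok is None else seq.alphabet[last_ok])
                    if last_ok is None:
                        raise ValueError("no state with observed successors")
                    cur = last_ok
                cur = int(np.searchsorted(cdfs[cur], u[i - a - 1],
                                          side="right"))
                cur = min(cur, k - 1)
                if has_succ[cur]:
                    last_ok = cur
                out[i] = cur
        labels = np.array(seq.alphabet, dtype=object)[out]
        reps.append(BehavioralSequence(
            individual_id=f"{seq.individual_id}#pseudo{r}",
            window_seconds=seq.window_seconds,
            states=labels,
            alphabet=seq.alphabet,
            segment_breaks=seq.segment_breaks,
        ))
    return reps
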