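"""Detrended fluctuation analysis of per-behavior indicator series.

For a focal behavior the sequence is turned into a +1/-1 indicator series;
DFA then quantifies long-range self-dependence: the series is mean-centered
and integrated, split into non-overlapping boxes of size s, a linear trend is
removed within each box, and the RMS residual F(s) is recorded. The scaling
exponent alpha_DFA is the log-log slope of F(s) against s: 0.5 for white
noise, ~1.0 for 1/f-like long memory, 1.5 for a random walk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sequences import BehavioralSequence

logger = logging.getLogger(__name__)

__all__ = ["binarize", "dfa_exponent", "DFAModel", "DFAResults"]


def binarize(seq: BehavioralSequence, focal: str) -> np.ndarray:
    """+1 where the animal is in ``focal``, -1 elsewhere.

    Segments are concatenated; recording gaps are ignored for DFA (logged).
    """
    if focal not in seq.alphabet:
        raise ValueError(f"{focal!r} not in alphabet {seq.alphabet}")
    if seq.segment_breaks:
        logger.warning("DFA concatenates across %d recording gaps",
                       len(seq.segment_breaks))
    return np.where(seq.states == focal, 1.0, -1.0)


def _box_sizes(n: int, n_sizes: int = 16) -> np.ndarray:
    hi = max(n // 10, 5)
    sizes = np.unique(np.rint(np.geomspace(4, hi, n_sizes)).astype(int))
    return sizes[sizes >= 4]


def _fluctuation(profile: np.ndarray, s: int) -> float:
    n_boxes = profile.size // s
    y = profile[:n_boxes * s].reshape(n_boxes, s)
    x = np.arange(s, dtype=float)
    x = x - x.mean()
    sxx = float(np.sum(x * x))
    slope = (y * x).sum(axis=1) / sxx
    resid = y - y.mean(axis=1, keepdims=True) - slope[:, None] * x
    return float(np.sqrt(np.mean(resid ** 2)))


class DFAModel:
    """DFA of a one-dimensional series (order-1 detrending, non-overlapping
    boxes, log-spaced box sizes from 4 to n/10)."""

    def __init__(self, series, box_sizes=None, state: str = ""):
        x = np.asarray(series, dtype=float)
        if x.size < 100:
            raise ValueError("series too short for DFA (need >= 100)")
        if np.ptp(x) == 0:
            raise ValueError("constant series has no fluctuations")
        self.series = x
        self.state = state
        self.box_sizes = (np.asarray(box_sizes, dtype=int)
                          if box_sizes is not None else _box_sizes(x.size))

    @classmethod
    def from_sequence(cls, seq: BehavioralSequence, focal: str, **kw):
        return cls(binarize(seq, focal), state=focal, **kw)

    def fit(self) -> "DFAResults":
        profile = np.cumsum(self.series - self.series.mean())
        F = np.array([_fluctuation(profile, int(s)) for s in self.box_sizes])
        ok = F > 0
        if ok.sum() < 2:
            raise ValueError("not enough valid box sizes")
        slope, intercept = np.polyfit(np.log(self.box_sizes[ok]),
                                      np.log(F[ok]), 1)
        return DFAResults(self.state, self.box_sizes, F, float(slope), self)


@dataclass
class DFAResults:
    state: str
    box_sizes: np.ndarray
    fluctuation: np.ndarray
    alpha: float
    model: DFAModel

    def summary(self) -> str:
        return (f"DFA{' — ' + self.state if self.state else ''}: "
                f"alpha_DFA={self.alpha:.3f} over box sizes "
                f"{self.box_sizes[0]}..{self.box_sizes[-1]} "
                f"(n={self.model.series.size})")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.loglog(self.box_sizes, self.fluctuation, "o")
        ax.set_xlabel("box size s")
        ax.set_ylabel("F(s)")
        ax.set_title(f"alpha_DFA = {self.alpha:.3f}")
        return ax


def dfa_exponent(series, box_sizes=None, state: str = "") -> DFAResults:
    """Functional wrapper: fit a :class:`DFAModel`."""
    return DFAModel(series, box_sizes=box_sizes, state=state).fit()
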