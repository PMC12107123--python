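"""Activity-level inference from raw triaxial accelerometry.

VeDBA (vectorial dynamic body acceleration) is the Euclidean norm of the
acceleration vector after removing its running-mean static (gravitational)
component; it is a standard biologging proxy for activity level. When VeDBA
is bimodal, a two-component Gaussian mixture on (log-)VeDBA defines an
activity threshold at the equal-posterior point between the components, and
each time window is labeled low- or high-activity. The resulting
two-state sequence feeds the downstream sequence analyses unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from sklearn.mixture import GaussianMixture

from .sequences import BehavioralSequence

__all__ = ["AccelerometerTrace", "ActivityTrace", "read_accelerometer",
           "compute_vedba", "window_vedba", "fit_activity_threshold",
           "label_activity"]


@dataclass
class AccelerometerTrace:
    """Raw triaxial accelerometer recording, channels in g."""

    individual_id: str
    sample_rate_hz: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self):
        for c in ("t", "ax", "ay", "az"):
            setattr(self, c, np.asarray(getattr(self, c), dtype=float))
        n = self.t.size
        if not (self.ax.size == self.ay.size == self.az.size == n):
            raise ValueError("channel lengths differ")
        if n >= 2:
            implied = (n - 1) / (self.t[-1] - self.t[0])
            if abs(implied - self.sample_rate_hz) > 0.01 * self.sample_rate_hz:
                raise ValueError(
                    f"time vector implies {implied:.3f} Hz, "
                    f"declared {self.sample_rate_hz} Hz")


@dataclass
class ActivityTrace:
    """Per-window mean VeDBA, optionally with threshold and labels."""

    window_seconds: float
    vedba: np.ndarray
    threshold: float | None = None
    labels: np.ndarray | None = None


def read_accelerometer(path, sample_rate_hz: float | None = None,
                       individual_id: str | None = None) -> AccelerometerTrace:
    """Read a ``time,ax,ay,az`` CSV (units g, time in seconds)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"time", "ax", "ay", "az"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    t = df["time"].to_numpy(dtype=float)
    if sample_rate_hz is None:
        sample_rate_hz = (len(t) - 1) / (t[-1] - t[0])
    return AccelerometerTrace(individual_id or str(path), sample_rate_hz, t,
                              df["ax"].to_numpy(), df["ay"].to_numpy(),
                              df["az"].to_numpy())


def compute_vedba(trace: AccelerometerTrace,
                  smooth_seconds: float = 2.0) -> np.ndarray:
    """Per-sample VeDBA in g.

    The static component is a centered boxcar running mean over
    ``smooth_seconds`` (edge-truncated); VeDBA is the norm of the dynamic
    residual across the three axes.
    """
    w = int(round(smooth_seconds * trace.sample_rate_hz))
    if w < 2:
        raise ValueError("smoothing window shorter than 2 samples")
    if trace.t.size < w:
        raise ValueError("trace shorter than the smoothing window")
    sq = np.zeros(trace.t.size)
    for ch in (trace.ax, trace.ay, trace.az):
        static = ndimage.uniform_filter1d(ch, size=w, mode="nearest")
        sq += (ch - static) ** 2
    return np.sqrt(sq)


def window_vedba(vedba: np.ndarray, window_seconds: float,
                 sample_rate_hz: float) -> ActivityTrace:
    """Non-overlapping per-window arithmetic means; trailing partial window
    dropped."""
    n = int(round(window_seconds * sample_rate_hz))
    if n < 1:
        raise ValueError("window shorter than one sample")
    k = vedba.size // n
    means = np.asarray(vedba[:k * n], dtype=float).reshape(k, n).mean(axis=1)
    return ActivityTrace(window_seconds, means)


def fit_activity_threshold(activity: ActivityTrace, log_transform: bool = True,
                           seed: int | None = 0) -> float:
    """Two-component GMM threshold between low and high activity.

    Fitted on log-VeDBA by default (the bimodality is multiplicative). The
    threshold is the point between the two component means where the
    posterior responsibilities are equal, returned on the original g scale.
    """
    v = np.asarray(activity.vedba, dtype=float)
    if v.size < 100:
        raise ValueError("need at least 100 windows to fit a threshold")
    if log_transform:
        if np.any(v <= 0):
            raise ValueError("log transform requires positive VeDBA")
        x = np.log(v)
    else:
        x = v
    gm = GaussianMixture(n_components=2, n_init=5, random_state=seed)
    gm.fit(x[:, None])
    w = gm.weights_
    if w.min() < 1e-3:
        raise ValueError("no bimodality: degenerate mixture component")
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]

    def diff(z):  # difference of weighted component log-densities
        return (np.log(w[0]) - 0.5 * ((z - mu[0]) / sd[0]) ** 2 - np.log(sd[0])
                - np.log(w[1]) + 0.5 * ((z - mu[1]) / sd[1]) ** 2
                + np.log(sd[1]))

    try:
        z = optimize.brentq(diff, mu[0], mu[1])
    except ValueError:  # no sign change between the means (rare, skewed fit)
        z = 0.5 * (mu[0] + mu[1])
    thr = float(np.exp(z)) if log_transform else float(z)
    activity.threshold = thr
    return thr


def label_activity(activity: ActivityTrace, threshold: float,
                   individual_id: str = "accel") -> BehavioralSequence:
    """Label windows low/high by the threshold; high iff vedba > threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    labels = np.where(activity.vedba > threshold, "high", "low")
    activity.labels = labels
    activity.threshold = float(threshold)
    return BehavioralSequence(individual_id, activity.window_seconds,
                              labels, alphabet=("high", "low"))
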