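"""Predictivity decay: adjusted mutual information over time lags.

How predictive is an animal's current behavioral state of its state ``tau``
windows later? We measure the adjusted mutual information (AMI) between the
state series and itself lagged by ``tau``, over a log-spaced grid of integer
lags. AMI corrects raw mutual information for chance agreement by subtracting
its expectation under the permutation model and normalizing, so independent
series score ~0 and identical ones score 1.

Mutual information estimators are biased at finite sample size, and the bias
does not vanish like 1/sqrt(N); following the standard finite-size
correction, AMI is computed on random subsamples of the (state_t,
state_{t+tau}) pairs at five fractions n in {0.5N..0.9N} (five subsets each)
and extrapolated to infinite data by the intercept of a linear regression of
AMI on 1/n.

Three decay laws are fitted to the extrapolated curve: exponential
``m exp(-lambda tau)``, power law ``m tau^-alpha``, and exponentially
truncated power law ``m tau^-alpha exp(-lambda tau)``. All three are linear
in log-AMI, so fits are (bounded) linear least squares on the positive part
of the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .sequences import BehavioralSequence

__all__ = ["lag_grid", "ami", "ami_extrapolated", "finite_size_intercept",
           "PredictivityModel", "AMICurve", "DecayFit", "fit_decay_models"]

DEFAULT_FRACTIONS = (0.5, 0.6, 0.7, 0.8, 0.9)


def lag_grid(min_lag: int = 1, max_lag: int = 5000, count: int = 44) -> np.ndarray:
    """Distinct integer lags approximately equally spaced on the log axis.

    Duplicates from rounding are resolved by advancing to the next unused
    integer; endpoints are always included.
    """
    if not (max_lag > min_lag >= 1):
        raise ValueError("need max_lag > min_lag >= 1")
    if count > max_lag - min_lag + 1:
        raise ValueError("count exceeds number of available integers")
    v = np.rint(np.geomspace(min_lag, max_lag, count)).astype(np.int64)
    for i in range(1, count):  # forward: strictly increasing
        v[i] = max(v[i], v[i - 1] + 1)
    v[-1] = max_lag
    for i in range(count - 2, -1, -1):  # backward: stay below the ceiling
        v[i] = min(v[i], v[i + 1] - 1)
    v[0] = min_lag
    return v


# ----------------------------------------------------------------- fast AMI

def _contingency(a: np.ndarray, b: np.ndarray):
    ka = int(a.max()) + 1 if a.size else 1
    kb = int(b.max()) + 1 if b.size else 1
    n = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb)
    return n[n.sum(1) > 0][:, n.sum(0) > 0]


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log(p)))


def expected_mutual_information(a_counts: np.ndarray, b_counts: np.ndarray,
                                n: int, tail: float = 20.0) -> float:
    """E[MI] under the permutation (hypergeometric) model, in nats.

    The inner sum over cell counts is truncated to mean +- ``tail`` standard
    deviations of the hypergeometric; omitted terms are < 1e-12 of the total.
    """
    gln = special.gammaln
    lg_n = gln(n + 1)
    emi = 0.0
    for ai in a_counts:
        for bj in b_counts:
            mean = ai * bj / n
            var = mean * (n - ai) * (n - bj) / (n * max(n - 1, 1))
            lo = max(1, int(ai + bj - n), int(np.floor(mean - tail * np.sqrt(var) - 1)))
            hi = min(int(ai), int(bj), int(np.ceil(mean + tail * np.sqrt(var) + 1)))
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1, dtype=np.float64)
            logp = (gln(ai + 1) + gln(bj + 1) + gln(n - ai + 1)
                    + gln(n - bj + 1) - lg_n - gln(nij + 1)
                    - gln(ai - nij + 1) - gln(bj - nij + 1)
                    - gln(n - ai - bj + nij + 1))
            term = nij / n * (np.log(nij * n) - np.log(ai * bj))
            emi += float(np.sum(np.exp(logp) * term))
    return emi


def ami(states_a, states_b) -> float:
    """Adjusted mutual information between two equal-length labelings.

    Matches scikit-learn's ``adjusted_mutual_info_score`` (arithmetic-mean
    normalization) but with a truncated expected-MI sum that stays fast on
    very long sequences.
    """
    a = np.asarray(states_a)
    b = np.asarray(states_b)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    if a.dtype.kind not in "iu":
        _, a = np.unique(a, return_inverse=True)
    if b.dtype.kind not in "iu":
        _, b = np.unique(b, return_inverse=True)
    a = a - a.min()
    b = b - b.min()
    cont = _contingency(a.astype(np.int64), b.astype(np.int64))
    n = int(cont.sum())
    ac, bc = cont.sum(axis=1), cont.sum(axis=0)
    if len(ac) == 1 and len(bc) == 1:
        return 1.0  # both partitions trivial: conventionally perfect agreement
    ha, hb = _entropy(ac, n), _entropy(bc, n)
    nz = cont[cont > 0].astype(float)
    outer = np.outer(ac, bc)[cont > 0].astype(float)
    mi = float(np.sum(nz / n * (np.log(nz * n) - np.log(outer))))
    emi = expected_mutual_information(ac, bc, n)
    denom = 0.5 * (ha + hb) - emi
    if denom < 0:
        denom = min(denom, -np.finfo(float).eps)
    else:
        denom = max(denom, np.finfo(float).eps)
    return float((mi - emi) / denom)


# -------------------------------------------------------- lagged pair series

def _lagged_pairs(seq: BehavioralSequence, lag: int):
    codes = seq.state_codes()
    aa, bb = [], []
    for s, e in seq.segments:
        if e - s > lag:
            aa.append(codes[s:e - lag])
            bb.append(codes[s + lag:e])
    if not aa:
        return (np.empty(0, dtype=np.int64),) * 2
    return np.concatenate(aa), np.concatenate(bb)


def ami_extrapolated(seq: BehavioralSequence, lag: int, n_subsets: int = 5,
                     fractions=DEFAULT_FRACTIONS, seed=None,
                     rng: np.random.Generator | None = None,
                     ci_level: float = 0.99):
    """Finite-size-corrected AMI at one lag.

    Returns ``(ami_inf, (ci_lo, ci_hi), n_pairs)``: the 1/n -> 0 intercept of
    a linear regression of subsample AMI on 1/n, its t-based confidence
    interval, and the total pair count N at this lag.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    a, b = _lagged_pairs(seq, lag)
    n_pairs = a.size
    if n_pairs < 20:
        raise ValueError(f"too few pairs at lag {lag} ({n_pairs} < 20)")
    ns, ys = [], []
    for f in fractions:
        n_sub = int(round(f * n_pairs))
        for _ in range(n_subsets):
            idx = rng.permutation(n_pairs)[:n_sub]
            ns.append(n_sub)
            ys.append(ami(a[idx], b[idx]))
    est, ci = finite_size_intercept(ns, ys, ci_level=ci_level)
    return est, ci, n_pairs


def finite_size_intercept(subset_sizes, ami_values, ci_level: float = 0.99):
    """Extrapolate AMI to infinite data: regress AMI on 1/n and return the
    intercept with its t-based confidence interval."""
    x = 1.0 / np.asarray(subset_sizes, dtype=float)
    y = np.asarray(ami_values, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - 2
    s2 = float(resid @ resid) / max(dof, 1)
    cov = s2 * np.linalg.inv(X.T @ X)
    tq = stats.t.ppf(0.5 + ci_level / 2, max(dof, 1))
    half = tq * np.sqrt(cov[0, 0])
    return float(beta[0]), (float(beta[0] - half), float(beta[0] + half))


@dataclass
class AMICurve:
    """Extrapolated AMI and CI band over the lag grid."""

    lags: np.ndarray
    ami: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_pairs: np.ndarray
    fractions: tuple = DEFAULT_FRACTIONS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": self.lags, "ami": self.ami,
                             "ci_lo": self.ci_lo, "ci_hi": self.ci_hi,
                             "n_pairs": self.n_pairs})


@dataclass
class DecayFit:
    """One fitted decay law for the AMI curve.

    ``family`` is one of ``exponential`` (m e^{-lambda tau}), ``power_law``
    (m tau^{-alpha}) or ``truncated_power_law`` (m tau^{-alpha}
    e^{-lambda tau}); ``r_squared`` and ``aic`` are computed on log(AMI).
    """

    family: str
    m: float
    alpha: float
    lam: float
    r_squared: float
    aic: float
    n_points: int

    def predict(self, lags) -> np.ndarray:
        tau = np.asarray(lags, dtype=float)
        return self.m * tau ** (-self.alpha) * np.exp(-self.lam * tau)


_DECAY_FAMILIES = {
    # family -> (design column builder, n free params incl. m)
    "exponential": (lambda tau: [-tau], 2),
    "power_law": (lambda tau: [-np.log(tau)], 2),
    "truncated_power_law": (lambda tau: [-np.log(tau), -tau], 3),
}


def fit_decay_models(curve: AMICurve, rank_by: str = "aic") -> list[DecayFit]:
    """Fit the three decay laws to the positive part of the AMI curve.

    All three laws are linear in log(AMI); the power exponent and decay rate
    are constrained nonnegative (bounded linear least squares). Lags with
    nonpositive extrapolated AMI are dropped. When the curve carries a
    confidence band, fitting further stops at the first lag whose band
    reaches zero: beyond the detection floor the estimates scatter around
    zero and isolated noise-positive points would dominate a log-scale fit,
    so only the contiguous significantly-positive prefix is informative
    about the decay law. Fits are ranked by the
    small-sample AIC of the log-space regression (``rank_by="aic"``, the
    default, which penalizes the extra parameter of the truncated family) or
    by raw ``r_squared``; ties break toward fewer parameters.
    """
    pos = curve.ami > 0
    ci_lo = np.asarray(curve.ci_lo, dtype=float)
    if np.all(np.isfinite(ci_lo)):
        sig = pos & (ci_lo > 0)
        first_floor = np.argmin(sig) if not sig.all() else sig.size
        if first_floor >= 5:  # contiguous detectable prefix
            pos = np.zeros_like(pos)
            pos[:first_floor] = True
    tau = curve.lags[pos].astype(float)
    if tau.size < 5:
        raise ValueError("fewer than 5 lags with positive AMI")
    logy = np.log(curve.ami[pos])
    fits = []
    for family, (cols, k) in _DECAY_FAMILIES.items():
        A = np.column_stack([np.ones_like(tau), *cols(tau)])
        lb = np.full(A.shape[1], 0.0)
        lb[0] = -np.inf
        sol = optimize.lsq_linear(A, logy, bounds=(lb, np.inf))
        resid = logy - A @ sol.x
        rss = float(resid @ resid)
        tss = float(np.sum((logy - logy.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-12 else 0.0)
        n = tau.size
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
        alpha = lam = 0.0
        if family in ("power_law", "truncated_power_law"):
            alpha = float(sol.x[1])
        if family == "exponential":
            lam = float(sol.x[1])
        elif family == "truncated_power_law":
            lam = float(sol.x[2])
        fits.append(DecayFit(family, float(np.exp(sol.x[0])), alpha, lam,
                             r2, float(aic), n))
    if rank_by == "aic":
        fits.sort(key=lambda f: (f.aic, _DECAY_FAMILIES[f.family][1]))
    elif rank_by == "r_squared":
        fits.sort(key=lambda f: (-f.r_squared, _DECAY_FAMILIES[f.family][1]))
    else:
        raise ValueError("rank_by must be 'aic' or 'r_squared'")
    return fits


class PredictivityModel:
    """AMI-decay model of a behavioral sequence.

    ``fit`` computes the finite-size-extrapolated AMI at every lag of the
    grid (skipping lags with fewer than 20 pairs) and fits the three decay
    laws; the returned results object carries the curve, the ranked fits and
    a text summary.
    """

    def __init__(self, seq: BehavioralSequence, lags=None):
        self.seq = seq
        if lags is None:
            lags = lag_grid(1, min(5000, max(2, len(seq) // 4)),
                            count=min(44, min(5000, max(2, len(seq) // 4))))
        self.lags = np.asarray(lags, dtype=np.int64)

    def fit(self, seed=None, rng=None, n_subsets: int = 5,
            fractions=DEFAULT_FRACTIONS,
            rank_by: str = "aic") -> "PredictivityResults":
        if rng is None:
            rng = np.random.default_rng(seed)
        rows = []
        for lag in self.lags:
            try:
                a, ci, npairs = ami_extrapolated(
                    self.seq, int(lag), n_subsets=n_subsets,
                    fractions=fractions, rng=rng)
            except ValueError:
                continue
            rows.append((lag, a, ci[0], ci[1], npairs))
        if not rows:
            raise ValueError("no lag had enough pairs")
        arr = np.array(rows)
        curve = AMICurve(arr[:, 0].astype(np.int64), arr[:, 1], arr[:, 2],
                         arr[:, 3], arr[:, 4].astype(np.int64),
                         tuple(fractions))
        try:
            fits = fit_decay_models(curve, rank_by=rank_by)
        except ValueError:
            fits = []
        return PredictivityResults(curve, fits, self)


@dataclass
class PredictivityResults:
    curve: AMICurve
    decay_fits: list[DecayFit]
    model: PredictivityModel
    best: DecayFit | None = field(init=False)

    def __post_init__(self):
        self.best = self.decay_fits[0] if self.decay_fits else None

    def summary(self) -> str:
        lines = [f"Predictivity decay over {len(self.curve.lags)} lags "
                 f"(1..{self.curve.lags[-1]})"]
        for f in self.decay_fits:
            lines.append(
                f"  {f.family:>21}: m={f.m:.4g} alpha={f.alpha:.4g} "
                f"lambda={f.lam:.4g}  R2={f.r_squared:.4f} AIC={f.aic:.1f}")
        if self.best:
            lines.append(f"  best: {self.best.family}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        c = self.curve
        ax.loglog(c.lags, np.clip(c.ami, 1e-12, None), "k.-", label="AMI")
        if self.best is not None:
            ax.loglog(c.lags, self.best.predict(c.lags), "r-",
                      label=self.best.family)
        ax.set_xlabel(r"lag $\tau$ (windows)")
        ax.set_ylabel("extrapolated AMI")
        ax.legend()
        return ax
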