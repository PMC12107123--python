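# Methods

This note documents the statistical procedures implemented in `ethodyn`,
the assumptions behind them, the defaults and why they were chosen, and the
limits of what the synthetic validation can show.

## Data model

A behavioral sequence is a uniform time-windowed series of categorical
state labels for one individual (window length 1–3 s in typical collar
deployments). Recording gaps are first-class: any time step larger than
1.5 windows in an input CSV starts a new *segment*, and no bout, transition
pair, or lagged AMI pair ever spans a segment boundary. This matters for
deployments that record in daily blocks — joining across gaps would
manufacture fictitious long bouts and transitions.

Bouts are maximal same-state runs within a segment, indexed 0-based with
half-open intervals. Bouts touching a sequence end or a gap are flagged
`boundary_truncated`; they are right-censored observations of the true bout
length. By default they are **included** as observed durations (excluding
them would preferentially delete long bouts and bias every downstream
estimate much more than the censoring does); a flag excludes them. Bouts
shorter than 2 windows are dropped throughout the analysis stages — at
1–3 s windows, 1-window runs are dominated by classifier noise — but they
still occupy the timeline, so with the filter at 1 the durations exactly
partition each segment.

## Hazard estimation

For duration *t* (windows), `h(t) = n_ending(t) / n_at_risk(t)`. This is
the discrete-time Kaplan–Meier hazard with complete observation; the
product `Π_{s<t}(1−h(s))` reconstructs the empirical CCDF exactly, which
the test suite asserts as an identity.

*Confidence bands.* Wilson score intervals per *t* (via statsmodels).
Wilson was chosen over Wald because `n_at_risk` decays geometrically along
the axis and `h` sits near 0 for heavy-tailed states; Wald bands collapse
or escape [0, 1] there. The bands are **pointwise**: across ~50 displayed
durations, ~5% of points are expected to miss the true hazard even when
the model is exactly right.

*Display cutoff.* Estimates use all bouts, but plots and the trend test
stop at the duration of the 100th-longest bout, which keeps the local
resolution of `h` finer than 0.01.

*Trend test.* The field often judges hazard trends visually; `ethodyn`
makes the judgment explicit with a weighted Spearman correlation of `h`
against *t* (weights `n_at_risk`, range restricted to the display cutoff
and to points with ≥100 bouts at risk) and a permutation *p*-value
(999 permutations, two-sided, 5% level). Verdicts: `decreasing`, `flat`,
`increasing`, or `indeterminate` when fewer than 5 usable points exist.
The permutation test is distribution-free; its 5% size means that on truly
memoryless input ~1 sequence in 20 is called non-flat.

## Predictivity decay

AMI between the sequence and its lag-τ shift is mutual information
corrected for chance agreement: `(MI − E[MI]) / (mean(H_a, H_b) − E[MI])`
with the expectation under the hypergeometric permutation model. The
in-package implementation matches scikit-learn's
`adjusted_mutual_info_score` to machine precision (asserted in tests); the
only difference is that the expected-MI sum truncates each cell's
hypergeometric range at ±20 standard deviations (omitted mass < 1e-12),
which makes the 44-lag × 26-subset computation on 10⁶-window sequences
tractable.

*Finite-size correction.* MI-type estimators are biased upward at finite
N and the bias is ∝ 1/N to first order. For each lag, AMI is computed on
five random pair-subsets at each fraction {0.5, …, 0.9} of the N available
pairs, and a linear regression of AMI on 1/n is extrapolated to its
intercept. The 99% interval is the regression-intercept t-interval over
the 25 points; subsets overlap, so the interval is approximate. Subsets
are drawn as random pair-subsamples (not contiguous blocks) — blocks would
change the within-subset dependence structure with the fraction, bending
the 1/n line.

*Lag grid.* 44 integers spaced evenly on the log axis between 1 and 5000;
rounding duplicates are resolved by advancing to the next unused integer,
keeping the grid strictly increasing with both endpoints.

*Decay-law fits.* All three candidate laws are linear in log AMI, so fits
are bounded linear least squares (α, λ ≥ 0) on the log scale, which
equalizes relative error across the decades the curve spans. Nonpositive
extrapolated AMI values cannot enter a log fit and are dropped; moreover,
fitting stops at the first lag whose 99% band reaches zero — beyond the
detection floor estimates scatter around zero, and isolated noise-positive
points at huge lags would otherwise dominate the fit. Goodness of fit is
R² on log AMI. Families are *ranked* by the small-sample AIC of the
log-space regression, `n·ln(RSS/n) + 2k`: the truncated power law nests
both other laws, so raw R² can never prefer a simpler family; the AIC
penalty restores a meaningful comparison while reproducing the R² ordering
within equal parameter counts. `rank_by="r_squared"` is available.

A caveat worth knowing: the exact MI curve of a finite Markov chain is not
a pure exponential in τ (its local log-slope drifts from a steeper initial
value toward 2·|ln r|, with r the relevant eigenvalue), so on long
memoryless inputs the truncated power law typically edges out the
exponential by a small AIC margin with α̂ near 0. The exponential-family
fit still recovers the asymptotic rate accurately — on the two-state
symmetric chain with stay-probability 0.9 the fitted λ matches the
closed-form MI decay rate −2 ln 0.8 within a few percent.

## Bout-duration distribution fitting

Discrete MLE on the support {xmin, xmin+1, …} with xmin = 2 (matching the
1-window exclusion; Clauset-style xmin estimation is deliberately not the
default, to keep all states on a common support):

- *Exponential (geometric).* pmf (1−e^(−λ))e^(−λ(t−xmin)); closed-form
  MLE from the sample mean.
- *Power law.* pmf t^(−α)/ζ(α, xmin) with the Hurwitz zeta; 1-D bounded
  likelihood optimization.
- *Truncated power law.* pmf ∝ t^(−α)e^(−λt). The normalizing constant has
  no convenient closed form; it is computed as an exact partial sum to a
  horizon well past the data plus an Euler–Maclaurin tail integral
  λ^(α−1)Γ(1−α, λ·(H+½)) (accurate to ~1e-10 relative; the pmf-sums-to-1
  invariant is asserted to 1e-8 in tests). Nelder–Mead in (α, log λ) with
  3 starts; the λ → 0 boundary is snapped to the pure power law.
- *Lognormal.* Discretized by unit-interval integration of the continuous
  density, renormalized to the support; cell probabilities are computed
  entirely in log space via `log_ndtr` (naive Φ differences underflow in
  the far tail, which once let a degenerate parameter ridge fake a perfect
  fit). The MLE is box-bounded (|μ| ≤ 200, σ ≤ 25) because the
  unconstrained problem has an improper supremum at μ → −∞, σ → ∞ where
  the lognormal degenerates toward ~1/t.

Model selection minimizes AIC with θ = 1, 1, 2, 2 parameters respectively;
ties break toward fewer parameters. The default is the standard
AIC = 2θ − 2L; the variant 2θ − L, which appears in print in this
literature, is selectable (`variant="paper"`) and is recorded in every
fit object. The two agree whenever log-likelihood differences dominate
parameter-count differences. Fits are refused below 250 bouts: at smaller
n the four families are not reliably distinguishable.

Exact inverse-CDF samplers accompany each family (with a ζ-based bisection
fallback for deep power-law tails), so generator-recovery tests compare
against the same discrete laws they fit.

## DFA

Standard detrended fluctuation analysis of the ±1 indicator series of a
focal behavior: mean-center, integrate, split into non-overlapping boxes,
remove a linear trend per box, record the RMS residual F(s); α_DFA is the
log-log slope over box sizes 4 … n/10 (16 log-spaced sizes). Order-1
detrending and non-overlapping boxes are the reference configuration.
Segments are concatenated across gaps (with a warning): DFA needs one long
series, and the bias from a handful of splices is far below the exponent's
sampling noise. Note the small-scale crossover: a memoryless chain with
mean bout length b shows α > 0.5 at box sizes comparable to b and settles
to 0.5 only beyond its correlation time — white-noise behavior is a
statement about asymptotic scales.

## Markov surrogates

30 replicate pseudosequences per individual (count configurable) preserve
the empirical one-step transition probabilities: each segment starts with
the true segment's first state, and every subsequent state is a
categorical draw from the empirical successor distribution — equivalent
to with-replacement draws from the observed successor pool, in O(1) per
step. Surrogates inherit length and segment structure, hence the same
finite-size effects as the data. If a state with no observed successors is
reached (only possible for the terminal state of the data), the draw
restarts from the most recent state that has successors, and the event is
logged.

## Activity inference from accelerometry

VeDBA per sample is the Euclidean norm of the acceleration vector minus
its running mean (centered 2 s boxcar, edge-truncated) — the static,
gravitational component — making it invariant to collar orientation.
Windows of 1 s take the arithmetic mean (trailing partial window dropped).
A two-component Gaussian mixture fitted to log VeDBA (activity bimodality
is multiplicative; a flag fits the raw scale) defines the low/high
threshold at the equal-posterior point between the components — the
principled boundary under the fitted model, unlike the midpoint of means —
mapped back to the g scale. Degenerate fits (component weight < 1e-3)
are rejected as "no bimodality". The smoothing window, window statistic
and GMM scale are exposed as configuration since deployments differ.

## Simulators and bias studies

The generators are first-class, tested code; every analysis stage is
validated against them.

- *Markov chains*: bout durations of state s are geometric with parameter
  1 − P(s→s); ground truth for "flat hazard, exponential fit, fast AMI
  decay".
- *Semi-Markov*: embedded chain with zero diagonal plus per-state duration
  laws drawn from the fitted families' exact samplers; the final bout is
  truncated at the target length and flagged. Ground truth for heavy
  tails.
- *Social reinforcement*: n memoryless agents; an agent in state s
  switches with probability p·(1 − c·f_same), f_same the fraction of
  *other* agents in s, new state uniform over the rest, synchronous
  updates. The functional form is this package's concrete instantiation of
  "peers doing the same thing prolong your bout"; its design anchor is the
  exact reduction to independent chains at c = 0 (asserted by KS test).
  With 10 agents, p = 0.1, c = 0.8 the pooled hazard verdict is
  "decreasing" — positive feedback alone, with no individual memory,
  produces the self-reinforcement signature.
- *Classifier error*: i.i.d. per-window relabeling by a row-stochastic
  confusion matrix. The error study simulates two-state sequences with
  known duration law, corrupts them at rates {0, 0.05, 0.1, 0.2}
  (symmetric), and tabulates best-fit frequencies. Reproduced findings:
  heavy-tail detection for power-law truth degrades monotonically with
  error, and exponential truth at intermediate error is systematically
  misread as a truncated power law (run-splitting shortens long bouts
  preferentially).
- *Exponential mixtures*: k rates on {xmin, …}; the study draws rates
  log-uniform on [1e-3, 1e-1] and weights uniform on the simplex
  (defaults chosen to span the bout-duration decades seen in field data,
  n = 5000 samples per mixture, 300 mixtures) and tabulates best-fit
  fractions. With these ranges the truncated power law wins in roughly
  60% of three-rate mixtures and the lognormal in roughly 30% — arbitrary
  rate mixtures do *not* all masquerade as one family, and which family
  wins is systematically tied to the rate configuration (the per-mixture
  table records rates, weights and winner for inspection).

All generators are seed-deterministic; every stochastic routine accepts
either a seed or a NumPy `Generator`.

## What the synthetic validation does and does not show

The generators emulate categorical window sequences with controlled
duration laws, memoryless social coupling, and i.i.d. label noise. They do
not emulate autocorrelated classifier errors, state-dependent
misclassification, diurnal nonstationarity, or observation gaps correlated
with behavior — all present in real deployments. Passing tests therefore
demonstrate that the estimators recover known structure under the stated
models, not that real collar data satisfy those models. Species-specific
quantities (decay exponents near 0.19, truncation timescales of
15–45 min, α_DFA ≈ 1) require the original field datasets and are outside
what this package's synthetic suite can or does claim to reproduce.

## Problem sizes

Defaults used by the test suite and the acceptance script: memoryless
oracle chains of 10⁶ windows; semi-Markov recovery at ≥10⁴ bouts × 20
seeds; AMI closed-form checks at N = 10⁵ pairs; DFA at 10⁵ samples;
surrogate panels of 30 replicates on 2×10⁴-window inputs; error studies at
25–50 replicates per rate on 3×10⁴-window sequences; 300 random mixtures
of 5000 samples. These sizes put Monte-Carlo error comfortably below the
assertion tolerances while keeping a full run in minutes on one CPU.
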