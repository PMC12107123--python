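"""Synthetic generators: correctness of their sampling distributions."""

import numpy as np
import pytest
from scipy import stats

from ethodyn import (ErrorSpec, MixtureSpec, SemiMarkovSpec, SocialSimSpec,
                     bout_durations, corrupt_labels, estimate_hazard,
                     sample_mixture, simulate_markov, simulate_semimarkov,
                     simulate_social)
from ethodyn import distributions as dist


def _self_chain(k, stay):
    P = np.full((k, k), (1 - stay) / (k - 1))
    np.fill_diagonal(P, stay)
    return P


class TestSimulateMarkov:
    def test_mean_bout_duration(self):
        seq = simulate_markov(_self_chain(3, 0.9), 500_000, seed=0)
        d = bout_durations(seq, min_duration=1)
        assert d.mean() == pytest.approx(10.0, rel=0.02)

    def test_no_self_transitions_no_long_bouts(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        seq = simulate_markov(P, 5000, seed=1)
        assert bout_durations(seq, min_duration=1).max() == 1

    def test_flat_hazard(self):
        seq = simulate_markov(_self_chain(3, 0.9), 300_000, seed=2)
        est = estimate_hazard(bout_durations(seq, state="A"))
        v, _, _ = est.trend(seed=0)
        assert v == "flat"
        m = est.t <= est.display_cutoff
        assert ((est.ci_lo[m] <= 0.1) & (0.1 <= est.ci_hi[m])).mean() > 0.85

    def test_seed_determinism(self):
        a = simulate_markov(_self_chain(2, 0.8), 1000, seed=9)
        b = simulate_markov(_self_chain(2, 0.8), 1000, seed=9)
        c = simulate_markov(_self_chain(2, 0.8), 1000, seed=10)
        assert np.array_equal(a.states, b.states)
        assert not np.array_equal(a.states, c.states)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            simulate_markov(np.array([[0.5, 0.6], [0.5, 0.5]]), 100, seed=0)


class TestSimulateSemiMarkov:
    def _spec(self, family, params, length=50_000, seed=0):
        laws = {"A": (family, params), "B": (family, params)}
        return SemiMarkovSpec(("A", "B"),
                              np.array([[0.0, 1.0], [1.0, 0.0]]),
                              laws, length, seed=seed)

    def test_power_law_roundtrip_recovery(self):
        seq = simulate_semimarkov(self._spec("power_law", {"alpha": 2.5}))
        d = bout_durations(seq)
        assert d.size >= 8000
        alpha = dist.mle(d, "power_law")["alpha"]
        assert alpha == pytest.approx(2.5, abs=0.1)

    def test_exponential_bouts_flat_hazard(self):
        seq = simulate_semimarkov(self._spec("exponential", {"lam": 0.2},
                                             seed=1))
        v, _, _ = estimate_hazard(bout_durations(seq, state="A")).trend(
            seed=0)
        assert v == "flat"

    def test_sampler_matches_generator_cdf(self):
        # two-sided KS between drawn durations and the target law
        rng = np.random.default_rng(2)
        draws = dist.sample("power_law", {"alpha": 2.5}, 10_000, xmin=2,
                            rng=rng)
        t = np.arange(2, draws.max() + 2, dtype=float)
        cdf = np.cumsum(dist.pmf(t, "power_law", {"alpha": 2.5}, 2))
        emp = np.searchsorted(np.sort(draws), t, side="right") / draws.size
        assert np.max(np.abs(emp - cdf)) < 0.02

    def test_diagonal_rejected(self):
        with pytest.raises(ValueError, match="Self-transitions|self-trans"):
            SemiMarkovSpec(("A", "B"), np.array([[0.5, 0.5], [1.0, 0.0]]),
                           {"A": ("exponential", {"lam": 1.0}),
                            "B": ("exponential", {"lam": 1.0})}, 100)


class TestSimulateSocial:
    def test_uncoupled_hazard_flat_at_p(self):
        spec = SocialSimSpec(5, ("A", "B", "C"), 0.1, 0.0, 40_000, seed=0)
        seqs = simulate_social(spec)
        d = np.concatenate([bout_durations(s) for s in seqs])
        est = estimate_hazard(d)
        v, _, _ = est.trend(seed=0)
        assert v == "flat"
        m = est.t <= est.display_cutoff
        assert ((est.ci_lo[m] <= 0.1) & (0.1 <= est.ci_hi[m])).mean() > 0.85

    def test_single_agent_ignores_coupling(self):
        s1 = simulate_social(SocialSimSpec(1, ("A", "B"), 0.2, 0.9, 5000,
                                           seed=3))[0]
        s2 = simulate_social(SocialSimSpec(1, ("A", "B"), 0.2, 0.0, 5000,
                                           seed=3))[0]
        assert np.array_equal(s1.states, s2.states)

    def test_coupling_produces_decreasing_hazard(self):
        spec = SocialSimSpec(10, ("A", "B", "C"), 0.1, 0.8, 50_000, seed=4)
        d = np.concatenate([bout_durations(s)
                            for s in simulate_social(spec)])
        v, rho, _ = estimate_hazard(d).trend(seed=0)
        assert v == "decreasing"

    def test_uncoupled_matches_markov_distribution(self):
        # KS test between social(c=0) and matched plain chain bouts
        spec = SocialSimSpec(3, ("A", "B", "C"), 0.1, 0.0, 30_000, seed=5)
        d1 = np.concatenate([bout_durations(s)
                             for s in simulate_social(spec)])
        seq = simulate_markov(_self_chain(3, 0.9), 90_000, seed=6)
        d2 = bout_durations(seq)
        assert stats.ks_2samp(d1, d2).pvalue > 0.05

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SocialSimSpec(3, ("A", "B"), 0.0, 0.5, 100)
        with pytest.raises(ValueError):
            SocialSimSpec(3, ("A", "B"), 0.1, 1.0, 100)


class TestCorruptLabels:
    def test_identity_matrix_noop(self):
        seq = simulate_markov(_self_chain(2, 0.9), 2000, seed=7)
        out = corrupt_labels(seq, ErrorSpec(("A", "B"), np.eye(2)), seed=0)
        assert np.array_equal(out.states, seq.states)

    def test_symmetric_half_gives_iid_runs(self):
        seq = simulate_markov(_self_chain(2, 0.95), 100_000, seed=8)
        out = corrupt_labels(seq, ErrorSpec.symmetric(("A", "B"), 0.5),
                             seed=9)
        d = bout_durations(out, min_duration=1)
        assert d.mean() == pytest.approx(2.0, rel=0.02)

    def test_mean_bout_decreasing_in_error(self):
        seq = simulate_markov(_self_chain(2, 0.95), 50_000, seed=10)
        means = []
        for eps in (0.0, 0.05, 0.1, 0.2):
            out = corrupt_labels(seq, ErrorSpec.symmetric(("A", "B"), eps),
                                 seed=11)
            means.append(bout_durations(out, min_duration=1).mean())
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_stationary_frequencies_preserved(self):
        seq = simulate_markov(_self_chain(3, 0.9), 60_000, seed=12)
        out = corrupt_labels(seq, ErrorSpec.symmetric(("A", "B", "C"), 0.1),
                             seed=13)
        for st in "ABC":
            f_in = (seq.states == st).mean()
            f_out = (out.states == st).mean()
            assert f_out == pytest.approx(f_in, abs=0.01)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            ErrorSpec(("A", "B"), np.array([[0.9, 0.2], [0.1, 0.9]]))


class TestSampleMixture:
    def test_degenerate_weight_is_pure_exponential(self):
        spec = MixtureSpec((0.1, 0.5), (1.0, 0.0), 20_000, seed=0)
        d = sample_mixture(spec)
        pure = dist.sample("exponential", {"lam": 0.1}, 20_000, xmin=2,
                           rng=np.random.default_rng(1))
        assert stats.ks_2samp(d, pure).pvalue > 0.01

    def test_equal_rates_collapse(self):
        spec = MixtureSpec((0.2, 0.2), (0.5, 0.5), 10_000, seed=2)
        d = sample_mixture(spec)
        t = np.arange(2, d.max() + 2, dtype=float)
        cdf = np.cumsum(dist.pmf(t, "exponential", {"lam": 0.2}, 2))
        emp = np.searchsorted(np.sort(d), t, side="right") / d.size
        assert np.max(np.abs(emp - cdf)) < 0.02

    def test_mixture_mean_identity(self):
        rates, weights = (0.05, 0.3), (0.4, 0.6)
        spec = MixtureSpec(rates, weights, 100_000, seed=3)
        d = sample_mixture(spec)
        q = np.exp(-np.asarray(rates))
        mean_comp = 2 + q / (1 - q)  # discrete exp on {2,...}
        expected = np.dot(weights, mean_comp)
        assert d.mean() == pytest.approx(expected, rel=0.02)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            MixtureSpec((0.1, 0.2), (0.7, 0.7), 100)
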