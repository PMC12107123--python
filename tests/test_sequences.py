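"""Sequence data model: I/O, bout extraction, transitions, surrogates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ethodyn import (BehavioralSequence, bout_durations, extract_bouts,
                     fit_transitions, generate_pseudosequence, read_sequence,
                     simulate_markov)
from conftest import make_seq


class TestReadSequence:
    def test_direct_mapping(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("time,state\n" + "\n".join(
            f"{t},{s}" for t, s in zip(range(6), "AAABBA")))
        seq = read_sequence(p, 1.0)
        assert len(seq) == 6
        assert seq.segment_breaks == ()
        assert "".join(seq.states) == "AAABBA"

    def test_gap_inserts_segment_break(self, tmp_path):
        p = tmp_path / "s.csv"
        rows = [(0, "A"), (1, "A"), (2, "A"), (100, "B"), (101, "B"),
                (102, "A")]
        p.write_text("time,state\n" + "\n".join(f"{t},{s}" for t, s in rows))
        seq = read_sequence(p, 1.0)
        assert seq.segment_breaks == (3,)
        assert seq.segments == [(0, 3), (3, 6)]

    def test_index_layout(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("index,state\n0,A\n1,A\n2,B\n5,B\n6,A\n")
        seq = read_sequence(p, 3.0)
        assert seq.segment_breaks == (3,)

    def test_single_row_yields_no_bouts_downstream(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("time,state\n0,A\n")
        seq = read_sequence(p, 1.0)
        assert len(seq) == 1
        assert bout_durations(seq, min_duration=2).size == 0

    @pytest.mark.parametrize("content,err", [
        ("time,state\n", "empty"),
        ("foo,bar\n1,A\n", "column layout"),
        ("time,state\n2,A\n1,B\n", "increasing"),
    ])
    def test_rejects_bad_files(self, tmp_path, content, err):
        p = tmp_path / "bad.csv"
        p.write_text(content)
        with pytest.raises(ValueError, match=err):
            read_sequence(p, 1.0)


class TestExtractBouts:
    def test_min_duration_two(self, simple_seq):
        bouts = extract_bouts(simple_seq, min_duration=2)
        flat = {(b.state, b.start_index, b.duration)
                for bs in bouts.values() for b in bs}
        assert flat == {("A", 0, 3), ("B", 3, 2)}

    def test_min_duration_one_keeps_final_singleton(self, simple_seq):
        bouts = extract_bouts(simple_seq, min_duration=1)
        flat = {(b.state, b.start_index, b.duration)
                for bs in bouts.values() for b in bs}
        assert ("A", 5, 1) in flat
        assert len(flat) == 3

    def test_bouts_do_not_span_segment_breaks(self):
        seq = make_seq("AAAA", breaks=(2,))
        bouts = extract_bouts(seq, min_duration=1)["A"]
        assert sorted((b.start_index, b.duration) for b in bouts) == \
            [(0, 2), (2, 2)]
        assert all(b.boundary_truncated for b in bouts)

    def test_truncation_flags(self, simple_seq):
        bouts = extract_bouts(simple_seq, min_duration=1)
        by_start = {b.start_index: b for bs in bouts.values() for b in bs}
        assert by_start[0].boundary_truncated          # touches left end
        assert not by_start[3].boundary_truncated      # interior
        assert by_start[5].boundary_truncated          # touches right end

    @given(st.text(alphabet="ABC", min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_durations_partition_sequence(self, labels):
        seq = make_seq(labels)
        total = sum(b.duration
                    for bs in extract_bouts(seq, min_duration=1).values()
                    for b in bs)
        assert total == len(seq)


class TestFitTransitions:
    def test_counts(self):
        tm = fit_transitions(make_seq("AABA"))
        i = {s: j for j, s in enumerate(tm.alphabet)}
        assert tm.counts[i["A"], i["A"]] == 1
        assert tm.counts[i["A"], i["B"]] == 1
        assert tm.counts[i["B"], i["A"]] == 1
        assert tm.probabilities[i["A"], i["A"]] == pytest.approx(0.5)

    def test_alternating_is_deterministic(self):
        tm = fit_transitions(make_seq("ABABAB"))
        i = {s: j for j, s in enumerate(tm.alphabet)}
        assert tm.probabilities[i["A"], i["B"]] == 1.0
        assert tm.probabilities[i["B"], i["A"]] == 1.0

    def test_rows_sum_to_one(self):
        tm = fit_transitions(make_seq("AABBCCABCA"))
        np.testing.assert_allclose(tm.probabilities.sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_no_pair_spans_break(self):
        tm = fit_transitions(make_seq("AABB", breaks=(2,)))
        i = {s: j for j, s in enumerate(tm.alphabet)}
        assert tm.counts[i["A"], i["B"]] == 0  # the A->B step is the gap

    def test_all_singleton_segments_error(self):
        with pytest.raises(ValueError, match="no transitions"):
            fit_transitions(make_seq("AB", breaks=(1,)))

    def test_recovers_known_matrix(self):
        P = np.array([[0.7, 0.2, 0.1], [0.3, 0.6, 0.1], [0.25, 0.25, 0.5]])
        seq = simulate_markov(P, 100_000, seed=42)
        tm = fit_transitions(seq)
        n_row = tm.counts.sum(axis=1, keepdims=True)
        se = np.sqrt(P * (1 - P) / n_row)
        assert np.all(np.abs(tm.probabilities - P) < 3 * se + 1e-12)


class TestPseudosequences:
    def test_alternating_input_reproduced_exactly(self):
        seq = make_seq("ABABABAB")
        for rep in generate_pseudosequence(seq, n_replicates=5, seed=0):
            assert "".join(rep.states) == "ABABABAB"

    def test_default_replicate_count_is_30(self):
        reps = generate_pseudosequence(make_seq("AABBAABB"), seed=0)
        assert len(reps) == 30

    def test_same_seed_identical(self):
        seq = make_seq("AABBABABBBAA")
        r1 = generate_pseudosequence(seq, n_replicates=3, seed=7)
        r2 = generate_pseudosequence(seq, n_replicates=3, seed=7)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.states, b.states)

    def test_starts_and_structure_preserved(self):
        seq = make_seq("AABBABAB", breaks=(4,))
        for rep in generate_pseudosequence(seq, n_replicates=4, seed=1):
            assert len(rep) == len(seq)
            assert rep.segment_breaks == seq.segment_breaks
            assert rep.states[0] == seq.states[0]
            assert rep.states[4] == seq.states[4]

    def test_transition_matrix_preserved_chi2(self):
        P = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6]])
        seq = simulate_markov(P, 100_000, seed=3)
        tm = fit_transitions(seq)
        rep = generate_pseudosequence(seq, n_replicates=1, seed=4)[0]
        tm_rep = fit_transitions(rep)
        # chi-square GOF of replicate counts against source probabilities
        for i in range(3):
            exp = tm.probabilities[i] * tm_rep.counts[i].sum()
            chi2 = np.sum((tm_rep.counts[i] - exp) ** 2 / exp)
            assert stats.chi2.sf(chi2, df=2) > 0.01
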