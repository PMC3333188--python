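"""The windowed miner: embedding, DFS search, summarization, tabulation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from winspm import (
    PatternSet,
    SearchParams,
    SequentialPattern,
    embed,
    filter_min_length,
    is_subsequence,
    naive_spm,
    sp_searching,
    summarize_maximal,
    tabulate_distribution,
    to_sequence_db,
)

from conftest import make_matrix, random_db

# sample sequence (g3, g1, g5, g2, g4): rank positions g3=1, g1=2, g5=3, g2=4, g4=5
POSITIONS = {"g3": 1, "g1": 2, "g5": 3, "g2": 4, "g4": 5}


class TestEmbed:
    def test_forward_gap_within_window(self):
        r = embed(POSITIONS, ["g1", "g2"], w_f=2, w_b=0)
        assert (r.supported, r.forward, r.backward) == (True, 1, 0)

    def test_backward_step_within_window(self):
        r = embed(POSITIONS, ["g5", "g1"], w_f=4, w_b=1)
        assert (r.supported, r.forward, r.backward) == (True, 0, 1)

    def test_gap_exceeding_window_unsupported(self):
        assert not embed(POSITIONS, ["g1", "g4"], w_f=1, w_b=0).supported

    def test_reference_only_advances_forward(self):
        # g5(3) -> g1(2) backward keeps ref at 3, so g2(4) is 1 ahead of ref
        r = embed(POSITIONS, ["g5", "g1", "g2"], w_f=1, w_b=1)
        assert (r.supported, r.forward, r.backward) == (True, 1, 1)

    def test_unknown_gene_fatal(self):
        with pytest.raises(KeyError):
            embed(POSITIONS, ["g1", "gX"], w_f=2, w_b=0)


class TestSearchParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(u=0, l=2, w_f=1), dict(u=1, l=1, w_f=1), dict(u=1, l=2, w_f=0),
                   dict(u=1, l=2, w_f=1, w_b=-1)]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SearchParams(**kwargs)


class TestSpSearching:
    def test_identical_sequences_single_full_pattern(self, identical_db):
        P = sp_searching(identical_db, SearchParams(u=4, l=4, w_f=3, w_b=0))
        assert len(P) == 1
        (p,) = P.patterns
        assert p.genes == ("g1", "g2", "g3", "g4")
        assert p.samples == frozenset("abcd")
        assert (p.forward_steps, p.backward_steps) == (12, 0)

    def test_unsatisfiable_support_warns_empty(self, identical_db):
        with pytest.warns(UserWarning, match="support"):
            P = sp_searching(identical_db, SearchParams(u=5, l=2, w_f=3))
        assert len(P) == 0

    def test_matches_naive_oracle_on_random_databases(self):
        """With no backward window and a full forward window the windowed DFS
        must enumerate exactly what exhaustive mining enumerates."""
        rng = np.random.default_rng(42)
        db = random_db(rng, 8, 6)
        P = sp_searching(db, SearchParams(u=4, l=3, w_f=7, w_b=0))
        Q = naive_spm(db, u=4, l=3)
        assert P.key_set() == Q.key_set()

    def test_gene_sequences_unique(self):
        rng = np.random.default_rng(3)
        db = random_db(rng, 7, 5)
        P = sp_searching(db, SearchParams(u=3, l=2, w_f=7, w_b=1))
        seqs = [p.genes for p in P.patterns]
        assert len(seqs) == len(set(seqs))

    def test_emission_gates_hold(self):
        rng = np.random.default_rng(5)
        db = random_db(rng, 8, 6)
        params = SearchParams(u=3, l=2, w_f=4, w_b=2)
        P = sp_searching(db, params)
        assert len(P) > 0
        for p in P:
            assert p.length >= params.l
            assert p.support >= params.u
            assert p.forward_steps > p.backward_steps
            assert p.forward_steps + p.backward_steps == (p.length - 1) * p.support

    def test_support_is_exact_per_sample_embedding(self):
        """Each emitted pattern's sample set is exactly the samples whose
        unique embedding satisfies the window constraints (checked via embed)."""
        rng = np.random.default_rng(11)
        db = random_db(rng, 8, 6)
        params = SearchParams(u=3, l=2, w_f=5, w_b=1)
        for p in sp_searching(db, params):
            supporting = {
                db.sample_ids[j]
                for j in range(db.n_samples)
                if embed(db.position_map(j), p.genes, params.w_f, params.w_b).supported
            }
            assert supporting == p.samples

    def test_anti_monotone_prefix_support(self):
        """Every prefix of an emitted pattern is supported by a superset of
        its samples and itself reaches the support threshold (exact pruning)."""
        rng = np.random.default_rng(13)
        db = random_db(rng, 8, 6)
        params = SearchParams(u=3, l=3, w_f=6, w_b=1)
        pos_maps = [db.position_map(j) for j in range(db.n_samples)]
        for p in sp_searching(db, params):
            for cut in range(2, p.length):
                prefix_support = {
                    db.sample_ids[j]
                    for j, pm in enumerate(pos_maps)
                    if embed(pm, p.genes[:cut], params.w_f, params.w_b).supported
                }
                assert p.samples <= prefix_support
                assert len(prefix_support) >= params.u

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(21)
        vals = rng.random((7, 5))
        E = make_matrix(vals)
        E2 = make_matrix(vals[:, ::-1], sample_ids=tuple(f"s{j}" for j in (5, 4, 3, 2, 1)))
        params = SearchParams(u=3, l=2, w_f=4, w_b=1)
        a = sp_searching(to_sequence_db(E), params)
        b = sp_searching(to_sequence_db(E2), params)
        assert a.key_set() == b.key_set()

    def test_invariant_to_gene_relabeling(self):
        rng = np.random.default_rng(22)
        vals = rng.random((6, 5))
        perm = rng.permutation(6)
        names = tuple(f"g{i + 1}" for i in range(6))
        E = make_matrix(vals, gene_ids=names)
        E2 = make_matrix(vals[perm], gene_ids=tuple(names[i] for i in perm))
        params = SearchParams(u=3, l=2, w_f=6, w_b=0)
        a = sp_searching(to_sequence_db(E), params)
        b = sp_searching(to_sequence_db(E2), params)
        assert a.key_set() == b.key_set()

    def test_deterministic_reruns(self):
        rng = np.random.default_rng(8)
        vals = rng.random((8, 5))
        params = SearchParams(u=3, l=2, w_f=5, w_b=2)
        a = sp_searching(to_sequence_db(make_matrix(vals)), params)
        b = sp_searching(to_sequence_db(make_matrix(vals)), params)
        assert [(p.genes, p.samples, p.forward_steps) for p in a] == [
            (p.genes, p.samples, p.forward_steps) for p in b
        ]
        assert a.candidates_evaluated == b.candidates_evaluated


class TestFilterAndSummary:
    def _ps(self, specs):
        return PatternSet(
            patterns=[SequentialPattern(genes=g, samples=frozenset(s)) for g, s in specs]
        )

    def test_filter_min_length(self):
        P = self._ps([(("a", "b"), "xy"), (("a", "b", "c"), "xy"),
                      (("a", "b", "c", "d", "e", "f"), "xy")])
        P.candidates_evaluated = 7
        Q = filter_min_length(P, 6)
        assert [p.length for p in Q] == [6]
        assert Q.candidates_evaluated == 7
        assert len(filter_min_length(P, 2)) == 3
        assert len(filter_min_length(PatternSet(), 2)) == 0

    def test_strict_enclosure_removed(self):
        P = self._ps([(("g1", "g2"), "ab"), (("g1", "g2", "g3"), "ab")])
        Q = summarize_maximal(P)
        assert [p.genes for p in Q] == [("g1", "g2", "g3")]

    def test_sample_superset_blocks_enclosure(self):
        P = self._ps([(("g1", "g2"), "abc"), (("g1", "g2", "g3"), "ab")])
        assert len(summarize_maximal(P)) == 2

    def test_summary_of_full_subsequence_lattice(self, identical_db):
        """All subsequences of one shared 4-gene order collapse to the full
        sequence; verified against an explicit enclosure enumeration."""
        P = sp_searching(identical_db, SearchParams(u=4, l=2, w_f=3, w_b=0))
        full = ("g1", "g2", "g3", "g4")
        # independent check: every pattern is a subsequence of the full order
        for p in P:
            assert is_subsequence(p.genes, full)
            assert p.samples == frozenset("abcd")
        Q = summarize_maximal(P)
        assert [p.genes for p in Q] == [full]

    def test_summary_idempotent(self):
        rng = np.random.default_rng(17)
        db = random_db(rng, 7, 5)
        P = sp_searching(db, SearchParams(u=3, l=2, w_f=7, w_b=0))
        Q = summarize_maximal(P)
        R = summarize_maximal(Q)
        assert [p.genes for p in Q] == [p.genes for p in R]

    def test_summary_output_pairwise_non_enclosing(self):
        rng = np.random.default_rng(19)
        db = random_db(rng, 7, 5)
        Q = summarize_maximal(sp_searching(db, SearchParams(u=3, l=2, w_f=7, w_b=0)))
        for p, q in itertools.permutations(Q.patterns, 2):
            assert not (
                p.length < q.length
                and p.samples <= q.samples
                and is_subsequence(p.genes, q.genes)
            )


class TestTabulate:
    def _pat(self, length, support):
        return SequentialPattern(
            genes=tuple(f"g{i}" for i in range(length)),
            samples=frozenset(f"s{j}{length}{support}" for j in range(support)),
        )

    def test_counts(self):
        P = PatternSet(patterns=[self._pat(6, 32), self._pat(6, 33), self._pat(7, 32)])
        # distinct gene tuples needed
        P.patterns[1] = SequentialPattern(
            genes=tuple(f"h{i}" for i in range(6)),
            samples=frozenset(f"s{j}" for j in range(33)),
        )
        tab = tabulate_distribution(P)
        assert tab.loc[32, 6] == 1
        assert tab.loc[33, 6] == 1
        assert tab.loc[32, 7] == 1
        assert tab.loc["Total", "Total"] == 3

    def test_empty(self):
        tab = tabulate_distribution(PatternSet())
        assert tab.loc["Total", "Total"] == 0

    def test_subsequence_lattice_counts(self, identical_db):
        """4 identical sequences, l=2, exhaustive windows: C(4,2)=6 pairs,
        C(4,3)=4 triples, 1 quadruple, all at support 4."""
        P = sp_searching(identical_db, SearchParams(u=4, l=2, w_f=3, w_b=0))
        tab = tabulate_distribution(P)
        assert tab.loc[4, 2] == 6
        assert tab.loc[4, 3] == 4
        assert tab.loc[4, 4] == 1
        assert tab.loc["Total", "Total"] == 11


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 10**6))
def test_windowed_support_never_exceeds_relaxed_windows(seed):
    """Widening the windows can only grow each pattern's supporting set."""
    rng = np.random.default_rng(seed)
    db = random_db(rng, 6, 4)
    tight = sp_searching(db, SearchParams(u=2, l=2, w_f=2, w_b=0))
    loose = sp_searching(db, SearchParams(u=2, l=2, w_f=4, w_b=1))
    loose_map = {p.genes: p.samples for p in loose}
    for p in tight:
        if p.genes in loose_map:
            assert p.samples <= loose_map[p.genes]
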