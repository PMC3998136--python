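"""Match discovery: worked examples, oracle equivalence, invariants."""

import numpy as np
import pytest

import pbwtkit as pk
from pbwtkit import Match

from conftest import copying_panel, panel_grid, random_panel


def multiset(it):
    return sorted(it)


def assert_match_invariants(panel, matches, query=None):
    """Every emitted match agrees on its interval and is mismatch-or-
    boundary at both ends."""
    X = panel.alleles
    for m in matches:
        xa = query if query is not None else X[m.seq_a]
        xb = X[m.seq_b]
        assert m.start < m.end
        assert (xa[m.start : m.end] == xb[m.start : m.end]).all()
        assert m.start == 0 or xa[m.start - 1] != xb[m.start - 1]
        assert m.end == panel.N or xa[m.end] != xb[m.end]


class TestLongMatches:
    def test_p4_worked_example(self, p4):
        got = multiset(pk.long_matches(p4, 2))
        assert got == [Match(0, 1, 1, 3), Match(0, 3, 1, 4), Match(1, 3, 0, 3)]

    def test_identical_sequences_full_interval(self):
        panel = pk.HaplotypePanel(np.zeros((4, 4), dtype=np.uint8))
        got = multiset(pk.long_matches(panel, 4))
        assert len(got) == 6  # all unordered pairs
        assert all(m.start == 0 and m.end == 4 for m in got)

    def test_threshold_above_n_rejected(self, p4):
        with pytest.raises(pk.PanelError):
            list(pk.long_matches(p4, 5))
        with pytest.raises(pk.PanelError):
            list(pk.long_matches(p4, 0))

    def test_no_duplicates(self):
        for panel in panel_grid(10, offset=300):
            got = list(pk.long_matches(panel, max(1, panel.N // 4)))
            assert len(got) == len(set(got))


class TestSetMaximal:
    def test_p4_worked_example(self, p4):
        got = multiset(pk.set_maximal_matches(p4))
        assert got == [
            Match(0, 2, 0, 1),
            Match(0, 3, 1, 4),
            Match(1, 2, 3, 4),
            Match(1, 3, 0, 3),
            Match(2, 0, 0, 1),
            Match(2, 1, 3, 4),
            Match(3, 0, 1, 4),
            Match(3, 1, 0, 3),
        ]

    def test_two_identical_sequences(self):
        panel = pk.HaplotypePanel(["0110", "0110"])
        got = multiset(pk.set_maximal_matches(panel))
        assert got == [Match(0, 1, 0, 4), Match(1, 0, 0, 4)]

    def test_single_sequence_rejected(self):
        panel = pk.HaplotypePanel(["0101"])
        with pytest.raises(pk.PanelError):
            list(pk.set_maximal_matches(panel))
        with pytest.raises(pk.PanelError):
            list(pk.naive_set_maximal(panel))

    def test_count_bound_on_tie_free_panels(self):
        """Total set-maximal matches stay below a small multiple of NM."""
        for seed in range(20):
            panel = random_panel(seed + 1000, max_m=40, max_n=80)
            rows = {tuple(r) for r in panel.alleles}
            if len(rows) < panel.M:
                continue  # tie: identical sequences excluded from the bound
            n = len(list(pk.set_maximal_matches(panel)))
            assert n <= 4 * panel.N * panel.M

    def test_stats_sweep_agrees_with_match_stream(self):
        for seed in range(5):
            panel = copying_panel(seed + 50, m=35, n=90)
            ms = list(pk.set_maximal_matches(panel))
            stats = pk.set_maximal_length_stats(
                panel.iter_columns(), panel.M, panel.N, panel.positions
            )
            assert stats.n_matches == len(ms)
            assert stats.total_sites == sum(m.end - m.start for m in ms)
            assert stats.n_intervals == len({(m.seq_a, m.start, m.end) for m in ms})


class TestQuery:
    def test_p4_worked_example(self, p4):
        index = pk.build_index(p4)
        got = multiset(pk.query_set_maximal(index, "1111"))
        assert got == [
            Match(0, 0, 3, 4),
            Match(0, 1, 0, 2),
            Match(0, 2, 2, 3),
            Match(0, 3, 0, 2),
            Match(0, 3, 3, 4),
        ]

    def test_query_equal_to_panel_member(self):
        panel = random_panel(17)
        index = pk.build_index(panel)
        i = panel.M // 2
        got = multiset(pk.query_set_maximal(index, panel.sequence(i)))
        assert Match(0, i, 0, panel.N) in got
        assert all(m.start == 0 and m.end == panel.N for m in got)

    def test_bad_query_rejected(self, p4):
        index = pk.build_index(p4)
        with pytest.raises(pk.PanelError):
            list(pk.query_set_maximal(index, "111"))
        with pytest.raises(pk.PanelError):
            list(pk.query_set_maximal(index, "1121"))

    def test_query_oracle_equivalence(self):
        rng = np.random.default_rng(42)
        for t in range(25):
            panel = random_panel(t + 200, max_m=30, max_n=60)
            index = pk.build_index(panel, checkpoint_interval=13)
            for _ in range(4):
                z = (rng.random(panel.N) < 0.5).astype(np.uint8)
                got = multiset(pk.query_set_maximal(index, z))
                assert got == multiset(pk.naive_query(panel, z))
                assert_match_invariants(panel, got, query=z)


class TestQueryBatch:
    def test_single_query_matches_indexed_route(self, p4):
        got = multiset(pk.query_batch(p4, ["1111"]))
        assert got == multiset(pk.query_set_maximal(pk.build_index(p4), "1111"))
        assert len(got) == 5

    def test_empty_query_list(self, p4):
        assert list(pk.query_batch(p4, [])) == []

    def test_batch_equals_per_query(self):
        rng = np.random.default_rng(9)
        for t in range(8):
            panel = random_panel(t + 700, max_m=50, max_n=80)
            queries = [(rng.random(panel.N) < 0.5).astype(np.uint8) for _ in range(5)]
            got = multiset(pk.query_batch(panel, queries))
            ref = multiset(
                m
                for qid, z in enumerate(queries)
                for m in pk.naive_query(panel, z, query_id=qid)
            )
            assert got == ref


class TestCenteredBlocks:
    def test_all_zero_panel_single_block(self):
        panel = pk.HaplotypePanel(np.zeros((6, 10), dtype=np.uint8))
        index = pk.build_index(panel)
        blocks = list(pk.centered_blocks(index, 5, 3))
        assert blocks == [((2, 8), frozenset(range(6)))]

    def test_planted_segment_recovered(self):
        panel = copying_panel(5, m=20, n=60)
        planted = pk.plant_shared_segment(panel, [2, 5, 7], (10, 40), donor=2)
        index = pk.build_index(planted)
        blocks = list(pk.centered_blocks(index, 25, 10))  # window [15, 35)
        containing = [b for _, b in blocks if {2, 5, 7} <= b]
        assert len(containing) == 1

    def test_oracle_pairwise_identity(self):
        for seed in range(6):
            panel = random_panel(seed + 400, max_m=25, max_n=40)
            index = pk.build_index(panel)
            L2 = 3
            for k in range(L2, panel.N - L2 + 1, 5):
                lo, hi = k - L2, k + L2
                windows = {}
                for i in range(panel.M):
                    windows.setdefault(tuple(panel.alleles[i, lo:hi]), set()).add(i)
                got = {b for _, b in pk.centered_blocks(index, k, L2)}
                assert got == {frozenset(v) for v in windows.values()}

    def test_window_out_of_range(self, p4):
        index = pk.build_index(p4)
        with pytest.raises(pk.PanelError):
            list(pk.centered_blocks(index, 0, 2))


class TestOracleEquivalenceGrid:
    """The central correctness property: fast and naive outputs agree as
    multisets on a broad grid of seeded random and copying panels."""

    @pytest.mark.parametrize("chunk", range(4))
    def test_long_and_set_maximal(self, chunk):
        for panel in panel_grid(12, offset=chunk * 12):
            L = max(1, panel.N // 5)
            assert multiset(pk.long_matches(panel, L)) == multiset(
                pk.naive_long_matches(panel, L)
            )
            got = multiset(pk.set_maximal_matches(panel))
            assert got == multiset(pk.naive_set_maximal(panel))
            assert_match_invariants(panel, list(pk.long_matches(panel, L)))

    def test_naive_oracle_self_consistency(self):
        """Querying a held-out sequence against the rest agrees with the
        within-panel scan restricted to that target (tie-free case)."""
        done = 0
        for seed in range(100):
            panel = random_panel(seed + 4000, max_m=15, max_n=30)
            i = 0
            rest = panel.subset_sequences([j for j in range(panel.M) if j != i])
            if len({tuple(r) for r in panel.alleles}) < panel.M:
                continue
            q = multiset(
                (m.seq_b, m.start, m.end)
                for m in pk.naive_query(rest, panel.sequence(i))
            )
            within = multiset(
                (m.seq_b - (m.seq_b > i), m.start, m.end)
                for m in pk.naive_set_maximal(panel)
                if m.seq_a == i
            )
            assert q == within
            done += 1
            if done >= 25:
                break
        assert done >= 10
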