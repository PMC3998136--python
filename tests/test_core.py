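"""Prefix/divergence sweep, extension mapping and index reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pbwtkit as pk
from pbwtkit.core import SweepState, build_prefix_divergence_step, build_prefix_step

from conftest import brute_divergence, brute_prefix_order, panel_grid, random_panel


class TestPrefixStep:
    def test_all_zero_column_is_identity(self):
        state = SweepState.initial(5)
        nxt = build_prefix_step(state, np.zeros(5, dtype=np.uint8))
        assert list(nxt.a) == [0, 1, 2, 3, 4]

    def test_p4_first_two_steps(self, p4):
        X = p4.alleles
        st0 = SweepState.initial(4)
        st1 = build_prefix_step(st0, X[st0.a, 0])
        assert list(st1.a) == [0, 2, 1, 3]
        st2 = build_prefix_step(st1, X[st1.a, 1])
        assert list(st2.a) == [2, 0, 1, 3]

    def test_wrong_column_length_rejected(self):
        with pytest.raises(pk.PanelError):
            build_prefix_step(SweepState.initial(4), np.zeros(3, dtype=np.uint8))


class TestDivergenceStep:
    def test_all_zero_panel_divergence(self):
        st = SweepState.initial(6)
        for k in range(5):
            st = build_prefix_divergence_step(st, np.zeros(6, dtype=np.uint8))
            assert st.d[0] == st.k
            assert list(st.d[1:]) == [0] * 5

    def test_p4_divergence_at_two(self, p4):
        X = p4.alleles
        st = SweepState.initial(4)
        for k in range(2):
            st = build_prefix_divergence_step(st, X[st.a, k])
        assert list(st.d) == [2, 2, 1, 0]

    def test_single_sequence_panel_is_sentinel_only(self):
        st = SweepState.initial(1)
        for k in range(6):
            st = build_prefix_divergence_step(st, np.array([k % 2], dtype=np.uint8))
            assert list(st.d) == [st.k]

    @pytest.mark.parametrize("seed", range(12))
    def test_sweep_matches_brute_force_everywhere(self, seed):
        panel = random_panel(seed, max_m=25, max_n=40)
        X = panel.alleles
        st = SweepState.initial(panel.M)
        for k in range(panel.N + 1):
            order = brute_prefix_order(X, k)
            assert list(st.a) == order
            assert list(st.d) == brute_divergence(X, order, k)
            if k < panel.N:
                st = build_prefix_divergence_step(st, X[st.a, k])

    @pytest.mark.parametrize("seed", range(6))
    def test_biallelic_neighbour_property(self, seed):
        """Where d[i] > 0 the neighbouring sorted prefixes carry alleles
        0 then 1 at the site just before the match start."""
        panel = random_panel(seed, max_m=30, max_n=50)
        X = panel.alleles
        st = SweepState.initial(panel.M)
        for k in range(panel.N):
            for i in range(1, panel.M):
                if 0 < st.d[i] <= st.k:
                    j = st.d[i] - 1
                    assert X[st.a[i - 1], j] == 0
                    assert X[st.a[i], j] == 1
            st = build_prefix_divergence_step(st, X[st.a, k])

    def test_permutation_conserved(self):
        panel = random_panel(99)
        expected = set(range(panel.M))
        for st in pk.sweep(panel):
            assert set(int(x) for x in st.a) == expected


class TestColumnRanks:
    @pytest.mark.parametrize(
        "column,u,v,c",
        [
            ([0, 0, 1, 1], [0, 1, 2, 2, 2], [0, 0, 0, 1, 2], 2),
            ([], [0], [0], 0),
            ([1, 1, 1, 1], [0, 0, 0, 0, 0], [0, 1, 2, 3, 4], 0),
        ],
    )
    def test_worked_examples(self, column, u, v, c):
        uu, vv, cc = pk.compute_column_ranks(np.array(column, dtype=np.uint8))
        assert list(uu) == u and list(vv) == v and cc == c

    def test_non_binary_rejected(self):
        with pytest.raises(pk.PanelError):
            pk.compute_column_ranks(np.array([0, 2, 1]))

    @given(st.lists(st.integers(0, 1), max_size=200))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_rank_identity(self, column):
        u, v, c = pk.compute_column_ranks(np.array(column, dtype=np.uint8))
        for i in range(len(column) + 1):
            assert u[i] + v[i] == i
        assert u[-1] == c


class TestExtend:
    def test_boundary_values(self):
        state = SweepState.initial(4)
        state.set_column([0, 0, 1, 1])
        assert state.extend(0, 0) == 0
        assert state.extend(0, 1) == state.c
        assert state.extend(4, 0) == state.c
        assert state.extend(4, 1) == 4
        assert state.extend(3, 1) == 3  # c + v[3] = 2 + 1

    def test_errors(self):
        state = SweepState.initial(3)
        state.set_column([0, 1, 0])
        with pytest.raises(pk.PanelError):
            state.extend(4, 0)
        with pytest.raises(pk.PanelError):
            state.extend(0, 2)
        with pytest.raises(pk.PanelError):
            SweepState.initial(3).extend(0, 0)  # ranks not set

    @pytest.mark.parametrize("seed", range(8))
    def test_extend_agrees_with_prefix_step(self, seed):
        """Applying extend at every boundary reproduces the inverse of
        the next permutation."""
        panel = random_panel(seed, max_m=20, max_n=30)
        X = panel.alleles
        st = SweepState.initial(panel.M)
        for k in range(panel.N):
            col = X[st.a, k]
            nxt = build_prefix_divergence_step(st, col)
            inv_next = np.empty(panel.M, dtype=int)
            inv_next[nxt.a] = np.arange(panel.M)
            for i in range(panel.M):
                assert st.extend(i, int(col[i])) == inv_next[st.a[i]]
            # monotone non-decreasing in i for each allele
            for allele in (0, 1):
                vals = [st.extend(i, allele) for i in range(panel.M + 1)]
                assert vals == sorted(vals)
            st = nxt


class TestIndex:
    @pytest.mark.parametrize("seed", range(50))
    def test_round_trip_random_panels(self, seed):
        panel = random_panel(seed, max_m=20, max_n=30)
        assert pk.decode_panel(pk.build_index(panel)) == panel

    def test_all_zero_panel_single_run_columns(self):
        panel = pk.HaplotypePanel(np.zeros((4, 4), dtype=np.uint8))
        index = pk.build_index(panel)
        for payload in index.payloads:
            assert payload == bytes([0x04])  # one run of four 0s

    def test_p4_final_checkpoint(self, p4):
        index = pk.build_index(p4)
        assert list(index.a_checkpoints[4]) == [1, 2, 0, 3]

    def test_empty_panels(self):
        for shape in ((0, 0), (0, 5), (5, 0)):
            panel = pk.HaplotypePanel(np.zeros(shape, dtype=np.uint8))
            index = pk.build_index(panel)
            decoded = pk.decode_panel(index)
            assert decoded.alleles.shape == shape

    @pytest.mark.parametrize("checkpoint", [1, 5, 64])
    def test_state_at_equals_uninterrupted_sweep(self, checkpoint):
        rng = np.random.default_rng(7)
        panel = pk.HaplotypePanel((rng.random((30, 200)) < 0.4).astype(np.uint8))
        index = pk.build_index(panel, checkpoint_interval=checkpoint)
        states = list(pk.sweep(panel))
        for k in range(panel.N + 1):
            st = pk.state_at(index, k)
            assert np.array_equal(st.a, states[k].a)
            assert np.array_equal(st.d, states[k].d)

    def test_state_at_checkpoint_verbatim(self):
        panel = random_panel(3, max_m=15, max_n=64)
        index = pk.build_index(panel, checkpoint_interval=16)
        for k in index.a_checkpoints:
            assert np.array_equal(pk.state_at(index, k).a, index.a_checkpoints[k])

    def test_state_at_zero(self):
        panel = random_panel(5)
        index = pk.build_index(panel)
        st = pk.state_at(index, 0)
        assert list(st.a) == list(range(panel.M))
        assert list(st.d) == [0] * panel.M

    def test_state_at_out_of_range(self):
        index = pk.build_index(random_panel(1))
        with pytest.raises(pk.PanelError):
            pk.state_at(index, index.N + 1)

    def test_truncated_payload_integrity_error(self, p4):
        index = pk.build_index(p4)
        index.payloads[-1] = index.payloads[-1][:-1] or b"\x01"
        index._runs_cache.clear()
        with pytest.raises(pk.IntegrityError) as exc:
            pk.decode_panel(index)
        assert "column" in str(exc.value)

    def test_cross_checkpoint_configs_decode_identically(self):
        panel = random_panel(11)
        p1 = pk.decode_panel(pk.build_index(panel, checkpoint_interval=1))
        p64 = pk.decode_panel(pk.build_index(panel, checkpoint_interval=64))
        assert p1 == p64 == panel
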