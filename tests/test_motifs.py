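import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroentropy import motifs as mo
from neuroentropy.exceptions import ConfigurationError, ValidationError
from neuroentropy.io import RegionTimeSeries


def _seq(codes, k=4, spec=None):
    return mo.MotifSequence(np.asarray(codes), spec or mo.WindowSpec(), 0.5,
                            tuple(f"r{i}" for i in range(k)))


class TestWindowedConnectivity:
    def test_window_count_formula(self, region_series):
        spec = mo.WindowSpec(window_len=30, step=10)
        wc = mo.windowed_connectivity(region_series, spec, (0, 100))
        assert len(wc.matrices) == (100 - 30) // 10 + 1 == 8

    def test_duplicated_region_gives_unit_offdiagonal(self, rng):
        a = rng.standard_normal(50)
        series = RegionTimeSeries(["x", "y"], np.stack([a, a.copy()]), 1.0)
        wc = mo.windowed_connectivity(series, mo.WindowSpec(window_len=20, step=5))
        assert np.allclose(wc.matrices[:, 0, 1], 1.0)

    def test_matches_bruteforce_per_window_correlation(self, region_series):
        spec = mo.WindowSpec(window_len=25, step=7)
        wc = mo.windowed_connectivity(region_series, spec, (0, 90))
        for mat, start in zip(wc.matrices, wc.window_starts):
            win = region_series.data[:, start:start + 25]
            for i, j in itertools.combinations(range(4), 2):
                x, y = win[i], win[j]
                xm, ym = x - x.mean(), y - y.mean()
                oracle = (xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
                assert mat[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_constant_region_window_dropped_and_counted(self, rng):
        data = rng.standard_normal((3, 60))
        data[1, :20] = 5.0  # constant inside early windows only
        series = RegionTimeSeries(["a", "b", "c"], data, 1.0)
        wc = mo.windowed_connectivity(series, mo.WindowSpec(window_len=10, step=10))
        assert wc.n_dropped == 2
        assert len(wc.matrices) == 4


class TestBinarize:
    def test_strong_correlations_give_complete_graph(self):
        c = np.full((4, 4), 0.9)
        np.fill_diagonal(c, 1.0)
        adj = mo.binarize(c, 0.5)
        assert adj.sum() == 12  # all 6 undirected edges, both triangle halves

    def test_weak_correlations_give_empty_graph(self):
        c = np.full((4, 4), 0.1)
        np.fill_diagonal(c, 1.0)
        assert mo.binarize(c, 0.5).sum() == 0

    def test_negative_edge_needs_absolute_mode(self):
        c = np.eye(2)
        c[0, 1] = c[1, 0] = -0.8
        assert mo.binarize(c, 0.5, use_absolute=False)[0, 1] == 0
        assert mo.binarize(c, 0.5, use_absolute=True)[0, 1] == 1

    def test_asymmetric_matrix_rejected(self):
        c = np.eye(3)
        c[0, 1] = 0.9
        with pytest.raises(ValidationError, match="symmetric"):
            mo.binarize(c, 0.5)


class TestMotifCoding:
    def test_empty_graph_is_code_zero(self):
        assert mo.encode_motif(np.zeros((4, 4), dtype=int)) == 0

    def test_complete_graph_is_code_sixty_three(self):
        adj = 1 - np.eye(4, dtype=int)
        assert mo.encode_motif(adj) == 63

    def test_first_pair_edge_is_code_one(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        assert mo.encode_motif(adj) == 1

    def test_encode_decode_bijection_over_all_four_node_patterns(self):
        seen = set()
        for code in range(64):
            adj = mo.decode_motif(code, 4)
            assert np.array_equal(adj, adj.T) and not np.any(np.diag(adj))
            back = mo.encode_motif(adj)
            assert back == code
            seen.add(back)
        assert len(seen) == 64

    def test_nonzero_diagonal_rejected(self):
        assert mo.encode_motif(np.zeros((3, 3), dtype=int)) == 0
        with pytest.raises(ValidationError, match="diagonal"):
            mo.encode_motif(np.eye(3, dtype=int))


class TestCountPossibleMotifs:
    @pytest.mark.parametrize("k,expected", [(4, 64), (2, 2)])
    def test_printed_counts(self, k, expected):
        assert mo.count_possible_motifs(k) == expected

    def test_five_nodes_match_exhaustive_enumeration(self):
        pairs = list(itertools.combinations(range(5), 2))
        count = 0
        for bits in itertools.product((0, 1), repeat=len(pairs)):
            adj = np.zeros((5, 5), dtype=int)
            for b, (i, j) in zip(bits, pairs):
                adj[i, j] = adj[j, i] = b
            count += 1
        assert mo.count_possible_motifs(5) == count == 1024

    def test_single_node_rejected(self):
        with pytest.raises(ValidationError):
            mo.count_possible_motifs(1)


class TestRepertoire:
    def test_constant_sequence_has_repertoire_one(self):
        rep = mo.motif_repertoire(_seq([0, 0, 0]), _seq([0, 0, 0]))
        assert rep.n_distinct == 1
        assert rep.exclusive == frozenset()

    def test_exclusive_motifs_vs_baseline(self):
        rep = mo.motif_repertoire(_seq([1, 2, 3]), _seq([1, 2]))
        assert rep.exclusive == frozenset({3})

    def test_node_count_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            mo.motif_repertoire(_seq([1, 2], k=4), _seq([1], k=3))


class TestMotifEntropy:
    def test_constant_sequence_zero_bits_both_orders(self):
        s = _seq([5] * 10)
        assert mo.motif_entropy(s, 0) == 0.0
        assert mo.motif_entropy(s, 1) == 0.0

    def test_uniform_cover_of_all_codes_is_six_bits(self):
        s = _seq(list(range(64)) * 3)
        assert mo.motif_entropy(s, 0) == pytest.approx(6.0)

    def test_deterministic_alternation(self):
        s = _seq([7, 9] * 20)
        assert mo.motif_entropy(s, 0) == pytest.approx(1.0)
        assert mo.motif_entropy(s, 1) == pytest.approx(0.0, abs=1e-12)

    def test_matches_count_and_sum_oracle(self, rng):
        codes = rng.integers(0, 64, 300)
        s = _seq(codes)
        counts = {}
        for c in codes:
            counts[c] = counts.get(c, 0) + 1
        oracle = -sum((n / 300) * np.log2(n / 300) for n in counts.values())
        assert mo.motif_entropy(s, 0) == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 9),
           st.integers(min_value=20, max_value=300))
    def test_conditioning_never_increases_entropy(self, seed, length):
        codes = np.random.default_rng(seed).integers(0, 64, length)
        s = _seq(codes)
        assert mo.motif_entropy(s, 1) <= mo.motif_entropy(s, 0) + 1e-9

    def test_invariant_under_code_relabeling(self, rng):
        codes = rng.integers(0, 64, 200)
        perm = rng.permutation(64)
        h0 = mo.motif_entropy(_seq(codes), 0)
        h0p = mo.motif_entropy(_seq(perm[codes]), 0)
        h1 = mo.motif_entropy(_seq(codes), 1)
        h1p = mo.motif_entropy(_seq(perm[codes]), 1)
        assert h0 == pytest.approx(h0p, abs=1e-12)
        assert h1 == pytest.approx(h1p, abs=1e-12)

    def test_invalid_order_rejected(self):
        with pytest.raises(ConfigurationError):
            mo.motif_entropy(_seq([1, 2, 3]), order=2)
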