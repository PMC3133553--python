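import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swpa import (
    PeakList,
    SWParams,
    align_peaklists,
    build_score_matrix,
    postfilter_pairs,
    traceback_single,
    traceback_swre,
    traceback_swrm,
    traceback_swrme,
)
from conftest import random_peaklist
from oracles import brute_force_best_local_score, segment_score

VARIANTS = {1: traceback_swrm, 2: traceback_swre, 3: traceback_swrme}


def matches(segment):
    return [(s.i, s.j) for s in segment if s.kind == "match"]


def identity_sim(n, off=-0.5):
    sim = np.full((n, n), off)
    np.fill_diagonal(sim, 1.0)
    return sim


def two_block_sim():
    """Peaks 0-1 and 3-4 conserved (second block slightly stronger), peak 2 orphaned."""
    sim = np.full((5, 5), -0.5)
    for i, s in [(0, 0.95), (1, 0.95), (3, 0.96), (4, 0.97)]:
        sim[i, i] = s
    return sim


TWO_BLOCK_PARAMS = SWParams(u=1, v=3, d=2, rho=0.9)


class TestTracebackSingle:
    def test_zero_matrix_gives_empty_segment(self):
        sim = np.full((3, 3), -0.5)
        sm = build_score_matrix(None, None, sim, SWParams(rho=0.9))
        assert traceback_single(sm, sim) == []

    def test_identity_diagonal_recovered(self):
        sim = identity_sim(3)
        sm = build_score_matrix(None, None, sim, SWParams(u=1, v=1, d=0.5, rho=0.9))
        assert matches(traceback_single(sm, sim)) == [(0, 0), (1, 1), (2, 2)]

    def test_single_positive_cell(self):
        sim = np.array([[0.95]])
        sm = build_score_matrix(None, None, sim, SWParams(rho=0.9))
        assert matches(traceback_single(sm, sim)) == [(0, 0)]


class TestRepeatTracebacks:
    @pytest.mark.parametrize("variant", [traceback_swrm, traceback_swre, traceback_swrme])
    def test_zero_matrix_gives_no_segments(self, variant):
        sim = np.full((4, 4), -0.2)
        sm = build_score_matrix(None, None, sim, SWParams(rho=0.9))
        assert variant(sm, sim) == []

    @pytest.mark.parametrize("variant", [traceback_swrm, traceback_swre, traceback_swrme])
    def test_two_disjoint_blocks_both_recovered(self, variant):
        sim = two_block_sim()
        sm = build_score_matrix(None, None, sim, TWO_BLOCK_PARAMS)
        segs = variant(sm, sim)
        assert len(segs) == 2
        found = sorted(pair for seg in segs for pair in matches(seg))
        assert found == [(0, 0), (1, 1), (3, 3), (4, 4)]

    def test_swrm_block_scores_are_local_optima(self):
        # cross-check both segment scores against the brute-force enumerator
        sim = two_block_sim()
        p = TWO_BLOCK_PARAMS
        sm = build_score_matrix(None, None, sim, p)
        segs = traceback_swrm(sm, sim)
        first_score = segment_score(segs[0], sim, p.u, p.v, p.rho, p.d)
        assert first_score == pytest.approx(brute_force_best_local_score(sim, p.u, p.v, p.rho, p.d))
        assert segment_score(segs[1], sim, p.u, p.v, p.rho, p.d) == pytest.approx(1.90)

    def test_identical_lists_give_full_diagonal_in_one_segment(self):
        sim = identity_sim(10)
        sm = build_score_matrix(None, None, sim, SWParams(rho=0.9))
        segs = traceback_swrm(sm, sim)
        assert len(segs) == 1
        assert matches(segs[0]) == [(i, i) for i in range(10)]
        assert segs[0] == traceback_single(sm, sim)

    def test_swre_first_segment_matches_swrm_when_max_is_at_corner(self):
        sim = identity_sim(6)
        sm = build_score_matrix(None, None, sim, SWParams(rho=0.9))
        assert traceback_swre(sm, sim)[0] == traceback_swrm(sm, sim)[0]

    def test_swrme_equals_swrm_when_run_ends_in_last_column(self):
        sim = np.full((4, 4), -0.5)
        for i in range(4):
            sim[i, i] = 0.95
        sm = build_score_matrix(None, None, sim, SWParams(u=1, v=1, d=0.5, rho=0.9))
        assert traceback_swrme(sm, sim) == traceback_swrm(sm, sim)

    def test_swrme_scan_falls_through_zero_ending_columns(self):
        # only the centre pair is similar and gaps are too costly to carry
        # positive scores into the last column, so the scan falls back to it
        sim = np.full((3, 3), -0.5)
        sim[1, 1] = 0.95
        sm = build_score_matrix(None, None, sim, SWParams(u=1, v=1, d=2.0, rho=0.9))
        assert (sm.H[1:, 3] == 0).all()
        segs = traceback_swrme(sm, sim)
        assert [matches(s) for s in segs] == [[(1, 1)]]


class TestPostFilter:
    def test_threshold_count(self):
        sim = np.diag([0.95, 0.5, 0.91])
        sm = build_score_matrix(None, None, sim, SWParams(rho=0.0, v=0.0))
        segs = traceback_swrm(sm, sim)
        assert len(postfilter_pairs(segs, sim, 0.9)) == 2
        assert len(postfilter_pairs(segs, sim, 0.0)) == 3

    def test_empty_segments_give_no_pairs(self):
        assert postfilter_pairs([], np.zeros((2, 2)), 0.5) == []


class TestAlignPeaklists:
    def test_identity_recovery(self, rng):
        X = random_peaklist(rng, 20)
        for q in (1, 2, 3):
            a = align_peaklists(X, X, SWParams(rho=0.8, q=q))
            assert a.k == 20
            assert [(i, j) for i, j, _ in a.pairs] == [(i, i) for i in range(20)]

    def test_all_variants_identical_on_identical_inputs(self, rng):
        X = random_peaklist(rng, 12)
        results = [align_peaklists(X, X, SWParams(rho=0.8, q=q)) for q in (1, 2, 3)]
        assert results[0].pairs == results[1].pairs == results[2].pairs
        assert results[0].segments == results[1].segments == results[2].segments

    def test_deleted_peaks_leave_surviving_compounds_matched_to_themselves(self, rng):
        from swpa import order_peaklist

        X = order_peaklist(random_peaklist(rng, 25))
        keep = [i for i in range(25) if i % 5 != 0]  # 20% deletion
        Y = PeakList([X[i] for i in keep], name="thinned")
        a = align_peaklists(X, Y, SWParams(rho=0.8))
        assert a.k == len(keep)
        for i, j, s in a.pairs:
            assert X[i].label == Y[j].label
            assert s == pytest.approx(1.0)

    def test_no_overlap_yields_empty_alignment(self, rng):
        X = random_peaklist(rng, 5)
        Y = random_peaklist(rng, 5)
        a = align_peaklists(X, Y, SWParams(rho=0.99))
        assert a.k == 0

    @given(st.integers(0, 2**31 - 1), st.sampled_from([1, 2, 3]))
    @settings(max_examples=40, deadline=None)
    def test_pair_invariants_on_random_matrices(self, seed, q):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(1, 9, size=2)
        sim = rng.uniform(-1, 1, size=(m, n))
        p = SWParams(rho=float(rng.uniform(0, 1)), d=float(rng.uniform(0.1, 1.5)), q=q)
        sm = build_score_matrix(None, None, sim, p)
        segs = VARIANTS[q](sm, sim)
        pairs = postfilter_pairs(segs, sim, p.rho)
        assert len(pairs) <= min(m, n)
        for (i1, j1, s1), (i2, j2, _) in zip(pairs, pairs[1:]):
            assert i1 < i2 and j1 < j2  # order preservation, both coordinates
        assert all(s >= p.rho for _, _, s in pairs)
        seen_i = [i for i, _, _ in pairs]
        seen_j = [j for _, j, _ in pairs]
        assert len(set(seen_i)) == len(seen_i) and len(set(seen_j)) == len(seen_j)
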