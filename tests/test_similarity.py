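"""Built-in aligner vs independent oracles; e-value and threshold semantics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from Bio import Align
from Bio.Align import substitution_matrices

from conftest import make_model, random_protein
from phyletic.io_formats import HitRecord
from phyletic.similarity import (
    DEFAULT_PARAMS,
    AlignmentParams,
    SimilarityThreshold,
    align_pair,
    all_vs_all,
    cross_hits,
    encode_sequence,
    filter_hits,
    local_score,
)

B62 = substitution_matrices.load("BLOSUM62")


def brute_enumerate_score(a: str, b: str, gap_open=11, gap_extend=1) -> int:
    """Exhaustive enumeration of every local alignment (all start pairs,
    all edit paths, ends anywhere).  Exponential; lengths <= 6 only."""
    best = 0

    def rec(i, j, score, last):
        nonlocal best
        if score > best:
            best = score
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + B62[a[i], b[j]], "M")
        if i < len(a):
            rec(i + 1, j, score - (gap_extend if last == "I" else gap_open + gap_extend), "I")
        if j < len(b):
            rec(i, j + 1, score - (gap_extend if last == "D" else gap_open + gap_extend), "D")

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            rec(i0, j0, 0, None)
    return int(best)


def gotoh_score(a: str, b: str, gap_open=11, gap_extend=1) -> int:
    """Plain-python quadratic affine-gap local alignment (independent of
    the compiled kernel)."""
    n, m = len(a), len(b)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + B62[a[i - 1], b[j - 1]], E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def kernel_score(a: str, b: str) -> int:
    return local_score(encode_sequence(a), encode_sequence(b))


class TestLocalScore:
    def test_matches_exhaustive_enumeration_on_tiny_strings(self, rng):
        for _ in range(12):
            a = random_protein(rng, int(rng.integers(1, 6)))
            b = random_protein(rng, int(rng.integers(1, 6)))
            assert kernel_score(a, b) == brute_enumerate_score(a, b)

    def test_gotoh_oracle_matches_enumeration(self, rng):
        # validates the quadratic oracle itself before it is trusted below
        for _ in range(8):
            a = random_protein(rng, int(rng.integers(2, 6)))
            b = random_protein(rng, int(rng.integers(2, 6)))
            assert gotoh_score(a, b) == brute_enumerate_score(a, b)

    def test_matches_quadratic_oracle_on_random_pairs(self, rng):
        for _ in range(60):
            a = random_protein(rng, int(rng.integers(5, 51)))
            b = random_protein(rng, int(rng.integers(5, 51)))
            assert kernel_score(a, b) == gotoh_score(a, b)

    def test_matches_biopython_on_random_pairs(self, rng):
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = B62
        aligner.open_gap_score = -12
        aligner.extend_gap_score = -1
        for _ in range(30):
            a = random_protein(rng, int(rng.integers(20, 120)))
            b = random_protein(rng, int(rng.integers(20, 120)))
            assert kernel_score(a, b) == int(aligner.score(a, b))

    def test_score_symmetric(self, rng):
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(5, 60)))
            b = random_protein(rng, int(rng.integers(5, 60)))
            assert kernel_score(a, b) == kernel_score(b, a)


class TestAlignPair:
    def test_self_alignment_full_identity(self, rng):
        for length in (10, 37, 120):
            seq = random_protein(rng, length)
            hit = align_pair(make_model("x", "aa", seq), make_model("y", "bb", seq))
            assert hit is not None
            assert hit.pident == 100.0
            assert (hit.qstart, hit.qend) == (1, length)
            assert (hit.sstart, hit.send) == (1, length)
            assert hit.mismatch == 0 and hit.gapopen == 0

    def test_unalignable_pair_returns_nothing(self):
        hit = align_pair(make_model("x", "aa", "KKKK"), make_model("y", "bb", "GGGG"))
        assert hit is None

    def test_selenocysteine_scored_as_cysteine(self):
        a = make_model("x", "aa", "MUUKLMNPQRST")
        b = make_model("y", "bb", "MCCKLMNPQRST")
        hit = align_pair(a, b)
        assert hit is not None and hit.pident == 100.0


class TestEvalue:
    def test_strictly_decreasing_in_score(self):
        p = DEFAULT_PARAMS
        evs = [p.evalue(s, 200, 10000) for s in range(10, 200, 5)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_scales_with_search_space(self):
        p = DEFAULT_PARAMS
        assert p.evalue(60, 200, 20000) == pytest.approx(2 * p.evalue(60, 200, 10000))

    def test_invalid_params_rejected(self):
        with pytest.raises(Exception):
            AlignmentParams(gap_open=0)
        with pytest.raises(Exception):
            AlignmentParams(lam=-1.0)
        with pytest.raises(Exception):
            SimilarityThreshold(max_evalue=0.0)


def _hit(q, s, evalue):
    return HitRecord(q, s, 100.0, 10, 0, 0, 1, 10, 1, 10, evalue, 50.0)


class TestFilterHits:
    def test_inclusive_boundary(self):
        thr = SimilarityThreshold(max_evalue=0.0001)
        kept = filter_hits([_hit("a", "b", 0.0001), _hit("a", "c", 0.000100001)], thr)
        assert [h.sseqid for h in kept] == ["b"]

    def test_example_cutoff(self):
        thr = SimilarityThreshold(max_evalue=1e-4)
        kept = filter_hits([_hit("a", "b", 1e-5), _hit("a", "c", 0.001)], thr)
        assert [h.evalue for h in kept] == [1e-5]

    def test_empty(self):
        assert filter_hits([], SimilarityThreshold()) == []

    @given(
        st.lists(
            st.tuples(st.sampled_from("abcdef"), st.sampled_from("ghijkl"),
                      st.floats(0, 1, allow_nan=False)),
            max_size=40,
        )
    )
    def test_idempotent_and_order_preserving(self, triples):
        hits = [_hit(q, s, e) for q, s, e in triples]
        thr = SimilarityThreshold(max_evalue=0.01)
        once = filter_hits(hits, thr)
        assert filter_hits(once, thr) == once
        assert [h for h in hits if h.evalue <= 0.01] == once


class TestAllVsAll:
    def test_single_gene_self_pair_excluded(self, rng):
        g = make_model("g1", "aa", random_protein(rng, 50))
        assert all_vs_all([g], [g]) == []

    def test_planted_families_recovered(self, rng):
        # 4 families x 2 genomes, plus noise singletons
        models_a, models_b, expect = [], [], set()
        for f in range(4):
            seq = random_protein(rng, 200)
            models_a.append(make_model(f"a{f}", "aa", seq))
            models_b.append(make_model(f"b{f}", "bb", seq))
            expect.add((f"a{f}", f"b{f}"))
        models_a.append(make_model("a_noise", "aa", random_protein(rng, 200)))
        hits = all_vs_all(models_a + models_b, models_a + models_b)
        linked = {tuple(sorted((h.qseqid, h.sseqid))) for h in hits
                  if h.qseqid[0] != h.sseqid[0]}
        assert linked == expect
        # deterministic order
        assert hits == sorted(hits, key=lambda h: (h.qseqid, h.sseqid))

    def test_cross_hits_directions_consistent(self, rng):
        seq = random_protein(rng, 150)
        a = [make_model("a1", "aa", seq), make_model("a2", "aa", random_protein(rng, 150))]
        b = [make_model("b1", "bb", seq)]
        ab, ba = cross_hits(a, b)
        assert {(h.qseqid, h.sseqid) for h in ab} == {("a1", "b1")}
        assert {(h.qseqid, h.sseqid) for h in ba} == {("b1", "a1")}
        # coordinates swap between the two directions of the same pair
        assert (ab[0].qstart, ab[0].qend) == (ba[0].sstart, ba[0].send)
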