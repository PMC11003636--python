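"""Alignment kernel: scores, statistics, and the brute-force DP oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from prokbrowse.align import (AlignParams, KmerIndex, batch_search, evalue,
                              local_align, raw_local_score, score_ratio,
                              self_score)
from prokbrowse.datastore import ProteinSeq

from conftest import mutate, prot, random_protein

_B62 = substitution_matrices.load("BLOSUM62")


def _sub_score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[a, b])


def sw_affine_oracle(a: str, b: str, gap_open=11.0, gap_extend=1.0):
    """Independent Gotoh dynamic program: optimal local score and endpoint.

    A gap of length L costs gap_open + L * gap_extend.  Returns
    (score, qend, send) with 1-based inclusive endpoints of the best cell.
    """
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    best, best_ij = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + _sub_score(a[i - 1], b[j - 1]),
                          E[i][j], F[i][j])
            if H[i][j] > best:
                best, best_ij = H[i][j], (i, j)
    return best, best_ij[0], best_ij[1]


def _best_diagonal_window(a: str, b: str):
    """Kadane-style best-scoring window on the main diagonal (no gaps).

    Valid oracle for equal-length substitution-only pairs where the optimal
    local alignment is gapless.  Returns (score, start, end), 1-based.
    """
    best = (0.0, 1, 0)
    run, run_start = 0.0, 1
    for i in range(len(a)):
        run += _sub_score(a[i], b[i])
        if run <= 0:
            run, run_start = 0.0, i + 2
        elif run > best[0]:
            best = (run, run_start, i + 1)
    return best


class TestLocalAlign:
    def test_identical_sequences_are_perfect_hits(self):
        rng = np.random.default_rng(0)
        seq = random_protein(rng, 100)
        h = local_align(prot(seq, "a"), prot(seq, "b"))
        assert h.pct_identity == 100.0
        assert h.query_cov == 100.0 and h.subject_cov == 100.0
        assert h.bit_score == pytest.approx(self_score(prot(seq, "a")))

    def test_dissimilar_homopolymers_do_not_align(self):
        assert local_align(prot("A" * 40, "a"), prot("W" * 40, "b")) is None

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_score_matches_dp_oracle_on_divergent_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = random_protein(rng, 60)
        b = mutate(a, 12, rng)
        score, qend, send = sw_affine_oracle(a, b)
        h = local_align(prot(a, "a"), prot(b, "b"))
        assert h.raw_score == pytest.approx(score)
        assert (h.qend, h.send) == (qend, send)
        # substitution-only pair: the optimum is gapless on the main diagonal,
        # so an independent best-substring scan fixes start, end, and identity
        k_score, k_start, k_end = _best_diagonal_window(a, b)
        assert h.raw_score == pytest.approx(k_score)
        assert (h.qstart, h.qend) == (k_start, k_end)
        matches = sum(a[i] == b[i] for i in range(k_start - 1, k_end))
        assert h.pct_identity == pytest.approx(
            100.0 * matches / (k_end - k_start + 1))

    @pytest.mark.parametrize("seed", [10, 20])
    def test_score_matches_dp_oracle_with_indels(self, seed):
        rng = np.random.default_rng(seed)
        a = random_protein(rng, 50)
        b = a[:20] + a[26:]  # 6-residue deletion
        score, _, _ = sw_affine_oracle(a, b)
        h = local_align(prot(a, "a"), prot(b, "b"))
        assert h.raw_score == pytest.approx(score)

    def test_score_is_symmetric(self):
        rng = np.random.default_rng(7)
        a, b = random_protein(rng, 80), random_protein(rng, 70)
        assert raw_local_score(a, b) == pytest.approx(raw_local_score(b, a))

    def test_unknown_residues_rejected(self):
        with pytest.raises(ValueError, match="residues"):
            ProteinSeq("bad", "MKVLO")

    def test_x_scores_zero(self):
        # an all-X region contributes nothing to the score
        assert raw_local_score("MKVLH" + "X" * 10, "MKVLH") == pytest.approx(
            raw_local_score("MKVLH", "MKVLH"))


class TestScoreRatioAndEvalue:
    def test_self_hit_has_ratio_one(self):
        rng = np.random.default_rng(3)
        p = prot(random_protein(rng, 90))
        h = local_align(p, p)
        assert score_ratio(h.bit_score, self_score(p)) == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        assert score_ratio(50.0, 100.0) == 0.5

    def test_zero_self_score_rejected(self):
        with pytest.raises(ValueError):
            score_ratio(10.0, 0.0)

    def test_evalue_closed_form(self):
        # bit 30, query 100 aa, db 1e4 residues: E = 1e6 * 2^-30 ~ 9.3e-4
        e = evalue(30.0, 100, 10_000)
        assert e == pytest.approx(1e6 * 2.0 ** -30)
        assert e < 1e-3

    def test_evalue_scaling(self):
        e1 = evalue(40.0, 100, 1000)
        assert evalue(50.0, 100, 1000) == pytest.approx(e1 * 2.0 ** -10)
        assert evalue(40.0, 100, 2000) == pytest.approx(2 * e1)

    def test_ratio_below_one_for_any_hit(self):
        rng = np.random.default_rng(8)
        q = prot(random_protein(rng, 100), "q")
        ss = self_score(q)
        for seed in range(5):
            sub = prot(mutate(q.sequence, 30, np.random.default_rng(seed)), f"s{seed}")
            h = local_align(q, sub)
            assert h.bit_score / ss <= 1.0 + 1e-12


class TestBatchSearch:
    def _family_index(self, seed=0, n=30, length=120, n_sub=36):
        rng = np.random.default_rng(seed)
        root = random_protein(rng, length)
        prots = {f"m{i:02d}": prot(mutate(root, n_sub, rng), f"m{i:02d}")
                 for i in range(n)}
        return prot(root, "root"), prots

    def test_query_in_db_is_rank_one_with_ratio_one(self):
        root, prots = self._family_index(seed=1)
        prots["self"] = prot(root.sequence, "self")
        hits = batch_search(root, KmerIndex(prots), e_max=1e-3)
        assert hits[0].subject_id == "self" and hits[0].rank == 1
        assert hits[0].bit_score == pytest.approx(self_score(root))

    def test_agrees_with_exhaustive_alignment_oracle(self):
        root, prots = self._family_index(seed=2, n=25)
        db_len = sum(p.length for p in prots.values())
        hits = batch_search(root, KmerIndex(prots), db_len=db_len, e_max=1e-3)
        expected = {}
        for pid, p in prots.items():
            h = local_align(root, p, db_len=db_len)
            if h is not None and h.e_value <= 1e-3:
                expected[pid] = h
        assert {h.subject_id for h in hits} == set(expected)
        for h in hits:
            assert h.bit_score == pytest.approx(expected[h.subject_id].bit_score)
        bits = [h.bit_score for h in hits]
        assert bits == sorted(bits, reverse=True)
        assert [h.rank for h in hits] == list(range(1, len(hits) + 1))

    def test_null_database_yields_no_significant_hits(self):
        # unrelated random sequences: E <= 1e-3 hits in at most 1% of trials
        n_bad = 0
        for trial in range(100):
            rng = np.random.default_rng(1000 + trial)
            q = prot(random_protein(rng, 120), "q")
            prots = {f"r{i}": prot(random_protein(rng, 120), f"r{i}")
                     for i in range(20)}
            hits = batch_search(q, KmerIndex(prots), e_max=1e-3)
            n_bad += bool(hits)
        assert n_bad <= 1

    def test_prefilter_recall_on_real_families(self):
        # members pairwise >= ~70% identity: the 4-mer prefilter loses nothing
        missed = total = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            root = random_protein(rng, 110)
            prots = {f"m{i}": prot(mutate(root, 16, rng), f"m{i}")
                     for i in range(20)}
            index = KmerIndex(prots)
            db_len = sum(p.length for p in prots.values())
            for qid, q in prots.items():
                found = {h.subject_id for h in batch_search(q, index, db_len=db_len,
                                                            e_max=1e-3)}
                for pid, p in prots.items():
                    h = local_align(q, p, db_len=db_len)
                    if h is not None and h.e_value <= 1e-3:
                        total += 1
                        missed += pid not in found
        assert total > 500
        assert missed / total <= 0.001

    def test_short_query_falls_back_to_exhaustive(self):
        prots = {"a": prot("MKV", "a"), "b": prot("WWWW", "b")}
        index = KmerIndex(prots)
        assert index.candidates("MK") == ["a", "b"]
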