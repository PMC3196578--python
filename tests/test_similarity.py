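"""Similarity engine: seeded banded search vs exact oracles."""
import math
import random

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings, strategies as st

from chromosurvey.similarity import (Hit, SearchParams, SimilaritySearcher,
                                     ThresholdProfile, best_hit_per_query,
                                     evalue_of, filter_hits,
                                     reciprocal_best_hits, revcomp, search)


def _rnd(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutated(rng, seq, n_ops):
    out = list(seq)
    for _ in range(n_ops):
        i = rng.randrange(len(out))
        op = rng.random()
        if op < 0.7:
            out[i] = rng.choice("ACGT")
        elif op < 0.85:
            out[i] = ""
        else:
            out[i] = out[i] + rng.choice("ACGT")
    return "".join(x for x in out if x)


class TestSearch:
    def test_identical_sequence_full_hit(self):
        rng = random.Random(0)
        s = _rnd(rng, 300)
        hits = search([("q", s)], [("s", s)], "nucleotide",
                      SearchParams(max_evalue=1e-6))
        assert len(hits) == 1
        h = hits[0]
        assert h.identity_pct == 100.0
        assert h.query_cov_pct == 100.0
        assert h.subject_cov_pct == 100.0
        assert h.strand == "+"

    def test_reverse_complement_strand_symmetry(self):
        rng = random.Random(1)
        s = _rnd(rng, 200)
        plus = search([("q", s)], [("s", s)], "nucleotide")[0]
        minus = search([("q", revcomp(s))], [("s", s)], "nucleotide")[0]
        assert minus.strand == "-"
        assert minus.score == plus.score
        assert minus.subject_interval == plus.subject_interval

    def test_matches_smith_waterman_oracle_on_toy_set(self):
        """Above-cutoff hit set and scores equal full Smith-Waterman."""
        rng = random.Random(7)
        seqs = []
        for i in range(20):
            seqs.append((f"s{i}", _rnd(rng, rng.randint(120, 300))))
        # plant homologous pairs so there is signal to find
        for i in range(10):
            src = seqs[i][1]
            core = src[20:140]
            seqs.append((f"h{i}",
                         _rnd(rng, 15) + _mutated(rng, core, 8) + _rnd(rng, 15)))
        params = SearchParams(min_seed_count=1, max_targets=100,
                              max_evalue=1e9)
        cutoff = 40
        mine = {}
        for qid, q in seqs:
            searcher = SimilaritySearcher(
                [(sid, s) for sid, s in seqs if sid != qid], "nucleotide",
                params)
            for h in searcher.search_one(qid, q):
                if h.score >= cutoff:
                    mine[(qid, h.subject_id)] = h.score

        aln = Align.PairwiseAligner()
        aln.mode = "local"
        aln.match_score = 1
        aln.mismatch_score = -2
        aln.open_gap_score = -7
        aln.extend_gap_score = -2
        oracle = {}
        for qid, q in seqs:
            for sid, s in seqs:
                if sid == qid:
                    continue
                sc = max(int(aln.score(q, s)), int(aln.score(revcomp(q), s)))
                if sc >= cutoff:
                    oracle[(qid, sid)] = sc
        assert mine == oracle

    def test_alphabet_mismatch_raises(self):
        with pytest.raises(ValueError):
            search([("q", "MKVLW" * 10)], [("s", "ACGT" * 20)], "nucleotide")

    def test_bitscore_monotone_in_length_on_identical_seqs(self):
        rng = random.Random(3)
        bits = []
        evals = []
        for n in (60, 120, 240):
            s = _rnd(rng, n)
            h = search([("q", s)], [("s", s)], "nucleotide")[0]
            bits.append(h.bitscore)
            evals.append(h.evalue)
        assert bits == sorted(bits)
        assert evals == sorted(evals, reverse=True)


class TestEvalue:
    def test_definition_and_linearity(self):
        assert evalue_of(0.0, 1, 1) == 1.0
        assert evalue_of(10.0, 5, 100) == pytest.approx(
            2 * evalue_of(10.0, 5, 50))
        # hand computation of m*n*2^-bits
        assert evalue_of(20.0, 300, 1000) == pytest.approx(
            300 * 1000 * 2.0 ** -20)

    def test_strictly_decreasing_in_score(self):
        e = [evalue_of(b, 100, 1000) for b in (0, 5, 10, 20)]
        assert e == sorted(e, reverse=True)


def _mk_hit(q="q", s="s", ev=1e-9, ident=90.0, sim=95.0, qc=80.0, sc=10.0,
            mm=3, bits=50.0):
    return Hit(query_id=q, subject_id=s, identity_pct=ident,
               similarity_pct=sim, evalue=ev, bitscore=bits,
               query_cov_pct=qc, subject_cov_pct=sc, strand="+", frame=0,
               query_interval=(0, 10), subject_interval=(0, 10),
               mismatches=mm)


class TestFilterHits:
    def test_identity_boundary(self):
        prof = ThresholdProfile(min_identity_pct=30.0)
        assert filter_hits([_mk_hit(ident=29.9)], prof) == []
        assert len(filter_hits([_mk_hit(ident=30.0)], prof)) == 1

    def test_empty(self):
        assert filter_hits([], ThresholdProfile()) == []

    def test_equals_independent_bound_oracle_and_idempotent(self):
        rng = random.Random(5)
        hits = [_mk_hit(q=f"q{i}", ev=10 ** -rng.randint(0, 40),
                        ident=rng.uniform(0, 100), sim=rng.uniform(0, 100),
                        qc=rng.uniform(0, 100), sc=rng.uniform(0, 100),
                        mm=rng.randint(0, 10)) for i in range(200)]
        prof = ThresholdProfile(max_evalue=1e-6, min_identity_pct=30,
                                min_similarity_pct=50, min_query_cov_pct=50,
                                min_subject_cov_pct=1, max_mismatches=5,
                                mode="translated")
        expected = [h for h in hits
                    if h.evalue <= 1e-6 and h.identity_pct >= 30
                    and h.similarity_pct >= 50 and h.query_cov_pct >= 50
                    and h.subject_cov_pct >= 1 and h.mismatches <= 5]
        got = filter_hits(hits, prof)
        assert got == expected
        assert filter_hits(got, prof) == got


class TestBestAndReciprocal:
    def test_lowest_evalue_wins(self):
        hits = [_mk_hit(s="a", ev=1e-8), _mk_hit(s="b", ev=1e-20)]
        assert best_hit_per_query(hits)["q"].subject_id == "b"

    def test_tie_broken_by_bits_then_subject(self):
        hits = [_mk_hit(s="b", ev=1e-8, bits=50), _mk_hit(s="a", ev=1e-8,
                                                          bits=50)]
        assert best_hit_per_query(hits)["q"].subject_id == "a"
        hits = [_mk_hit(s="b", ev=1e-8, bits=60), _mk_hit(s="a", ev=1e-8,
                                                          bits=50)]
        assert best_hit_per_query(hits)["q"].subject_id == "b"

    def test_best_hit_equals_sort_oracle(self):
        rng = random.Random(11)
        hits = [_mk_hit(q=f"q{rng.randint(0, 5)}", s=f"s{i}",
                        ev=10 ** -rng.randint(0, 30),
                        bits=rng.randint(20, 90)) for i in range(100)]
        best = best_hit_per_query(hits)
        for qid in {h.query_id for h in hits}:
            expect = sorted((h for h in hits if h.query_id == qid),
                            key=lambda h: (h.evalue, -h.bitscore,
                                           h.subject_id))[0]
            assert best[qid] is expect

    def test_rbh_toy_cases(self):
        ab = [_mk_hit(q="a", s="b")]
        ba = [_mk_hit(q="b", s="a")]
        assert reciprocal_best_hits(ab, ba) == {("a", "b")}
        ba_wrong = [_mk_hit(q="b", s="c")]
        assert reciprocal_best_hits(ab, ba_wrong) == set()

    def test_rbh_equals_exhaustive_oracle_on_random_matrix(self):
        rng = np.random.default_rng(4)
        n = 20
        scores = rng.random((n, n))
        ab, ba = [], []
        for i in range(n):
            for j in range(n):
                ev = 10 ** (-30 * scores[i, j])
                ab.append(_mk_hit(q=f"a{i}", s=f"b{j}", ev=ev,
                                  bits=float(scores[i, j])))
                ba.append(_mk_hit(q=f"b{j}", s=f"a{i}", ev=ev,
                                  bits=float(scores[i, j])))
        got = reciprocal_best_hits(ab, ba)
        expect = set()
        for i in range(n):
            j = int(np.argmax(scores[i]))
            if int(np.argmax(scores[:, j])) == i:
                expect.add((f"a{i}", f"b{j}"))
        assert got == expect


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_filter_idempotence_property(seed):
    """filter o filter == filter for any random hit set and profile."""
    rng = random.Random(seed)
    hits = [_mk_hit(q=f"q{i}", ev=10 ** -rng.randint(0, 12),
                    ident=rng.uniform(0, 100), qc=rng.uniform(0, 100))
            for i in range(30)]
    prof = ThresholdProfile(max_evalue=10 ** -rng.randint(0, 8),
                            min_identity_pct=rng.uniform(0, 100))
    once = filter_hits(hits, prof)
    assert filter_hits(once, prof) == once
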