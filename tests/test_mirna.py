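"""miRNA pipeline: mature hits, pairing, extraction, folding, MFEI."""
import random

import pytest

from chromosurvey import mirna
from chromosurvey.mirna import (MatureHit, MirnaCandidate, MirnaConfig,
                                extract_precursor, find_mature_hits,
                                fold_hairpin, gc_percent, mfei, pair_hits,
                                pair_table, validate_candidate)
from chromosurvey.simulate import revcomp


def _rnd(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="module")
def setup():
    rng = random.Random(21)
    mature = _rnd(rng, 21)
    return rng, mature


class TestMatureHits:

    def test_exact_direct_hit(self, setup):
        rng, mature = setup
        subj = _rnd(rng, 80) + mature + _rnd(rng, 80)
        hits = find_mature_hits([("s1", subj)], [("tae-miR1000", mature)])
        direct = [h for h in hits if h.orientation == "direct"]
        assert len(direct) == 1
        assert direct[0].mismatches == 0
        assert direct[0].family == "miR1000"

    def test_revcomp_hit_retained_despite_mismatches(self, setup):
        rng, mature = setup
        # 5 mutations clustered at the 5' end: a direct hit this bad would
        # be discarded, but reverse-complement hits are always retained
        star = list(revcomp(mature))
        for i in (2, 4, 6, 8, 10):
            star[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[star[i]]
        subj = _rnd(rng, 60) + "".join(star) + _rnd(rng, 60)
        hits = find_mature_hits([("s1", subj)], [("tae-miR1000", mature)])
        assert any(h.orientation == "revcomp" for h in hits)

    def test_direct_hit_with_four_mismatches_discarded(self, setup):
        rng, mature = setup
        mut = list(mature)
        for i in (2, 7, 12, 17):
            mut[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mut[i]]
        subj = _rnd(rng, 60) + "".join(mut) + _rnd(rng, 60)
        hits = find_mature_hits([("s1", subj)], [("tae-miR1000", mature)])
        assert not [h for h in hits if h.orientation == "direct"]

    def test_empty_mature_db_rejected(self):
        with pytest.raises(ValueError):
            find_mature_hits([("s", "ACGT" * 30)], [])


def _mh(sid, orient, iv, fam="miR1", mid="m1", mm=0):
    return MatureHit(subject_seq_id=sid, orientation=orient, interval=iv,
                     mature_id=mid, family=fam, mismatches=mm)


class TestPairHits:
    def test_direct_only_no_locus(self):
        assert pair_hits([_mh("s", "direct", (10, 31))]) == []

    def test_simple_pair(self):
        loci = pair_hits([_mh("s", "direct", (100, 120)),
                          _mh("s", "revcomp", (180, 200))])
        assert len(loci) == 1
        assert loci[0].five_hit.interval == (100, 120)

    def test_overlapping_pair_rejected(self):
        assert pair_hits([_mh("s", "direct", (100, 121)),
                          _mh("s", "revcomp", (110, 131))]) == []

    def test_family_mismatch_rejected(self):
        assert pair_hits([_mh("s", "direct", (0, 21), fam="miR1"),
                          _mh("s", "revcomp", (50, 71), fam="miR2")]) == []

    def test_span_cap(self):
        assert pair_hits([_mh("s", "direct", (0, 21)),
                          _mh("s", "revcomp", (600, 621))]) == []

    def test_equals_brute_force_pair_enumeration(self):
        rng = random.Random(6)
        hits = []
        for i in range(40):
            sid = f"s{rng.randint(0, 4)}"
            a = rng.randint(0, 600)
            hits.append(_mh(sid, rng.choice(["direct", "revcomp"]),
                            (a, a + 21), fam=f"miR{rng.randint(1, 3)}"))
        got = {(l.subject_seq_id, l.five_hit.interval, l.three_hit.interval,
                l.family) for l in pair_hits(hits)}
        expect = set()
        for d in hits:
            for r in hits:
                if (d.orientation, r.orientation) != ("direct", "revcomp"):
                    continue
                if d.subject_seq_id != r.subject_seq_id or d.family != r.family:
                    continue
                if d.interval[1] > r.interval[0] and \
                        r.interval[1] > d.interval[0]:
                    continue
                span = max(d.interval[1], r.interval[1]) - \
                    min(d.interval[0], r.interval[0])
                if span > 500:
                    continue
                five, three = ((d, r) if d.interval[0] < r.interval[0]
                               else (r, d))
                expect.add((d.subject_seq_id, five.interval, three.interval,
                            d.family))
        assert got == expect


class TestExtract:
    def test_flank_arithmetic(self):
        rng = random.Random(1)
        subj = _rnd(rng, 300)
        locus = mirna.CandidateLocus(
            subject_seq_id="s", family="f",
            five_hit=_mh("s", "direct", (113, 134)),
            three_hit=_mh("s", "revcomp", (160, 181)),
            mature_hit=_mh("s", "direct", (113, 134)),
            star_hit=_mh("s", "revcomp", (160, 181)))
        prec, iv, clipped = extract_precursor(subj, locus, flank=13)
        assert iv == (100, 194)
        assert len(prec) == 94
        assert not clipped

    def test_clipping_at_sequence_start(self):
        rng = random.Random(2)
        subj = _rnd(rng, 120)
        locus = mirna.CandidateLocus(
            subject_seq_id="s", family="f",
            five_hit=_mh("s", "direct", (5, 26)),
            three_hit=_mh("s", "revcomp", (60, 81)),
            mature_hit=_mh("s", "direct", (5, 26)),
            star_hit=_mh("s", "revcomp", (60, 81)))
        prec, iv, clipped = extract_precursor(subj, locus, flank=13)
        assert iv[0] == 0
        assert clipped


class TestFold:
    def test_perfect_hairpin_full_stem(self):
        stem = "GC" * 10
        seq = stem + "AAAA" + revcomp(stem)
        db, mfe_val = fold_hairpin(seq)
        pt = pair_table(db)
        assert mfe_val < -40
        assert all(pt[i] >= 0 for i in range(len(stem)))

    def test_poly_a_has_no_structure(self):
        db, mfe_val = fold_hairpin("A" * 60)
        assert mfe_val == 0.0
        assert db == "." * 60

    def test_equals_exhaustive_enumeration_oracle(self):
        """MFE equals a brute-force enumeration over all nested structures
        under the same energy model (random sequences <= 30 nt)."""
        def canpair(a, b):
            return mirna.PAIR_E["ACGU".index(a), "ACGU".index(b)] < 1e8

        def enum(seq):
            def rec(avail):
                if not avail:
                    yield frozenset()
                    return
                i, rest = avail[0], avail[1:]
                yield from rec(rest)
                for j in rest:
                    if j - i - 1 >= mirna.MIN_LOOP and canpair(seq[i], seq[j]):
                        inside = tuple(p for p in rest if i < p < j)
                        outside = tuple(p for p in rest if p > j)
                        for s1 in rec(inside):
                            for s2 in rec(outside):
                                yield s1 | s2 | {(i, j)}
            return rec(tuple(range(len(seq))))

        def energy(seq, pairs):
            pairs = sorted(pairs)
            e = 0.0
            for (i, j) in pairs:
                e += mirna.PAIR_E["ACGU".index(seq[i]), "ACGU".index(seq[j])]
                kids = [(k, l) for (k, l) in pairs if i < k < l < j and
                        not any(i < a < k and l < b < j for (a, b) in pairs
                                if (a, b) != (k, l))]
                if not kids:
                    e += mirna.HAIRPIN_PEN
                elif len(kids) == 1:
                    k, l = kids[0]
                    if (k - i - 1) + (j - l - 1) > mirna.MAX_INTERNAL:
                        return None
                    e += mirna.BULGE_PEN * ((k - i - 1) + (j - l - 1))
                else:
                    e += mirna.MULTI_PEN
            return e

        rng = random.Random(17)
        for _ in range(12):
            n = rng.randint(10, 16)
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            best = 0.0
            for s in enum(seq):
                ev = energy(seq, s)
                if ev is not None and ev < best:
                    best = ev
            db, mfe_val = fold_hairpin(seq)
            assert mfe_val == pytest.approx(best)
            pt = pair_table(db)
            pairs = {(i, int(pt[i])) for i in range(n) if pt[i] > i}
            if mfe_val < 0:
                assert energy(seq, pairs) == pytest.approx(mfe_val)

    def test_n_is_unpairable(self):
        db, mfe_val = fold_hairpin("N" * 50)
        assert mfe_val == 0.0


class TestMfei:
    def test_cutoff_arithmetic(self):
        amfe, idx = mfei(-34.0, 100, 40.0)
        assert amfe == 34.0
        assert idx == pytest.approx(0.85)
        amfe, idx = mfei(-50.0, 200, 50.0)
        assert (amfe, idx) == (25.0, 0.5)

    def test_invariant_under_sequence_duplication(self):
        a = mfei(-30.0, 120, 42.0)
        b = mfei(-60.0, 240, 42.0)
        assert a == pytest.approx(b)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mfei(-10.0, 100, 0.0)
        with pytest.raises(ValueError):
            mfei(-10.0, 0, 40.0)


def _planted_candidate(rng, star_mutations=0):
    mature = _rnd(rng, 21)
    star = list(revcomp(mature))
    pos = rng.sample(range(2, 19), star_mutations)
    for i in pos:
        star[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[star[i]]
    loop = _rnd(rng, 12)
    prec = _rnd(rng, 13) + mature + loop + "".join(star) + _rnd(rng, 13)
    db, mfe_val = fold_hairpin(prec)
    c = MirnaCandidate(
        precursor_seq=prec, source_seq_id="s", interval=(0, len(prec)),
        mature_hit=_mh("s", "direct", (13, 34)),
        star_hit=_mh("s", "revcomp", (34 + len(loop), 55 + len(loop))),
        family="miR1", structure=db, mfe=mfe_val, gc_pct=gc_percent(prec))
    if mfe_val < 0:
        c.amfe, c.mfei = mfei(mfe_val, len(prec), c.gc_pct)
    return c


class TestValidate:
    def test_mfei_boundary_exclusive(self):
        rng = random.Random(3)
        c = _planted_candidate(rng)
        c.mfei = 0.84
        assert not validate_candidate(c)
        assert "mfei" in c.fail_reasons

    def test_planted_hairpin_passes(self):
        rng = random.Random(4)
        c = _planted_candidate(rng, star_mutations=2)
        assert validate_candidate(c), c.fail_reasons
        assert c.mature_arm == "5'"

    def test_shuffled_decoys_fail(self):
        rng = random.Random(5)
        n_pass = 0
        for i in range(10):
            c = _planted_candidate(rng, star_mutations=1)
            shuf = "".join(rng.sample(c.precursor_seq, len(c.precursor_seq)))
            db, mfe_val = fold_hairpin(shuf)
            c.precursor_seq, c.structure, c.mfe = shuf, db, mfe_val
            c.gc_pct = gc_percent(shuf)
            c.mfei = 0.0
            if mfe_val < 0:
                c.amfe, c.mfei = mfei(mfe_val, len(shuf), c.gc_pct)
            if validate_candidate(c):
                n_pass += 1
        assert n_pass <= 1

    def test_unfolded_candidate_rejected(self):
        rng = random.Random(6)
        c = _planted_candidate(rng)
        c.structure = ""
        with pytest.raises(ValueError):
            validate_candidate(c)


class TestAnnotate:
    def test_known_precursor_similarity_flag(self):
        rng = random.Random(8)
        c = _planted_candidate(rng)
        known = list(c.precursor_seq)
        for i in rng.sample(range(len(known)), int(0.25 * len(known))):
            known[i] = rng.choice("ACGT")
        sim72 = list(c.precursor_seq)
        for i in rng.sample(range(len(sim72)), int(0.1 * len(sim72))):
            sim72[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sim72[i]]
        cands, report = mirna.annotate_candidates(
            [c], known_precursor_db=[("kp1", "".join(sim72))])
        assert cands[0].flags.get("known_precursor_similar")

    def test_family_report_schema(self):
        rng = random.Random(9)
        cands = [_planted_candidate(rng) for _ in range(3)]
        for c in cands:
            validate_candidate(c)
        _, report = mirna.annotate_candidates(cands)
        row = report[0]
        assert set(row) == {"family", "n_precursors", "length_range",
                            "mature_position"}
        assert row["n_precursors"] == 3
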