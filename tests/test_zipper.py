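"""Synteny windows, zipper codes, marker collinearity."""
import random

import numpy as np
import pytest

from chromosurvey.similarity import Hit
from chromosurvey.zipper import (Bin, BinMap, RefGene, ZipperEntry,
                                 build_zipper, call_syntenic_regions,
                                 collinearity_check, window_density,
                                 zipper_quality)


class TestWindowDensity:
    def test_hand_count(self):
        t = window_density([10_000, 500_000, 1_200_000], 2_000_000)
        assert t.density[0] == 2
        assert t.window_starts[0] == 0

    def test_no_hits_all_zero(self):
        t = window_density([], 2_000_000)
        assert (t.density == 0).all()

    def test_equals_brute_force_interval_count(self):
        rng = np.random.default_rng(0)
        pos = sorted(set(rng.integers(0, 3_000_000, 200).tolist()))
        t = window_density(pos, 3_000_000, window=1_000_000, step=20_000)
        for idx in rng.integers(0, t.window_starts.size, 20):
            s = t.window_starts[idx]
            expect = sum(1 for p in pos if s <= p < s + 1_000_000)
            assert t.density[idx] == expect

    def test_conservation_with_nonoverlapping_windows(self):
        rng = np.random.default_rng(1)
        pos = sorted(set(rng.integers(0, 10 ** 6, 300).tolist()))
        t = window_density(pos, 10 ** 6, window=50_000, step=50_000)
        assert int(t.density.sum()) == len(pos)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            window_density([10 ** 7], 10 ** 6)


class TestSyntenicRegions:
    def _track(self, dens):
        return window_density([], len(dens) * 20_000, window=20_000,
                              step=20_000)._replace_density(dens) \
            if False else None

    def test_patterns(self):
        import numpy as np
        from chromosurvey.zipper import SyntenyDensityTrack
        def track(vals):
            return SyntenyDensityTrack(
                chromosome="c",
                window_starts=np.arange(0, len(vals) * 20_000, 20_000),
                density=np.array(vals), window=1_000_000, step=20_000)
        assert call_syntenic_regions(track([60])) == [(0, 1_000_000)]
        assert call_syntenic_regions(track([40, 30])) == []
        got = call_syntenic_regions(track([40, 60, 60, 40]))
        assert got == [(20_000, 20_000 * 2 + 1_000_000)]


def _nt_hit(q, s, ev=1e-20, bits=100.0):
    return Hit(query_id=q, subject_id=s, identity_pct=90, similarity_pct=90,
               evalue=ev, bitscore=bits, query_cov_pct=90,
               subject_cov_pct=90, strand="+", frame=0,
               query_interval=(0, 100), subject_interval=(0, 100),
               mismatches=5)


class TestBuildZipper:
    def _genes(self):
        gA = [RefGene("A", "a1", "chrA", 100), RefGene("A", "a2", "chrA", 200),
              RefGene("A", "a3", "chrA", 300)]
        gB = {"b1": RefGene("B", "b1", "chrB_syn", 50),
              "b2": RefGene("B", "b2", "chrB_dec", 60)}
        gC = {"c1": RefGene("C", "c1", "chrC_syn", 70)}
        return gA, gB, gC

    def test_full_reciprocal_gene_gets_all_ones(self):
        gA, gB, gC = self._genes()
        ab = [_nt_hit("a1", "b1")]
        ba = [_nt_hit("b1", "a1")]
        ac = [_nt_hit("a1", "c1")]
        ca = [_nt_hit("c1", "a1")]
        bc = [_nt_hit("b1", "c1")]
        cb = [_nt_hit("c1", "b1")]
        z = build_zipper(gA, (ab, ba), (ac, ca), (bc, cb),
                         {"chrB_syn"}, {"chrC_syn"},
                         genesB=gB, genesC=gC)
        assert len(z) == 1
        assert z[0].code == "O1S1(111)"

    def test_off_syntenic_chromosome_and_no_rbh_all_zero(self):
        gA, gB, gC = self._genes()
        ab = [_nt_hit("a2", "b2")]
        ba = [_nt_hit("b2", "a1")]       # not reciprocal
        z = build_zipper(gA, (ab, ba), ([], []), ([], []),
                         {"chrB_syn"}, {"chrC_syn"}, genesB=gB, genesC=gC)
        assert len(z) == 1
        assert z[0].code == "O0S0(000)"

    def test_gene_without_homolog_excluded_and_order_by_position(self):
        gA, gB, gC = self._genes()
        ab = [_nt_hit("a3", "b1"), _nt_hit("a1", "b1")]
        ba = [_nt_hit("b1", "a1")]
        z = build_zipper(gA, (ab, ba), ([], []), ([], []),
                         {"chrB_syn"}, {"chrC_syn"}, genesB=gB, genesC=gC)
        assert [e.ref_gene.gene_id for e in z] == ["a1", "a3"]
        assert [e.rank for e in z] == [0, 1]

    def test_homology_to_unknown_gene_rejected(self):
        gA, gB, gC = self._genes()
        with pytest.raises(ValueError):
            build_zipper(gA, ([_nt_hit("zz", "b1")], []), ([], []), ([], []),
                         {"chrB_syn"}, {"chrC_syn"}, genesB=gB, genesC=gC)

    def test_swap_b_and_c_swaps_code_bits(self):
        """Recomputing with species B and C swapped swaps the O/S and h/y
        bits and leaves z unchanged."""
        gA, gB, gC = self._genes()
        ab, ba = [_nt_hit("a1", "b1")], [_nt_hit("b1", "a1")]
        ac, ca = [_nt_hit("a1", "c1")], []      # A-C not reciprocal
        bc, cb = [_nt_hit("b1", "c1")], [_nt_hit("c1", "b1")]
        z1 = build_zipper(gA, (ab, ba), (ac, ca), (bc, cb), {"chrB_syn"},
                          {"chrC_syn"}, genesB=gB, genesC=gC)[0]
        z2 = build_zipper(gA, (ac, ca), (ab, ba), (cb, bc), {"chrC_syn"},
                          {"chrB_syn"}, genesB=gC, genesC=gB)[0]
        o1, s1 = z1.code[1], z1.code[3]
        h1, y1, zz1 = z1.code[5], z1.code[6], z1.code[7]
        o2, s2 = z2.code[1], z2.code[3]
        h2, y2, zz2 = z2.code[5], z2.code[6], z2.code[7]
        assert (o1, s1) == (s2, o2)
        assert (h1, y1) == (y2, h2)
        assert zz1 == zz2


def _entry(rank, gid="g"):
    return ZipperEntry(ref_gene=RefGene("A", f"{gid}{rank}", "chrA",
                                        rank * 1000), rank=rank,
                       code="O1S1(111)")


class TestCollinearity:
    def test_perfect_collinearity_zero_out_of_place(self):
        zipper = [_entry(i) for i in range(9)]
        ranks = {f"m{i}": i for i in range(9)}
        bins = {f"m{i}": f"b{i // 3}" for i in range(9)}
        r = collinearity_check(zipper, ranks, bins, ["b0", "b1", "b2"])
        assert r["total_out_of_place"] == 0
        assert r["inversions"] == []

    def test_one_marker_out_of_place(self):
        zipper = [_entry(i) for i in range(9)]
        ranks = {f"m{i}": i for i in range(9)}
        bins = {f"m{i}": f"b{i // 3}" for i in range(9)}
        bins["m7"] = "b0"      # a b0 marker deep inside b2 territory
        r = collinearity_check(zipper, ranks, bins, ["b0", "b1", "b2"])
        assert r["total_out_of_place"] == 1

    def test_reversed_segment_flagged_as_inversion(self):
        zipper = [_entry(i) for i in range(10)]
        ranks = {}
        bins = {}
        order = ["b0", "b0", "b0", "b2", "b2", "b1", "b1", "b3", "b3", "b3"]
        for i, b in enumerate(order):
            ranks[f"m{i}"] = i
            bins[f"m{i}"] = b
        r = collinearity_check(zipper, ranks, bins, ["b0", "b1", "b2", "b3"])
        assert len(r["inversions"]) == 1
        inv = r["inversions"][0]
        assert inv["bins"] == ["b1", "b2"]

    def test_small_bins_skipped(self):
        zipper = [_entry(i) for i in range(3)]
        ranks = {"m0": 0, "m1": 1, "m2": 2}
        bins = {"m0": "b0", "m1": "b0", "m2": "b1"}
        r = collinearity_check(zipper, ranks, bins, ["b0", "b1"])
        assert r["skipped_bins"] == ["b1"]


class TestBinMap:
    def test_marker_assignment_midpoint(self):
        bm = BinMap(bins=[Bin("b1", "S", 0.0, 0.4), Bin("b2", "S", 0.4, 0.75),
                          Bin("b3", "S", 0.75, 1.0)])
        bm.assign_marker("m", "S", 0.5)
        assert bm.marker_to_bin["m"] == "b2"

    def test_unassignable_marker_rejected(self):
        bm = BinMap(bins=[Bin("b1", "S", 0.0, 0.4)])
        with pytest.raises(ValueError):
            bm.assign_marker("m", "S", 0.9)


class TestQualityStats:
    def test_fractions(self):
        entries = [
            ZipperEntry(RefGene("A", "a", "chrA", 0), 0, "O1S1(111)"),
            ZipperEntry(RefGene("A", "b", "chrA", 1), 1, "O0S0(000)"),
            ZipperEntry(RefGene("A", "c", "chrA", 2), 2, "O1S0(000)"),
            ZipperEntry(RefGene("A", "d", "chrA", 3), 3, "O0S1(001)"),
        ]
        q = zipper_quality(entries)
        assert q["n_genes"] == 4
        assert q["pct_syntenic"] == 75.0
        assert q["pct_true_ortholog"] == pytest.approx(100 * 2 / 3)
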