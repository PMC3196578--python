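"""Synthetic-world generator: determinism, planted-truth self-consistency,
composition targets."""
import numpy as np
import pytest

from chromosurvey.simulate import (SimulationConfig, TrioData, revcomp,
                                   shred_reads, simulate_arm,
                                   simulate_reference_trio, simulate_survey,
                                   make_te_families, make_mirna_db)


@pytest.fixture(scope="module")
def arm_world():
    """One 2 Mb arm pair with error-free reads for exactness checks."""
    cfg = SimulationConfig(seed=11, arm_len={"S": 2_000_000, "L": 500_000},
                           n_hairpins=10, sub_rate=0.0,
                           homopolymer_indel_rate=0.0)
    return cfg, simulate_survey(cfg)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(seed=5, arm_len={"S": 150_000, "L": 150_000},
                               n_hairpins=4)
        w1 = simulate_survey(cfg)
        w2 = simulate_survey(SimulationConfig(seed=5,
                                              arm_len={"S": 150_000,
                                                       "L": 150_000},
                                              n_hairpins=4))
        assert w1.arms["S"].seq == w2.arms["S"].seq
        assert w1.reads["L"] == w2.reads["L"]
        assert [m.member_read_ids for m in w1.assemblies["S"].memberships] \
            == [m.member_read_ids for m in w2.assemblies["S"].memberships]

    def test_different_seed_differs(self):
        a = simulate_survey(SimulationConfig(
            seed=5, arm_len={"S": 100_000, "L": 100_000}, n_hairpins=2))
        b = simulate_survey(SimulationConfig(
            seed=6, arm_len={"S": 100_000, "L": 100_000}, n_hairpins=2))
        assert a.arms["S"].seq != b.arms["S"].seq


class TestArmComposition:
    def test_realized_te_fraction_near_target(self, arm_world):
        cfg, w = arm_world
        frac = float((w.arms["S"].base_class == 1).mean())
        assert 0.73 <= frac <= 0.77

    def test_zero_te_fraction_means_no_library_similarity(self):
        cfg = SimulationConfig(seed=7, arm_len={"S": 60_000, "L": 60_000},
                               te_fraction=0.0, n_hairpins=2)
        w = simulate_survey(cfg)
        assert not w.arms["S"].te_intervals
        from chromosurvey.similarity import SearchParams, SimilaritySearcher
        searcher = SimilaritySearcher(w.repeat_nt_db, "nucleotide",
                                      SearchParams(max_evalue=1e-6))
        hits = [h for rid, s in w.reads["S"][:150]
                for h in searcher.search_one(rid, s)]
        assert len(hits) == 0

    def test_infeasible_packing_rejected(self):
        cfg = SimulationConfig(seed=1, arm_len={"S": 30_000, "L": 30_000},
                               te_fraction=0.99, gene_count=20)
        rng = np.random.default_rng(0)
        fams = make_te_families(cfg, rng)
        matures, _ = make_mirna_db(cfg, rng)
        with pytest.raises(ValueError):
            simulate_arm(cfg, rng, "S", fams, matures)


class TestTruthSelfConsistency:
    def test_hairpin_intervals_extract_planted_sequences(self, arm_world):
        cfg, w = arm_world
        t = w.arms["S"]
        mature_seq = dict(w.mature_db)
        for hp in t.hairpins:
            m = t.seq[hp.mature_interval[0]:hp.mature_interval[1]]
            assert m == mature_seq[hp.mature_id]
            star = t.seq[hp.star_interval[0]:hp.star_interval[1]]
            diffs = sum(a != b for a, b in zip(star, revcomp(m)))
            assert diffs <= cfg.star_max_mutations

    def test_gene_exons_concatenate_to_transcript(self, arm_world):
        cfg, w = arm_world
        t = w.arms["S"]
        for g in t.genes:
            spliced = "".join(t.seq[a:b] for a, b in g.exons)
            if g.strand == "-":
                spliced = revcomp(spliced)
            assert spliced == g.transcript


class TestReads:
    def test_error_free_reads_are_exact_substrings(self, arm_world):
        cfg, w = arm_world
        for rid, seq in w.reads["S"][:300]:
            o = w.origins["S"][rid]
            src = w.arms[o.origin_arm].seq[o.start:o.end]
            assert seq == (src if o.strand == "+" else revcomp(src))

    def test_total_bases_within_sampling_bound(self, arm_world):
        cfg, w = arm_world
        total = sum(len(s) for _, s in w.reads["S"])
        target = cfg.coverage * w.arms["S"].arm_len
        assert abs(total - target) / target < 0.05

    def test_contamination_rate_recovered(self, arm_world):
        cfg, w = arm_world
        origins = w.origins["S"]
        cross = sum(1 for o in origins.values() if o.origin_arm != "S")
        frac = 100.0 * cross / len(origins)
        assert abs(frac - 5.3) <= 1.0


class TestPseudoAssembly:
    def test_memberships_consistent_and_collapsed_high_coverage(self,
                                                                arm_world):
        cfg, w = arm_world
        asm = w.assemblies["S"]
        seen = set()
        for m in asm.memberships:
            assert m.n_reads >= 2
            assert not (set(m.member_read_ids) & seen)
            seen.update(m.member_read_ids)
        collapsed = [m for m in asm.memberships
                     if asm.contig_origins[m.contig_id] is None]
        assert collapsed
        covs = [m.n_reads * m.avg_read_len / m.consensus_len
                for m in collapsed]
        assert max(covs) > 5

    def test_positional_contig_consensus_matches_arm(self, arm_world):
        cfg, w = arm_world
        asm = w.assemblies["S"]
        for cid, co in list(asm.contig_origins.items())[:50]:
            if co is None:
                continue
            a, s, e = co
            assert dict(asm.contigs)[cid] == w.arms[a].seq[s:e]


class TestTrio:
    def test_full_retention_zero_divergence_gives_all_ones(self, arm_world):
        cfg, w = arm_world
        cfg2 = SimulationConfig(seed=2, retention_B=1.0, retention_C=1.0,
                                syn_chrom_prob=1.0, div_AB=0.0, div_AC=0.0,
                                n_extra_ref_genes=0)
        rng = np.random.default_rng(3)
        trio = simulate_reference_trio(cfg2, rng, w.arms["L"])
        from chromosurvey.survey import run_zipper
        # direct structural check: every A gene has both orthologs on
        # syntenic chromosomes
        assert len(trio.genesB) == len(trio.genesA)
        assert all(g.chromosome == "chrB_syn" for g in trio.genesB.values())

    def test_zero_retention_means_no_b_genes(self, arm_world):
        cfg, w = arm_world
        cfg2 = SimulationConfig(seed=2, retention_B=0.0)
        rng = np.random.default_rng(3)
        trio = simulate_reference_trio(cfg2, rng, w.arms["L"])
        assert trio.genesB == {}

    def test_inversion_reverses_a_order_for_planted_segment(self, arm_world):
        cfg, w = arm_world
        rng = np.random.default_rng(4)
        trio = simulate_reference_trio(cfg, rng, w.arms["S"], invert=True)
        assert trio.inversion_gene_ids
        pos_of = {g.gene_id: g.position for g in trio.genesA}
        a_pos = [pos_of[trio.a_of_arm_gene[g]]
                 for g in trio.inversion_gene_ids]
        assert a_pos == sorted(a_pos, reverse=True)


class TestUnigenesAndMarkers:
    def test_markers_assigned_to_correct_bins(self, arm_world):
        cfg, w = arm_world
        bm = w.bin_maps["S"]
        genes = {g.gene_id: g for g in w.arms["S"].genes}
        for mid, bname in bm.marker_to_bin.items():
            g = genes[w.marker_gene["S"][mid]]
            frac = g.start / w.arms["S"].arm_len
            b = next(b for b in bm.bins if b.name == bname)
            assert b.frac_start <= frac < b.frac_end

    def test_homeolog_unigenes_distinguishable_at_identity_floor(self,
                                                                 arm_world):
        cfg, w = arm_world
        ug = dict(w.unigenes["S"])
        homs = [u for u in ug if u.endswith("_hom")]
        assert homs
        for h in homs:
            parent = ug[h.replace("_hom", "")]
            diffs = sum(a != b for a, b in zip(ug[h], parent))
            div = diffs / len(parent)
            assert 0.005 < div < 0.05
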