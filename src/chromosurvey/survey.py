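"""End-to-end survey pipeline over a simulated world.

Each function runs one published-analysis stage on a planted-truth world
from :mod:`chromosurvey.simulate` and returns both the analysis output and
the truth-comparison statistics the acceptance checks use.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from . import genecontent, mirna, repeats, scaffold, zipper
from .simulate import World
from .similarity import SearchParams, SimilaritySearcher, search


# ---------------------------------------------------------------------------
# classification


def run_classification(world: World, arm_id: str):
    """Classify one arm's reads; returns (labels, summary, truth_stats)."""
    reads = world.reads[arm_id]
    asm = world.assemblies[arm_id]
    labels = repeats.classify_reads(
        reads,
        repeat_nt_db=world.repeat_nt_db,
        repeat_prot_db=world.repeat_prot_db,
        viral_prot_db=world.viral_db,
        gene_dbs=(world.protein_db, world.est_db),
        memberships=asm.memberships,
        excluded_domain_tags=world.domain_tags,
    )
    summary = repeats.summarize_classes(labels, len(reads))
    origins = world.origins[arm_id]
    n = len(reads)
    truth_stats = {
        "pct_true_repeat": 100.0 * sum(
            1 for o in origins.values() if o.true_class == "repeat") / n,
        "pct_true_gene": 100.0 * sum(
            1 for o in origins.values() if o.true_class == "gene") / n,
    }
    return labels, summary, truth_stats


# ---------------------------------------------------------------------------
# gene content


def run_gene_content(world: World, arm_id: str,
                     labels: Mapping[str, repeats.ClassLabel]):
    """Arm-level coding fraction and gene-count estimate vs planted truth."""
    reads = world.reads[arm_id]
    truth = world.arms[arm_id]
    gene_ids = {rid for rid, lab in labels.items() if lab.label == repeats.GENE}
    read_len = {rid: len(s) for rid, s in reads}
    st = genecontent.ArmStats(
        arm_id=arm_id,
        total_reads=len(reads),
        total_bases=sum(read_len.values()),
        predicted_arm_len=truth.arm_len,
        matched_gene_reads=len(gene_ids),
        matched_gene_bases=sum(read_len[r] for r in gene_ids),
    )
    avg_cds = int(round(np.mean([g.cds_len for g in truth.genes])))
    return {
        "arm_stats": st,
        "coding_fraction_pct": st.coding_fraction(),
        "estimated_gene_count": st.gene_count(avg_cds_len=2000),
        "planted_gene_count": len(truth.genes),
        "planted_mean_cds": avg_cds,
    }


def run_assembly_metrics(world: World, arm_id: str):
    asm = world.assemblies[arm_id]
    lens = {cid: len(s) for cid, s in asm.contigs}
    total_bases = sum(len(s) for _, s in world.reads[arm_id])
    return genecontent.assembly_metrics(lens, asm.memberships, total_bases)


# ---------------------------------------------------------------------------
# synteny / zipper


def _read_true_gene(world: World, arm_id: str, rid: str) -> Optional[str]:
    """The planted gene a read mostly comes from, if any."""
    o = world.origins[arm_id][rid]
    truth = world.arms[o.origin_arm]
    best = None
    for g in truth.genes:
        ov = min(o.end, g.end) - max(o.start, g.start)
        if ov > 0 and (best is None or ov > best[1]):
            best = (g.gene_id, ov)
    return best[0] if best else None


def run_zipper(world: World, arm_id: str,
               gene_read_ids: Optional[set] = None,
               search_params: Optional[SearchParams] = None):
    """Build the arm zipper, anchor reads and markers, check collinearity."""
    trio = world.trios[arm_id]
    params = search_params or SearchParams()
    a = [(g.gene_id, g.nucleotide) for g in trio.genesA]
    b = [(g.gene_id, g.nucleotide) for g in trio.genesB.values()]
    c = [(g.gene_id, g.nucleotide) for g in trio.genesC.values()]
    hits = {}
    for name, q, s in (("ab", a, b), ("ba", b, a), ("ac", a, c),
                       ("ca", c, a), ("bc", b, c), ("cb", c, b)):
        hits[name] = search(q, s, "nucleotide", params) if q and s else []
    entries = zipper.build_zipper(
        trio.genesA, (hits["ab"], hits["ba"]), (hits["ac"], hits["ca"]),
        (hits["bc"], hits["cb"]),
        syntenic_chroms_B={trio.syn_chrom_B},
        syntenic_chroms_C={trio.syn_chrom_C},
        genesB=trio.genesB, genesC=trio.genesC)
    quality = zipper.zipper_quality(entries)

    # anchor survey gene reads onto the zipper
    reads = world.reads[arm_id]
    if gene_read_ids is not None:
        reads = [(rid, s) for rid, s in reads if rid in gene_read_ids]
    entries, anchors, anchor_stats = zipper.anchor_reads(reads, entries)

    rank_of_a = {e.ref_gene.gene_id: e.rank for e in entries}
    # anchoring accuracy vs planted origin
    n_known = 0
    n_correct = 0
    for rid, rank in anchors.items():
        gid = _read_true_gene(world, arm_id, rid)
        if gid is None or gid not in trio.a_of_arm_gene:
            continue
        true_rank = rank_of_a.get(trio.a_of_arm_gene[gid])
        if true_rank is None:
            continue
        n_known += 1
        if true_rank == rank:
            n_correct += 1
    anchor_stats["anchor_accuracy"] = (n_correct / n_known if n_known else
                                       float("nan"))

    # collinearity of planted arm order vs zipper rank
    xs, ys = [], []
    for i, gid in enumerate(trio.arm_order):
        aid = trio.a_of_arm_gene.get(gid)
        if aid in rank_of_a:
            xs.append(i)
            ys.append(rank_of_a[aid])
    tau = sps.kendalltau(xs, ys).statistic if len(xs) > 1 else float("nan")

    # marker anchoring onto zipper genes
    markers = world.markers[arm_id]
    bin_map = world.bin_maps[arm_id]
    marker_ranks = {}
    if markers:
        searcher = SimilaritySearcher(
            [(e.ref_gene.gene_id, e.ref_gene.nucleotide) for e in entries],
            "nucleotide", params)
        for mid, mseq in markers:
            mh = [h for h in searcher.search_one(mid, mseq)
                  if h.evalue <= 1e-10]
            if mh:
                rank = rank_of_a[mh[0].subject_id]
                marker_ranks[mid] = rank
                entries[rank].anchored_markers.append(mid)
    selected = [b.name for b in bin_map.bins
                if not bin_map.overlap_flags()[b.name] or
                b.name.startswith("C-")]
    # keep physical order, drop the overlapped non-centromeric duplicate
    coll = zipper.collinearity_check(entries, marker_ranks,
                                     bin_map.marker_to_bin, selected)
    return {
        "zipper": entries,
        "quality": quality,
        "anchors": anchors,
        "anchor_stats": anchor_stats,
        "kendall_tau": tau,
        "marker_ranks": marker_ranks,
        "collinearity": coll,
        "inversion_truth": trio.inversion_gene_ids,
    }


def run_marker_arm_check(world: World, arm_id: str,
                         max_reads: Optional[int] = None):
    """Anchor reads to bin-mapped markers of both arms; cross-arm report."""
    all_markers = []
    bins = []
    for a in world.markers:
        all_markers.extend(world.markers[a])
        bins.extend(world.bin_maps[a].bins)
    bin_map = zipper.BinMap(bins=bins)
    for a in world.bin_maps:
        bin_map.marker_to_bin.update(world.bin_maps[a].marker_to_bin)
    reads = world.reads[arm_id]
    if max_reads is not None:
        reads = reads[:max_reads]
    read_arms = {rid: world.origins[arm_id][rid].origin_arm
                 for rid, _ in reads}
    anchors, report = zipper.anchor_markers(reads, all_markers, bin_map,
                                            read_arms=read_arms)
    # cross-arm fraction relative to the *sample* arm (assigned arm),
    # which is what a real experiment observes
    n_own = sum(1 for rid, (m, bname) in anchors.items()
                if {b.name: b.arm for b in bin_map.bins}[bname] == arm_id)
    n_tot = len(anchors)
    return {
        "anchors": anchors,
        "per_origin_arm": report,
        "pct_own_arm": 100.0 * n_own / n_tot if n_tot else float("nan"),
    }


# ---------------------------------------------------------------------------
# miRNA


def run_mirna(world: World, arm_id: str,
              config: Optional[mirna.MirnaConfig] = None):
    """Hairpin discovery on contigs+singletons with planted-truth scoring."""
    asm = world.assemblies[arm_id]
    read_seq = dict(world.reads[arm_id])
    subjects = list(asm.contigs) + [(rid, read_seq[rid])
                                    for rid in asm.singleton_ids]
    cands, report = mirna.discover_mirnas(
        subjects, world.mature_db, protein_db=world.protein_db,
        known_precursor_db=world.known_precursor_db,
        repeat_nt_db=world.repeat_nt_db, config=config)

    # absolute position of each candidate
    origins = world.origins[arm_id]

    def abs_interval(c):
        if c.source_seq_id in origins:       # singleton read
            o = origins[c.source_seq_id]
            return (o.origin_arm, o.start, o.end)
        co = asm.contig_origins.get(c.source_seq_id)
        if co is None:
            return None
        a, s, e = co
        return (a, s + c.interval[0], s + c.interval[1])

    # coverage of planted hairpins by assembly pieces
    spans = []
    for cid, co in asm.contig_origins.items():
        if co is not None:
            spans.append(co)
    for rid in asm.singleton_ids:
        o = origins[rid]
        spans.append((o.origin_arm, o.start, o.end))
    truth = world.arms[arm_id]
    covered = []
    for hp in truth.hairpins:
        s, e = hp.interval
        if any(a == arm_id and cs <= s and e <= ce for a, cs, ce in spans):
            covered.append(hp)
    recovered = set()
    n_true_pos = 0
    for c in cands:
        ai = abs_interval(c)
        matched = False
        if ai is not None:
            a, s, e = ai
            for hp in world.arms[a].hairpins if a in world.arms else []:
                hs, he = hp.interval
                if min(e, he) - max(s, hs) > 0:
                    matched = True
                    if a == arm_id:
                        recovered.add(hp.hairpin_id)
        if matched:
            n_true_pos += 1
    covered_ids = {hp.hairpin_id for hp in covered}
    sens = (len(recovered & covered_ids) / len(covered_ids)
            if covered_ids else float("nan"))
    prec = n_true_pos / len(cands) if cands else float("nan")
    return {
        "candidates": cands,
        "family_report": report,
        "n_planted": len(truth.hairpins),
        "n_covered": len(covered_ids),
        "sensitivity_covered": sens,
        "precision": prec,
    }


# ---------------------------------------------------------------------------
# scaffolding


def run_scaffolding(world: World, arm_id: str):
    """Unigene mapping + scaffolding with planted-order verification."""
    asm = world.assemblies[arm_id]
    contig_arms = {}
    for cid, co in asm.contig_origins.items():
        contig_arms[cid] = co[0] if co is not None else arm_id
    matches, summary, per_unigene = scaffold.map_unigenes(
        world.unigenes[arm_id], asm.contigs, contig_arms=contig_arms)
    flags = scaffold.flag_problem_unigenes(matches)
    scaffolds, st = scaffold.scaffold_contigs(matches, asm.contig_seqs(),
                                              flags)
    # order correctness against planted contig coordinates
    n_checked = 0
    n_correct = 0
    for sc in scaffolds:
        pos = []
        ok = True
        for cid in sc.contig_ids:
            co = asm.contig_origins.get(cid)
            if co is None:
                ok = False
                break
            pos.append(co[1])
        if not ok or len(pos) < 2:
            continue
        n_checked += 1
        if pos == sorted(pos) or pos == sorted(pos, reverse=True):
            n_correct += 1
    return {
        "matches": matches,
        "summary": summary,
        "per_unigene": per_unigene,
        "flags": flags,
        "scaffolds": scaffolds,
        "stats": st,
        "order_accuracy": n_correct / n_checked if n_checked else float("nan"),
    }
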