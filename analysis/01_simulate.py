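#!/usr/bin/env python
"""Generate the synthetic survey world and export its planted truth.

Writes per-arm reads (FASTA), contigs (FASTA), planted-feature annotations
(GFF3) and the composition summary so later stages can be audited against
the truth bundle.
"""
from _common import get_world, outdir, parse_args


def main():
    args = parse_args(__doc__)
    world = get_world(args)
    out = outdir()
    from chromosurvey import io_formats as io

    rows = []
    for arm, truth in world.arms.items():
        io.write_fasta(world.reads[arm], out / f"reads_{arm}.fa")
        io.write_fasta(world.assemblies[arm].contigs, out / f"contigs_{arm}.fa")
        anns = []
        for s, e, fam, kind in truth.te_intervals:
            anns.append(io.IntervalAnnotation(arm, s, e, ".", "repeat_region",
                                              {"family": fam, "kind": kind}))
        for g in truth.genes:
            anns.append(io.IntervalAnnotation(arm, g.start, g.end, g.strand,
                                              "gene", {"ID": g.gene_id}))
            for i, (a, b) in enumerate(g.exons):
                anns.append(io.IntervalAnnotation(
                    arm, a, b, g.strand, "exon",
                    {"Parent": g.gene_id, "rank": str(i + 1)}))
        for hp in truth.hairpins:
            anns.append(io.IntervalAnnotation(
                arm, hp.interval[0], hp.interval[1], "+", "miRNA_primary_transcript",
                {"ID": hp.hairpin_id, "mature": hp.mature_id}))
        io.write_gff3(anns, out / f"truth_{arm}.gff3")
        te_frac = float((truth.base_class == 1).mean())
        exon_frac = float((truth.base_class == 4).mean())
        rows.append((arm, truth.arm_len, len(world.reads[arm]),
                     round(te_frac, 4), round(exon_frac, 4),
                     len(truth.genes), len(truth.hairpins)))
        print(f"arm {arm}: {truth.arm_len:,} bp, {len(world.reads[arm]):,} "
              f"reads, TE fraction {te_frac:.3f}, coding {exon_frac:.4f}, "
              f"{len(truth.genes)} genes, {len(truth.hairpins)} hairpins")

    with open(out / "simulation_summary.tsv", "w") as fh:
        fh.write("arm\tarm_len\tn_reads\tte_fraction\tcoding_fraction\t"
                 "n_genes\tn_hairpins\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


if __name__ == "__main__":
    main()
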