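#!/usr/bin/env python
"""Build the genome zipper per arm and check marker collinearity.

Maps gene reads onto the reference trio, orders the zipper by the
species-A gene positions with OxSx(hyz) reliability codes, anchors reads
and bin-mapped EST markers, and reports collinearity statistics and
inversion candidates against the planted truth.
"""
from _common import get_world, outdir, parse_args


def main():
    args = parse_args(__doc__)
    world = get_world(args)
    out = outdir()
    from chromosurvey.repeats import GENE
    from chromosurvey.survey import run_classification, run_zipper
    from chromosurvey.zipper import zipper_to_rows

    for arm in world.arms:
        labels, _, _ = run_classification(world, arm)
        gene_ids = {r for r, l in labels.items() if l.label == GENE}
        res = run_zipper(world, arm, gene_read_ids=gene_ids)
        with open(out / f"zipper_{arm}.tsv", "w") as fh:
            fh.write("rank\tgene_id\tchromosome\tposition\tcode\t"
                     "n_anchored_reads\tmarkers\n")
            for row in zipper_to_rows(res["zipper"]):
                fh.write("\t".join(str(row[k]) for k in (
                    "rank", "gene_id", "chromosome", "position", "code",
                    "n_anchored_reads", "markers")) + "\n")
        q = res["quality"]
        coll = res["collinearity"]
        print(f"arm {arm}: {q['n_genes']} zipper genes, "
              f"{q['pct_syntenic']:.0f}% syntenic, "
              f"{q['pct_true_ortholog']:.0f}% true orthologs; "
              f"kendall tau {res['kendall_tau']:.3f}; "
              f"{coll['total_out_of_place']} markers out of place; "
              f"{len(coll['inversions'])} inversion candidate(s) "
              f"(planted: {'yes' if res['inversion_truth'] else 'no'})")


if __name__ == "__main__":
    main()
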