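#!/usr/bin/env python
"""Estimate coverage, coding fraction and gene count per arm.

Also reports the assembly metrics (N50, coverage-histogram mode, implied
genome size) that frame the estimates.
"""
from _common import get_world, outdir, parse_args


def main():
    args = parse_args(__doc__)
    world = get_world(args)
    out = outdir()
    from chromosurvey import genecontent as gc
    from chromosurvey.survey import (run_assembly_metrics, run_classification,
                                     run_gene_content)

    with open(out / "gene_content.tsv", "w") as fh:
        fh.write("arm\ttotal_reads\ttotal_bases\ttheoretical_coverage\t"
                 "gene_reads\tgene_bases\tcoding_pct\test_gene_count\t"
                 "planted_gene_count\tn50_large\test_assembly_coverage\n")
        for arm in world.arms:
            labels, summary, _ = run_classification(world, arm)
            res = run_gene_content(world, arm, labels)
            st = res["arm_stats"]
            cov = gc.theoretical_coverage(st.total_bases, st.predicted_arm_len)
            am = run_assembly_metrics(world, arm)
            fh.write("\t".join(map(str, [
                arm, st.total_reads, st.total_bases, cov,
                st.matched_gene_reads, st.matched_gene_bases,
                round(res["coding_fraction_pct"], 3),
                res["estimated_gene_count"], res["planted_gene_count"],
                am.n50_large, am.estimated_coverage])) + "\n")
            print(f"arm {arm}: coverage {cov}x, coding "
                  f"{res['coding_fraction_pct']:.3f}%, estimated "
                  f"{res['estimated_gene_count']} genes "
                  f"(planted {res['planted_gene_count']})")


if __name__ == "__main__":
    main()
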