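#!/usr/bin/env python
"""Scaffold contigs along unigenes with 100-N joins.

Maps unigenes onto the pseudo-assembly at identity >= 97% / windows >= 50
bp, drops repetitive and homeolog unigenes, scaffolds the rest, and writes
scaffolds (FASTA), an AGP-style placement table and the summary statistics.
"""
from _common import get_world, outdir, parse_args


def main():
    args = parse_args(__doc__)
    world = get_world(args)
    out = outdir()
    from chromosurvey import io_formats as io
    from chromosurvey.survey import run_scaffolding

    for arm in world.arms:
        res = run_scaffolding(world, arm)
        scaffolds = res["scaffolds"]
        io.write_fasta([(s.scaffold_id, s.sequence) for s in scaffolds],
                       out / f"scaffolds_{arm}.fa")
        with open(out / f"scaffold_placements_{arm}.tsv", "w") as fh:
            fh.write("scaffold\tpart\tcontig\tunigene\n")
            for s in scaffolds:
                for i, cid in enumerate(s.contig_ids):
                    fh.write(f"{s.scaffold_id}\t{i + 1}\t{cid}\t"
                             f"{s.unigene_id}\n")
        st = res["stats"]
        with open(out / f"scaffold_stats_{arm}.tsv", "w") as fh:
            for k, v in {**res["summary"], **st}.items():
                fh.write(f"{k}\t{v}\n")
        print(f"arm {arm}: {res['summary']['matched']} unigenes matched "
              f"({res['summary']['pct_matched']}%), {st['n_scaffolds']} "
              f"scaffolds, {st['contigs_per_scaffold']} contigs/scaffold, "
              f"{st['bases_per_scaffold']} bases/scaffold; planted order "
              f"accuracy {res['order_accuracy']:.2f}")


if __name__ == "__main__":
    main()
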