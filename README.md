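# chromosurvey

Analysis pipeline for **chromosome survey sequencing**: low-coverage
(~2x) shotgun reads from a flow-sorted chromosome arm are used to
characterize the arm's composition without assembling it. The package
implements the full survey analysis for a wheat-5A-style experiment —
two telocentric arms, 454-style reads, grass reference genomes — plus a
synthetic-data generator with planted truth so that every stage is
verifiable without any external downloads.

## What it computes

1. **Repeat landscape** (`chromosurvey.repeats`): each read is classified
   by a sequential cascade — *Known TE* (nucleotide match to a curated
   repeat library, E < 1e-6) → *Novel TE* (match to TE proteins only) →
   viral screen → *Genes* (protein ∪ EST evidence with TE-Pfam-domain
   exclusion) → *Repeats* (members of collapsed contigs with coverage
   (n·r)/c ≥ 5) → *Other*; summarized as a per-class read ledger with a
   TE family census.
2. **Gene content** (`chromosurvey.genecontent`): theoretical coverage
   = sequenced bases / predicted arm length; coding fraction =
   gene-read bases / sequenced bases; gene count =
   ⌊coding fraction × arm length / 2,000 bp⌋; assembly metrics (N50,
   coverage-histogram mode, implied genome size).
3. **Genome zipper** (`chromosurvey.zipper`): gene reads are mapped onto
   three related reference genomes (best hit only); sliding-window
   densities (1 Mb window, 20 kb step) call syntenic regions
   (≥ 50 genes/Mb); a virtual gene order is built on the species-A gene
   order, each entry coded `OxSx(hyz)` — x bits for homologs on syntenic
   chromosomes, h/y/z for reciprocal-best-hit orthology of the A–B, A–C
   and B–C pairs; reads and bin-mapped EST markers are anchored at
   E < 1e-10 and marker/bin collinearity flags candidate inversions.
4. **miRNA discovery** (`chromosurvey.mirna`): known mature miRNAs are
   searched (word 7, E ≤ 10, ≤ 10 hits/query); subjects with a direct hit
   (≤ 3 mismatches) and a reverse-complement hit form a locus; the
   precursor is excised 13 nt beyond the hits, folded, and kept when
   MFEI = AMFE / GC% > 0.85 (AMFE = −MFE·100/length) with ≤ 4
   mature–star duplex mismatches, small bulges, and no protein-coding
   similarity; candidates are annotated against known precursors (> 70%
   identity) and repeat libraries.
5. **Unigene scaffolding** (`chromosurvey.scaffold`): unigenes are mapped
   onto contigs (identity ≥ 97%, windows ≥ 50 bp), repetitive (> 10
   contigs per region) and homeolog unigenes are resolved, and contigs
   uniquely ordered by one unigene are joined with rows of 100 Ns.

The similarity searches run on an internal k-mer-seeded, banded,
affine-gap local aligner (`chromosurvey.similarity`, numba-accelerated,
verified against exact Smith–Waterman in the tests); externally produced
BLAST outfmt-6 tables can be ingested via `chromosurvey.io_formats`.

## Worked example

Run the numbered drivers (1 Mb arm pair, seeded, ~1 minute total):

```
python analysis/01_simulate.py
python analysis/02_classify_repeats.py
python analysis/03_gene_content.py
python analysis/04_synteny_zipper.py
python analysis/05_mirna_discovery.py
python analysis/06_unigene_scaffolding.py
```

Output of a run with the default seed (42):

```
arm S: 1,000,000 bp, 6,666 reads, TE fraction 0.753, coding 0.0122, 5 genes, 30 hairpins
arm S: combined repeats 78.08% (planted read-level 79.10%), 24 TE families seen
arm S: coverage 2.3x, coding 1.145%, estimated 5 genes (planted 5)
arm S: 9 zipper genes, 100% syntenic, 100% true orthologs; kendall tau 1.000; 0 markers out of place
arm S: 44 passing precursors in 12 families; sensitivity on covered planted hairpins 0.86, precision 1.00
arm S: 7 unigenes matched (100.0%), 1 scaffolds, 4.0 contigs/scaffold; planted order accuracy 1.00
```

Reading this: the generator planted 75% TE content and ~1.2% coding
sequence; the cascade recovers the read-level repeat fraction within a
point; the coding-fraction estimator recovers the planted gene count
exactly; the zipper order is perfectly collinear with the planted order
on the rearrangement-free arm; and most covered planted hairpins pass
the MFEI/duplex filters with no false positives. Tables land in
`results/` (`repeat_ledger.tsv`, `zipper_S.tsv`,
`mirna_candidates_S.tsv`, `scaffold_stats_S.tsv`, ...).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the short-arm gene-count estimate from the published per-arm
read-ledger inputs (gene-read bases, total sequenced bases, 295 Mb
predicted arm length, 2,000 bp average CDS) through
`coding_fraction`/`estimate_gene_count`, after exercising the full
pipeline on a small seeded synthetic survey, and writes the result as
JSON.

## Layout

```
src/chromosurvey/   library (io_formats, similarity, repeats, genecontent,
                    zipper, mirna, scaffold, simulate, survey)
analysis/           numbered narrative drivers over the library
tests/              pytest suite incl. planted-truth acceptance checks
scripts/            acceptance.py
docs/methods.md     models, parameters, design choices, limitations
```
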