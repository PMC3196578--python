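# Methods

This note records the models behind each stage, the parameters that
matter, what the synthetic world does and does not emulate, and the
numerical choices made where the design was genuinely open. Nothing here
states an empirical result that the tests or `scripts/acceptance.py` do
not themselves compute.

## Similarity engine

All searches run on an internal seeded local aligner rather than an
external program, so the pipeline is hermetic and testable end to end.

* **Seeding**: exact k-mers (word 11 nucleotide, 7 in miRNA mode, 4 on
  peptides) indexed in sorted arrays; seed matches are clustered by
  (subject, diagonal) with a 50-diagonal gap tolerance, clusters wider
  than 96 diagonals are trimmed around the densest diagonal, and
  single-seed clusters are ignored by default (noise at word 11; the
  miRNA mode lowers this to 1 because mature queries are 21 nt).
* **Extension**: banded affine-gap Smith–Waterman (numba) over the
  cluster's diagonal range ± 8. With the band spanning the full matrix
  the kernel *is* Smith–Waterman; the test suite asserts score equality
  with Biopython's exact local aligner on toy sets.
* **Scoring**: nucleotide +1/−2, gap 5/2 (open/extend, BLAST-style
  first-gap cost open+extend); translated mode BLOSUM62 with gap 11/1,
  all six frames, "similarity" = % positive-scoring columns, query
  coverage measured in nucleotides. The source analysis never states
  word sizes or gap penalties for the non-miRNA searches; these defaults
  mirror the common defaults of the era's tools and are exposed in
  `SearchParams`.
* **E-values**: Karlin–Altschul form E = m·n·2^(−bits) with fixed
  (λ, K) constants for the two scoring systems — (1.28, 0.46)
  nucleotide, (0.267, 0.041) BLOSUM62. The calibration is documentary,
  not fitted: every pipeline threshold (1e-6, 1e-10, 1e-30, 0.001) is
  coarse, and the planted-truth checks do not depend on absolute
  E-values.
* **Early termination**: cascade stages whose profile bounds only the
  E-value let the search stop at the first hit below the stage cutoff.
  This cannot change *whether* a read is labeled, only which family a
  multi-family read is attributed to, and the family census checks count
  distinct families, not per-family totals.

## Read classification

Stage order is known TE → novel TE → viral → gene → high-coverage repeat
→ other, following the methods description (the repeat class contains
reads escaping the TE and gene classes); the order is configurable. The
coverage statistic is (n·r)/c with an inclusive cutoff (≥ 5): "above a
cutoff of 5" is read inclusively because the estimate is coarse.
Singletons have no contig coverage and can never be REPEAT. The stated
viral bound "E-value ≥ 0.001" is treated as a typo for ≤ 0.001.
Viral-labeled reads are reported separately and are not folded into the
combined repeat row by default (the published ledger has no viral row).

Gene evidence is the union of translated-protein matches (E ≤ 1e-6,
identity ≥ 30%, similarity ≥ 50%, read coverage ≥ 50%, subject coverage
≥ 1%) and nucleotide EST matches (same bounds, E ≤ 1e-30). Reads
matching proteins tagged with any of the 21 TE-associated Pfam codes
(PF00078 reverse transcriptase, PF00665 integrase, ...) are excluded
from the gene fraction entirely, even with EST support — the stronger of
the two plausible readings, matching the stated practice of purging all
sequences matching those domains.

## Estimators

Coding fraction is computed as gene-read bases / total read bases — the
algebraic simplification of "matched bases ÷ coverage ÷ arm length" —
to avoid compounding the rounding of a printed coverage value. Gene
count uses floor rounding (the two published arms are mutually
inconsistent; floor reproduces the short-arm value, and the long-arm
printed value is noted as unreproducible from the unrounded inputs).
Assembly coverage is estimated as the mode of the contig-coverage
histogram at 0.1x binning restricted to (0, 5); the histogram export
pools everything above 10x in one class.

## Genome zipper

Zipper entries are species-A genes, restricted to configured syntenic
intervals, that have a nucleotide-level homolog (E < 1e-10) in at least
one of the other two species, ordered by A position. Syntenic-chromosome
membership is configured per species, never inferred. The code bits are
O/S = best homolog on a syntenic chromosome, (hyz) = reciprocal best
hits for A–B, A–C, B–C. Reads and markers anchor by best hit at
E < 1e-10; a read anchoring equally well to two entries goes to the
lower rank and is flagged ambiguous.

**Marker collinearity**: the out-of-place count is the number of markers
that must be removed for the remaining bin labels, in zipper-rank order,
to follow the physical bin order (longest non-decreasing subsequence).
A "maximal contiguous run" formulation was considered and rejected
because a single displaced marker would also break the invaded bin's
run and be double-counted. Inversion candidates are maximal
non-increasing bin-order segments of ≥ 3 markers containing a strict
decrease — so an inversion must span at least two bins to be visible,
which matches how deletion-bin maps localize rearrangements. Bins with
fewer than 2 markers are skipped; overlapping bins are excluded from
the statistic (marker counts may still be summed into them for
display).

## miRNA discovery

The internal folder is a Zuker-style two-matrix dynamic program over a
deliberately simple energy model: pair energies GC −3, AU −2, GU −1
kcal/mol; internal-loop/bulge bases +1 each (total loop ≤ 30 nt);
hairpin loops ≥ 3 nt; and loop-initiation penalties of +3 for hairpin
and multibranch loops. The initiation penalties stand in for the
entropic terms of full nearest-neighbor models; without them the model
happily decorates sequences with isolated 2-bp hairpins, which both
distorts structures and inflates decoy MFEI. Absolute energies therefore
differ from production folders (the MFEI cutoff is configurable, and
external dot-bracket + MFE output can be substituted per candidate);
planted-truth checks, not absolute energies, carry the validation.

Duplex assessment is structural: a mature position is a mismatch when it
is unpaired or paired outside the star interval; G:U wobbles do not
count (configurable). Two robustness allowances reflect how local
alignments and helix ends behave: the star interval is padded by 6 nt
(the star-side alignment regularly under-runs the true miRNA* ends),
and 2 terminal mature positions are excluded (miRNA/miRNA* duplexes
carry 2-nt overhangs and helix ends breathe). "Few and small asymmetric
bulges" is operationalized as no bulge > 3 nt and at most 2 bulges in
the assessed duplex. Mature-arm assignment compares the mature-hit
midpoint with the main hairpin-loop midpoint. Direct-hit mismatches
count substitutions plus unaligned mature overhang; gapped direct hits
are discarded. The 10-hit cap applies per query overall.

## Unigene scaffolding

"Uniquely and univocally" is interpreted as: every member contig matches
only that unigene above thresholds (contigs claimed by two unigenes are
excluded from both and logged), and the matched unigene intervals are
non-overlapping up to a 15 bp tolerance for ragged exon-boundary
alignments. Gaps are always exactly 100 Ns regardless of the unknown
intron span. Minus-strand contigs are reverse-complemented so scaffolds
read in transcript orientation. A relaxed preset (identity ≥ 80%) is
provided for distant-paralog searches.

## Synthetic world

The generator states the survey's assumed conditions as defaults: 5 Mb
per arm (a scaled-down stand-in for 295/532 Mb arms), 2.3x coverage,
truncated-normal read lengths (mean 345, sd 60, min 50), substitution
rate 0.002 and homopolymer-indel rate 0.001 (454-like error structure
without flowgram realism), 5.3% cross-arm contamination, 75% TE content
from 30 generated families (log-uniform 1.5–12 kb consensi, up to 15%
copy divergence, 30% nested insertions; 2 families are "novel" — absent
from the nucleotide library but with their TE protein present — and 2
are "unknown" — absent from both, discoverable only through collapsed-
contig coverage), ~1% coding fraction from genes with mean 2,000 bp CDS
(sd 600, half single-exon, otherwise 2–3 exons with 80–250 bp introns),
and one inversion on the long arm spanning arm fractions 0.55–0.85.
Thirty hairpins per arm embed generated mature miRNAs with a ≤ 2-
mutation star; this density is far above the real genome's (where ~100
precursors span hundreds of Mb) and is chosen purely so recovery
statistics have statistical power at 5 Mb. The reference trio derives
species A from the arm transcripts at 10% divergence (plus as many
A-only genes again, as real zippers contain genes the survey reads never
touch), and B and C from A at 10% with retention 0.85/0.80 and a 90%
chance of landing on the syntenic chromosome.

The pseudo-assembly is truth-guided, not a real assembler: reads
overlapping ≥ 40 bp merge into contigs whose consensus is the error-free
arm substring, and reads dominated by one TE family collapse into a
single family contig with probability 0.9 — the one knob that produces
the collapsed high-coverage contigs the (n·r)/c statistic must detect.
Consequences: contig consensi carry no sequencing error (unigene
identity thresholds are exercised by planted homeolog divergence, not by
assembly noise), no chimeric or misassembled contigs exist, and
coverage-gap structure is the only source of gene fragmentation. A green
end-to-end test therefore establishes that the *analysis* logic recovers
planted truth under the stated read model — not that it is robust to
real assembler artifacts.

**Read-level truth**: the classifier, like the published ledger, claims
a read when any part of it matches a repeat; comparing that read-level
percentage against the base-level planted fraction (0.75) would mix
units and differ by ~3 points from boundary reads alone at these TE
lengths. The planted truth therefore labels a read repeat-true when it
overlaps planted repeat by ≥ 50 bp (the pipeline's minimal-match
window), gene-true when it is otherwise majority-exonic; the realized
base-level TE fraction is checked separately against the configured
target (± 2 points).

## Known limitations

* E-value calibration is approximate; results at thresholds tighter
  than ~1e-30 depend on the documented constants.
* The folder ignores stacking sequence dependence, dangles and
  coaxial terms; MFEI values are comparable only within this model.
* One best alignment is kept per (subject, strand); intron-spanning
  unigene matches therefore appear as one interval per contig rather
  than per exon, and exon counts per scaffold are interval counts.
* The long-arm published gene count (3,495) and whole-chromosome
  coverage derivations are not reproducible from the printed inputs and
  are not asserted anywhere.
* Marker "correct arm" fractions are reported both read-wise and
  marker-wise because the published wording is ambiguous between them.
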