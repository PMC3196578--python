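"""Gene-evidence identification and the coverage / gene-count estimators.

A read counts as gene evidence when it matches either a protein database
(translated search) or an EST/unigene database (nucleotide search) at the
survey thresholds, unless it matches a protein annotated with a
TE-associated Pfam domain (reverse transcriptases, integrases, ...), in
which case it is excluded entirely.

The arm-level estimators are deliberately simple algebra over read-ledger
totals: theoretical coverage = sequenced bases / predicted arm length;
coding fraction = gene-read bases / sequenced bases (the depth terms
cancel); gene count = coding fraction * arm length / average CDS length.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .similarity import (SearchParams, SimilaritySearcher, ThresholdProfile,
                         filter_hits, Hit)
from .repeats import ContigMembership, contig_coverage

# TE-associated Pfam domains excluded from the gene fraction
DEFAULT_EXCLUDED_PFAM = (
    "PF00078", "PF03732", "PF05380", "PF07727", "PF07999", "PF08284",
    "PF12382", "PF00098", "PF02992", "PF03004", "PF03017", "PF04827",
    "PF10536", "PF10551", "PF12620", "PF01021", "PF04195", "PF01480",
    "PF04094", "PF05754", "PF00665",
)

PROTEIN_PROFILE = ThresholdProfile(max_evalue=1e-6, min_identity_pct=30,
                                   min_similarity_pct=50, min_query_cov_pct=50,
                                   min_subject_cov_pct=1, mode="translated")
EST_PROFILE = ThresholdProfile(max_evalue=1e-30, min_identity_pct=30,
                               min_query_cov_pct=50, min_subject_cov_pct=1,
                               mode="nucleotide")


@dataclass
class GeneEvidence:
    read_id: str
    protein_hit: Optional[Hit] = None
    est_hit: Optional[Hit] = None
    excluded_by_domain: Optional[str] = None


def identify_gene_reads(reads: Sequence[tuple],
                        protein_db: Optional[Sequence[tuple]],
                        est_db: Optional[Sequence[tuple]],
                        excluded_domain_tags: Optional[Mapping[str, set]] = None,
                        protein_profile: ThresholdProfile = PROTEIN_PROFILE,
                        est_profile: ThresholdProfile = EST_PROFILE,
                        search_params: Optional[SearchParams] = None,
                        ) -> List[GeneEvidence]:
    """Union of reads matching proteins or ESTs, with TE-domain exclusion.

    ``excluded_domain_tags`` maps protein subject ids to the set of Pfam
    codes they carry; a read whose best passing protein hit carries an
    excluded code is dropped from the gene fraction (recorded with the
    offending code), matching the practice of purging reads that match
    TE-domain proteins even when they also have EST support.
    """
    params = search_params or SearchParams()
    excluded_domain_tags = excluded_domain_tags or {}
    excluded_set = set(DEFAULT_EXCLUDED_PFAM)
    evidence: Dict[str, GeneEvidence] = {}

    if protein_db:
        searcher = SimilaritySearcher(protein_db, "translated", params)
        for rid, seq in reads:
            hits = filter_hits(searcher.search_one(rid, seq), protein_profile)
            if not hits:
                continue
            bad_code = None
            good_hit = None
            for h in hits:
                tags = set(excluded_domain_tags.get(h.subject_id, ())) & excluded_set
                if tags:
                    bad_code = bad_code or sorted(tags)[0]
                elif good_hit is None:
                    good_hit = h
            ev = evidence.setdefault(rid, GeneEvidence(read_id=rid))
            ev.protein_hit = good_hit or hits[0]
            if bad_code is not None:
                ev.excluded_by_domain = bad_code

    if est_db:
        searcher = SimilaritySearcher(est_db, "nucleotide", params)
        for rid, seq in reads:
            hits = filter_hits(searcher.search_one(rid, seq), est_profile)
            if hits:
                ev = evidence.setdefault(rid, GeneEvidence(read_id=rid))
                ev.est_hit = hits[0]

    return [evidence[rid] for rid, _ in reads if rid in evidence]


def theoretical_coverage(total_bases: int, predicted_len: int) -> float:
    """Sequenced bases over predicted arm length, to two decimals."""
    if total_bases < 0 or predicted_len <= 0:
        raise ValueError("invalid inputs")
    return round(total_bases / predicted_len, 2)


def coding_fraction(matched_gene_bases: int, total_bases: int) -> float:
    """Percent of sequenced bases in gene-evidence reads.

    Algebraically equal to matched bases / coverage / arm length, without
    compounding the rounding of a printed coverage value.
    """
    if matched_gene_bases > total_bases:
        raise ValueError("matched bases exceed total bases")
    if total_bases == 0:
        return 0.0
    return 100.0 * matched_gene_bases / total_bases


def estimate_gene_count(coding_fraction_pct: float, predicted_arm_len: int,
                        avg_cds_len: int = 2000) -> int:
    """floor(coding fraction * arm length / average CDS length)."""
    if not (0.0 <= coding_fraction_pct <= 100.0):
        raise ValueError("coding fraction must be a percentage")
    return math.floor(coding_fraction_pct / 100.0 * predicted_arm_len / avg_cds_len)


@dataclass
class ArmStats:
    arm_id: str
    total_reads: int
    total_bases: int
    predicted_arm_len: int
    matched_gene_reads: int = 0
    matched_gene_bases: int = 0

    def coding_fraction(self) -> float:
        return coding_fraction(self.matched_gene_bases, self.total_bases)

    def gene_count(self, avg_cds_len: int = 2000) -> int:
        return estimate_gene_count(self.coding_fraction(),
                                   self.predicted_arm_len, avg_cds_len)


@dataclass
class AssemblyMetrics:
    n_contigs: int
    n_large_contigs: int
    bases_large: int
    avg_large_contig: int
    n50_large: int
    largest: int
    estimated_coverage: float
    estimated_genome_size: float
    coverage_histogram: Optional[tuple] = None


def n50(lengths: Sequence[int]) -> int:
    """Smallest length whose cumulative sum (descending) reaches half the total."""
    if not lengths:
        return 0
    s = sorted(lengths, reverse=True)
    half = sum(s) / 2.0
    acc = 0
    for L in s:
        acc += L
        if acc >= half:
            return L
    return s[-1]


def assembly_metrics(contig_lengths: Mapping[str, int],
                     memberships: Sequence[ContigMembership],
                     total_read_bases: int,
                     large_cutoff: int = 500,
                     cov_bin: float = 0.1,
                     cov_mode_range: tuple = (0.0, 5.0),
                     pool_above: float = 10.0) -> AssemblyMetrics:
    """Assembly-ledger metrics plus the coverage-histogram estimators.

    Estimated coverage is the mode of the contig-coverage histogram at
    ``cov_bin`` binning restricted to ``cov_mode_range`` (the real peak of
    the distribution; collapsed repeat contigs pool far above it), and
    estimated genome size is total read bases divided by that mode.  The
    emitted histogram pools all contigs above ``pool_above`` in one class.
    """
    if not contig_lengths:
        raise ValueError("empty assembly")
    lens = list(contig_lengths.values())
    large = [L for L in lens if L > large_cutoff]
    covs = []
    for m in memberships:
        if m.avg_read_len is None:
            continue
        covs.append(contig_coverage(m.n_reads, m.avg_read_len, m.consensus_len))
    covs = np.asarray(covs, dtype=float)

    lo, hi = cov_mode_range
    est_cov = float("nan")
    if covs.size:
        inside = covs[(covs > lo) & (covs < hi)]
        if inside.size:
            nbins = int(round((hi - lo) / cov_bin))
            counts, edges = np.histogram(inside, bins=nbins, range=(lo, hi))
            b = int(np.argmax(counts))
            est_cov = round(float((edges[b] + edges[b + 1]) / 2.0), 2)
    genome_size = total_read_bases / est_cov if est_cov == est_cov else float("nan")

    hist = None
    if covs.size:
        nbins = int(round(pool_above / cov_bin))
        counts, edges = np.histogram(covs[covs <= pool_above],
                                     bins=nbins, range=(0.0, pool_above))
        hist = (edges, counts, int((covs > pool_above).sum()))

    return AssemblyMetrics(
        n_contigs=len(lens),
        n_large_contigs=len(large),
        bases_large=sum(large),
        avg_large_contig=round(sum(large) / len(large)) if large else 0,
        n50_large=n50(large),
        largest=max(lens),
        estimated_coverage=est_cov,
        estimated_genome_size=genome_size,
        coverage_histogram=hist,
    )
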