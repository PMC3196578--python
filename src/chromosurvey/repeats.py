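"""Read-classification cascade for the repetitive landscape of a survey.

Each read receives exactly one label, tested stage by stage:
known TE (nucleotide repeat library) -> novel TE (TE protein domains) ->
viral -> gene evidence -> high-coverage repeat -> other.  The "Repeats"
class captures reads from collapsed contigs: at ~2x sequencing coverage any
contig coverage (n*r)/c >= 5 very likely marks a sensu stricto repeat.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import io_formats
from .similarity import (SearchParams, SimilaritySearcher, ThresholdProfile,
                         filter_hits)

KNOWN_TE = "KNOWN_TE"
NOVEL_TE = "NOVEL_TE"
REPEAT = "REPEAT"
GENE = "GENE"
VIRAL = "VIRAL"
OTHER = "OTHER"
ALL_LABELS = (KNOWN_TE, NOVEL_TE, REPEAT, GENE, VIRAL, OTHER)


@dataclass
class ClassLabel:
    label: str
    family: Optional[str] = None


@dataclass
class ContigMembership:
    """Contig read membership; coverage = n * r / c."""

    contig_id: str
    member_read_ids: List[str]
    consensus_len: int
    avg_read_len: Optional[float] = None

    @property
    def n_reads(self) -> int:
        return len(self.member_read_ids)


def contig_coverage(n: int, r: float, c: int) -> float:
    """(n*r)/c with n reads of average length r on a consensus of length c."""
    if c <= 0:
        raise ValueError("consensus length must be positive")
    return n * r / c


def high_coverage_read_set(memberships: Sequence[ContigMembership],
                           cutoff: float = 5.0,
                           read_lengths: Optional[Mapping[str, int]] = None) -> set:
    """Reads belonging to contigs whose coverage is >= cutoff (inclusive)."""
    out = set()
    for m in memberships:
        r = m.avg_read_len
        if r is None:
            if read_lengths is None:
                raise ValueError(f"no average read length for {m.contig_id}")
            r = sum(read_lengths[i] for i in m.member_read_ids) / m.n_reads
        if contig_coverage(m.n_reads, r, m.consensus_len) >= cutoff:
            out.update(m.member_read_ids)
    return out


def default_family_of(subject_id: str) -> str:
    """TE family from a library entry id ('Sabrina#RLC_copy3' -> 'Sabrina')."""
    return subject_id.split("#")[0].split("|")[0].split("_copy")[0]


DEFAULT_PROFILES = {
    "known_te": ThresholdProfile(max_evalue=1e-6, mode="nucleotide"),
    "novel_te": ThresholdProfile(max_evalue=1e-6, mode="translated"),
    # the stated viral bound "E-value >= 0.001" is treated as a typo for <=
    "viral": ThresholdProfile(max_evalue=1e-3, min_identity_pct=30,
                              min_similarity_pct=50, min_query_cov_pct=50,
                              min_subject_cov_pct=1, mode="translated"),
}


def classify_reads(reads: Sequence[tuple],
                   repeat_nt_db: Optional[Sequence[tuple]],
                   repeat_prot_db: Optional[Sequence[tuple]],
                   viral_prot_db: Optional[Sequence[tuple]],
                   gene_dbs: Optional[tuple],
                   memberships: Sequence[ContigMembership],
                   profiles: Optional[dict] = None,
                   coverage_cutoff: float = 5.0,
                   search_params: Optional[SearchParams] = None,
                   family_of=default_family_of,
                   excluded_domain_tags: Optional[Mapping[str, set]] = None,
                   ) -> Dict[str, ClassLabel]:
    """Sequential cascade: a read reaches a stage only if still unlabeled.

    ``gene_dbs`` is a (protein_db, est_db) pair handed to
    :func:`chromosurvey.genecontent.identify_gene_reads`.  A ``None``
    database skips its stage.  Singleton reads have no contig coverage and
    can never be labeled REPEAT.
    """
    from .genecontent import identify_gene_reads

    profiles = {**DEFAULT_PROFILES, **(profiles or {})}
    params = search_params or SearchParams()
    labels: Dict[str, ClassLabel] = {}
    remaining = list(reads)
    read_lengths = {rid: len(seq) for rid, seq in reads}

    def run_stage(db, mode, profile, label, with_family=False,
                  early_stop=False):
        nonlocal remaining
        if db is None or not db or not remaining:
            return
        stage_params = params
        if early_stop:
            # the stage profile bounds E only, so the search may stop at the
            # first hit below the stage cutoff
            from dataclasses import replace as _replace
            stage_params = _replace(params, stop_evalue=profile.max_evalue)
        searcher = SimilaritySearcher(db, mode, stage_params)
        still = []
        for rid, seq in remaining:
            hits = filter_hits(searcher.search_one(rid, seq), profile)
            if hits:
                fam = family_of(hits[0].subject_id) if with_family else None
                labels[rid] = ClassLabel(label, fam)
            else:
                still.append((rid, seq))
        io_formats.log_stage(label.lower(), len(remaining),
                             len(remaining) - len(still))
        remaining = still

    run_stage(repeat_nt_db, "nucleotide", profiles["known_te"], KNOWN_TE,
              with_family=True, early_stop=True)
    run_stage(repeat_prot_db, "translated", profiles["novel_te"], NOVEL_TE,
              early_stop=True)
    run_stage(viral_prot_db, "translated", profiles["viral"], VIRAL)

    if gene_dbs is not None and remaining:
        protein_db, est_db = gene_dbs
        evidence = identify_gene_reads(remaining, protein_db, est_db,
                                       excluded_domain_tags=excluded_domain_tags,
                                       search_params=params)
        gene_ids = {e.read_id for e in evidence if e.excluded_by_domain is None}
        n_before = len(remaining)
        remaining = [(rid, s) for rid, s in remaining if rid not in gene_ids]
        for rid in gene_ids:
            labels[rid] = ClassLabel(GENE)
        io_formats.log_stage("gene", n_before, len(gene_ids))

    assembled_ids = {rid for m in memberships for rid in m.member_read_ids}
    high_cov = high_coverage_read_set(memberships, coverage_cutoff,
                                      read_lengths={k: read_lengths[k]
                                                    for k in assembled_ids
                                                    if k in read_lengths})
    n_before = len(remaining)
    still = []
    for rid, seq in remaining:
        if rid in high_cov:
            labels[rid] = ClassLabel(REPEAT)
        else:
            still.append((rid, seq))
    io_formats.log_stage("repeat", n_before, n_before - len(still))

    for rid, _ in still:
        labels[rid] = ClassLabel(OTHER)
    io_formats.log_stage("other", len(still), len(still))
    return labels


@dataclass
class ClassificationSummary:
    """Per-class ledger of read counts and percentages (two decimals)."""

    counts: Dict[str, int]
    percentages: Dict[str, float]
    total_reads: int
    combined_repeat_count: int
    combined_repeat_pct: float

    def to_rows(self) -> List[tuple]:
        rows = [(lbl, self.counts.get(lbl, 0), self.percentages.get(lbl, 0.0))
                for lbl in ALL_LABELS]
        rows.insert(3, ("KNOWN_TE+NOVEL_TE+REPEAT",
                        self.combined_repeat_count, self.combined_repeat_pct))
        return rows


def summarize_classes(labels, total_reads: int) -> ClassificationSummary:
    """Build the per-class ledger.

    ``labels`` is either a mapping read_id -> ClassLabel/str or a mapping
    class name -> count (for published-ledger arithmetic).
    """
    if labels and all(isinstance(v, int) for v in labels.values()):
        counts = dict(labels)
    else:
        c: Counter = Counter()
        for v in labels.values():
            c[v.label if isinstance(v, ClassLabel) else v] += 1
        counts = dict(c)
    n_labeled = sum(counts.values())
    if n_labeled > total_reads:
        raise ValueError("more labels than reads")
    if not all(isinstance(v, int) for v in labels.values()) and n_labeled < total_reads:
        raise ValueError("labels missing for some reads")
    pcts = {k: round(100.0 * v / total_reads, 2) for k, v in counts.items()}
    comb = sum(counts.get(k, 0) for k in (KNOWN_TE, NOVEL_TE, REPEAT))
    return ClassificationSummary(
        counts=counts, percentages=pcts, total_reads=total_reads,
        combined_repeat_count=comb,
        combined_repeat_pct=round(100.0 * comb / total_reads, 2))


def te_family_census(labels: Mapping[str, ClassLabel]):
    """Per-family read counts among KNOWN_TE reads, sorted descending."""
    c: Counter = Counter()
    for v in labels.values():
        if isinstance(v, ClassLabel) and v.label == KNOWN_TE and v.family:
            c[v.family] += 1
    return dict(sorted(c.items(), key=lambda kv: (-kv[1], kv[0])))
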