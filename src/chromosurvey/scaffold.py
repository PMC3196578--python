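"""Unigene-guided contig scaffolding.

Unigenes (non-redundant transcript consensi) are mapped onto assembly
contigs at high stringency (identity >= 97%, matched windows >= 50 bp) so
that homeologous copies are kept apart.  A unigene that matches several
contigs on different portions of its sequence orders those contigs; they
are joined with a row of 100 Ns because the intron span between them
cannot be determined from transcript evidence.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import io_formats
from .similarity import (SearchParams, SimilaritySearcher, revcomp)

GAP_N = 100


@dataclass
class UnigeneMatch:
    unigene_id: str
    contig_id: str
    unigene_interval: tuple     # 0-based half-open on the unigene
    contig_interval: tuple
    identity_pct: float
    strand: str


@dataclass
class Scaffold:
    scaffold_id: str
    contig_ids: List[str]
    sequence: str
    unigene_id: str
    n_exons_covered: int


@dataclass
class StringencyPreset:
    min_identity: float = 97.0
    min_match_len: int = 50


RELAXED_PRESET = StringencyPreset(min_identity=80.0, min_match_len=50)


def map_unigenes(unigenes: Sequence[tuple], contigs: Sequence[tuple],
                 preset: StringencyPreset = StringencyPreset(),
                 contig_arms: Optional[Mapping[str, str]] = None,
                 search_params: Optional[SearchParams] = None):
    """Match unigenes against contigs; returns (matches, summary, per_unigene).

    summary follows the published schema: total unigenes, fraction matched,
    single/multi-hit counts and (when ``contig_arms`` is given) the
    only-arm-1 / only-arm-2 / both-arms partition.  per_unigene carries the
    coverage percentage and contig count used for the histograms.
    """
    params = search_params or SearchParams()
    searcher = SimilaritySearcher(list(contigs), "nucleotide", params)
    matches: List[UnigeneMatch] = []
    per_unigene: Dict[str, dict] = {}
    for uid, useq in unigenes:
        hits = [h for h in searcher.search_one(uid, useq)
                if h.identity_pct >= preset.min_identity
                and h.aln_len >= preset.min_match_len]
        if not hits:
            continue
        ivs = []
        cset = set()
        for h in hits:
            matches.append(UnigeneMatch(
                unigene_id=uid, contig_id=h.subject_id,
                unigene_interval=h.query_interval,
                contig_interval=h.subject_interval,
                identity_pct=h.identity_pct, strand=h.strand))
            ivs.append(h.query_interval)
            cset.add(h.subject_id)
        covered = _union_len(ivs)
        per_unigene[uid] = {
            "n_contigs": len(cset),
            "coverage_pct": 100.0 * covered / len(useq),
            "arms": (sorted({contig_arms.get(c) for c in cset} - {None})
                     if contig_arms else []),
        }
    n_total = len(unigenes)
    n_matched = len(per_unigene)
    summary = {
        "total_unigenes": n_total,
        "matched": n_matched,
        "pct_matched": round(100.0 * n_matched / n_total, 1) if n_total else 0.0,
        "one_hit": sum(1 for d in per_unigene.values() if d["n_contigs"] == 1),
        "multi_hit": sum(1 for d in per_unigene.values() if d["n_contigs"] > 1),
    }
    if contig_arms:
        arms = sorted({a for a in contig_arms.values()})
        for a in arms:
            summary[f"only_{a}"] = sum(1 for d in per_unigene.values()
                                       if d["arms"] == [a])
        summary["both_arms"] = sum(1 for d in per_unigene.values()
                                   if len(d["arms"]) > 1)
    io_formats.log_stage("map_unigenes", n_total, n_matched)
    return matches, summary, per_unigene


def _union_len(intervals: Sequence[tuple]) -> int:
    total = 0
    last = -1
    for a, b in sorted(intervals):
        a = max(a, last)
        if b > a:
            total += b - a
            last = b
        last = max(last, b)
    return total


def flag_problem_unigenes(matches: Sequence[UnigeneMatch],
                          repeat_threshold: int = 10) -> Dict[str, str]:
    """Repetitive and homeolog flags.

    A unigene is repetitive when the same region is present on more than
    ``repeat_threshold`` distinct contigs (max depth of contig matches
    along the unigene).  Unigenes matching an identical contig set are
    treated as a homeolog group: all but the highest-identity one are
    flagged for removal.
    """
    flags: Dict[str, str] = {}
    by_unigene: Dict[str, list] = defaultdict(list)
    for m in matches:
        by_unigene[m.unigene_id].append(m)
    for uid, ms in by_unigene.items():
        events = []
        for m in ms:
            a, b = m.unigene_interval
            events.append((a, 1))
            events.append((b, -1))
        depth = 0
        max_depth = 0
        for _, delta in sorted(events):
            depth += delta
            max_depth = max(max_depth, depth)
        if max_depth > repeat_threshold:
            flags[uid] = "repetitive"
    groups: Dict[frozenset, list] = defaultdict(list)
    for uid, ms in by_unigene.items():
        if uid in flags:
            continue
        groups[frozenset(m.contig_id for m in ms)].append(uid)
    for cset, uids in groups.items():
        if len(uids) < 2:
            continue
        ident = {u: max(m.identity_pct for m in by_unigene[u]) for u in uids}
        keep = max(uids, key=lambda u: (ident[u], u))
        for u in uids:
            if u != keep:
                flags[u] = "homeolog"
    return flags


def scaffold_contigs(matches: Sequence[UnigeneMatch],
                     contig_seqs: Mapping[str, str],
                     flags: Optional[Mapping[str, str]] = None,
                     overlap_tolerance: int = 15):
    """Join contigs along their guiding unigenes with 100-N spacers.

    Eligible unigenes match more than one contig, carry no problem flag,
    and their member contigs match no other unigene; a contig claimed by
    two unigenes is excluded from both (logged).  Contig order follows the
    unigene coordinate order; minus-strand matches are reverse-complemented
    so the scaffold reads in transcript orientation.  Returns
    (scaffolds, stats).
    """
    flags = flags or {}
    usable = [m for m in matches if flags.get(m.unigene_id) is None]
    claimed: Dict[str, set] = defaultdict(set)
    for m in usable:
        claimed[m.contig_id].add(m.unigene_id)
    shared = {c for c, us in claimed.items() if len(us) > 1}
    for c in sorted(shared):
        io_formats.log_stage("contig_shared_between_unigenes", 1, 0, contig=c)
    by_unigene: Dict[str, list] = defaultdict(list)
    for m in usable:
        if m.contig_id not in shared:
            by_unigene[m.unigene_id].append(m)

    scaffolds: List[Scaffold] = []
    for uid in sorted(by_unigene):
        ms = by_unigene[uid]
        # one interval per contig: keep the best (longest) match per contig
        per_contig: Dict[str, UnigeneMatch] = {}
        for m in ms:
            prev = per_contig.get(m.contig_id)
            if prev is None or (m.unigene_interval[1] - m.unigene_interval[0] >
                                prev.unigene_interval[1] - prev.unigene_interval[0]):
                per_contig[m.contig_id] = m
        if len(per_contig) < 2:
            continue
        ordered = sorted(per_contig.values(), key=lambda m: m.unigene_interval)
        ok = all(ordered[i + 1].unigene_interval[0] >=
                 ordered[i].unigene_interval[1] - overlap_tolerance
                 for i in range(len(ordered) - 1))
        if not ok:
            continue
        parts = []
        for m in ordered:
            seq = contig_seqs[m.contig_id]
            parts.append(seq if m.strand == "+" else revcomp(seq))
        n_exons = sum(len([x for x in by_unigene[uid]
                           if x.contig_id == m.contig_id]) for m in ordered)
        scaffolds.append(Scaffold(
            scaffold_id=f"scaffold_{uid}",
            contig_ids=[m.contig_id for m in ordered],
            sequence=("N" * GAP_N).join(parts),
            unigene_id=uid,
            n_exons_covered=n_exons))
    stats = scaffold_stats(scaffolds)
    io_formats.log_stage("scaffold", len(by_unigene), len(scaffolds))
    return scaffolds, stats


def scaffold_stats(scaffolds: Sequence[Scaffold]) -> dict:
    """Published-schema statistics; bases exclude the joining Ns."""
    n = len(scaffolds)
    if n == 0:
        return {"n_scaffolds": 0, "contigs_per_scaffold": 0.0,
                "bases_per_scaffold": 0.0, "exons_per_scaffold": 0.0,
                "n_contigs_in_scaffolds": 0}
    n_contigs = sum(len(s.contig_ids) for s in scaffolds)
    bases = sum(len(s.sequence) - GAP_N * (len(s.contig_ids) - 1)
                for s in scaffolds)
    exons = sum(s.n_exons_covered for s in scaffolds)
    return {"n_scaffolds": n,
            "n_contigs_in_scaffolds": n_contigs,
            "contigs_per_scaffold": round(n_contigs / n, 1),
            "bases_per_scaffold": round(bases / n, 1),
            "exons_per_scaffold": round(exons / n, 1)}
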