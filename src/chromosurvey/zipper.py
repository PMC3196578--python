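"""Synteny mapping and the genome zipper.

A "genome zipper" is a virtual gene order for an unassembled chromosome,
inferred from the collinear gene order of a fully sequenced relative
(species A) and validated with two further relatives (B and C).  Each
zipper entry carries a reliability code OxSx(hyz): the two x bits say
whether the best B (O) and C (S) homolog lies on a configured syntenic
chromosome, and h/y/z whether the A-B, A-C and B-C pairs are reciprocal
best hits.  Survey reads and bin-mapped EST markers are then anchored onto
the zipper, and marker/bin collinearity is used to score the predicted
order and flag candidate inversions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import io_formats
from .similarity import (Hit, SearchParams, SimilaritySearcher,
                         ThresholdProfile, best_hit_per_query, filter_hits,
                         reciprocal_best_hits)


@dataclass
class RefGene:
    species: str
    gene_id: str
    chromosome: str
    position: int            # bp midpoint on its chromosome
    nucleotide: str = ""
    protein: str = ""


@dataclass
class ZipperEntry:
    ref_gene: RefGene
    rank: int
    code: str                # "OxSx(hyz)"
    anchored_read_ids: List[str] = field(default_factory=list)
    anchored_markers: List[str] = field(default_factory=list)
    ambiguous_read_ids: List[str] = field(default_factory=list)


@dataclass
class Bin:
    name: str
    arm: str
    frac_start: float
    frac_end: float

    def contains(self, frac: float) -> bool:
        return self.frac_start <= frac < self.frac_end


@dataclass
class BinMap:
    bins: List[Bin]
    marker_to_bin: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.bins = sorted(self.bins, key=lambda b: (b.arm, b.frac_start,
                                                     b.frac_end))

    def overlap_flags(self) -> Dict[str, bool]:
        flags = {b.name: False for b in self.bins}
        for i, a in enumerate(self.bins):
            for b in self.bins[i + 1:]:
                if a.arm == b.arm and a.frac_start < b.frac_end and \
                        b.frac_start < a.frac_end:
                    flags[a.name] = flags[b.name] = True
        return flags

    def bin_of(self, arm: str, frac: float) -> Optional[str]:
        for b in self.bins:
            if b.arm == arm and b.contains(frac):
                return b.name
        return None

    def assign_marker(self, marker_id: str, arm: str, frac: float) -> None:
        name = self.bin_of(arm, frac)
        if name is None:
            raise ValueError(f"no bin covers arm {arm} fraction {frac}")
        self.marker_to_bin[marker_id] = name


@dataclass
class SyntenyDensityTrack:
    chromosome: str
    window_starts: np.ndarray
    density: np.ndarray      # matching genes per window
    window: int
    step: int


# ---------------------------------------------------------------------------

MAP_PROFILE = ThresholdProfile(max_evalue=1e-6, min_identity_pct=30,
                               min_similarity_pct=50, min_query_cov_pct=50,
                               mode="translated")


def map_gene_reads(gene_reads: Sequence[tuple],
                   proteomes: Mapping[str, Sequence[tuple]],
                   profile: ThresholdProfile = MAP_PROFILE,
                   search_params: Optional[SearchParams] = None):
    """Best protein hit per read per species + the Venn partition of reads.

    Returns (per_read: read_id -> {species: Hit}, venn: pattern -> count)
    where pattern is the sorted concatenation of species keys hit
    (e.g. 'A', 'AB', 'ABC'); reads hitting no species are excluded.
    """
    params = search_params or SearchParams()
    per_read: Dict[str, Dict[str, Hit]] = {}
    for sp in sorted(proteomes):
        searcher = SimilaritySearcher(proteomes[sp], "translated", params)
        for rid, seq in gene_reads:
            hits = filter_hits(searcher.search_one(rid, seq), profile)
            if hits:
                best = best_hit_per_query(hits)[rid]
                per_read.setdefault(rid, {})[sp] = best
    venn: Dict[str, int] = {}
    for rid, d in per_read.items():
        pat = "".join(sorted(d))
        venn[pat] = venn.get(pat, 0) + 1
    return per_read, venn


def window_density(hit_positions: Sequence[int], chrom_len: int,
                   chromosome: str = "", window: int = 1_000_000,
                   step: int = 20_000) -> SyntenyDensityTrack:
    """Distinct matched genes per sliding window (trailing windows truncated)."""
    pos = np.unique(np.asarray(list(hit_positions), dtype=np.int64))
    if pos.size and (pos.min() < 0 or pos.max() >= chrom_len):
        raise ValueError("positions outside chromosome")
    starts = np.arange(0, max(chrom_len, 1), step, dtype=np.int64)
    dens = np.array([np.count_nonzero((pos >= s) & (pos < s + window))
                     for s in starts])
    return SyntenyDensityTrack(chromosome=chromosome, window_starts=starts,
                               density=dens, window=window, step=step)


def call_syntenic_regions(track: SyntenyDensityTrack,
                          min_density: float = 50.0) -> List[tuple]:
    """Maximal runs of windows with density >= min_density, merged."""
    hot = track.density >= min_density
    out = []
    i = 0
    n = hot.size
    while i < n:
        if hot[i]:
            j = i
            while j + 1 < n and hot[j + 1]:
                j += 1
            start = int(track.window_starts[i])
            end = int(track.window_starts[j]) + track.window
            out.append((start, end))
            i = j + 1
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# zipper construction


def _in_intervals(pos: int, intervals: Optional[Sequence[tuple]]) -> bool:
    if intervals is None:
        return True
    return any(a <= pos < b for a, b in intervals)


def build_zipper(genesA: Sequence[RefGene],
                 homology_AB: tuple, homology_AC: tuple, homology_BC: tuple,
                 syntenic_chroms_B: set, syntenic_chroms_C: set,
                 syntenic_intervals_A: Optional[Sequence[tuple]] = None,
                 genesB: Optional[Mapping[str, RefGene]] = None,
                 genesC: Optional[Mapping[str, RefGene]] = None,
                 max_evalue: float = 1e-10) -> List[ZipperEntry]:
    """Ordered zipper entries with OxSx(hyz) reliability codes.

    Each ``homology_XY`` is a pair (hits_xy, hits_yx) of nucleotide-level
    hit lists between the gene sets; hits above ``max_evalue`` are ignored.
    A species-A gene enters the zipper iff it lies in the configured
    syntenic intervals and has a homolog in B or C.
    """
    prof = ThresholdProfile(max_evalue=max_evalue)
    ab, ba = (filter_hits(h, prof) for h in homology_AB)
    ac, ca = (filter_hits(h, prof) for h in homology_AC)
    bc, cb = (filter_hits(h, prof) for h in homology_BC)
    known = {g.gene_id for g in genesA}
    for hits in (ab, ac):
        for h in hits:
            if h.query_id not in known:
                raise ValueError(f"homology table references unknown gene "
                                 f"{h.query_id}")
    best_ab = best_hit_per_query(ab)
    best_ac = best_hit_per_query(ac)
    rbh_ab = reciprocal_best_hits(ab, ba)
    rbh_ac = reciprocal_best_hits(ac, ca)
    rbh_bc = reciprocal_best_hits(bc, cb)

    entries = []
    for g in sorted(genesA, key=lambda g: (g.position, g.gene_id)):
        if not _in_intervals(g.position, syntenic_intervals_A):
            continue
        hb = best_ab.get(g.gene_id)
        hc = best_ac.get(g.gene_id)
        if hb is None and hc is None:
            continue
        o = 0
        s = 0
        if hb is not None and genesB is not None:
            o = int(genesB[hb.subject_id].chromosome in syntenic_chroms_B)
        if hc is not None and genesC is not None:
            s = int(genesC[hc.subject_id].chromosome in syntenic_chroms_C)
        h_bit = int(hb is not None and (g.gene_id, hb.subject_id) in rbh_ab)
        y_bit = int(hc is not None and (g.gene_id, hc.subject_id) in rbh_ac)
        z_bit = int(hb is not None and hc is not None and
                    (hb.subject_id, hc.subject_id) in rbh_bc)
        entries.append(ZipperEntry(
            ref_gene=g, rank=len(entries),
            code=f"O{o}S{s}({h_bit}{y_bit}{z_bit})"))
    return entries


def zipper_quality(entries: Sequence[ZipperEntry]) -> dict:
    """Fraction of genes on syntenic chromosomes and of true orthologs."""
    n = len(entries)
    syn = sum(1 for e in entries if "O1" in e.code or "S1" in e.code)
    orth = sum(1 for e in entries
               if ("O1" in e.code or "S1" in e.code) and "1" in e.code[5:8])
    return {"n_genes": n,
            "pct_syntenic": 100.0 * syn / n if n else 0.0,
            "pct_true_ortholog": 100.0 * orth / syn if syn else 0.0}


def anchor_reads(reads: Sequence[tuple], zipper: List[ZipperEntry],
                 max_evalue: float = 1e-10,
                 search_params: Optional[SearchParams] = None):
    """Anchor survey reads to zipper genes by best nucleotide hit.

    Each read lands on at most one entry; equally good anchors go to the
    lower rank and are flagged ambiguous.  Returns (zipper, anchors, stats).
    """
    subjects = [(e.ref_gene.gene_id, e.ref_gene.nucleotide) for e in zipper]
    rank_of = {e.ref_gene.gene_id: e.rank for e in zipper}
    searcher = SimilaritySearcher(subjects, "nucleotide",
                                  search_params or SearchParams())
    anchors: Dict[str, int] = {}
    for rid, seq in reads:
        hits = [h for h in searcher.search_one(rid, seq)
                if h.evalue <= max_evalue]
        if not hits:
            continue
        best_key = (hits[0].evalue, -hits[0].bitscore)
        ties = [h for h in hits if (h.evalue, -h.bitscore) == best_key]
        ranks = sorted(rank_of[h.subject_id] for h in ties)
        entry = zipper[ranks[0]]
        entry.anchored_read_ids.append(rid)
        if len(ranks) > 1:
            entry.ambiguous_read_ids.append(rid)
        anchors[rid] = ranks[0]
    anchored_entries = [e for e in zipper if e.anchored_read_ids]
    n_anch = len(anchored_entries)
    good = sum(1 for e in anchored_entries
               if ("O1" in e.code or "S1" in e.code) and "1" in e.code[5:8])
    stats = {"n_entries_anchored": n_anch,
             "n_reads_anchored": len(anchors),
             "pct_anchored_syntenic_ortholog":
                 100.0 * good / n_anch if n_anch else 0.0}
    io_formats.log_stage("anchor_reads", len(list(reads)), len(anchors))
    return zipper, anchors, stats


def anchor_markers(reads: Sequence[tuple], markers: Sequence[tuple],
                   bin_map: BinMap,
                   read_arms: Optional[Mapping[str, str]] = None,
                   max_evalue: float = 1e-10,
                   search_params: Optional[SearchParams] = None):
    """Anchor reads to bin-mapped EST markers.

    Returns (anchors: read_id -> (marker_id, bin_name), report).  The
    report gives, per arm of read origin, the fraction of anchored reads
    whose marker sits on their own arm vs the opposite arm — counted both
    by reads and by distinct markers, since published "correct arm"
    fractions are ambiguous between the two.
    """
    for mid, _ in markers:
        if mid not in bin_map.marker_to_bin:
            raise ValueError(f"marker {mid} has no bin assignment")
    arm_of_bin = {b.name: b.arm for b in bin_map.bins}
    searcher = SimilaritySearcher(list(markers), "nucleotide",
                                  search_params or SearchParams())
    anchors: Dict[str, tuple] = {}
    for rid, seq in reads:
        hits = [h for h in searcher.search_one(rid, seq)
                if h.evalue <= max_evalue]
        if not hits:
            continue
        mid = hits[0].subject_id
        anchors[rid] = (mid, bin_map.marker_to_bin[mid])
    report: Dict[str, dict] = {}
    if read_arms:
        per_arm: Dict[str, dict] = {}
        for rid, (mid, bname) in anchors.items():
            arm = read_arms.get(rid)
            if arm is None:
                continue
            d = per_arm.setdefault(arm, {"own_reads": 0, "cross_reads": 0,
                                         "own_markers": set(),
                                         "cross_markers": set()})
            if arm_of_bin[bname] == arm:
                d["own_reads"] += 1
                d["own_markers"].add(mid)
            else:
                d["cross_reads"] += 1
                d["cross_markers"].add(mid)
        for arm, d in per_arm.items():
            nr = d["own_reads"] + d["cross_reads"]
            nm = len(d["own_markers"]) + len(d["cross_markers"])
            report[arm] = {
                "n_reads": nr,
                "pct_own_arm_reads": 100.0 * d["own_reads"] / nr if nr else 0.0,
                "pct_own_arm_markers":
                    100.0 * len(d["own_markers"]) / nm if nm else 0.0,
            }
    return anchors, report


# ---------------------------------------------------------------------------
# collinearity


def collinearity_check(zipper: Sequence[ZipperEntry],
                       marker_ranks: Mapping[str, int],
                       marker_bins: Mapping[str, str],
                       selected_bins: Sequence[str],
                       min_markers: int = 2,
                       min_inversion_markers: int = 3):
    """Marker/bin consistency statistics and inversion candidates.

    ``selected_bins`` lists non-overlapping bins in physical (arm) order.
    A marker is out of place when it must be removed for the remaining
    bin labels (in zipper-rank order) to follow the physical bin order —
    i.e. the markers off the longest non-decreasing subsequence of bin
    indices.  An inversion candidate is any maximal non-increasing
    bin-order segment of >= min_inversion_markers markers containing a
    strict decrease.
    """
    bin_idx = {b: i for i, b in enumerate(selected_bins)}
    per_bin_count: Dict[str, int] = {}
    for m, rank in marker_ranks.items():
        b = marker_bins.get(m)
        if b in bin_idx:
            per_bin_count[b] = per_bin_count.get(b, 0) + 1
    skipped = [b for b, c in per_bin_count.items() if c < min_markers]
    sel = [(rank, marker_bins[m], m) for m, rank in marker_ranks.items()
           if marker_bins.get(m) in bin_idx
           and marker_bins[m] not in skipped]
    sel.sort()

    # longest non-decreasing subsequence of bin indices (kept markers)
    out_of_place: Dict[str, int] = {b: 0 for b in selected_bins
                                    if b not in skipped}
    n_sel = len(sel)
    if n_sel:
        idxs = [bin_idx[b] for _, b, _ in sel]
        length = [1] * n_sel
        prev = [-1] * n_sel
        for i in range(n_sel):
            for j in range(i):
                if idxs[j] <= idxs[i] and length[j] + 1 > length[i]:
                    length[i] = length[j] + 1
                    prev[i] = j
        end = max(range(n_sel), key=lambda i: (length[i], -i))
        keep = set()
        while end >= 0:
            keep.add(end)
            end = prev[end]
        for pos, (rank, b, m) in enumerate(sel):
            if pos not in keep:
                out_of_place[b] = out_of_place.get(b, 0) + 1

    inversions = []
    i = 0
    n = len(sel)
    while i < n:
        j = i
        dec = 0
        while j + 1 < n and bin_idx[sel[j + 1][1]] <= bin_idx[sel[j][1]]:
            if bin_idx[sel[j + 1][1]] < bin_idx[sel[j][1]]:
                dec += 1
            j += 1
        if j - i + 1 >= min_inversion_markers and dec >= 1:
            inversions.append({
                "rank_start": sel[i][0], "rank_end": sel[j][0],
                "bins": sorted({sel[k][1] for k in range(i, j + 1)},
                               key=lambda b: bin_idx[b]),
                "n_markers": j - i + 1,
            })
        i = j + 1 if j > i else i + 1
    return {"out_of_place": out_of_place,
            "total_out_of_place": sum(out_of_place.values()),
            "skipped_bins": skipped,
            "inversions": inversions}


def zipper_to_rows(zipper: Sequence[ZipperEntry]) -> List[dict]:
    """TSV-ready rows (rank, gene, chromosome, position, code, anchors)."""
    return [{
        "rank": e.rank,
        "gene_id": e.ref_gene.gene_id,
        "chromosome": e.ref_gene.chromosome,
        "position": e.ref_gene.position,
        "code": e.code,
        "n_anchored_reads": len(e.anchored_read_ids),
        "markers": ",".join(e.anchored_markers),
    } for e in zipper]
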