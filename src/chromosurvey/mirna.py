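"""Conserved-miRNA precursor discovery by homology + hairpin scoring.

Pipeline: (i) search known mature miRNAs against contigs/singletons
(word 7, E <= 10, <= 10 hits per query); (ii) keep subjects with both a
direct hit (<= 3 mismatches) and a reverse-complement hit (the miRNA*
side, kept regardless of mismatches); (iii) excise the putative precursor
13 nt outside the two hits; (iv) fold it and score MFEI = AMFE / GC%,
where AMFE = -MFE * 100 / length; (v) apply the duplex and protein-coding
filters and annotate against known precursors and repeat libraries.

The internal folder is a Zuker-lite dynamic program with pair energies
GC -3, AU -2, GU -1 kcal/mol, free hairpin/multiloop bases, +1 kcal/mol per
unpaired base in internal loops/bulges, and hairpin loops >= 3 nt.  It is
deliberately simple: absolute energies differ from production folders, so
the MFEI cutoff is configurable and external dot-bracket + MFE output can
be plugged in per candidate.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._kernels import fold_energy
from .similarity import (SearchParams, SimilaritySearcher, ThresholdProfile,
                         filter_hits)

_RNA_LUT = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGU"):
    _RNA_LUT[ord(_c)] = _i
_RNA_LUT[ord("T")] = 3

PAIR_E = np.full((4, 4), 1.0e9)
for _a, _b, _e in (("G", "C", -3.0), ("A", "U", -2.0), ("G", "U", -1.0)):
    _ia, _ib = "ACGU".index(_a), "ACGU".index(_b)
    PAIR_E[_ia, _ib] = _e
    PAIR_E[_ib, _ia] = _e

BULGE_PEN = 1.0
MIN_LOOP = 3
MAX_INTERNAL = 30
# loop-initiation penalties (kcal/mol): discourage spurious tiny hairpins
# and multibranch junk, as entropic terms do in full energy models
HAIRPIN_PEN = 3.0
MULTI_PEN = 3.0


@dataclass
class MirnaConfig:
    word_size: int = 7
    max_evalue: float = 10.0
    max_hits_per_query: int = 10
    direct_max_mismatches: int = 3
    flank: int = 13
    max_precursor_len: int = 500
    min_fold_len: int = 40
    mfei_cutoff: float = 0.85
    max_mature_star_mismatches: int = 4
    max_bulge_len: int = 3
    max_n_bulges: int = 2
    known_precursor_min_identity: float = 70.0
    count_wobble_as_mismatch: bool = False
    # the star-side local alignment often under-runs the true miRNA* ends;
    # the duplex test accepts partners within this many nt of the star hit
    star_pad: int = 6
    # terminal mature positions excluded from the duplex test (miRNA/miRNA*
    # duplexes carry 2-nt overhangs and helix ends breathe)
    duplex_end_slack: int = 2


@dataclass
class MatureHit:
    subject_seq_id: str
    orientation: str            # 'direct' | 'revcomp'
    interval: tuple             # on the subject, 0-based half-open
    mature_id: str
    family: str
    mismatches: int


@dataclass
class CandidateLocus:
    subject_seq_id: str
    family: str
    five_hit: MatureHit
    three_hit: MatureHit
    mature_hit: MatureHit       # the direct hit
    star_hit: MatureHit         # the reverse-complement hit


@dataclass
class MirnaCandidate:
    precursor_seq: str
    source_seq_id: str
    interval: tuple
    mature_hit: MatureHit
    star_hit: MatureHit
    family: str
    clipped: bool = False
    structure: str = ""
    mfe: float = 0.0
    amfe: float = 0.0
    mfei: float = 0.0
    gc_pct: float = 0.0
    mature_star_mismatches: int = -1
    mature_arm: str = ""
    flags: dict = field(default_factory=dict)
    fail_reasons: list = field(default_factory=list)


def family_of_mature(mature_id: str) -> str:
    """'tae-miR1122a' -> 'miR1122'; falls back to the full id."""
    m = re.search(r"(miR|MIR)[-]?(\d+)", mature_id)
    return f"miR{m.group(2)}" if m else mature_id


def find_mature_hits(sequences: Sequence[tuple], mature_db: Sequence[tuple],
                     config: Optional[MirnaConfig] = None) -> List[MatureHit]:
    """Direct/reverse-complement mature matches on the subject sequences.

    Direct hits with more than ``direct_max_mismatches`` substitutions (or
    any gap) are discarded; all reverse-complement hits are retained.
    Unaligned mature overhang counts as mismatch.
    """
    cfg = config or MirnaConfig()
    if not mature_db:
        raise ValueError("empty mature miRNA database")
    params = SearchParams(word_size=cfg.word_size, max_evalue=cfg.max_evalue,
                          max_hits_per_query=cfg.max_hits_per_query,
                          max_targets=4 * cfg.max_hits_per_query,
                          min_seed_count=1)
    searcher = SimilaritySearcher([(sid, s) for sid, s in sequences],
                                  "nucleotide", params)
    out: List[MatureHit] = []
    for mid, mseq in mature_db:
        mseq = mseq.upper().replace("U", "T")
        fam = family_of_mature(mid)
        for h in searcher.search_one(mid, mseq):
            qs, qe = h.query_interval
            mm = h.mismatches + (len(mseq) - (qe - qs))
            orient = "direct" if h.strand == "+" else "revcomp"
            if orient == "direct" and (mm > cfg.direct_max_mismatches
                                       or h.gap_opens > 0):
                continue
            out.append(MatureHit(
                subject_seq_id=h.subject_id, orientation=orient,
                interval=h.subject_interval, mature_id=mid,
                family=fam, mismatches=mm))
    return out


def pair_hits(hits: Sequence[MatureHit],
              config: Optional[MirnaConfig] = None) -> List[CandidateLocus]:
    """(direct, revcomp) pairs of the same family on the same subject.

    Overlapping pairs are rejected; the pair span must not exceed the
    configured maximum precursor length.
    """
    cfg = config or MirnaConfig()
    by_subject: Dict[str, List[MatureHit]] = {}
    for h in hits:
        by_subject.setdefault(h.subject_seq_id, []).append(h)
    loci = []
    for sid, hs in sorted(by_subject.items()):
        directs = [h for h in hs if h.orientation == "direct"]
        revs = [h for h in hs if h.orientation == "revcomp"]
        for d in directs:
            for r in revs:
                if d.family != r.family:
                    continue
                if d.interval[1] > r.interval[0] and r.interval[1] > d.interval[0]:
                    continue  # overlapping intervals
                span = max(d.interval[1], r.interval[1]) - min(d.interval[0],
                                                               r.interval[0])
                if span > cfg.max_precursor_len:
                    continue
                five, three = (d, r) if d.interval[0] < r.interval[0] else (r, d)
                loci.append(CandidateLocus(
                    subject_seq_id=sid, family=d.family,
                    five_hit=five, three_hit=three,
                    mature_hit=d, star_hit=r))
    return loci


def extract_precursor(subject_seq: str, locus: CandidateLocus,
                      flank: int = 13) -> tuple:
    """Excise flank nt before the 5' hit and after the 3' hit.

    Returns (precursor_sequence, (start, end), clipped_flag).
    """
    start5 = locus.five_hit.interval[0]
    end3 = locus.three_hit.interval[1]
    if end3 <= start5:
        raise ValueError("degenerate locus interval")
    start = max(0, start5 - flank)
    end = min(len(subject_seq), end3 + flank)
    clipped = (start5 - flank < 0) or (end3 + flank > len(subject_seq))
    return subject_seq[start:end], (start, end), clipped


# ---------------------------------------------------------------------------
# folding


def _traceback_pairs(codes, V, Wm, W1, eps=1e-6):
    n = codes.shape[0]
    pairs = []
    INF = 1.0e9 / 2

    def trace_W(i, j):
        while j > i:
            if Wm[i, j] >= -eps:
                return
            if abs(Wm[i, j] - Wm[i, j - 1]) < eps:
                j -= 1
                continue
            for k in range(i, j + 1):
                left = 0.0 if k == i else Wm[i, k - 1]
                if V[k, j] < INF and abs(left + V[k, j] - Wm[i, j]) < eps:
                    trace_V(k, j)
                    if k > i:
                        j = k - 1
                        break
                    return
            else:
                return
        return

    def trace_W1(i, j):
        while j > i:
            if j - 1 >= i and W1[i, j - 1] < INF and \
                    abs(W1[i, j] - W1[i, j - 1]) < eps:
                j -= 1
                continue
            for k in range(i, j + 1):
                left = 0.0 if k == i else Wm[i, k - 1]
                if V[k, j] < INF and abs(left + V[k, j] - W1[i, j]) < eps:
                    trace_V(k, j)
                    if k > i:
                        trace_W(i, k - 1)
                    return
            return

    def trace_V(i, j):
        pairs.append((i, j))
        pe = PAIR_E[codes[i], codes[j]]
        target = V[i, j] - pe
        if abs(target - HAIRPIN_PEN) < eps and j - i - 1 >= MIN_LOOP:
            return
        for k in range(i + 1, j - 1):
            lo = k - i - 1
            if lo > MAX_INTERNAL:
                break
            for l in range(j - 1, k, -1):
                ro = j - l - 1
                if lo + ro > MAX_INTERNAL:
                    break
                if V[k, l] < INF and \
                        abs(V[k, l] + BULGE_PEN * (lo + ro) - target) < eps:
                    trace_V(k, l)
                    return
        for m in range(i + 1, j - 1):
            a = W1[i + 1, m]
            b = W1[m + 1, j - 1]
            if a < INF and b < INF and abs(a + b + MULTI_PEN - target) < eps:
                trace_W1(i + 1, m)
                trace_W1(m + 1, j - 1)
                return

    trace_W(0, n - 1)
    return pairs


def fold_hairpin(precursor: str) -> tuple:
    """Minimum-energy nested structure; returns (dot-bracket, MFE <= 0).

    N and other ambiguity codes are unpairable; deterministic for a fixed
    sequence.
    """
    seq = precursor.upper().replace("T", "U")
    codes = _RNA_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.shape[0]
    if n == 0:
        return "", 0.0
    mfe, V, Wm, W1 = fold_energy(codes.astype(np.int64), PAIR_E, BULGE_PEN,
                                 MAX_INTERNAL, MIN_LOOP, HAIRPIN_PEN,
                                 MULTI_PEN)
    if mfe >= 0.0:
        return "." * n, 0.0
    pairs = _traceback_pairs(codes, V, Wm, W1)
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db), float(mfe)


def pair_table(structure: str) -> np.ndarray:
    """partner index per position, -1 if unpaired."""
    pt = np.full(len(structure), -1, dtype=np.int64)
    stack = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pt[i] = j
            pt[j] = i
    return pt


def mfei(mfe: float, length: int, gc_pct: float) -> tuple:
    """(AMFE, MFEI): AMFE = -MFE*100/length; MFEI = AMFE / GC%."""
    if mfe > 0:
        raise ValueError("MFE must be <= 0")
    if length <= 0:
        raise ValueError("length must be positive")
    if gc_pct <= 0 or gc_pct > 100:
        raise ValueError("GC% must be in (0, 100]")
    amfe = -mfe * 100.0 / length
    return amfe, amfe / gc_pct


def gc_percent(seq: str) -> float:
    seq = seq.upper()
    return 100.0 * sum(seq.count(c) for c in "GC") / len(seq) if seq else 0.0


# ---------------------------------------------------------------------------
# validation


def _duplex_stats(cand: MirnaCandidate, cfg: MirnaConfig) -> tuple:
    """(mismatches, bulge_runs) of the mature side within the mature-star
    duplex, judged on the folded structure: an unpaired mature position, or
    one paired outside the star interval, is a mismatch; G:U wobble pairs
    are not (configurable)."""
    pt = pair_table(cand.structure)
    start, _ = cand.interval
    m_lo = cand.mature_hit.interval[0] - start
    m_hi = cand.mature_hit.interval[1] - start
    s_lo = cand.star_hit.interval[0] - start - cfg.star_pad
    s_hi = cand.star_hit.interval[1] - start + cfg.star_pad
    seq = cand.precursor_seq.upper().replace("T", "U")
    mism = 0
    bulges = []
    run = 0
    for p in range(m_lo + cfg.duplex_end_slack, m_hi - cfg.duplex_end_slack):
        partner = pt[p]
        unpaired = partner < 0 or not (s_lo <= partner < s_hi)
        if unpaired:
            mism += 1
            run += 1
        else:
            if cfg.count_wobble_as_mismatch and \
                    {seq[p], seq[partner]} == {"G", "U"}:
                mism += 1
            if run:
                bulges.append(run)
            run = 0
    if run:
        bulges.append(run)
    return mism, bulges


def _loop_midpoint(structure: str) -> float:
    """Midpoint of the main hairpin loop (between the innermost pair)."""
    first_close = structure.find(")")
    if first_close < 0:
        return len(structure) / 2.0
    last_open = structure.rfind("(", 0, first_close)
    return (last_open + first_close) / 2.0


def validate_candidate(cand: MirnaCandidate,
                       config: Optional[MirnaConfig] = None,
                       protein_db: Optional[Sequence[tuple]] = None,
                       protein_searcher: Optional[SimilaritySearcher] = None,
                       ) -> bool:
    """Apply MFEI, duplex and protein-coding filters; records reasons.

    Pass requires MFEI strictly greater than the cutoff, <= 4 mature-star
    mismatches, no asymmetric bulge longer than 3 nt (and at most 2 bulges)
    in the duplex, and no protein-coding similarity.
    """
    cfg = config or MirnaConfig()
    if not cand.structure:
        raise ValueError("candidate must be folded first")
    reasons = []
    if not (cand.mfei > cfg.mfei_cutoff):
        reasons.append("mfei")
    mism, bulges = _duplex_stats(cand, cfg)
    cand.mature_star_mismatches = mism
    if mism > cfg.max_mature_star_mismatches:
        reasons.append("mature_star_mismatches")
    if any(b > cfg.max_bulge_len for b in bulges) or \
            len(bulges) > cfg.max_n_bulges:
        reasons.append("bulges")
    mature_mid = (cand.mature_hit.interval[0] + cand.mature_hit.interval[1]) / 2.0
    cand.mature_arm = "5'" if (mature_mid - cand.interval[0]) < \
        _loop_midpoint(cand.structure) else "3'"
    searcher = protein_searcher
    if searcher is None and protein_db:
        searcher = SimilaritySearcher(protein_db, "translated")
    if searcher is not None:
        profile = ThresholdProfile(max_evalue=1e-3, min_identity_pct=30,
                                   min_similarity_pct=50, min_query_cov_pct=50,
                                   min_subject_cov_pct=1, mode="translated")
        hits = filter_hits(searcher.search_one("prec", cand.precursor_seq),
                           profile)
        if hits:
            cand.flags["protein_coding"] = True
            reasons.append("protein_coding")
    cand.fail_reasons = reasons
    return not reasons


def annotate_candidates(candidates: Sequence[MirnaCandidate],
                        known_precursor_db: Optional[Sequence[tuple]] = None,
                        repeat_nt_db: Optional[Sequence[tuple]] = None,
                        config: Optional[MirnaConfig] = None):
    """Known-precursor similarity (>70% identity), repeat content, and the
    per-family report (count, precursor length range, mature arms)."""
    cfg = config or MirnaConfig()
    if known_precursor_db:
        searcher = SimilaritySearcher(known_precursor_db, "nucleotide",
                                      SearchParams(word_size=7))
        for c in candidates:
            hits = searcher.search_one("c", c.precursor_seq)
            if hits and hits[0].identity_pct > cfg.known_precursor_min_identity:
                c.flags["known_precursor_similar"] = True
    if repeat_nt_db:
        searcher = SimilaritySearcher(repeat_nt_db, "nucleotide")
        for c in candidates:
            if searcher.search_one("c", c.precursor_seq):
                c.flags["contains_repeat"] = True
    report = []
    byfam: Dict[str, list] = {}
    for c in candidates:
        byfam.setdefault(c.family, []).append(c)
    for fam in sorted(byfam):
        cs = byfam[fam]
        lens = [len(c.precursor_seq) for c in cs]
        arms = sorted({c.mature_arm for c in cs if c.mature_arm})
        report.append({
            "family": fam,
            "n_precursors": len(cs),
            "length_range": (f"{min(lens)}" if min(lens) == max(lens)
                             else f"{min(lens)}-{max(lens)}"),
            "mature_position": " - ".join(arms),
        })
    return list(candidates), report


def discover_mirnas(sequences: Sequence[tuple], mature_db: Sequence[tuple],
                    protein_db: Optional[Sequence[tuple]] = None,
                    known_precursor_db: Optional[Sequence[tuple]] = None,
                    repeat_nt_db: Optional[Sequence[tuple]] = None,
                    config: Optional[MirnaConfig] = None):
    """Full pipeline; returns (passing candidates, per-family report)."""
    cfg = config or MirnaConfig()
    seq_by_id = {sid: s.upper() for sid, s in sequences}
    hits = find_mature_hits(sequences, mature_db, cfg)
    loci = pair_hits(hits, cfg)
    seen = set()
    candidates = []
    prot_searcher = (SimilaritySearcher(protein_db, "translated")
                     if protein_db else None)
    for locus in loci:
        seq = seq_by_id[locus.subject_seq_id]
        prec, iv, clipped = extract_precursor(seq, locus, cfg.flank)
        key = (locus.subject_seq_id, iv)
        if key in seen or len(prec) < cfg.min_fold_len:
            continue
        seen.add(key)
        structure, mfe = fold_hairpin(prec)
        cand = MirnaCandidate(
            precursor_seq=prec, source_seq_id=locus.subject_seq_id,
            interval=iv, mature_hit=locus.mature_hit,
            star_hit=locus.star_hit, family=locus.family, clipped=clipped,
            structure=structure, mfe=mfe, gc_pct=gc_percent(prec))
        if mfe < 0 and cand.gc_pct > 0:
            cand.amfe, cand.mfei = mfei(mfe, len(prec), cand.gc_pct)
        if validate_candidate(cand, cfg, protein_searcher=prot_searcher):
            candidates.append(cand)
    return annotate_candidates(candidates, known_precursor_db, repeat_nt_db,
                               cfg)
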