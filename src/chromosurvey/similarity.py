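"""Seeded local similarity search (nucleotide and translated).

The survey pipeline needs BLAST-like search over synthetic-scale data
without external binaries: a k-mer seeded, diagonal-clustered, banded
affine-gap extension aligner.  Externally produced 12-column hit tables can
be ingested through :mod:`chromosurvey.io_formats` so real-data runs remain
possible.

E-values use the Karlin-Altschul form E = m * n * 2**(-bits) with the
lambda/K constants of the default scoring systems folded into the bitscore
conversion.  The calibration is documentary, not fitted: the pipeline's
thresholds (1e-6, 1e-10, 1e-30) are coarse.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._kernels import banded_align, expand_ranges

# ---------------------------------------------------------------------------
# alphabets and encodings

_DNA_LUT = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _DNA_LUT[ord(_c)] = _i
    _DNA_LUT[ord(_c.lower())] = _i
_DNA_LUT[ord("U")] = 3
_DNA_LUT[ord("u")] = 3

_BLOSUM = substitution_matrices.load("BLOSUM62")
PROTEIN_ALPHABET = "".join(_BLOSUM.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
_PROT_X = PROTEIN_ALPHABET.index("X")
_PROT_LUT = np.full(256, _PROT_X, dtype=np.int8)
for _i, _c in enumerate(PROTEIN_ALPHABET):
    _PROT_LUT[ord(_c)] = _i
    _PROT_LUT[ord(_c.lower())] = _i

BLOSUM62 = np.array(_BLOSUM, dtype=np.int32)

# codon (base-5 packed DNA codes, N=4) -> protein code, for fast 6-frame
# translation without string round-trips
_CODON_LUT = np.full(125, _PROT_X, dtype=np.int8)
for _i0 in range(4):
    for _i1 in range(4):
        for _i2 in range(4):
            _codon = "ACGT"[_i0] + "ACGT"[_i1] + "ACGT"[_i2]
            _aa = str(Seq(_codon).translate())
            _CODON_LUT[_i0 * 25 + _i1 * 5 + _i2] = PROTEIN_ALPHABET.index(_aa)


def translate_codes(dna_codes: np.ndarray, frame: int) -> np.ndarray:
    """Protein codes of one reading frame of a DNA code array."""
    c = dna_codes[frame:]
    nc = c.shape[0] // 3
    c = c[: 3 * nc].astype(np.int64)
    vals = c[0::3] * 25 + c[1::3] * 5 + c[2::3]
    return _CODON_LUT[vals]


_COMP = str.maketrans("ACGTUacgtuNn", "TGCAAtgcaaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (U treated as T)."""
    return seq.translate(_COMP)[::-1]


def encode_dna(seq: str) -> np.ndarray:
    return _DNA_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_protein(seq: str) -> np.ndarray:
    return _PROT_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def dna_submatrix(match: int = 1, mismatch: int = -2) -> np.ndarray:
    m = np.full((5, 5), mismatch, dtype=np.int32)
    np.fill_diagonal(m, match)
    m[4, :] = mismatch
    m[:, 4] = mismatch
    return m


# Karlin-Altschul constants: (lambda, K) for the two default scoring systems.
_KA_NT = (1.28, 0.46)        # +1/-2 nucleotide scoring
_KA_PROT = (0.267, 0.041)    # BLOSUM62, gap 11/1


def bits_from_score(score: float, mode: str) -> float:
    lam, k = _KA_NT if mode == "nucleotide" else _KA_PROT
    return (lam * score - math.log(k)) / math.log(2.0)


def evalue_of(score_bits: float, query_len: int, subject_db_len: int) -> float:
    """Expectation value E = m * n * 2**(-bits)."""
    if query_len <= 0 or subject_db_len <= 0:
        raise ValueError("lengths must be positive")
    return query_len * subject_db_len * 2.0 ** (-score_bits)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Hit:
    """One local-similarity match.

    Intervals are 0-based half-open on the forward orientation of both
    sequences; ``strand`` records the query strand, ``frame`` the translated
    reading frame (0 in nucleotide mode).
    """

    query_id: str
    subject_id: str
    identity_pct: float
    similarity_pct: float
    evalue: float
    bitscore: float
    query_cov_pct: float
    subject_cov_pct: float
    strand: str
    frame: int
    query_interval: tuple
    subject_interval: tuple
    mismatches: int
    gap_opens: int = 0
    aln_len: int = 0
    score: int = 0
    query_len: int = 0
    subject_len: int = 0


@dataclass
class ThresholdProfile:
    """Filter bounds for hit lists; ``None`` disables a bound."""

    max_evalue: Optional[float] = None
    min_identity_pct: Optional[float] = None
    min_similarity_pct: Optional[float] = None
    min_query_cov_pct: Optional[float] = None
    min_subject_cov_pct: Optional[float] = None
    max_mismatches: Optional[int] = None
    mode: str = "nucleotide"

    def passes(self, h: Hit) -> bool:
        if self.max_evalue is not None and not (h.evalue <= self.max_evalue):
            return False
        if self.min_identity_pct is not None and h.identity_pct < self.min_identity_pct:
            return False
        if (self.mode == "translated" and self.min_similarity_pct is not None
                and h.similarity_pct < self.min_similarity_pct):
            return False
        if self.min_query_cov_pct is not None and h.query_cov_pct < self.min_query_cov_pct:
            return False
        if self.min_subject_cov_pct is not None and h.subject_cov_pct < self.min_subject_cov_pct:
            return False
        if self.max_mismatches is not None and h.mismatches > self.max_mismatches:
            return False
        return True


@dataclass
class SearchParams:
    """Seeding and scoring parameters.

    Defaults mirror common nucleotide megablast-era settings (+1/-2, gap
    5/2, word 11); translated mode uses BLOSUM62 with gap 11/1 and peptide
    word 4.  The source thresholds never state word sizes or gap penalties
    for the non-miRNA searches; these defaults are assumptions surfaced in
    the run configuration.
    """

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_ext: int = 2
    prot_word_size: int = 4
    prot_gap_open: int = 11
    prot_gap_ext: int = 1
    max_evalue: float = 10.0
    max_targets: int = 25
    max_hits_per_query: Optional[int] = None
    band_pad: int = 8
    diag_cluster_gap: int = 50
    max_diag_span: int = 96
    # clusters need >= 2 seed matches by default; single-seed candidates are
    # almost always noise at word size 11 (set to 1 for short queries)
    min_seed_count: int = 2
    # early termination: stop searching once a hit at least this good is
    # found (safe when the caller only thresholds on E-value)
    stop_evalue: Optional[float] = None


# ---------------------------------------------------------------------------
# k-mer index


class KmerIndex:
    """Sorted-array index of all k-mers of a subject set."""

    def __init__(self, codes_list: Sequence[np.ndarray], k: int, n_symbols: int,
                 max_code: Optional[int] = None):
        self.k = k
        self.n_symbols = n_symbols
        kmers = []
        subj = []
        pos = []
        self.powers = n_symbols ** np.arange(k - 1, -1, -1, dtype=np.int64)
        for idx, codes in enumerate(codes_list):
            if codes.shape[0] < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, k)
            vals = win.astype(np.int64) @ self.powers
            if max_code is not None:
                ok = (win < max_code).all(axis=1)
                vals = vals[ok]
                p = np.nonzero(ok)[0]
            else:
                p = np.arange(vals.shape[0])
            kmers.append(vals)
            subj.append(np.full(vals.shape[0], idx, dtype=np.int32))
            pos.append(p.astype(np.int32))
        if kmers:
            kv = np.concatenate(kmers)
            order = np.argsort(kv, kind="stable")
            self.kv = kv[order]
            self.subj = np.concatenate(subj)[order]
            self.pos = np.concatenate(pos)[order]
        else:
            self.kv = np.empty(0, dtype=np.int64)
            self.subj = np.empty(0, dtype=np.int32)
            self.pos = np.empty(0, dtype=np.int32)

    def query_kmers(self, codes: np.ndarray, max_code: Optional[int] = None):
        k = self.k
        if codes.shape[0] < k:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        vals = win.astype(np.int64) @ self.powers
        qpos = np.arange(vals.shape[0], dtype=np.int64)
        if max_code is not None:
            ok = (win < max_code).all(axis=1)
            vals = vals[ok]
            qpos = qpos[ok]
        return vals, qpos

    def seeds(self, codes: np.ndarray, max_code: Optional[int] = None):
        """Return (subject_idx, subject_pos, query_pos) arrays of seed matches."""
        vals, qpos = self.query_kmers(codes, max_code)
        if vals.size == 0 or self.kv.size == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e, e
        lo = np.searchsorted(self.kv, vals, side="left")
        hi = np.searchsorted(self.kv, vals, side="right")
        if int((hi - lo).sum()) == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e, e
        idx, src = expand_ranges(lo, hi)
        return (self.subj[idx].astype(np.int64),
                self.pos[idx].astype(np.int64), qpos[src])


def _cluster_candidates(subj: np.ndarray, diag: np.ndarray, gap: int,
                        min_count: int, max_targets: int,
                        max_span: int = 96):
    """Group seeds into (subject, diag_lo, diag_hi, count) candidate clusters.

    Clusters wider than ``max_span`` diagonals are trimmed to a window
    around their densest diagonal.
    """
    if subj.size == 0:
        return []
    order = np.lexsort((diag, subj))
    subj = subj[order]
    diag = diag[order]
    cands = []
    start = 0
    n = subj.size
    for i in range(1, n + 1):
        if i == n or subj[i] != subj[start] or diag[i] - diag[i - 1] > gap:
            cnt = i - start
            if cnt >= min_count:
                d_lo = int(diag[start])
                d_hi = int(diag[i - 1])
                if d_hi - d_lo > max_span:
                    med = int(np.median(diag[start:i]))
                    d_lo = max(d_lo, med - max_span // 2)
                    d_hi = min(d_hi, med + max_span // 2)
                cands.append((int(subj[start]), d_lo, d_hi, cnt))
            start = i
    cands.sort(key=lambda c: (-c[3], c[0], c[1]))
    return cands[: 3 * max_targets]


class SimilaritySearcher:
    """Reusable searcher over a fixed subject set.

    mode 'nucleotide': DNA queries vs DNA subjects, both strands.
    mode 'translated': DNA queries translated in all six frames vs protein
    subjects (blastx-like); identity/similarity measured on amino-acid
    columns, query coverage on nucleotides.
    """

    def __init__(self, subjects: Sequence[tuple], mode: str = "nucleotide",
                 params: Optional[SearchParams] = None):
        if mode not in ("nucleotide", "translated"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.params = params or SearchParams()
        self.subject_ids = [sid for sid, _ in subjects]
        self.subject_seqs = [s.upper() for _, s in subjects]
        if mode == "nucleotide":
            self.codes = [encode_dna(s) for s in self.subject_seqs]
            self.index = KmerIndex(self.codes, self.params.word_size, 5, max_code=4)
            self.submat = dna_submatrix(self.params.match, self.params.mismatch)
            self.gap_open = self.params.gap_open
            self.gap_ext = self.params.gap_ext
        else:
            bad = [sid for sid, s in zip(self.subject_ids, self.subject_seqs)
                   if set(s) <= set("ACGTUN") and len(s) > 20]
            if len(bad) == len(self.subject_ids) and bad:
                raise ValueError("translated mode requires protein subjects")
            self.codes = [encode_protein(s) for s in self.subject_seqs]
            self.index = KmerIndex(self.codes, self.params.prot_word_size,
                                   len(PROTEIN_ALPHABET))
            self.submat = BLOSUM62
            self.gap_open = self.params.prot_gap_open
            self.gap_ext = self.params.prot_gap_ext
        self.db_len = sum(len(s) for s in self.subject_seqs)
        if self.db_len == 0:
            raise ValueError("empty subject set")

    # -- helpers -----------------------------------------------------------
    def _align_candidates(self, qcodes, cands, qid, qlen, strand, frame,
                          unit, best_per_subject):
        p = self.params
        hits = best_per_subject
        satisfied = False
        for sidx, dlo, dhi, _cnt in cands:
            if satisfied:
                break
            scodes = self.codes[sidx]
            res = banded_align(qcodes, scodes, self.submat,
                               self.gap_open, self.gap_ext,
                               dlo - p.band_pad, dhi + p.band_pad)
            score = int(res[0])
            if score <= 0:
                continue
            bits = bits_from_score(score, "nucleotide" if unit == "nt" else "protein")
            ev = evalue_of(bits, qlen, self.db_len)
            if ev > p.max_evalue:
                continue
            qs, qe, ss, se = res[1], res[2], res[3], res[4]
            n_ident, n_pos, n_mis, n_gopen, n_gcols, aln_len = res[5:]
            if aln_len == 0:
                continue
            slen = len(self.subject_seqs[sidx])
            if unit == "nt":
                q_nt = (qs, qe)
            else:  # aa coords of the frame-translated query
                q_nt = (frame + 3 * qs, frame + 3 * qe)
            if strand == "-":
                q_nt = (qlen - q_nt[1], qlen - q_nt[0])
            hit = Hit(
                query_id=qid,
                subject_id=self.subject_ids[sidx],
                identity_pct=100.0 * n_ident / aln_len,
                similarity_pct=100.0 * n_pos / aln_len,
                evalue=ev,
                bitscore=bits,
                query_cov_pct=100.0 * (q_nt[1] - q_nt[0]) / qlen,
                subject_cov_pct=100.0 * (se - ss) / slen,
                strand=strand,
                frame=frame,
                query_interval=q_nt,
                subject_interval=(int(ss), int(se)),
                mismatches=int(n_mis),
                gap_opens=int(n_gopen),
                aln_len=int(aln_len),
                score=score,
                query_len=qlen,
                subject_len=slen,
            )
            key = (sidx, strand)
            prev = hits.get(key)
            if prev is None or hit.score > prev.score:
                hits[key] = hit
            if p.stop_evalue is not None and ev <= p.stop_evalue:
                satisfied = True
        return hits, satisfied

    def search_one(self, qid: str, seq: str) -> list:
        seq = seq.upper()
        p = self.params
        qlen = len(seq)
        best: dict = {}
        if self.mode == "nucleotide":
            if set(seq) - set("ACGTUN"):
                raise ValueError(f"query {qid}: not a nucleotide sequence")
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                qc = encode_dna(s)
                subj, spos, qpos = self.index.seeds(qc, max_code=4)
                cands = _cluster_candidates(subj, spos - qpos,
                                            p.diag_cluster_gap,
                                            p.min_seed_count, p.max_targets,
                                            p.max_diag_span)
                best, done = self._align_candidates(qc, cands, qid, qlen,
                                                    strand, 0, "nt", best)
                if done:
                    break
        else:
            done = False
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                dna = encode_dna(s)
                for frame in range(3):
                    qc = translate_codes(dna, frame)
                    subj, spos, qpos = self.index.seeds(qc)
                    cands = _cluster_candidates(subj, spos - qpos,
                                                p.diag_cluster_gap,
                                                p.min_seed_count,
                                                p.max_targets,
                                                p.max_diag_span)
                    best, done = self._align_candidates(qc, cands, qid, qlen,
                                                        strand, frame, "aa",
                                                        best)
                    if done:
                        break
                if done:
                    break
        hits = sorted(best.values(),
                      key=lambda h: (h.evalue, -h.bitscore, h.subject_id, h.strand))
        if p.max_hits_per_query is not None:
            hits = hits[: p.max_hits_per_query]
        return hits

    def search_many(self, queries: Iterable[tuple]) -> list:
        out = []
        for qid, seq in queries:
            out.extend(self.search_one(qid, seq))
        return out


def search(queries: Sequence[tuple], subjects: Sequence[tuple],
           mode: str = "nucleotide", params: Optional[SearchParams] = None) -> list:
    """Search every query against every subject; deterministic for fixed input."""
    if not queries or not subjects:
        raise ValueError("non-empty query and subject sets required")
    return SimilaritySearcher(subjects, mode, params).search_many(queries)


# ---------------------------------------------------------------------------
# hit-list operations


def filter_hits(hits: Sequence[Hit], profile: ThresholdProfile) -> list:
    """Hits satisfying every bound of the profile, input order preserved."""
    return [h for h in hits if profile.passes(h)]


def best_hit_per_query(hits: Sequence[Hit]) -> dict:
    """Per query the lowest-E hit; ties by higher bitscore, then subject id."""
    best: dict = {}
    for h in hits:
        prev = best.get(h.query_id)
        if prev is None:
            best[h.query_id] = h
            continue
        a = (h.evalue, -h.bitscore, h.subject_id)
        b = (prev.evalue, -prev.bitscore, prev.subject_id)
        if a < b:
            best[h.query_id] = h
    return best


def reciprocal_best_hits(hits_ab: Sequence[Hit], hits_ba: Sequence[Hit]) -> set:
    """(a, b) pairs where b is a's best hit and a is b's best hit."""
    best_ab = best_hit_per_query(hits_ab)
    best_ba = best_hit_per_query(hits_ba)
    out = set()
    for a, h in best_ab.items():
        b = h.subject_id
        back = best_ba.get(b)
        if back is not None and back.subject_id == a:
            out.add((a, b))
    return out
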