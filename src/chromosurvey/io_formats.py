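"""Readers/writers for the external formats the survey pipeline touches.

Conventions: in-memory coordinates are 0-based half-open; every serialized
coordinate (GFF3, 12-column hit tables) is 1-based closed.  FASTA output is
wrapped at 80 columns; readers accept any wrapping.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from .similarity import Hit

logger = logging.getLogger("chromosurvey")

FASTA_WRAP = 80


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    description: str = ""


@dataclass
class IntervalAnnotation:
    """A located feature; start/end are 0-based half-open internally."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    feature_type: str = "region"
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.start}..{self.end} on {self.seq_id}")


class FastaParseError(ValueError):
    pass


def read_fasta(path, dna: bool = False) -> Iterator[SequenceRecord]:
    """Stream records in file order, sequences uppercased.

    With ``dna=True`` U is mapped to T.  Malformed headers and empty
    sequences raise :class:`FastaParseError` naming the offending line.
    """
    seen = set()
    header = None
    header_line = 0
    chunks: List[str] = []

    def flush():
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"{path}: empty sequence for record at line {header_line}")
        sid, _, desc = header.partition(" ")
        if sid in seen:
            raise FastaParseError(
                f"{path}: duplicate id {sid!r} at line {header_line}")
        seen.add(sid)
        if dna:
            seq = seq.replace("U", "T")
        return SequenceRecord(sid, seq, desc)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise FastaParseError(f"{path}: empty header at line {lineno}")
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence before first header at line {lineno}")
                chunks.append(line.strip().upper())
    if header is not None:
        yield flush()


def write_fasta(records: Iterable, path) -> None:
    """Write (id, seq) pairs or SequenceRecords, wrapped at 80 columns."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, SequenceRecord):
                rid, seq, desc = rec.id, rec.sequence, rec.description
            else:
                rid, seq = rec
                desc = ""
            head = f">{rid} {desc}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i:i + FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# 12-column hit tables (outfmt-6 compatible)


def write_hits_table(hits: Iterable[Hit], path) -> None:
    """query, subject, %id, len, mism, gapopen, qstart, qend, sstart, send,
    evalue, bitscore — 1-based inclusive; subject coordinates reversed for
    minus-strand hits."""
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.query_interval
            ss, se = h.subject_interval
            if h.strand == "-":
                sstart, send = se, ss + 1
            else:
                sstart, send = ss + 1, se
            fh.write("\t".join([
                h.query_id, h.subject_id,
                f"{h.identity_pct:.2f}", str(h.aln_len), str(h.mismatches),
                str(h.gap_opens), str(qs + 1), str(qe),
                str(sstart), str(send),
                f"{h.evalue:.2e}", f"{h.bitscore:.1f}",
            ]) + "\n")


def read_hits_table(path) -> List[Hit]:
    """Parse a 12-column table back into Hits.

    Coverage percentages cannot be recovered from the 12 columns alone and
    are set to 0; callers ingesting external tables should re-derive them
    from the sequence lengths if a profile tests them.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(f)}")
            qs, qe = int(f[6]) - 1, int(f[7])
            ss, se = int(f[8]), int(f[9])
            if ss <= se:
                strand = "+"
                s_iv = (ss - 1, se)
            else:
                strand = "-"
                s_iv = (se - 1, ss)
            hits.append(Hit(
                query_id=f[0], subject_id=f[1],
                identity_pct=float(f[2]), similarity_pct=float(f[2]),
                evalue=float(f[10]), bitscore=float(f[11]),
                query_cov_pct=0.0, subject_cov_pct=0.0,
                strand=strand, frame=0,
                query_interval=(qs, qe), subject_interval=s_iv,
                mismatches=int(f[4]), gap_opens=int(f[5]),
                aln_len=int(f[3]),
            ))
    return hits


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(annotations: Iterable[IntervalAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = ";".join(f"{k}={v}" for k, v in a.attributes.items()) or "."
            fh.write("\t".join([
                a.seq_id, "chromosurvey", a.feature_type,
                str(a.start + 1), str(a.end), ".", a.strand, ".", attrs,
            ]) + "\n")


def read_gff3(path) -> List[IntervalAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = {}
            if f[8] != ".":
                for kv in f[8].split(";"):
                    if kv:
                        k, _, v = kv.partition("=")
                        attrs[k] = v
            out.append(IntervalAnnotation(
                seq_id=f[0], start=int(f[3]) - 1, end=int(f[4]),
                strand=f[6], feature_type=f[2], attributes=attrs))
    return out


# ---------------------------------------------------------------------------
# deletion-bin maps


def read_bin_map(path):
    """TSV (bin name, arm, fraction-start, fraction-end) -> BinMap."""
    from .zipper import Bin, BinMap

    bins = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, arm, fs, fe = line.split("\t")[:4]
            fs, fe = float(fs), float(fe)
            if not (0.0 <= fs < fe <= 1.0):
                raise ValueError(
                    f"{path}:{lineno}: invalid fraction interval {fs}..{fe}")
            bins.append(Bin(name=name, arm=arm, frac_start=fs, frac_end=fe))
    return BinMap(bins=bins)


# ---------------------------------------------------------------------------
# run config and stage logging


def load_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)


def log_stage(stage: str, n_in: int, n_out: int, **extra) -> None:
    """One structured line per pipeline stage for auditable ledgers."""
    kv = " ".join(f"{k}={v}" for k, v in extra.items())
    logger.info("stage=%s n_in=%d n_out=%d %s", stage, n_in, n_out, kv)
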