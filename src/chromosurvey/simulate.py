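"""Synthetic chromosome arms with planted truth.

Generates everything the survey pipeline consumes — chromosome arms packed
with transposable-element copies, genes and miRNA hairpins; 454-style
unoriented reads; a truth-guided pseudo-assembly with collapsed repeat
contigs; repeat/protein/EST/viral databases; a three-species reference trio
with planted ortholog structure and one inversion; unigenes and bin-mapped
EST markers — so that every downstream stage can be verified against the
planted truth without downloading anything.

Defaults state the world the analysis assumes: ~2.3x coverage of reads with
mean length 345 bp, ~75% TE content dominated by long (LTR-sized, often
nested) element copies, ~1% coding fraction with a mean coding sequence of
2,000 bp, 5.3% cross-arm contamination, and a reference trio at ~10%
nucleotide divergence per species pair with one planted inversion on the
long arm.  The hairpin count (30 per arm) is a scaled-up density chosen so
recovery statistics are meaningful on 5 Mb arms.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .repeats import ContigMembership
from .zipper import Bin, BinMap, RefGene

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# slight AT bias, as in wheat genomic DNA (~45% GC)
_BASE_P = np.array([0.275, 0.225, 0.225, 0.275])
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

_CODONS_OF = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_OF.setdefault(_aa, []).append(_codon)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def rand_dna(rng: np.random.Generator, n: int) -> str:
    return _decode(rng.choice(4, size=n, p=_BASE_P).astype(np.uint8))


def mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only divergence (coordinates preserved)."""
    if rate <= 0:
        return seq
    codes = _encode(seq)
    hit = rng.random(codes.size) < rate
    codes[hit] = (codes[hit] + rng.integers(1, 4, hit.sum())) % 4
    return _decode(codes)


def mutate_peptide(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _AA20[rng.integers(0, 20)]
    return "".join(out)


def rand_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(_AA20[i] for i in rng.integers(0, 20, n))


def encode_peptide_dna(pep: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS_OF[aa][rng.integers(0, len(_CODONS_OF[aa]))]
                   for aa in pep)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    seed: int = 1
    arm_len: Dict[str, int] = field(
        default_factory=lambda: {"S": 5_000_000, "L": 5_000_000})
    # repetitive landscape
    te_fraction: float = 0.75
    n_known_families: int = 26
    n_novel_families: int = 2
    n_unknown_families: int = 2
    te_len_range: tuple = (1_500, 12_000)
    te_max_divergence: float = 0.15
    te_nested_prob: float = 0.3
    # genes
    gene_count: Optional[int] = None      # default: 1% coding at 2 kb CDS
    cds_len_mean: float = 2_000.0
    cds_len_sd: float = 600.0
    cds_len_min: int = 300
    single_exon_prob: float = 0.5
    max_exons: int = 3
    intron_len_range: tuple = (80, 250)
    # miRNA hairpins
    n_hairpins: int = 30
    n_mirna_families: int = 16
    mature_len: int = 21
    hairpin_loop_range: tuple = (8, 25)
    star_max_mutations: int = 2
    # reads
    coverage: float = 2.3
    read_len_mean: float = 345.0
    read_len_sd: float = 60.0
    read_len_min: int = 50
    sub_rate: float = 0.002
    homopolymer_indel_rate: float = 0.001
    contamination: float = 0.053
    # pseudo-assembly
    collapse_q: float = 0.9
    min_overlap: int = 40
    # reference trio
    div_ref: float = 0.10
    div_AB: float = 0.10
    div_AC: float = 0.10
    retention_B: float = 0.85
    retention_C: float = 0.80
    syn_chrom_prob: float = 0.9
    n_extra_ref_genes: Optional[int] = None
    inversion_arm: Optional[str] = "L"
    inversion_frac: tuple = (0.55, 0.85)
    # expression / markers
    expressed_fraction: float = 0.8
    n_homeologs: int = 3
    homeolog_divergence: float = 0.025
    est_divergence: float = 0.015
    protein_divergence: float = 0.05
    marker_fraction: float = 0.6
    marker_len_range: tuple = (350, 600)
    n_viral_proteins: int = 5

    def genes_per_arm(self, arm: str) -> int:
        if self.gene_count is not None:
            return self.gene_count
        return max(2, round(0.01 * self.arm_len[arm] / self.cds_len_mean))


def default_bins(arm: str) -> List[Bin]:
    """Deletion-bin layout mirroring a wheat 5A-style physical map."""
    if arm == "S":
        layout = [("C-5AS1-0.40", 0.0, 0.40), ("5AS1-0.40-0.75", 0.40, 0.75),
                ("5AS3-0.75-0.98", 0.75, 0.98)]
    else:
        layout = [("C-5AL10-0.57", 0.0, 0.57), ("5AL12-0.35-0.57", 0.35, 0.57),
                ("5AL10-0.57-0.78", 0.57, 0.78), ("5AL17-0.78-0.87", 0.78, 0.87),
                ("5AL23-0.87-1.00", 0.87, 1.0)]
    return [Bin(name=n, arm=arm, frac_start=a, frac_end=b) for n, a, b in layout]


# ---------------------------------------------------------------------------
# planted truth containers


@dataclass
class TEFamily:
    name: str
    kind: str                 # known | novel | unknown
    consensus: str
    orf_peptide: str


@dataclass
class GeneModel:
    gene_id: str
    arm_id: str
    start: int
    end: int
    strand: str
    exons: List[tuple]        # absolute, 0-based half-open, ascending
    transcript: str           # spliced, transcript orientation

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class Hairpin:
    hairpin_id: str
    arm_id: str
    interval: tuple           # precursor truth interval (incl. 13 nt flanks)
    mature_id: str
    mature_interval: tuple
    star_interval: tuple


@dataclass
class ArmTruth:
    arm_id: str
    arm_len: int
    seq: str
    te_intervals: List[tuple]           # (start, end, family, kind)
    genes: List[GeneModel]
    hairpins: List[Hairpin]
    base_class: np.ndarray              # 0 bg,1 TE,4 exon,5 intron,6 hairpin
    base_family: np.ndarray             # family index or -1

    def gene_order(self) -> List[str]:
        return [g.gene_id for g in sorted(self.genes, key=lambda g: g.start)]


@dataclass
class ReadOrigin:
    origin_arm: str
    start: int
    end: int
    strand: str
    true_class: str           # repeat | gene | other


@dataclass
class Assembly:
    contigs: List[tuple]
    memberships: List[ContigMembership]
    contig_origins: Dict[str, Optional[tuple]]
    singleton_ids: List[str]

    def contig_seqs(self) -> Dict[str, str]:
        return dict(self.contigs)


@dataclass
class TrioData:
    genesA: List[RefGene]
    genesB: Dict[str, RefGene]
    genesC: Dict[str, RefGene]
    a_of_arm_gene: Dict[str, str]       # arm gene id -> A gene id
    arm_order: List[str]                # arm gene ids by arm position
    inversion_gene_ids: List[str]
    syn_chrom_B: str = "chrB_syn"
    syn_chrom_C: str = "chrC_syn"


@dataclass
class World:
    config: SimulationConfig
    te_families: List[TEFamily]
    arms: Dict[str, ArmTruth]
    reads: Dict[str, List[tuple]]
    origins: Dict[str, Dict[str, ReadOrigin]]
    assemblies: Dict[str, Assembly]
    repeat_nt_db: List[tuple]
    repeat_prot_db: List[tuple]
    viral_db: List[tuple]
    protein_db: List[tuple]
    domain_tags: Dict[str, set]
    est_db: List[tuple]
    mature_db: List[tuple]
    known_precursor_db: List[tuple]
    trios: Dict[str, TrioData]
    unigenes: Dict[str, List[tuple]]
    markers: Dict[str, List[tuple]]
    bin_maps: Dict[str, BinMap]
    marker_gene: Dict[str, Dict[str, str]]


# ---------------------------------------------------------------------------
# building blocks


def make_te_families(cfg: SimulationConfig, rng: np.random.Generator
                     ) -> List[TEFamily]:
    fams = []
    kinds = (["known"] * cfg.n_known_families +
             ["novel"] * cfg.n_novel_families +
             ["unknown"] * cfg.n_unknown_families)
    lo, hi = cfg.te_len_range
    for i, kind in enumerate(kinds):
        length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        pep = rand_peptide(rng, 280)
        orf = encode_peptide_dna(pep, rng)
        pos = rng.integers(0, max(1, length - len(orf))) if length > len(orf) else 0
        body = rand_dna(rng, max(length, len(orf) + 10))
        consensus = body[:pos] + orf + body[pos + len(orf):]
        fams.append(TEFamily(name=f"fam{i:02d}", kind=kind,
                             consensus=consensus, orf_peptide=pep))
    return fams


def _make_gene(cfg: SimulationConfig, rng: np.random.Generator,
               gene_id: str, arm_id: str):
    """Returns (genomic_seq, exon_offsets, strand, transcript)."""
    n_codons = max(cfg.cds_len_min // 3,
                   int(round(rng.normal(cfg.cds_len_mean, cfg.cds_len_sd) / 3)))
    pep = rand_peptide(rng, n_codons)
    cds = encode_peptide_dna(pep, rng)
    if rng.random() < cfg.single_exon_prob:
        n_exons = 1
    else:
        n_exons = int(rng.integers(2, cfg.max_exons + 1))
    cuts = sorted(rng.choice(np.arange(150, len(cds) - 150), size=n_exons - 1,
                             replace=False)) if n_exons > 1 else []
    pieces = np.split(np.frombuffer(cds.encode(), dtype=np.uint8),
                      [int(c) for c in cuts])
    exon_seqs = [p.tobytes().decode() for p in pieces]
    parts = []
    exon_offsets = []
    cursor = 0
    for k, es in enumerate(exon_seqs):
        parts.append(es)
        exon_offsets.append((cursor, cursor + len(es)))
        cursor += len(es)
        if k < len(exon_seqs) - 1:
            ilen = int(rng.integers(*cfg.intron_len_range))
            intron = "GT" + rand_dna(rng, ilen - 4) + "AG"
            parts.append(intron)
            cursor += ilen
    genomic = "".join(parts)
    strand = "+" if rng.random() < 0.5 else "-"
    transcript = cds
    if strand == "-":
        genomic = revcomp(genomic)
        L = len(genomic)
        exon_offsets = [(L - b, L - a) for a, b in reversed(exon_offsets)]
    return genomic, exon_offsets, strand, transcript, pep


def make_mirna_db(cfg: SimulationConfig, rng: np.random.Generator):
    """(mature_db, matures_by_family)"""
    mature_db = []
    fams: Dict[str, list] = {}
    for i in range(cfg.n_mirna_families):
        fam_num = 1000 + i
        base = rand_dna(rng, cfg.mature_len)
        n_members = int(rng.integers(1, 4))
        for j in range(n_members):
            seq = base if j == 0 else mutate_dna(base, 0.07, rng)
            mid = f"tae-miR{fam_num}{'abcdefg'[j]}"
            mature_db.append((mid, seq))
            fams.setdefault(f"miR{fam_num}", []).append((mid, seq))
    return mature_db, fams


def _make_hairpin(cfg: SimulationConfig, rng: np.random.Generator,
                  mature_id: str, mature_seq: str):
    """Hairpin segment: [13 nt][mature][loop][star][13 nt]."""
    loop = rand_dna(rng, int(rng.integers(*cfg.hairpin_loop_range)))
    k = int(rng.integers(0, cfg.star_max_mutations + 1))
    star = mutate_dna(revcomp(mature_seq), 0.0, rng)
    if k:
        codes = _encode(star)
        idx = rng.choice(codes.size, size=k, replace=False)
        codes[idx] = (codes[idx] + rng.integers(1, 4, k)) % 4
        star = _decode(codes)
    flank5 = rand_dna(rng, 13)
    flank3 = rand_dna(rng, 13)
    seg = flank5 + mature_seq + loop + star + flank3
    m_iv = (13, 13 + len(mature_seq))
    s_iv = (13 + len(mature_seq) + len(loop),
            13 + len(mature_seq) + len(loop) + len(star))
    return seg, m_iv, s_iv


# ---------------------------------------------------------------------------
# arm simulation


def simulate_arm(cfg: SimulationConfig, rng: np.random.Generator,
                 arm_id: str, te_families: List[TEFamily],
                 mature_pool: Sequence[tuple]) -> ArmTruth:
    """Assemble an arm left-to-right from TE copies, genes, hairpins and
    background, meeting the configured TE fraction within sampling noise."""
    arm_len = cfg.arm_len[arm_id]
    fam_weights = rng.dirichlet(np.ones(len(te_families)) * 0.6)

    items = []  # (kind, payload, length)
    te_target = cfg.te_fraction * arm_len
    te_total = 0
    while te_total < te_target:
        fi = int(rng.choice(len(te_families), p=fam_weights))
        fam = te_families[fi]
        copy = mutate_dna(fam.consensus,
                          rng.uniform(0.0, cfg.te_max_divergence), rng)
        nested = None
        if rng.random() < cfg.te_nested_prob:
            fj = int(rng.choice(len(te_families), p=fam_weights))
            inner = mutate_dna(te_families[fj].consensus,
                               rng.uniform(0.0, cfg.te_max_divergence), rng)
            at = int(rng.integers(50, len(copy) - 50))
            copy = copy[:at] + inner + copy[at:]
            nested = (fj, at, at + len(inner))
        items.append(("te", (fi, copy, nested), len(copy)))
        te_total += len(copy)

    genes_payload = []
    for gi in range(cfg.genes_per_arm(arm_id)):
        gid = f"{arm_id}g{gi:03d}"
        genomic, exoff, strand, transcript, pep = _make_gene(cfg, rng, gid,
                                                             arm_id)
        genes_payload.append((gid, genomic, exoff, strand, transcript, pep))
        items.append(("gene", genes_payload[-1], len(genomic)))

    hp_payload = []
    for hi in range(cfg.n_hairpins):
        mid, mseq = mature_pool[int(rng.integers(0, len(mature_pool)))]
        seg, m_iv, s_iv = _make_hairpin(cfg, rng, mid, mseq)
        hp_payload.append((f"{arm_id}hp{hi:02d}", mid, seg, m_iv, s_iv))
        items.append(("hairpin", hp_payload[-1], len(seg)))

    planted = sum(L for _, _, L in items)
    bg_total = arm_len - planted
    if bg_total < len(items) + 1:
        raise ValueError("infeasible packing: planted features exceed arm length")
    order = rng.permutation(len(items))
    n_slots = len(items) + 1
    bg_lens = rng.multinomial(bg_total, np.ones(n_slots) / n_slots)

    parts = []
    te_intervals = []
    genes: List[GeneModel] = []
    hairpins: List[Hairpin] = []
    base_class = np.zeros(arm_len + 20_000, dtype=np.uint8)
    base_family = np.full(arm_len + 20_000, -1, dtype=np.int16)
    cursor = 0

    def put_bg(n):
        nonlocal cursor
        parts.append(rand_dna(rng, int(n)))
        cursor += int(n)

    put_bg(bg_lens[0])
    for slot, oi in enumerate(order):
        kind, payload, L = items[oi]
        if kind == "te":
            fi, copy, nested = payload
            fam = te_families[fi]
            te_intervals.append((cursor, cursor + L, fam.name, fam.kind))
            base_class[cursor:cursor + L] = 1
            base_family[cursor:cursor + L] = fi
            if nested is not None:
                fj, a, b = nested
                base_family[cursor + a:cursor + b] = fj
                te_intervals.append((cursor + a, cursor + b,
                                     te_families[fj].name,
                                     te_families[fj].kind))
            parts.append(copy)
        elif kind == "gene":
            gid, genomic, exoff, strand, transcript, pep = payload
            exons = [(cursor + a, cursor + b) for a, b in exoff]
            genes.append(GeneModel(gene_id=gid, arm_id=arm_id, start=cursor,
                                   end=cursor + L, strand=strand,
                                   exons=exons, transcript=transcript))
            base_class[cursor:cursor + L] = 5
            for a, b in exons:
                base_class[a:b] = 4
            parts.append(genomic)
        else:
            hid, mid, seg, m_iv, s_iv = payload
            hairpins.append(Hairpin(
                hairpin_id=hid, arm_id=arm_id,
                interval=(cursor, cursor + L), mature_id=mid,
                mature_interval=(cursor + m_iv[0], cursor + m_iv[1]),
                star_interval=(cursor + s_iv[0], cursor + s_iv[1])))
            base_class[cursor:cursor + L] = 6
            parts.append(seg)
        cursor += L
        put_bg(bg_lens[slot + 1])

    seq = "".join(parts)
    return ArmTruth(arm_id=arm_id, arm_len=len(seq), seq=seq,
                    te_intervals=te_intervals, genes=genes,
                    hairpins=hairpins,
                    base_class=base_class[:len(seq)],
                    base_family=base_family[:len(seq)])


# ---------------------------------------------------------------------------
# reads


REPEAT_TRUTH_MIN_OVERLAP = 50   # bp; the pipeline's minimal-match window


def _true_class(truth: ArmTruth, start: int, end: int) -> str:
    """Read-level planted class under cascade semantics.

    A read is repeat-true when it contains at least a minimal alignable
    stretch (50 bp) of planted repeat — the same operational notion the
    read ledger uses, where any repeat match claims the read; gene-true
    when (otherwise) it is majority-exonic.
    """
    seg = truth.base_class[start:end]
    n = seg.size
    te = int((seg == 1).sum())
    exon = int((seg == 4).sum())
    if te >= min(REPEAT_TRUTH_MIN_OVERLAP, n):
        return "repeat"
    if exon * 2 >= n:
        return "gene"
    return "other"


def shred_reads(cfg: SimulationConfig, rng: np.random.Generator,
                arm_id: str, truths: Mapping[str, ArmTruth]):
    """454-style shotgun of one sorted-arm sample.

    Lengths are truncated-normal (mean 345, sd 60, min 50); strands are
    random; substitution and homopolymer-indel errors are applied; a
    configured fraction of reads comes from the sibling arm (sorting
    contamination).  Returns (reads, origins).
    """
    truth = truths[arm_id]
    sibling_id = next(a for a in truths if a != arm_id) \
        if len(truths) > 1 else arm_id
    target = cfg.coverage * truth.arm_len
    arm_codes = {a: _encode(t.seq) for a, t in truths.items()}
    reads = []
    origins: Dict[str, ReadOrigin] = {}
    total = 0
    i = 0
    while total < target:
        oarm = sibling_id if rng.random() < cfg.contamination else arm_id
        t = truths[oarm]
        L = int(max(cfg.read_len_min,
                    round(rng.normal(cfg.read_len_mean, cfg.read_len_sd))))
        start = int(rng.integers(0, max(1, t.arm_len - L)))
        end = min(t.arm_len, start + L)
        codes = arm_codes[oarm][start:end].copy()
        # substitutions
        hit = rng.random(codes.size) < cfg.sub_rate
        if hit.any():
            codes[hit] = (codes[hit] + rng.integers(1, 4, int(hit.sum()))) % 4
        # homopolymer indels
        if cfg.homopolymer_indel_rate > 0 and codes.size > 1:
            homo = np.nonzero(codes[:-1] == codes[1:])[0]
            homo = homo[rng.random(homo.size) < cfg.homopolymer_indel_rate]
            if homo.size:
                out = []
                prev = 0
                for p in homo:
                    out.append(codes[prev:p + 1])
                    if rng.random() < 0.5:
                        out.append(codes[p:p + 1])    # duplication
                    else:
                        out[-1] = out[-1][:-1]        # deletion
                    prev = p + 1
                out.append(codes[prev:])
                codes = np.concatenate(out)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            codes = (3 - codes)[::-1]
        rid = f"{arm_id}_r{i:06d}"
        reads.append((rid, _decode(codes)))
        origins[rid] = ReadOrigin(origin_arm=oarm, start=start, end=end,
                                  strand=strand,
                                  true_class=_true_class(t, start, end))
        total += codes.size
        i += 1
    return reads, origins


# ---------------------------------------------------------------------------
# pseudo-assembly


def pseudo_assemble(cfg: SimulationConfig, rng: np.random.Generator,
                    arm_id: str, reads: Sequence[tuple],
                    origins: Mapping[str, ReadOrigin],
                    truths: Mapping[str, ArmTruth],
                    te_families: List[TEFamily]) -> Assembly:
    """Truth-guided stand-in for a de novo assembler.

    Reads dominated by one TE family collapse into a single family contig
    with probability ``collapse_q`` (producing the high-coverage collapsed
    contigs the (n*r)/c statistic must detect); remaining reads merge
    positionally when they overlap by >= min_overlap on their arm of
    origin; unmerged reads stay singletons.
    """
    read_len = {rid: len(s) for rid, s in reads}
    collapsed: Dict[int, list] = {}
    positional: Dict[str, list] = {a: [] for a in truths}
    for rid, _seq in reads:
        o = origins[rid]
        fam_seg = truths[o.origin_arm].base_family[o.start:o.end]
        fam_ids, counts = np.unique(fam_seg[fam_seg >= 0], return_counts=True)
        dominant = None
        if fam_ids.size:
            top = int(np.argmax(counts))
            if counts[top] >= 0.6 * (o.end - o.start):
                dominant = int(fam_ids[top])
        if dominant is not None and rng.random() < cfg.collapse_q:
            collapsed.setdefault(dominant, []).append(rid)
        else:
            positional[o.origin_arm].append((o.start, o.end, rid))

    contigs = []
    memberships = []
    contig_origins: Dict[str, Optional[tuple]] = {}
    singletons: List[str] = []
    ci = 0
    for fi in sorted(collapsed):
        members = collapsed[fi]
        if len(members) < 2:
            singletons.extend(members)
            continue
        cid = f"{arm_id}_cfam{fi:02d}"
        cons = te_families[fi].consensus
        contigs.append((cid, cons))
        avg = sum(read_len[r] for r in members) / len(members)
        memberships.append(ContigMembership(
            contig_id=cid, member_read_ids=list(members),
            consensus_len=len(cons), avg_read_len=avg))
        contig_origins[cid] = None
        ci += 1
    for oarm in sorted(positional):
        runs = []
        for start, end, rid in sorted(positional[oarm]):
            if runs and start <= runs[-1][1] - cfg.min_overlap:
                runs[-1][1] = max(runs[-1][1], end)
                runs[-1][2].append(rid)
            else:
                runs.append([start, end, [rid]])
        for start, end, members in runs:
            if len(members) == 1:
                singletons.append(members[0])
                continue
            cid = f"{arm_id}_c{ci:05d}"
            cons = truths[oarm].seq[start:end]
            contigs.append((cid, cons))
            avg = sum(read_len[r] for r in members) / len(members)
            memberships.append(ContigMembership(
                contig_id=cid, member_read_ids=members,
                consensus_len=len(cons), avg_read_len=avg))
            contig_origins[cid] = (oarm, start, end)
            ci += 1
    return Assembly(contigs=contigs, memberships=memberships,
                    contig_origins=contig_origins, singleton_ids=singletons)


# ---------------------------------------------------------------------------
# reference trio


def simulate_reference_trio(cfg: SimulationConfig, rng: np.random.Generator,
                            truth: ArmTruth,
                            invert: bool = False) -> TrioData:
    """Species A/B/C gene sets with planted ortholog and order structure.

    Species A carries a diverged copy of every planted arm gene (plus extra
    A-only genes) in collinear order; with ``invert`` the configured
    fraction interval of the arm appears reversed in A — emulating an
    inversion between the surveyed chromosome and the reference.  B and C
    genes derive from A under the configured retention and divergence, on a
    syntenic or decoy chromosome.
    """
    arm_genes = sorted(truth.genes, key=lambda g: g.start)
    order = list(range(len(arm_genes)))
    inv_ids: List[str] = []
    if invert:
        f1, f2 = cfg.inversion_frac
        lo = f1 * truth.arm_len
        hi = f2 * truth.arm_len
        seg = [i for i in order if lo <= arm_genes[i].start < hi]
        if seg:
            first, last = order.index(seg[0]), order.index(seg[-1])
            order[first:last + 1] = order[first:last + 1][::-1]
            inv_ids = [arm_genes[i].gene_id for i in seg]

    n_extra = (cfg.n_extra_ref_genes if cfg.n_extra_ref_genes is not None
               else len(arm_genes))
    entries = []  # (sort key, a_gene_id, nt, arm_gene_id or None)
    for rank, i in enumerate(order):
        g = arm_genes[i]
        nt = mutate_dna(g.transcript, cfg.div_ref, rng)
        entries.append((rank + 0.0, f"A_{g.gene_id}", nt, g.gene_id))
    for j in range(n_extra):
        at = rng.uniform(0, len(order))
        nt = rand_dna(rng, int(rng.integers(900, 2200)))
        entries.append((at, f"A_extra{truth.arm_id}{j:03d}", nt, None))
    entries.sort(key=lambda e: e[0])

    genesA = []
    genesB: Dict[str, RefGene] = {}
    genesC: Dict[str, RefGene] = {}
    a_of_arm = {}
    for rank, (_, aid, nt, arm_gid) in enumerate(entries):
        genesA.append(RefGene(species="A", gene_id=aid, chromosome="chrA",
                              position=20_000 * rank + 10_000, nucleotide=nt))
        if arm_gid is not None:
            a_of_arm[arm_gid] = aid
        if rng.random() < cfg.retention_B:
            chrom = "chrB_syn" if rng.random() < cfg.syn_chrom_prob \
                else "chrB_dec"
            bid = aid.replace("A_", "B_", 1)
            genesB[bid] = RefGene(species="B", gene_id=bid, chromosome=chrom,
                                  position=15_000 * rank + 5_000,
                                  nucleotide=mutate_dna(nt, cfg.div_AB, rng))
        if rng.random() < cfg.retention_C:
            chrom = "chrC_syn" if rng.random() < cfg.syn_chrom_prob \
                else "chrC_dec"
            cid = aid.replace("A_", "C_", 1)
            genesC[cid] = RefGene(species="C", gene_id=cid, chromosome=chrom,
                                  position=18_000 * rank + 9_000,
                                  nucleotide=mutate_dna(nt, cfg.div_AC, rng))
    return TrioData(genesA=genesA, genesB=genesB, genesC=genesC,
                    a_of_arm_gene=a_of_arm,
                    arm_order=[g.gene_id for g in arm_genes],
                    inversion_gene_ids=inv_ids)


# ---------------------------------------------------------------------------
# unigenes and markers


def simulate_unigenes_and_markers(cfg: SimulationConfig,
                                  rng: np.random.Generator,
                                  truth: ArmTruth):
    """Spliced transcripts (with a few homeolog variants) and bin-mapped
    EST markers derived from the planted genes."""
    genes = sorted(truth.genes, key=lambda g: g.start)
    n_expr = max(1, int(round(cfg.expressed_fraction * len(genes))))
    expr_idx = sorted(rng.choice(len(genes), size=n_expr, replace=False))
    unigenes = []
    for i in expr_idx:
        g = genes[i]
        unigenes.append((f"ug_{g.gene_id}", g.transcript))
    hom_pool = [i for i in expr_idx]
    n_hom = min(cfg.n_homeologs, len(hom_pool))
    for i in rng.choice(hom_pool, size=n_hom, replace=False):
        g = genes[int(i)]
        unigenes.append((f"ug_{g.gene_id}_hom",
                         mutate_dna(g.transcript, cfg.homeolog_divergence,
                                    rng)))
    bin_map = BinMap(bins=default_bins(truth.arm_id))
    markers = []
    marker_gene = {}
    n_mark = max(1, int(round(cfg.marker_fraction * len(genes))))
    for i in sorted(rng.choice(len(genes), size=n_mark, replace=False)):
        g = genes[int(i)]
        frac = g.start / truth.arm_len
        if bin_map.bin_of(truth.arm_id, frac) is None:
            continue
        mlen = int(rng.integers(*cfg.marker_len_range))
        if len(g.transcript) <= mlen:
            frag = g.transcript
        else:
            at = int(rng.integers(0, len(g.transcript) - mlen))
            frag = g.transcript[at:at + mlen]
        mid = f"mk_{g.gene_id}"
        markers.append((mid, frag))
        marker_gene[mid] = g.gene_id
        bin_map.assign_marker(mid, truth.arm_id, frac)
    return unigenes, markers, bin_map, marker_gene


# ---------------------------------------------------------------------------
# databases


def make_databases(cfg: SimulationConfig, rng: np.random.Generator,
                   te_families: List[TEFamily],
                   arms: Mapping[str, ArmTruth]):
    repeat_nt_db = [(f.name, f.consensus) for f in te_families
                    if f.kind == "known"]
    repeat_prot_db = [(f"{f.name}_orf", f.orf_peptide) for f in te_families
                      if f.kind in ("known", "novel")]
    viral_db = [(f"virus{i}", rand_peptide(rng, 300))
                for i in range(cfg.n_viral_proteins)]
    protein_db = []
    domain_tags: Dict[str, set] = {}
    est_db = []
    for arm in arms.values():
        for g in arm.genes:
            pep = str(Seq(g.transcript).translate())
            protein_db.append((f"prot_{g.gene_id}",
                               mutate_peptide(pep, cfg.protein_divergence,
                                              rng)))
            est_db.append((f"est_{g.gene_id}",
                           mutate_dna(g.transcript, cfg.est_divergence, rng)))
    # TE-domain proteins present in the protein database, Pfam-tagged
    for f in te_families[:5]:
        pid = f"prot_te_{f.name}"
        protein_db.append((pid, f.orf_peptide))
        domain_tags[pid] = {"PF00078"}
    return repeat_nt_db, repeat_prot_db, viral_db, protein_db, domain_tags, \
        est_db


# ---------------------------------------------------------------------------
# orchestrator


def simulate_survey(cfg: Optional[SimulationConfig] = None) -> World:
    """Generate the full two-arm survey world with planted truth."""
    cfg = cfg or SimulationConfig()
    root = np.random.SeedSequence(cfg.seed)
    keys = ("families", "mirna", "armS", "armL", "readsS", "readsL",
            "asmS", "asmL", "trioS", "trioL", "ugS", "ugL", "dbs")
    rngs = {k: np.random.default_rng(s)
            for k, s in zip(keys, root.spawn(len(keys)))}

    te_families = make_te_families(cfg, rngs["families"])
    mature_db, _fams = make_mirna_db(cfg, rngs["mirna"])

    arms = {}
    for arm_id in cfg.arm_len:
        arms[arm_id] = simulate_arm(cfg, rngs[f"arm{arm_id}"], arm_id,
                                    te_families, mature_db)

    reads = {}
    origins = {}
    assemblies = {}
    for arm_id in arms:
        reads[arm_id], origins[arm_id] = shred_reads(
            cfg, rngs[f"reads{arm_id}"], arm_id, arms)
        assemblies[arm_id] = pseudo_assemble(
            cfg, rngs[f"asm{arm_id}"], arm_id, reads[arm_id],
            origins[arm_id], arms, te_families)

    trios = {}
    unigenes = {}
    markers = {}
    bin_maps = {}
    marker_gene = {}
    for arm_id in arms:
        invert = (cfg.inversion_arm == arm_id)
        trios[arm_id] = simulate_reference_trio(cfg, rngs[f"trio{arm_id}"],
                                                arms[arm_id], invert=invert)
        (unigenes[arm_id], markers[arm_id], bin_maps[arm_id],
         marker_gene[arm_id]) = simulate_unigenes_and_markers(
            cfg, rngs[f"ug{arm_id}"], arms[arm_id])

    (repeat_nt_db, repeat_prot_db, viral_db, protein_db, domain_tags,
     est_db) = make_databases(cfg, rngs["dbs"], te_families, arms)

    known_prec = []
    rng = rngs["dbs"]
    for arm in arms.values():
        for hp in arm.hairpins[::2]:
            s, e = hp.interval
            known_prec.append((f"known_{hp.hairpin_id}",
                               mutate_dna(arm.seq[s:e], 0.15, rng)))

    return World(config=cfg, te_families=te_families, arms=arms, reads=reads,
                 origins=origins, assemblies=assemblies,
                 repeat_nt_db=repeat_nt_db, repeat_prot_db=repeat_prot_db,
                 viral_db=viral_db, protein_db=protein_db,
                 domain_tags=domain_tags, est_db=est_db,
                 mature_db=mature_db, known_precursor_db=known_prec,
                 trios=trios, unigenes=unigenes, markers=markers,
                 bin_maps=bin_maps, marker_gene=marker_gene)
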