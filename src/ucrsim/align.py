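"""Read placement and pileups.

Two placement routes feed the same downstream statistics:

* :func:`oracle_place` — simulated reads carry their true origin, so their
  alignment is known exactly: the operation list falls out of the read's
  target-space allele array.  This replaces a long-read mapper for simulated
  data and keeps every statistic joinable to ground truth.
* :func:`seed_extend_map` — a deliberately simple gapless seed-and-extend
  mapper standing in for a short-read aligner.  A read is mapped iff its best
  end-to-end gapless placement has a mismatch rate at or below 2%, anchored to
  the observation that the vast majority of mapped short reads show <= 2%
  mismatches.  This reproduces the mechanism that matters here — error-dense
  assembly regions lose short-read coverage — without reimplementing bwa.

Real alignments (SAM) can be ingested for analysis-only mode; CIGAR
M/=/X/I/D/S are mapped onto the internal representation.

An alignment is stored as a target-space allele array (one emitted base per
consumed target position, 4 = deletion) plus attached insertions, exactly like
a simulated read; the run-length operation list is derived on demand.  A
pileup accumulates those arrays into per-position allele counts with a
deletion pseudo-allele and per-position attached-insertion length, following
the samtools-mpileup convention of attaching an insertion to the preceding
consumed position.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pysam

from .genome import GAP, N, BASES, PolyploidGenome, encode
from .reads import SimRead

MATCH = "match"
MISMATCH = "mismatch"
INSERTION = "insertion"
DELETION = "deletion"


@dataclass
class AlignmentRecord:
    """Placement of a query on a target.

    ``alleles[i]`` is the query base at target position ``start + i`` (4 =
    deletion); ``insertions`` maps relative junctions to inserted base-code
    arrays.  ``ops`` (a method) renders the conventional run-length operation
    list against a target sequence.
    """

    query_id: str
    target: str
    start: int
    strand: str
    alleles: np.ndarray
    insertions: dict[int, np.ndarray] = field(default_factory=dict)
    is_primary: bool = True
    n_mismatch: int = -1  # filled by the mapper; -1 = not scored

    @property
    def end(self) -> int:
        return self.start + len(self.alleles)

    @property
    def span(self) -> int:
        return len(self.alleles)

    @property
    def aligned_query_bases(self) -> int:
        return int((self.alleles != GAP).sum()) + sum(len(v) for v in self.insertions.values())

    def ops(self, target_seq: np.ndarray) -> list[tuple[str, int, str]]:
        """Ordered (op, length, bases) list vs ``target_seq``.

        Query-consuming ops carry their emitted bases; deletions carry ''.
        Sum of query-consuming lengths equals the query length, sum of
        target-consuming lengths equals the target span.
        """
        ref = target_seq[self.start:self.end]
        kinds = np.where(self.alleles == GAP, 3,
                         np.where(self.alleles == ref, 1, 2))  # 1=M,2=X,3=D
        out: list[tuple[str, int, str]] = []
        names = {1: MATCH, 2: MISMATCH, 3: DELETION}
        i = 0
        n = len(kinds)
        while i < n:
            if i in self.insertions:
                bases = self.insertions[i]
                out.append((INSERTION, len(bases), BASES[bases].tobytes().decode()))
            j = i
            while j < n and kinds[j] == kinds[i] and (j == i or (j not in self.insertions)):
                j += 1
            kind = int(kinds[i])
            seg = self.alleles[i:j]
            bases = "" if kind == 3 else BASES[seg].tobytes().decode()
            out.append((names[kind], j - i, bases))
            i = j
        if n in self.insertions:
            bases = self.insertions[n]
            out.append((INSERTION, len(bases), BASES[bases].tobytes().decode()))
        return out


def oracle_place(read: SimRead, targets: dict[str, np.ndarray]) -> AlignmentRecord:
    """Place a simulated read at its true origin on the matching target.

    The target must share the read's origin coordinate system — either the
    subgenome it was simulated from or a coordinate-preserving assembly of it.
    """
    if read.subgenome not in targets:
        raise KeyError(f"read origin {read.subgenome!r} not among targets")
    tseq = targets[read.subgenome]
    if read.end > len(tseq):
        raise ValueError("read origin extends past target end")
    return AlignmentRecord(
        query_id=read.id, target=read.subgenome, start=read.start,
        strand=read.strand, alleles=read.alleles,
        insertions={j: np.array([b], dtype=np.uint8) for j, b in read.insertions.items()},
        is_primary=True,
    )


def oracle_place_all(reads: list[SimRead], targets: dict[str, np.ndarray]) -> list[AlignmentRecord]:
    return [oracle_place(r, targets) for r in reads]


# -- seed-and-extend short-read mapper ---------------------------------------

class KmerIndex:
    """Exact k-mer index over one or more target sequences.

    K-mers containing non-ACGT codes are excluded.  Lookups return (target
    index, position) pairs for every exact occurrence.
    """

    def __init__(self, targets: dict[str, np.ndarray], k: int = 21):
        if k < 4 or k > 31:
            raise ValueError("k must be in [4, 31]")
        self.k = k
        self.names = list(targets)
        self.seqs = [targets[n] for n in self.names]
        kmers, tids, poss = [], [], []
        for t, seq in enumerate(self.seqs):
            v, valid = _kmer_codes(seq, k)
            kmers.append(v[valid])
            poss.append(np.nonzero(valid)[0])
            tids.append(np.full(int(valid.sum()), t, dtype=np.int32))
        allk = np.concatenate(kmers) if kmers else np.empty(0, dtype=np.int64)
        order = np.argsort(allk, kind="stable")
        self._kmers = allk[order]
        self._tid = np.concatenate(tids)[order] if tids else np.empty(0, dtype=np.int32)
        self._pos = np.concatenate(poss)[order] if poss else np.empty(0, dtype=np.int64)

    def lookup(self, kmer_vals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """For an array of query k-mer values return (query offsets, target ids, positions)."""
        lo = np.searchsorted(self._kmers, kmer_vals, side="left")
        hi = np.searchsorted(self._kmers, kmer_vals, side="right")
        counts = hi - lo
        qoff = np.repeat(np.arange(len(kmer_vals)), counts)
        idx = _ranges_concat(lo, hi)
        return qoff, self._tid[idx], self._pos[idx]


def _ranges_concat(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out = np.ones(total, dtype=np.int64)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    nz = counts > 0
    out[starts[nz]] = lo[nz]
    prev_end = (lo + counts - 1)[nz][:-1]
    out[starts[nz][1:]] = lo[nz][1:] - prev_end
    return np.cumsum(out)


def _kmer_codes(seq: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(k-mer integer per start position, validity mask)."""
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    x = seq.astype(np.int64)
    v = np.zeros(n, dtype=np.int64)
    for i in range(k):
        v = (v << 2) | (x[i:i + n] & 3)
    bad = (seq > 3).astype(np.int64)
    cb = np.concatenate(([0], np.cumsum(bad)))
    valid = (cb[k:] - cb[:-k]) == 0
    return v, valid


def seed_extend_map(
    query: np.ndarray | SimRead,
    index: KmerIndex,
    max_mismatch_rate: float = 0.02,
    keep_secondary: bool = False,
    tie_break: str = "lowest",
) -> list[AlignmentRecord]:
    """Map one read end-to-end gapless via exact k-mer seeds.

    Every query k-mer is looked up; each hit proposes a diagonal (a candidate
    end-to-end placement).  The placement with the fewest mismatches wins and
    the read is mapped iff mismatches / length <= ``max_mismatch_rate``.
    Equal-scoring placements are tie-broken per ``tie_break``: ``"lowest"``
    deterministically picks the lowest (target, coordinate); ``"hash"``
    spreads multireads over their equal-best placements by a stable hash of
    the read id, the way a practical aligner distributes repeats — without it,
    every read from a conserved block would pile onto one homoeologous copy
    and the other copy would look uncovered.  Returns [] when unmapped; with
    ``keep_secondary`` the other equal-scoring placements are returned as
    secondary records.
    """
    if isinstance(query, SimRead):
        qid = query.id
        q = query.forward_sequence_codes()
    else:
        qid, q = "query", query
    k = index.k
    if len(q) < k:
        return []
    qk, qvalid = _kmer_codes(q, k)
    qoffs = np.nonzero(qvalid)[0]
    qo, tids, poss = index.lookup(qk[qoffs])
    if len(tids) == 0:
        return []
    starts = poss - qoffs[qo]
    cand = np.unique(np.stack([tids.astype(np.int64), starts], axis=1), axis=0)
    best: list[tuple[int, int, int]] = []  # (mm, tid, start)
    for t, s in cand:
        t, s = int(t), int(s)
        tseq = index.seqs[t]
        if s < 0 or s + len(q) > len(tseq):
            continue
        w = tseq[s:s + len(q)]
        # N is an ambiguity code: it neither matches nor counts as mismatch
        mm = int(np.count_nonzero((w != q) & (w != N)))
        best.append((mm, t, s))
    if not best:
        return []
    best.sort()
    mm0 = best[0][0]
    if mm0 / len(q) > max_mismatch_rate:
        return []
    ties = [b for b in best if b[0] == mm0]
    if tie_break == "hash" and len(ties) > 1:
        pick = ties[zlib.crc32(qid.encode()) % len(ties)]
    elif tie_break in ("lowest", "hash"):
        pick = ties[0]
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    _, t0, s0 = pick
    records = [AlignmentRecord(
        query_id=qid, target=index.names[t0], start=s0, strand="+",
        alleles=q.copy(), is_primary=True, n_mismatch=mm0)]
    if keep_secondary:
        for mm, t, s in ties:
            if (t, s) == (t0, s0):
                continue
            records.append(AlignmentRecord(
                query_id=qid, target=index.names[t], start=s, strand="+",
                alleles=q.copy(), is_primary=False, n_mismatch=mm))
    return records


def map_reads(
    reads: list[SimRead],
    index: KmerIndex,
    max_mismatch_rate: float = 0.02,
    tie_break: str = "lowest",
) -> list[AlignmentRecord]:
    """Map a read set; unmapped reads are dropped (unmapped is a valid outcome)."""
    out: list[AlignmentRecord] = []
    for r in reads:
        recs = seed_extend_map(r, index, max_mismatch_rate, tie_break=tie_break)
        if recs:
            out.append(recs[0])
    return out


def filter_primary(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep primary records only (the samtools -F 0x900 equivalent). Idempotent."""
    return [r for r in records if r.is_primary]


# -- pileup -------------------------------------------------------------------

@dataclass
class PileupColumn:
    target: str
    position: int
    ref_base: str
    depth: int
    allele_counts: dict[str, int]
    insertion_length_total: int


@dataclass
class Pileup:
    """Per-position allele counts over one target.

    ``counts[p, a]`` counts reads presenting allele ``a`` (0..3 bases, 4 =
    deletion pseudo-allele) at position ``p``; ``depth = counts.sum(axis=1)``
    is the number of reads whose target-consuming ops span ``p``.
    ``ins_len[p]`` is the total inserted length attached to ``p``.
    """

    target: str
    ref: np.ndarray
    counts: np.ndarray
    ins_len: np.ndarray

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def columns(self) -> Iterator[PileupColumn]:
        depth = self.depth
        alphabet = "ACGT-"
        for p in np.nonzero(depth > 0)[0]:
            cnt = {alphabet[a]: int(self.counts[p, a])
                   for a in range(5) if self.counts[p, a] > 0}
            yield PileupColumn(
                target=self.target, position=int(p),
                ref_base=chr(BASES[self.ref[p]]), depth=int(depth[p]),
                allele_counts=cnt, insertion_length_total=int(self.ins_len[p]),
            )

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd
        rows = [(c.target, c.position, c.ref_base, c.depth,
                 ";".join(f"{a}:{n}" for a, n in sorted(c.allele_counts.items())),
                 c.insertion_length_total) for c in self.columns()]
        pd.DataFrame(rows, columns=["target", "pos", "ref", "depth", "alleles",
                                    "ins_len"]).to_csv(path, sep="\t", index=False)


def build_pileup(records: list[AlignmentRecord], target: str,
                 target_seq: np.ndarray) -> Pileup:
    """Accumulate records on one target into a pileup.

    Deletions contribute the deletion pseudo-allele at each deleted position;
    insertions accrue to the preceding consumed position's
    ``insertion_length_total``.
    """
    L = len(target_seq)
    counts = np.zeros((L, 5), dtype=np.int32)
    flat = counts.reshape(-1)
    ins_len = np.zeros(L, dtype=np.int64)
    for rec in records:
        if rec.target != target:
            continue
        if rec.end > L:
            raise ValueError(f"record {rec.query_id} extends past target end")
        idx = (np.arange(rec.start, rec.end, dtype=np.int64) * 5
               + rec.alleles.astype(np.int64))
        flat[idx] += 1  # indices unique within a record: one allele per position
        for j, bases in rec.insertions.items():
            p = rec.start + j - 1  # attach to preceding consumed position
            if 0 <= p < L:
                ins_len[p] += len(bases)
    return Pileup(target=target, ref=target_seq, counts=counts, ins_len=ins_len)


def write_sam(records: list[AlignmentRecord], targets: dict[str, np.ndarray],
              path: str | Path) -> None:
    """Write records as coordinate-sorted SAM (match/mismatch collapsed to M)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": n, "LN": len(s)} for n, s in targets.items()]}
    order = {n: i for i, n in enumerate(targets)}
    recs = sorted(records, key=lambda r: (order[r.target], r.start))
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in recs:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.query_id
            a.reference_name = r.target
            a.reference_start = r.start
            a.mapping_quality = 60
            flag = 0
            if r.strand == "-":
                flag |= 0x10
            if not r.is_primary:
                flag |= 0x100
            a.flag = flag
            cigar = []
            seq_parts = []
            for op, ln, bases in r.ops(targets[r.target]):
                if op in (MATCH, MISMATCH):
                    code = 0
                    seq_parts.append(bases)
                elif op == INSERTION:
                    code = 1
                    seq_parts.append(bases)
                else:
                    code = 2
                if cigar and cigar[-1][0] == code:
                    cigar[-1] = (code, cigar[-1][1] + ln)
                else:
                    cigar.append((code, ln))
            a.cigartuples = cigar
            a.query_sequence = "".join(seq_parts)
            fh.write(a)


# -- SAM ingestion (real-data / analysis-only mode) ---------------------------

def read_sam(path: str | Path, targets: dict[str, np.ndarray],
             keep_secondary: bool = True) -> list[AlignmentRecord]:
    """Convert a SAM/BAM file into alignment records.

    CIGAR M/=/X consume both query and target (M is resolved against the
    reference sequence, so mismatches are exact when the FASTA is supplied);
    I attaches to the current junction; D emits deletion pseudo-alleles; S/H
    are clipped.  Records with the 0x900 bits set are marked non-primary.
    """
    out: list[AlignmentRecord] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            tname = aln.reference_name
            if tname not in targets:
                raise KeyError(f"SAM reference {tname!r} absent from FASTA")
            q = encode(aln.query_sequence)
            alleles: list[np.ndarray] = []
            insertions: dict[int, np.ndarray] = {}
            qi = 0
            rel = 0
            for op, ln in aln.cigartuples:
                if op in (0, 7, 8):  # M / = / X
                    alleles.append(q[qi:qi + ln])
                    qi += ln
                    rel += ln
                elif op == 1:  # I
                    insertions[rel] = q[qi:qi + ln].copy()
                    qi += ln
                elif op == 2:  # D
                    alleles.append(np.full(ln, GAP, dtype=np.uint8))
                    rel += ln
                elif op == 4:  # S
                    qi += ln
                elif op in (3, 5, 6):  # N / H / P: target skip or no-op
                    if op == 3:
                        alleles.append(np.full(ln, GAP, dtype=np.uint8))
                        rel += ln
                else:
                    raise ValueError(f"unsupported CIGAR op {op}")
            rec = AlignmentRecord(
                query_id=aln.query_name, target=tname,
                start=int(aln.reference_start),
                strand="-" if aln.is_reverse else "+",
                alleles=np.concatenate(alleles) if alleles else np.empty(0, np.uint8),
                insertions=insertions,
                is_primary=not (aln.flag & 0x900),
            )
            if rec.is_primary or keep_secondary:
                out.append(rec)
    return out
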