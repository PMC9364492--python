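"""Read simulation with per-base error ledgers.

Three read classes are modeled after the platforms the assembly-quality
analysis contrasts: noisy long reads (ONT-like, ~17.5% mismatch and ~7.5% gap
against an accurate reference), accurate long reads (CCS/HiFi-like, ~0.2%
error), and accurate short reads (NGS-like, 150 bp, ~0.2% error).

Every simulated read keeps complete ground truth: its origin interval on a
subgenome, the haplotype drawn at each heterozygous site it covers, and an
error ledger listing every injected mismatch, insertion and deletion.  The
ledger is invertible — removing its edits from the read sequence reproduces
the haplotype-resolved origin substring exactly — which is what later makes
removed/retained/introduced error accounting after self-correction exact
rather than estimated.

Internally a read is stored in *target space*: one allele code per covered
reference position (4 = deleted) plus a junction->base map of length-1
insertions.  Indels are length-1 events; the gap rate of a profile is the
total inserted+deleted length per emitted base.  Strand is drawn but sequences
are kept in target-forward orientation internally; FASTQ output is
reverse-complemented for '-' reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GAP, BASES, PolyploidGenome, decode, encode

_COMP = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)  # A<->T, C<->G

MISMATCH = "mismatch"
INSERTION = "insertion"
DELETION = "deletion"


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base error rates applied independently along a read."""

    mismatch_rate: float
    insertion_rate: float
    deletion_rate: float

    def __post_init__(self):
        for r in (self.mismatch_rate, self.insertion_rate, self.deletion_rate):
            if not (0.0 <= r <= 0.3):
                raise ValueError(f"error rates must be in [0, 0.3], got {r}")
        if self.mismatch_rate + self.insertion_rate + self.deletion_rate >= 0.5:
            raise ValueError("total error rate must be < 0.5")

    @property
    def gap_rate(self) -> float:
        return self.insertion_rate + self.deletion_rate


# The noisy long-read preset: 17.5% mismatches and 7.5% gaps, the gap total
# split evenly between insertions and deletions.
ONT_PROFILE = ErrorProfile(0.175, 0.0375, 0.0375)
CCS_ERROR_RATE = 0.002
CCS_READ_LEN = 12_000
NGS_ERROR_RATE = 0.002
NGS_READ_LEN = 150
ERROR_FREE = ErrorProfile(0.0, 0.0, 0.0)


@dataclass
class SimRead:
    """A simulated read with full ground truth.

    ``alleles[i]`` is the base emitted at reference position ``start + i``
    (4 = deleted); ``insertions`` maps a relative junction ``j`` (between
    positions ``start+j-1`` and ``start+j``) to the inserted base code.
    ``truth`` is the haplotype-resolved origin substring.
    """

    id: str
    subgenome: str
    start: int
    end: int
    strand: str
    alleles: np.ndarray
    truth: np.ndarray
    insertions: dict[int, int] = field(default_factory=dict)
    het_pos: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    het_choice: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint8))

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad read interval [{self.start}, {self.end})")

    @property
    def span(self) -> int:
        return self.end - self.start

    # -- emitted-sequence geometry -------------------------------------------
    def _offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """(emit offset of each target position's base, kept mask)."""
        kept = self.alleles != GAP
        n = self.span
        ins_arr = np.zeros(n + 1, dtype=np.int64)
        for j in self.insertions:
            ins_arr[j] = 1
        # base i is preceded by all kept bases < i and all insertions at junctions <= i
        kept_before = np.concatenate(([0], np.cumsum(kept)))[:-1]
        ins_upto = np.cumsum(ins_arr)[:-1]  # insertions at junctions <= i
        base_off = kept_before + ins_upto
        return base_off, kept

    def forward_sequence_codes(self) -> np.ndarray:
        """Emitted read bases in target-forward orientation."""
        base_off, kept = self._offsets()
        n_out = int(kept.sum()) + len(self.insertions)
        out = np.empty(n_out, dtype=np.uint8)
        out[base_off[kept]] = self.alleles[kept]
        if self.insertions:
            kept_before = np.concatenate(([0], np.cumsum(kept)))
            ins_sorted = sorted(self.insertions.items())
            ins_count = 0
            for j, b in ins_sorted:
                out[int(kept_before[j]) + ins_count] = b
                ins_count += 1
        return out

    @property
    def forward_sequence(self) -> str:
        return decode(self.forward_sequence_codes())

    @property
    def sequence(self) -> str:
        """Emitted sequence in sequencing orientation (reverse-complemented for '-')."""
        codes = self.forward_sequence_codes()
        if self.strand == "-":
            codes = _COMP[codes[::-1]]
        return decode(codes)

    def __len__(self) -> int:
        return int((self.alleles != GAP).sum()) + len(self.insertions)

    # -- ledger ---------------------------------------------------------------
    def error_ledger(self) -> list[tuple[int, str, str, str]]:
        """(read offset, type, true base(s), emitted base(s)) in forward orientation.

        Offsets index the forward emitted sequence; a deletion's offset is
        where the deleted base would have appeared.  Entries are ordered along
        the read (an insertion at a junction precedes the base that follows it).
        """
        base_off, kept = self._offsets()
        kept_before = np.concatenate(([0], np.cumsum(kept)))
        ins_sorted = sorted(self.insertions.items())
        ins_junc = np.array([j for j, _ in ins_sorted], dtype=np.int64)
        entries: list[tuple[int, int, str, str, str]] = []  # (sortkey, off, type, true, emitted)
        mism = np.nonzero(kept & (self.alleles != self.truth))[0]
        for i in mism:
            entries.append((2 * int(i) + 1, int(base_off[i]), MISMATCH,
                            chr(BASES[self.truth[i]]), chr(BASES[self.alleles[i]])))
        dele = np.nonzero(~kept)[0]
        for i in dele:
            # offset where the deleted base would sit: kept bases before i plus
            # insertions at junctions <= i
            off = int(kept_before[i]) + int(np.searchsorted(ins_junc, i, side="right"))
            entries.append((2 * int(i) + 1, off, DELETION, chr(BASES[self.truth[i]]), ""))
        ins_count = 0
        for j, b in ins_sorted:
            off = int(kept_before[j]) + ins_count
            entries.append((2 * int(j), off, INSERTION, "", chr(BASES[b])))
            ins_count += 1
        entries.sort(key=lambda e: e[0])
        return [(off, typ, tr, em) for _, off, typ, tr, em in entries]

    def n_errors(self) -> tuple[int, int, int]:
        """(mismatches, insertions, deletions) without building the ledger."""
        kept = self.alleles != GAP
        mm = int((kept & (self.alleles != self.truth)).sum())
        return mm, len(self.insertions), int((~kept).sum())


def reconstruct_origin(sequence: str, ledger: list[tuple[int, str, str, str]]) -> str:
    """Undo every ledger edit on a forward-orientation read sequence.

    Operates on the ledger alone (no access to simulator internals), so it
    serves as the independent check that the ledger is a complete and exact
    record of the injected errors.
    """
    s = list(sequence)
    for off, typ, true, emitted in reversed(ledger):
        if typ == MISMATCH:
            assert s[off] == emitted
            s[off] = true
        elif typ == INSERTION:
            assert s[off] == emitted
            del s[off]
        elif typ == DELETION:
            s.insert(off, true)
        else:  # pragma: no cover
            raise ValueError(f"unknown ledger op {typ}")
    return "".join(s)


# -- simulation ---------------------------------------------------------------

def _draw_length(rng: np.random.Generator, mean: int, minimum: int, cap: int) -> int:
    """Truncated geometric-like length with the stated mean and minimum."""
    if mean <= minimum:
        return min(mean, cap)
    length = minimum + rng.geometric(1.0 / (mean - minimum + 1)) - 1
    return int(min(length, cap))


def _make_read(
    rng: np.random.Generator,
    genome: PolyploidGenome,
    name: str,
    start: int,
    end: int,
    profile: ErrorProfile,
    read_id: str,
    het_lookup: dict[str, tuple[np.ndarray, np.ndarray]],
) -> SimRead:
    seq = genome.subgenomes[name]
    truth = seq[start:end].copy()
    hpos, halt = het_lookup[name]
    lo, hi = np.searchsorted(hpos, (start, end))
    cov_pos = hpos[lo:hi]
    cov_alt = halt[lo:hi]
    take_alt = rng.random(len(cov_pos)) < 0.5
    truth[cov_pos[take_alt] - start] = cov_alt[take_alt]
    choice = truth[cov_pos - start].copy()

    n = end - start
    alleles = truth.copy()
    insertions: dict[int, int] = {}
    if profile.mismatch_rate or profile.deletion_rate:
        u = rng.random(n)
        mm = u < profile.mismatch_rate
        de = (~mm) & (u < profile.mismatch_rate + profile.deletion_rate)
        idx = np.nonzero(mm)[0]
        alleles[idx] = (truth[idx] + rng.integers(1, 4, size=len(idx), dtype=np.uint8)) % 4
        alleles[de] = GAP
    if profile.insertion_rate:
        ji = np.nonzero(rng.random(n) < profile.insertion_rate)[0] + 1
        ins_bases = rng.integers(0, 4, size=len(ji), dtype=np.uint8)
        insertions = {int(j): int(b) for j, b in zip(ji, ins_bases)}
    strand = "+" if rng.random() < 0.5 else "-"
    return SimRead(
        id=read_id, subgenome=name, start=start, end=end, strand=strand,
        alleles=alleles, truth=truth, insertions=insertions,
        het_pos=cov_pos.astype(np.int64), het_choice=choice.astype(np.uint8),
    )


def simulate_long_reads(
    genome: PolyploidGenome,
    depth: float,
    length_dist: tuple[int, int] = (10_000, 1_000),
    profile: ErrorProfile = ONT_PROFILE,
    seed: int = 0,
    id_prefix: str = "ont",
) -> list[SimRead]:
    """Simulate long reads to ``depth``-fold coverage of the whole genome.

    Reads are drawn uniformly from both subgenomes until the total emitted
    bases reach ``depth x total genome length``; lengths follow a truncated
    geometric distribution with the stated (mean, minimum).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    mean_len, min_len = length_dist
    if mean_len < 1_000:
        raise ValueError("mean read length must be >= 1 kb for long reads")
    if genome.total_length == 0:
        raise ValueError("empty genome")
    rng = np.random.default_rng(seed)
    het_lookup = {name: (genome.het_alleles(name)[0], genome.het_alleles(name)[2])
                  for name in genome.names}
    target_bases = depth * genome.total_length
    reads: list[SimRead] = []
    total = 0
    i = 0
    names = genome.names
    while total < target_bases:
        name = names[rng.integers(len(names))]
        L = len(genome.subgenomes[name])
        length = _draw_length(rng, mean_len, min_len, L)
        start = int(rng.integers(0, L - length + 1))
        read = _make_read(rng, genome, name, start, start + length, profile,
                          f"{id_prefix}_{i:06d}", het_lookup)
        reads.append(read)
        total += len(read)
        i += 1
    return reads


def simulate_accurate_reads(
    genome: PolyploidGenome,
    depth: float,
    read_len: int = NGS_READ_LEN,
    error_rate: float = NGS_ERROR_RATE,
    paired: bool = False,
    seed: int = 0,
    id_prefix: str = "acc",
) -> list[SimRead]:
    """Simulate fixed-length accurate reads (CCS-like or NGS-like presets).

    Errors are substitutions at ``error_rate`` per base; reads are single-end
    (``paired`` is accepted for interface parity and must be False).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if paired:
        raise ValueError("paired-end reads are not modeled; reads are single-end")
    min_sub = min(len(s) for s in genome.subgenomes.values())
    if read_len > min_sub:
        raise ValueError(
            f"read_len {read_len} exceeds shortest subgenome length {min_sub}")
    rng = np.random.default_rng(seed)
    profile = ErrorProfile(error_rate, 0.0, 0.0)
    het_lookup = {name: (genome.het_alleles(name)[0], genome.het_alleles(name)[2])
                  for name in genome.names}
    n_reads = int(np.ceil(depth * genome.total_length / read_len))
    names = genome.names
    subs = rng.integers(len(names), size=n_reads)
    reads: list[SimRead] = []
    for i in range(n_reads):
        name = names[subs[i]]
        L = len(genome.subgenomes[name])
        start = int(rng.integers(0, L - read_len + 1))
        reads.append(_make_read(rng, genome, name, start, start + read_len, profile,
                                f"{id_prefix}_{i:06d}", het_lookup))
    return reads


def error_ledger_summary(reads: list[SimRead]) -> tuple[float, float, float]:
    """(mismatch, insertion, deletion) fractions over total emitted bases."""
    mm = ins = de = emitted = 0
    for r in reads:
        m, i, d = r.n_errors()
        mm += m
        ins += i
        de += d
        emitted += len(r)
    if emitted == 0:
        return (0.0, 0.0, 0.0)
    return (mm / emitted, ins / emitted, de / emitted)


# -- external interfaces ------------------------------------------------------

def write_fastq(reads: list[SimRead], path: str | Path, quality_char: str = "I") -> None:
    """FASTQ with constant placeholder quality; '-' reads are written RC."""
    with open(path, "w") as fh:
        for r in reads:
            seq = r.sequence
            fh.write(f"@{r.id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_origins_tsv(reads: list[SimRead], path: str | Path) -> None:
    pd.DataFrame({
        "id": [r.id for r in reads],
        "subgenome": [r.subgenome for r in reads],
        "start": [r.start for r in reads],
        "end": [r.end for r in reads],
        "strand": [r.strand for r in reads],
    }).to_csv(path, sep="\t", index=False)


def write_ledger_tsv(reads: list[SimRead], path: str | Path) -> None:
    rows = []
    for r in reads:
        for off, typ, true, emitted in r.error_ledger():
            rows.append((r.id, off, typ, true, emitted))
    pd.DataFrame(rows, columns=["id", "offset", "type", "true", "emitted"]).to_csv(
        path, sep="\t", index=False)


def save_reads(reads: list[SimRead], outdir: str | Path, prefix: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fastq(reads, outdir / f"{prefix}.fastq")
    write_origins_tsv(reads, outdir / f"{prefix}.origins.tsv")
    write_ledger_tsv(reads, outdir / f"{prefix}.ledger.tsv")


def load_reads(outdir: str | Path, prefix: str, genome: PolyploidGenome) -> list[SimRead]:
    """Rebuild SimReads from the FASTQ + origins + ledger triple."""
    outdir = Path(outdir)
    origins = pd.read_csv(outdir / f"{prefix}.origins.tsv", sep="\t")
    ledger = pd.read_csv(outdir / f"{prefix}.ledger.tsv", sep="\t",
                         keep_default_na=False, dtype={"true": str, "emitted": str})
    by_id: dict[str, list] = {}
    for row in ledger.itertuples(index=False):
        by_id.setdefault(row.id, []).append((row.offset, row.type, row.true, row.emitted))
    seqs: dict[str, str] = {}
    with open(outdir / f"{prefix}.fastq") as fh:
        lines = fh.read().splitlines()
    for i in range(0, len(lines), 4):
        seqs[lines[i][1:]] = lines[i + 1]
    reads = []
    for row in origins.itertuples(index=False):
        seq = seqs[row.id]
        if row.strand == "-":
            seq = decode(_COMP[encode(seq)[::-1]])
        led = by_id.get(row.id, [])
        reads.append(_read_from_ledger(row, seq, led, genome))
    return reads


def _read_from_ledger(row, forward_seq: str, ledger, genome: PolyploidGenome) -> SimRead:
    truth = encode(reconstruct_origin(forward_seq, ledger))
    n = row.end - row.start
    assert len(truth) == n, "ledger inconsistent with origin span"
    alleles = truth.copy()
    insertions: dict[int, int] = {}
    ins_before = de_before = 0
    for off, typ, true, emitted in ledger:
        if typ == MISMATCH:
            i = off - ins_before + de_before
            alleles[i] = encode(emitted)[0]
        elif typ == DELETION:
            i = off - ins_before + de_before
            alleles[i] = GAP
            de_before += 1
        else:  # insertion
            j = off - ins_before + de_before
            insertions[int(j)] = int(encode(emitted)[0])
            ins_before += 1
    hpos, _, halt = genome.het_alleles(row.subgenome)
    lo, hi = np.searchsorted(hpos, (row.start, row.end))
    cov = hpos[lo:hi]
    return SimRead(
        id=row.id, subgenome=row.subgenome, start=int(row.start), end=int(row.end),
        strand=row.strand, alleles=alleles, truth=truth, insertions=insertions,
        het_pos=cov.astype(np.int64), het_choice=truth[cov - row.start].copy(),
    )
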