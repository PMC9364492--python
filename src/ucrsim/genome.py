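"""Synthetic allopolyploid genomes with ground-truth site classes.

An allotetraploid carries two diverged subgenomes (A and B) that descend from
hybridization followed by whole-genome duplication.  Locally their sequences
alternate between *conserved* blocks (identical between subgenomes) and
*divergent* blocks, where fixed substitution differences accumulate at a few
percent per base.  On top of the between-subgenome divergence each subgenome
carries ordinary within-individual heterozygosity.

The generator here builds such genomes with substitution-only divergence on a
deterministic alternating block grid, and keeps an exhaustive truth table of
every non-trivial site — conserved positions are implicit, every divergent or
heterozygous position is recorded with its alleles.  Downstream modules use the
truth table as the oracle for error accounting.

Coordinates are 0-based, half-open throughout.  Because divergence is
substitution-only, position ``p`` on subgenome A is homologous to position
``p`` on subgenome B; this 1:1 projection is what makes cross-subgenome read
clustering exact and auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# -- base-code constants ------------------------------------------------------
# Sequence codes 0..3 = A,C,G,T; 5 = N (assemblies only).  Allele code 4 is the
# deletion pseudo-allele used by pileups/alignments, never by genome sequences.
A, C, G, T = 0, 1, 2, 3
GAP = 4
N = 5

BASES = np.frombuffer(b"ACGT-N", dtype=np.uint8)
_DECODE = {i: ch for i, ch in enumerate("ACGT-N")}
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate("ACGT-N"):
    _ENCODE[ord(_ch)] = _i
    _ENCODE[ord(_ch.lower())] = _i

DEFAULT_SEED = 42

CONSERVED = "conserved"
DIVERGENT = "divergent"
HETEROZYGOUS = "heterozygous"


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string to uint8 codes (0..3, 5=N)."""
    arr = _ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = chr(np.frombuffer(seq.encode(), dtype=np.uint8)[arr == 255][0])
        raise ValueError(f"non-ACGTN character in sequence: {bad!r}")
    return arr.copy()


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to an ACGT-N string."""
    return BASES[codes].tobytes().decode()


@dataclass
class PolyploidGenome:
    """Two (or one, for the diploid control) subgenomes plus full ground truth.

    Attributes
    ----------
    subgenomes : dict mapping subgenome name to uint8 code array.
    block_map : list of ``(start, end, cls)`` with cls in {conserved, divergent};
        the same grid applies to every subgenome (homologous coordinates).
    divergent_sites : positions where the subgenomes carry different fixed
        alleles (empty for a single-subgenome genome).
    het_sites : per-subgenome table of heterozygous positions with the two
        alleles; reads later draw one of the pair with probability 1/2.
    params : generation parameters (lengths, rates, seeds) for the manifest.
    """

    subgenomes: dict[str, np.ndarray]
    block_map: list[tuple[int, int, str]]
    divergent_sites: np.ndarray  # sorted positions, shared coordinate system
    het_sites: dict[str, pd.DataFrame]  # columns: pos, ref, alt (codes)
    params: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.subgenomes)

    @property
    def length(self) -> int:
        return len(next(iter(self.subgenomes.values())))

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.subgenomes.values())

    def divergent_blocks(self) -> list[tuple[int, int]]:
        return [(s, e) for s, e, c in self.block_map if c == DIVERGENT]

    def conserved_blocks(self) -> list[tuple[int, int]]:
        return [(s, e) for s, e, c in self.block_map if c == CONSERVED]

    def divergent_mask(self) -> np.ndarray:
        """Boolean mask over positions, True at subgenome-divergent sites."""
        m = np.zeros(self.length, dtype=bool)
        m[self.divergent_sites] = True
        return m

    def het_alleles(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(positions, ref codes, alt codes) of heterozygous sites on a subgenome."""
        df = self.het_sites[name]
        return (
            df["pos"].to_numpy(dtype=np.int64),
            df["ref"].to_numpy(dtype=np.uint8),
            df["alt"].to_numpy(dtype=np.uint8),
        )


def _block_grid(length: int, conserved_len: int, divergent_len: int) -> list[tuple[int, int, str]]:
    """Alternating conserved/divergent blocks covering [0, length) exactly once."""
    blocks: list[tuple[int, int, str]] = []
    pos = 0
    cls = CONSERVED
    while pos < length:
        size = conserved_len if cls == CONSERVED else divergent_len
        end = min(pos + size, length)
        blocks.append((pos, end, cls))
        pos = end
        cls = DIVERGENT if cls == CONSERVED else CONSERVED
    return blocks


def make_subgenomes(
    length: int,
    divergence: float,
    block_model: tuple[int, int] = (5_000, 5_000),
    seed: int = DEFAULT_SEED,
    n_subgenomes: int = 2,
) -> PolyploidGenome:
    """Generate a genome of ``n_subgenomes`` with block-structured divergence.

    Subgenome A is uniform random over {A,C,G,T}.  Subgenome B equals A
    everywhere except inside divergent blocks, where each position is
    substituted independently with probability ``divergence`` — so the realized
    fraction of differing bases *inside divergent blocks* matches the requested
    rate up to binomial noise.

    Parameters
    ----------
    length : subgenome length in bp.
    divergence : per-base substitution probability inside divergent blocks,
        in [0, 0.25] (beyond that the fixed-difference model breaks down).
    block_model : (conserved_len, divergent_len) in bp; blocks alternate
        deterministically starting with a conserved block.
    seed : RNG seed; the whole genome is a pure function of its parameters.
    n_subgenomes : 2 for the allotetraploid, 1 for the diploid control.
    """
    conserved_len, divergent_len = block_model
    if not (0.0 <= divergence <= 0.25):
        raise ValueError(f"divergence must be in [0, 0.25], got {divergence}")
    if n_subgenomes not in (1, 2):
        raise ValueError("n_subgenomes must be 1 or 2")
    if conserved_len <= 0 or divergent_len <= 0:
        raise ValueError("block lengths must be positive")
    if n_subgenomes == 2 and length < 2 * (conserved_len + divergent_len):
        raise ValueError("length must be >= 2 * (conserved_len + divergent_len)")

    rng = np.random.default_rng(seed)
    sub_a = rng.integers(0, 4, size=length, dtype=np.uint8)
    blocks = _block_grid(length, conserved_len, divergent_len)

    params = {
        "length": length,
        "divergence": divergence,
        "conserved_len": conserved_len,
        "divergent_len": divergent_len,
        "seed": seed,
        "n_subgenomes": n_subgenomes,
        "heterozygosity": 0.0,
        "het_seed": None,
    }

    if n_subgenomes == 1:
        return PolyploidGenome(
            subgenomes={"subA": sub_a},
            block_map=blocks,
            divergent_sites=np.empty(0, dtype=np.int64),
            het_sites={"subA": _empty_het()},
            params=params,
        )

    sub_b = sub_a.copy()
    div_positions: list[np.ndarray] = []
    if divergence > 0:
        for s, e in ((s, e) for s, e, c in blocks if c == DIVERGENT):
            hit = rng.random(e - s) < divergence
            pos = np.nonzero(hit)[0] + s
            # substitute to one of the three other bases, uniformly
            sub_b[pos] = (sub_b[pos] + rng.integers(1, 4, size=len(pos))) % 4
            div_positions.append(pos)
    div_sites = (
        np.sort(np.concatenate(div_positions)) if div_positions else np.empty(0, dtype=np.int64)
    )
    return PolyploidGenome(
        subgenomes={"subA": sub_a, "subB": sub_b},
        block_map=blocks,
        divergent_sites=div_sites.astype(np.int64),
        het_sites={"subA": _empty_het(), "subB": _empty_het()},
        params=params,
    )


def _empty_het() -> pd.DataFrame:
    return pd.DataFrame({"pos": pd.Series(dtype=np.int64),
                         "ref": pd.Series(dtype=np.uint8),
                         "alt": pd.Series(dtype=np.uint8)})


def add_heterozygosity(genome: PolyploidGenome, h: float, seed: int = DEFAULT_SEED) -> PolyploidGenome:
    """Return a copy of ``genome`` with heterozygous allele pairs at rate ``h``.

    Each subgenome independently acquires diploid allele pairs (ref from the
    subgenome sequence, alt a uniformly chosen other base) at randomly drawn
    positions at per-base rate ``h``.  Positions colliding with a divergent
    site are re-drawn, so heterozygous and divergent truth sites are disjoint.
    """
    if not (0.0 <= h <= 0.01):
        raise ValueError(f"heterozygosity must be in [0, 0.01], got {h}")
    rng = np.random.default_rng(seed)
    div_mask = genome.divergent_mask()
    het: dict[str, pd.DataFrame] = {}
    for name, seq in genome.subgenomes.items():
        if h == 0:
            het[name] = _empty_het()
            continue
        hit = rng.random(len(seq)) < h
        n_lost = int(hit[div_mask].sum())  # collisions with divergent sites: re-draw
        hit &= ~div_mask
        pos = np.nonzero(hit)[0]
        # re-draw the (rare) positions lost to divergent-site collisions
        while n_lost > 0:
            cand = rng.integers(0, len(seq), size=n_lost)
            ok = ~div_mask[cand] & ~np.isin(cand, pos)
            cand = np.unique(cand[ok])
            pos = np.union1d(pos, cand)
            n_lost -= len(cand)
        pos = np.sort(pos).astype(np.int64)
        ref = seq[pos]
        alt = ((ref + rng.integers(1, 4, size=len(pos))) % 4).astype(np.uint8)
        het[name] = pd.DataFrame({"pos": pos, "ref": ref, "alt": alt})
    params = dict(genome.params)
    params["heterozygosity"] = h
    params["het_seed"] = seed
    return PolyploidGenome(
        subgenomes={k: v.copy() for k, v in genome.subgenomes.items()},
        block_map=list(genome.block_map),
        divergent_sites=genome.divergent_sites.copy(),
        het_sites=het,
        params=params,
    )


def truth_table(genome: PolyploidGenome) -> pd.DataFrame:
    """Exhaustive, sorted 0-based table of all divergent and heterozygous sites.

    Columns: ``subgenome, pos, cls, ref_allele, alt_allele`` (alleles as
    letters).  Divergent sites appear once per subgenome, ref being that
    subgenome's own allele and alt the homoeologous allele of the other
    subgenome; heterozygous entries carry the diploid allele pair.
    """
    rows: list[pd.DataFrame] = []
    names = genome.names
    if len(names) == 2 and len(genome.divergent_sites):
        a, b = names
        pos = genome.divergent_sites
        for this, other in ((a, b), (b, a)):
            rows.append(pd.DataFrame({
                "subgenome": this,
                "pos": pos,
                "cls": DIVERGENT,
                "ref_allele": [_DECODE[c] for c in genome.subgenomes[this][pos]],
                "alt_allele": [_DECODE[c] for c in genome.subgenomes[other][pos]],
            }))
    for name in names:
        df = genome.het_sites[name]
        if len(df):
            rows.append(pd.DataFrame({
                "subgenome": name,
                "pos": df["pos"].to_numpy(),
                "cls": HETEROZYGOUS,
                "ref_allele": [_DECODE[c] for c in df["ref"]],
                "alt_allele": [_DECODE[c] for c in df["alt"]],
            }))
    if not rows:
        return pd.DataFrame(columns=["subgenome", "pos", "cls", "ref_allele", "alt_allele"])
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["subgenome", "pos"], kind="stable").reset_index(drop=True)


# -- external interfaces ------------------------------------------------------

def write_fasta(sequences: dict[str, np.ndarray], path: str | Path) -> None:
    """Write code arrays as FASTA, one record per sequence, 80-column lines."""
    records = [
        SeqRecord(Seq(decode(arr)), id=name, description="")
        for name, arr in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def read_fasta(path: str | Path) -> dict[str, np.ndarray]:
    return {rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_truth_tsv(genome: PolyploidGenome, path: str | Path) -> None:
    truth_table(genome).to_csv(path, sep="\t", index=False)


def write_params_json(genome: PolyploidGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(genome.params, fh, indent=2, sort_keys=True)


def save_genome(genome: PolyploidGenome, outdir: str | Path, prefix: str = "genome") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome.subgenomes, outdir / f"{prefix}.fasta")
    write_truth_tsv(genome, outdir / f"{prefix}.truth.tsv")
    write_params_json(genome, outdir / f"{prefix}.params.json")


def load_genome(outdir: str | Path, prefix: str = "genome") -> PolyploidGenome:
    """Reconstruct a genome from the FASTA + truth TSV + params JSON triple."""
    outdir = Path(outdir)
    with open(outdir / f"{prefix}.params.json") as fh:
        params = json.load(fh)
    seqs = read_fasta(outdir / f"{prefix}.fasta")
    truth = pd.read_csv(outdir / f"{prefix}.truth.tsv", sep="\t")
    blocks = _block_grid(params["length"], params["conserved_len"], params["divergent_len"])
    div = truth[truth["cls"] == DIVERGENT]
    div_sites = np.sort(div["pos"].unique()).astype(np.int64)
    het_sites = {}
    for name in seqs:
        sub = truth[(truth["cls"] == HETEROZYGOUS) & (truth["subgenome"] == name)]
        het_sites[name] = pd.DataFrame({
            "pos": sub["pos"].to_numpy(dtype=np.int64),
            "ref": np.array([_ENCODE[ord(x)] for x in sub["ref_allele"]], dtype=np.uint8),
            "alt": np.array([_ENCODE[ord(x)] for x in sub["alt_allele"]], dtype=np.uint8),
        })
    return PolyploidGenome(
        subgenomes=seqs, block_map=blocks, divergent_sites=div_sites,
        het_sites=het_sites, params=params,
    )
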