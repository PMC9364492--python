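"""Coordinate-preserving consensus assembly and polishing.

The phenomenon under study lives in base-level error density, not contig
topology, so instead of an overlap-layout-consensus assembler the pseudo-
assembly is a per-position plurality vote of the reads placed at their true
origins, one assembled sequence per subgenome with coordinates identical to
the truth.  That keeps every downstream statistic joinable to the truth
table.  Crucially, *corrected* reads are still placed at their original
origin even where correction moved their content toward the other subgenome —
this is exactly the channel through which correction artifacts harden into
the assembly.

Zero-coverage positions are emitted as N and excluded from every rate
denominator downstream.  Polishing re-votes each covered position with a
chosen (typically accurate) read set; ties keep the current assembly base, so
polishing with the assembly's own consensus input is a no-op.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GAP, N, PolyploidGenome
from .reads import SimRead


def _base_counts(reads: list[SimRead], name: str, length: int) -> np.ndarray:
    """(length, 4) base-vote counts from reads of one subgenome of origin.

    Deleted positions cast no base vote (they only thin local support);
    insertions carry no reference position and are ignored by the
    coordinate-preserving consensus.
    """
    counts = np.zeros((length, 4), dtype=np.int32)
    flat = counts.reshape(-1)
    for r in reads:
        if r.subgenome != name:
            continue
        kept = r.alleles != GAP
        pos = np.arange(r.start, r.end, dtype=np.int64)[kept]
        flat[pos * 4 + r.alleles[kept].astype(np.int64)] += 1
    return counts


def _resolve_ties(consensus: np.ndarray, counts: np.ndarray,
                  reads: list[SimRead], name: str) -> None:
    """Break plurality ties with the base of the first read in reference order."""
    top = counts.max(axis=1)
    tied = (top > 0) & ((counts == top[:, None]).sum(axis=1) > 1)
    if not tied.any():
        return
    order = sorted((r for r in reads if r.subgenome == name),
                   key=lambda r: (r.start, r.id))
    starts = np.array([r.start for r in order])
    for p in np.nonzero(tied)[0]:
        top_alleles = np.nonzero(counts[p] == top[p])[0]
        hi = np.searchsorted(starts, p, side="right")
        for r in order[:hi]:
            if r.end > p and r.alleles[p - r.start] in top_alleles:
                consensus[p] = r.alleles[p - r.start]
                break


def consensus_assembly(reads: list[SimRead],
                       genome: PolyploidGenome) -> dict[str, np.ndarray]:
    """Per-subgenome, per-position plurality consensus of the reads.

    Ties go to the base carried by the earliest read in reference-sorted
    order; positions without any base vote are emitted as N.  The assembly
    has exactly the subgenome's length (no contigging).
    """
    if not reads:
        raise ValueError("empty read set")
    assembly: dict[str, np.ndarray] = {}
    for name, seq in genome.subgenomes.items():
        counts = _base_counts(reads, name, len(seq))
        cov = counts.sum(axis=1)
        cons = counts.argmax(axis=1).astype(np.uint8)
        _resolve_ties(cons, counts, reads, name)
        cons[cov == 0] = N
        assembly[name] = cons
    return assembly


def polish(assembly: dict[str, np.ndarray], reads: list[SimRead],
           rounds: int = 1) -> dict[str, np.ndarray]:
    """Re-vote every covered position with the polishing read set.

    Plurality wins; ties keep the current assembly base; uncovered positions
    (including N) are untouched.  Polishing with truth-faithful reads never
    increases the number of positions differing from truth.
    """
    polished = {k: v.copy() for k, v in assembly.items()}
    for _ in range(rounds):
        for name, cur in polished.items():
            counts = _base_counts(reads, name, len(cur))
            cov = counts.sum(axis=1)
            top = counts.max(axis=1)
            winner = counts.argmax(axis=1).astype(np.uint8)
            tied = (counts == top[:, None]).sum(axis=1) > 1
            update = (cov > 0) & ~tied
            cur[update] = winner[update]
    return polished


def assembly_diff(assembly: dict[str, np.ndarray],
                  genome: PolyploidGenome) -> dict[str, np.ndarray]:
    """Positions (per subgenome) where the assembly differs from truth, N excluded."""
    out = {}
    for name, aseq in assembly.items():
        truth = genome.subgenomes[name]
        out[name] = np.nonzero((aseq != truth) & (aseq != N))[0]
    return out


def write_diff_tsv(assembly: dict[str, np.ndarray], genome: PolyploidGenome,
                   path) -> None:
    alphabet = "ACGT-N"
    rows = []
    for name, pos in assembly_diff(assembly, genome).items():
        truth = genome.subgenomes[name]
        for p in pos:
            rows.append((name, int(p), alphabet[truth[p]],
                         alphabet[assembly[name][p]]))
    pd.DataFrame(rows, columns=["subgenome", "pos", "truth", "assembly"]).to_csv(
        path, sep="\t", index=False)
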