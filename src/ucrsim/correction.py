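"""Long-read self-correction by overlap clustering and majority vote.

Non-hybrid long-read correctors polish each read against the consensus of the
reads it overlaps.  On an allotetraploid this goes wrong in a specific way:
conserved blocks make reads from *both* subgenomes overlap detectably, so a
read's correction cluster is chimeric wherever a conserved block sits next to
a divergent one.  At a subgenome-divergent site the cluster then carries both
fixed alleles at roughly equal frequency, and the majority vote — tipped by
local coverage fluctuations and sequencing errors — rewrites the minority
subgenome's reads with the other subgenome's allele.  The result is an error
that was never in the raw read: a *correction artifact* that later hardens
into the consensus assembly and repels accurate short reads.

This module implements that mechanism executably: overlap detection (exact,
through the truth coordinates, or via shared anchor k-mers), column-wise
plurality correction, exact removed/retained/introduced error accounting
against the per-read truth, and the self-contained two-subgenome worked
example (12 reads, two divergent sites, two sequencing errors) whose outcome
— two homozygous SNPs from accurate reads on the assembled subgenomes, one
heterozygous SNP from corrected reads on subgenome A — is reproduced exactly.

Because subgenome divergence is substitution-only, homologous positions share
one coordinate system; the cross-subgenome projection in truth mode is the
identity, which makes the chimeric-cluster mechanism exact and auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .genome import (A, C, G, T, GAP, CONSERVED, DIVERGENT, PolyploidGenome,
                     _empty_het)
from .reads import SimRead

TRUTH = "truth"
ANCHOR = "anchor-kmer"


# -- overlap detection --------------------------------------------------------

def _conserved_cumsum(genome: PolyploidGenome) -> np.ndarray:
    mask = np.zeros(genome.length, dtype=np.int64)
    for s, e in genome.conserved_blocks():
        mask[s:e] = 1
    return np.concatenate(([0], np.cumsum(mask)))


def find_overlaps(
    reads: list[SimRead],
    genome: PolyploidGenome,
    min_overlap: int = 2_000,
    mode: str = TRUTH,
    k: int = 15,
    t: int = 10,
    diag_band: int = 100,
) -> nx.Graph:
    """Build the overlap graph used for correction clustering.

    truth mode: two reads overlap iff their origin intervals, projected
    through the (identity) conserved-block homology, share at least
    ``min_overlap`` bases; a cross-subgenome pair additionally requires the
    shared span to intersect a conserved block (without a conserved anchor,
    ~5% divergence keeps the pair from clustering).

    anchor-kmer mode: two reads overlap iff they share >= ``t`` exact k-mers
    on a consistent diagonal (within ``diag_band``); intended for small,
    low-error read sets and cross-checks.
    """
    g = nx.Graph()
    for i, r in enumerate(reads):
        g.add_node(r.id, index=i)
    if mode == TRUTH:
        cons = _conserved_cumsum(genome)
        order = sorted(range(len(reads)), key=lambda i: (reads[i].start, reads[i].id))
        starts = np.array([reads[i].start for i in order])
        for oi, i in enumerate(order):
            ri = reads[i]
            hi = np.searchsorted(starts, ri.end - min_overlap, side="right")
            for oj in range(oi + 1, hi):
                j = order[oj]
                rj = reads[j]
                lo = max(ri.start, rj.start)
                hi_ = min(ri.end, rj.end)
                if hi_ - lo < min_overlap:
                    continue
                if ri.subgenome != rj.subgenome and cons[hi_] - cons[lo] == 0:
                    continue
                g.add_edge(ri.id, rj.id, offset=rj.start - ri.start,
                           overlap=hi_ - lo)
    elif mode == ANCHOR:
        _anchor_overlaps(g, reads, k, t, diag_band)
    else:
        raise ValueError(f"unknown overlap mode {mode!r}")
    return g


def _anchor_overlaps(g: nx.Graph, reads: list[SimRead], k: int, t: int,
                     diag_band: int) -> None:
    from .align import _kmer_codes

    seqs = [r.forward_sequence_codes() for r in reads]
    index: dict[int, list[tuple[int, int]]] = {}
    for i, s in enumerate(seqs):
        v, valid = _kmer_codes(s, k)
        for off in np.nonzero(valid)[0]:
            index.setdefault(int(v[off]), []).append((i, int(off)))
    diags: dict[tuple[int, int], list[int]] = {}
    for hits in index.values():
        if len(hits) < 2:
            continue
        for a in range(len(hits)):
            for b in range(a + 1, len(hits)):
                (i, oi), (j, oj) = hits[a], hits[b]
                if i == j:
                    continue
                key = (i, j) if i < j else (j, i)
                diag = oi - oj if i < j else oj - oi
                diags.setdefault(key, []).append(diag)
    for (i, j), ds in diags.items():
        ds = np.sort(np.array(ds))
        # max count of shared k-mers within one diagonal band
        best = int(np.max(np.searchsorted(ds, ds + diag_band, side="right")
                          - np.arange(len(ds))))
        if best >= t:
            g.add_edge(reads[i].id, reads[j].id,
                       offset=int(np.median(ds)), overlap=best)


# -- correction ---------------------------------------------------------------

def _read_ins_arrays(read: SimRead) -> tuple[np.ndarray, np.ndarray]:
    if not read.insertions:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint8)
    items = sorted(read.insertions.items())
    return (np.array([read.start + j for j, _ in items], dtype=np.int64),
            np.array([b for _, b in items], dtype=np.uint8))


def correct_read(
    target: SimRead,
    neighbors: list[SimRead],
    min_support: int = 3,
) -> SimRead:
    """Correct one read by column-wise plurality over its overlap cluster.

    For every target-read column with at least ``min_support`` member votes
    (the target itself is a member) the plurality allele is adopted; ties and
    under-supported columns keep the target's original base.  An insertion is
    adopted only if a strict majority of the members covering its junction
    carry one.  The corrected read keeps its origin metadata and truth, so a
    fresh effective-error ledger is implied by ``alleles`` vs ``truth``.
    """
    members = [target] + list(neighbors)
    s0, e0 = target.start, target.end
    span = e0 - s0
    counts = np.zeros((span, 5), dtype=np.int32)
    flat = counts.reshape(-1)
    for m in members:
        lo = max(s0, m.start)
        hi = min(e0, m.end)
        if hi <= lo:
            continue
        rel = np.arange(lo - s0, hi - s0, dtype=np.int64)
        flat[rel * 5 + m.alleles[lo - m.start:hi - m.start].astype(np.int64)] += 1

    votes = counts.sum(axis=1)
    order = np.argsort(counts, axis=1)
    winner = order[:, -1].astype(np.uint8)
    top = counts[np.arange(span), winner]
    runner = counts[np.arange(span), order[:, -2]]
    keep = (votes < min_support) | (top == runner)  # under-supported or tied
    new_alleles = np.where(keep, target.alleles, winner).astype(np.uint8)

    # insertion columns: strict majority of covering members must carry one
    ins_j: list[np.ndarray] = []
    ins_b: list[np.ndarray] = []
    for m in members:
        j, b = _read_ins_arrays(m)
        sel = (j > s0) & (j < e0)
        ins_j.append(j[sel])
        ins_b.append(b[sel])
    all_j = np.concatenate(ins_j)
    new_ins: dict[int, int] = {}
    if len(all_j):
        m_starts = np.sort(np.array([m.start for m in members]))
        m_ends = np.sort(np.array([m.end for m in members]))
        uj, cnt = np.unique(all_j, return_counts=True)
        covering = (np.searchsorted(m_starts, uj, side="left")
                    - np.searchsorted(m_ends, uj, side="right"))
        adopt = cnt > covering / 2
        if adopt.any():
            all_b = np.concatenate(ins_b)
            for j in uj[adopt]:
                bases = all_b[all_j == j]
                vals, n = np.unique(bases, return_counts=True)
                new_ins[int(j - s0)] = int(vals[np.argmax(n)])

    return SimRead(
        id=target.id, subgenome=target.subgenome, start=s0, end=e0,
        strand=target.strand, alleles=new_alleles, truth=target.truth,
        insertions=new_ins, het_pos=target.het_pos, het_choice=target.het_choice,
    )


def correct_reads(
    reads: list[SimRead],
    graph: nx.Graph,
    min_support: int = 3,
    phase_split: bool = False,
) -> list[SimRead]:
    """Correct every read against its overlap neighbors.

    ``phase_split`` is the counterfactual a divergence-aware corrector would
    realize: clusters are restricted to same-subgenome members (ideal phasing
    of the divergent sites), which removes the chimeric-cluster channel
    entirely.  Off by default.
    """
    by_id = {r.id: r for r in reads}
    out = []
    for r in reads:
        nbrs = [by_id[n] for n in graph.neighbors(r.id)]
        if phase_split:
            nbrs = [n for n in nbrs if n.subgenome == r.subgenome]
        out.append(correct_read(r, nbrs, min_support=min_support))
    return out


# -- accounting ---------------------------------------------------------------

@dataclass
class CorrectionAccount:
    """Exact per-type error bookkeeping of a correction run.

    removed — raw ledger errors reverted to truth; retained — raw errors
    surviving correction (typed by the raw error); introduced — positions
    correct in the raw read but wrong after correction (typed by the corrected
    state).  Conservation: removed + retained equals the raw error count over
    the corrected span, every run.
    """

    removed_mismatch: int = 0
    removed_gap: int = 0
    retained_mismatch: int = 0
    retained_gap: int = 0
    introduced_mismatch: int = 0
    introduced_gap: int = 0
    raw_errors: int = 0
    total_truth_bases: int = 0
    introduced_positions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def removed(self) -> int:
        return self.removed_mismatch + self.removed_gap

    @property
    def retained(self) -> int:
        return self.retained_mismatch + self.retained_gap

    @property
    def introduced(self) -> int:
        return self.introduced_mismatch + self.introduced_gap

    @property
    def removed_fraction(self) -> float:
        return self.removed / self.raw_errors if self.raw_errors else 0.0

    @property
    def introduced_rate(self) -> float:
        """Introduced errors per truth base of corrected reads."""
        return self.introduced / self.total_truth_bases if self.total_truth_bases else 0.0

    def to_json(self, path: str | Path) -> None:
        d = {k: int(getattr(self, k)) for k in (
            "removed_mismatch", "removed_gap", "retained_mismatch",
            "retained_gap", "introduced_mismatch", "introduced_gap",
            "raw_errors", "total_truth_bases")}
        d["removed"] = self.removed
        d["retained"] = self.retained
        d["introduced"] = self.introduced
        d["removed_fraction"] = self.removed_fraction
        d["introduced_rate"] = self.introduced_rate
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def correction_accounting(
    raw: list[SimRead],
    corrected: list[SimRead],
    genome: PolyploidGenome | None = None,
) -> CorrectionAccount:
    """Count removed / retained / introduced errors against per-read truth.

    Reads are paired by id; raw and corrected sets must pair exactly.
    ``introduced_positions`` collects the genome positions (per subgenome) of
    position-type introduced errors, ready to cross-tabulate against the
    truth table's divergent sites.
    """
    by_id = {r.id: r for r in corrected}
    if set(by_id) != {r.id for r in raw} or len(corrected) != len(raw):
        raise ValueError("raw and corrected read sets do not pair 1:1 by id")
    acc = CorrectionAccount()
    intro_pos: dict[str, list[np.ndarray]] = {}
    for r in raw:
        c = by_id[r.id]
        if (c.subgenome, c.start, c.end) != (r.subgenome, r.start, r.end):
            raise ValueError(f"corrected read {r.id} origin changed")
        truth = r.truth
        raw_err = r.alleles != truth
        cor_err = c.alleles != truth
        removed = raw_err & ~cor_err
        retained = raw_err & cor_err
        introduced = ~raw_err & cor_err
        raw_gap = r.alleles == GAP
        cor_gap = c.alleles == GAP
        acc.removed_gap += int((removed & raw_gap).sum())
        acc.removed_mismatch += int((removed & ~raw_gap).sum())
        acc.retained_gap += int((retained & raw_gap).sum())
        acc.retained_mismatch += int((retained & ~raw_gap).sum())
        acc.introduced_gap += int((introduced & cor_gap).sum())
        acc.introduced_mismatch += int((introduced & ~cor_gap).sum())
        acc.raw_errors += int(raw_err.sum())
        acc.total_truth_bases += r.span
        # insertions: truth never contains one, so every insertion is an error
        rj = set(r.insertions)
        cj = set(c.insertions)
        acc.removed_gap += len(rj - cj)
        acc.retained_gap += len(rj & cj)
        acc.introduced_gap += len(cj - rj)
        acc.raw_errors += len(rj)
        if introduced.any():
            intro_pos.setdefault(r.subgenome, []).append(
                np.nonzero(introduced)[0] + r.start)
    acc.introduced_positions = {
        k: np.concatenate(v) for k, v in intro_pos.items()}
    return acc


def introduced_at_divergent_fraction(
    account: CorrectionAccount, genome: PolyploidGenome
) -> float:
    """Fraction of position-type introduced errors at subgenome-divergent sites."""
    total = sum(len(v) for v in account.introduced_positions.values())
    if total == 0:
        return float("nan")
    div = genome.divergent_sites
    hit = sum(int(np.isin(v, div).sum())
              for v in account.introduced_positions.values())
    return hit / total


# -- the two-subgenome worked example ----------------------------------------

def fig7b_fixture(with_errors: bool = True) -> tuple[PolyploidGenome, list[SimRead]]:
    """The self-contained allotetraploid correction cartoon as data.

    A 2.4 kb genome with a conserved-divergent-conserved block grid and two
    divergent sites (alleles A/C on subgenome A vs G/T on subgenome B).
    Twelve error-free reads except: r3 carries C->G at the second site, r11
    carries G->T at the first.  r1–r4 (subgenome A) and r9–r12 (subgenome B)
    share the left conserved block; r5–r8 cover the second site from an
    adjacent subgenome-A region and overlap r1–r4 by only 150 bp — spatially
    overlapping, but below any sensible clustering threshold — and do not
    overlap r9–r12 at all in cluster terms.
    """
    length = 2_400
    rng = np.random.default_rng(7)
    sub_a = rng.integers(0, 4, size=length, dtype=np.uint8)
    site1, site2 = 900, 1_100
    sub_a[site1] = A
    sub_a[site2] = C
    sub_b = sub_a.copy()
    sub_b[site1] = G
    sub_b[site2] = T
    genome = PolyploidGenome(
        subgenomes={"subA": sub_a, "subB": sub_b},
        block_map=[(0, 800, CONSERVED), (800, 1_600, DIVERGENT),
                   (1_600, 2_400, CONSERVED)],
        divergent_sites=np.array([site1, site2], dtype=np.int64),
        het_sites={"subA": _empty_het(), "subB": _empty_het()},
        params={"length": length, "divergence": 2 / 800, "conserved_len": 800,
                "divergent_len": 800, "seed": 7, "n_subgenomes": 2,
                "heterozygosity": 0.0, "het_seed": None},
    )

    def mk(rid: str, sub: str, start: int, end: int,
           error: tuple[int, int] | None = None) -> SimRead:
        seq = genome.subgenomes[sub]
        truth = seq[start:end].copy()
        alleles = truth.copy()
        if error is not None and with_errors:
            pos, base = error
            alleles[pos - start] = base
        return SimRead(id=rid, subgenome=sub, start=start, end=end, strand="+",
                       alleles=alleles, truth=truth)

    reads = (
        [mk(f"r{i}", "subA", 0, 1_200, (site2, G) if i == 3 else None)
         for i in (1, 2, 3, 4)]
        + [mk(f"r{i}", "subA", 1_050, 2_250) for i in (5, 6, 7, 8)]
        + [mk(f"r{i}", "subB", 0, 1_200, (site1, T) if i == 11 else None)
           for i in (9, 10, 11, 12)]
    )
    return genome, reads


def fig7b_example(with_errors: bool = True) -> dict:
    """Run the worked example end to end and return its SNP counts.

    Returns a dict with ``ccs_homozygous_snp_count`` (accurate error-free
    reads piled on the two assembled subgenomes; sites where every read
    disagrees with the assembly, one per subgenome) and
    ``corrected_het_snp_count_on_subA`` (corrected reads piled on the true
    subgenome-A sequence; sites called heterozygous at AF in [0.25, 0.75],
    depth >= 5), plus the per-read corrected alleles at the two divergent
    sites.  With ``with_errors=False`` the two sequencing errors are omitted:
    every cluster column ties, correction keeps each read's own allele, and
    both counts collapse.
    """
    from .align import build_pileup, oracle_place_all
    from .assembly import consensus_assembly
    from .variants import HET, HOM_ALT, COMPLETE_DISCORDANCE, call_sites

    genome, reads = fig7b_fixture(with_errors=with_errors)
    graph = find_overlaps(reads, genome, min_overlap=400, mode=TRUTH)
    corrected = correct_reads(reads, graph, min_support=3)

    # assemble both subgenomes from the corrected long reads
    assembly = consensus_assembly(corrected, genome)

    # (i) error-free subgenome reads piled on the assembled subgenomes
    ccs_reads = []
    for name, seq in genome.subgenomes.items():
        for i in range(6):
            ccs_reads.append(SimRead(
                id=f"ccs_{name}_{i}", subgenome=name, start=0, end=len(seq),
                strand="+", alleles=seq.copy(), truth=seq.copy()))
    hom = 0
    for name, aseq in assembly.items():
        recs = oracle_place_all([r for r in ccs_reads if r.subgenome == name],
                                assembly)
        pile = build_pileup(recs, name, aseq)
        calls = call_sites(pile, min_depth=5)
        hom += int(calls.df["cls"].isin([HOM_ALT, COMPLETE_DISCORDANCE]).sum())

    # (ii) corrected subgenome-A reads piled on the true subgenome-A sequence
    a_corr = [r for r in corrected if r.subgenome == "subA"]
    recs = oracle_place_all(a_corr, genome.subgenomes)
    pile = build_pileup(recs, "subA", genome.subgenomes["subA"])
    calls = call_sites(pile, min_depth=5)
    het = int((calls.df["cls"] == HET).sum())

    site1, site2 = (int(p) for p in genome.divergent_sites)
    allele_chr = "ACGT-"
    per_read = {
        r.id: {
            "site1": allele_chr[r.alleles[site1 - r.start]]
            if r.start <= site1 < r.end else ".",
            "site2": allele_chr[r.alleles[site2 - r.start]]
            if r.start <= site2 < r.end else ".",
        }
        for r in corrected
    }
    return {
        "ccs_homozygous_snp_count": hom,
        "corrected_het_snp_count_on_subA": het,
        "corrected_alleles": per_read,
    }


def fig7a_example() -> dict:
    """The diploid correction cartoon: error repair and genotype loss.

    One diploid region, eight fully overlapping reads; a homozygous site where
    one read carries a sequencing error, and a heterozygous C/T site drawn 5:3
    across reads.  Majority vote repairs the error but collapses the
    heterozygous site to the majority allele — the corrected reads are
    unanimous, the minority haplotype is lost.
    """
    length = 1_000
    rng = np.random.default_rng(11)
    seq = rng.integers(0, 4, size=length, dtype=np.uint8)
    hom_site, het_site = 300, 600
    seq[hom_site] = A
    seq[het_site] = C
    genome = PolyploidGenome(
        subgenomes={"subA": seq},
        block_map=[(0, length, CONSERVED)],
        divergent_sites=np.empty(0, dtype=np.int64),
        het_sites={"subA": _empty_het()},
        params={"length": length, "divergence": 0.0, "conserved_len": length,
                "divergent_len": 1, "seed": 11, "n_subgenomes": 1,
                "heterozygosity": 1 / length, "het_seed": None},
    )
    reads = []
    for i in range(8):
        truth = seq.copy()
        if i >= 5:  # three reads drew the T haplotype
            truth[het_site] = T
        alleles = truth.copy()
        if i == 2:  # one sequencing error at the homozygous site
            alleles[hom_site] = G
        reads.append(SimRead(id=f"d{i + 1}", subgenome="subA", start=0,
                             end=length, strand="+", alleles=alleles,
                             truth=truth))
    graph = find_overlaps(reads, genome, min_overlap=400, mode=TRUTH)
    corrected = correct_reads(reads, graph, min_support=3)
    allele_chr = "ACGT-"
    return {
        "hom_site_alleles": "".join(allele_chr[r.alleles[hom_site]]
                                    for r in corrected),
        "het_site_alleles": "".join(allele_chr[r.alleles[het_site]]
                                    for r in corrected),
        "error_removed": corrected[2].alleles[hom_site] == A,
        "genotype_lost": all(r.alleles[het_site] == C for r in corrected),
    }


# -- external interfaces ------------------------------------------------------

def write_overlap_tsv(graph: nx.Graph, path: str | Path) -> None:
    import pandas as pd
    rows = [(a, b, d.get("offset", 0), d.get("overlap", 0))
            for a, b, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["read_a", "read_b", "offset", "overlap"]).to_csv(
        path, sep="\t", index=False)
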