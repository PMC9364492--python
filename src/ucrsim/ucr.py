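"""Assembly-evaluation statistics: depth, coverage, UCR, bin rates, correlation.

The central quality signal is the *uncovered region* (UCR): assembly
positions with zero short-read coverage.  Around it sit the statistics an
assembly evaluation reports: per-base depth profiles, coverage at depth
thresholds, per-100-bp-bin mismatch and gap rates of the mapped reads,
classification of bins into high-UCR (> 90% of the bin uncovered) versus the
rest, and the correlation between local assembly-vs-reference divergence and
UCR fraction over large bins.

All denominators exclude N positions (zero-coverage consensus positions),
mirroring how coverage percentages are quoted for non-N genomic regions.
Coordinates are 0-based half-open; UCR intervals are emitted BED-style.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentRecord
from .genome import GAP, N

DEPTH_CAP = 200  # histogram parity with `bedtools genomecov -max 200`


def depth_profile(records: list[AlignmentRecord], length: int,
                  cap: int = DEPTH_CAP) -> np.ndarray:
    """Per-base depth: count of reads whose target-consuming ops span a position.

    Expects primary-only records on one target.  Depths are capped at ``cap``
    for histogram parity with the usual genomecov invocation.
    """
    diff = np.zeros(length + 1, dtype=np.int64)
    for r in records:
        diff[r.start] += 1
        diff[r.end] -= 1
    depth = np.cumsum(diff[:-1])
    return np.minimum(depth, cap)


def coverage_at_thresholds(
    depth: np.ndarray,
    thresholds: tuple[int, ...] = (1, 5, 10, 20),
    n_mask: np.ndarray | None = None,
) -> dict[int, float]:
    """Fraction of non-N positions with depth >= t, for each threshold t."""
    if n_mask is not None:
        depth = depth[~n_mask]
    denom = len(depth)
    if denom == 0:
        return {t: float("nan") for t in thresholds}
    return {t: float((depth >= t).sum() / denom) for t in thresholds}


def ucr_intervals(depth: np.ndarray,
                  n_mask: np.ndarray | None = None) -> list[tuple[int, int]]:
    """Maximal zero-depth intervals over non-N positions (0-based, half-open).

    N positions belong to neither UCR nor covered intervals; together the UCR
    and covered intervals tile the non-N positions exactly.
    """
    zero = depth == 0
    if n_mask is not None:
        zero = zero & ~n_mask
    if not zero.any():
        return []
    padded = np.concatenate(([False], zero, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def interval_mask(intervals: list[tuple[int, int]], length: int) -> np.ndarray:
    m = np.zeros(length, dtype=bool)
    for s, e in intervals:
        m[s:e] = True
    return m


@dataclass
class BinStat:
    """Per-interval alignment discordance tallies (0-based half-open)."""

    start: int
    end: int
    aligned_read_bases: int
    mismatched_bases: int
    gap_length: int
    ucr_fraction: float

    @property
    def mismatch_rate(self) -> float:
        return (self.mismatched_bases / self.aligned_read_bases
                if self.aligned_read_bases else float("nan"))

    @property
    def gap_rate(self) -> float:
        return (self.gap_length / self.aligned_read_bases
                if self.aligned_read_bases else float("nan"))


def bin_discordance(
    target_seq: np.ndarray,
    records: list[AlignmentRecord],
    bin_size: int = 100,
    ngs_depth: np.ndarray | None = None,
) -> pd.DataFrame:
    """Split a target into bins and tally read bases, mismatches and gaps.

    Per bin: ``aligned_read_bases`` counts query bases consuming target
    positions inside the bin; ``mismatched_bases`` those disagreeing with the
    target; ``gap_length`` sums deleted reference positions inside the bin
    plus insertion lengths attached to positions inside it.  The mismatch and
    gap rates divide by ``aligned_read_bases`` and are NaN (flagged) where no
    base aligned.  When ``ngs_depth`` is given, ``ucr_fraction`` is the
    fraction of the bin's non-N positions at zero depth (NaN for all-N bins).
    The last partial bin is kept, flagged by ``partial``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    L = len(target_seq)
    nbins = (L + bin_size - 1) // bin_size
    aligned = np.zeros(nbins, dtype=np.int64)
    mismatched = np.zeros(nbins, dtype=np.int64)
    gap = np.zeros(nbins, dtype=np.int64)
    for r in records:
        pos = np.arange(r.start, r.end, dtype=np.int64)
        kept = r.alleles != GAP
        pb = pos[kept] // bin_size
        aligned += np.bincount(pb, minlength=nbins)
        ref = target_seq[r.start:r.end]
        mm = kept & (r.alleles != ref) & (ref != N)  # N: unknown, not mismatch
        mismatched += np.bincount(pos[mm] // bin_size, minlength=nbins)
        gap += np.bincount(pos[~kept] // bin_size, minlength=nbins)
        for j, bases in r.insertions.items():
            p = min(max(r.start + j - 1, 0), L - 1)  # anchoring position
            gap[p // bin_size] += len(bases)
    starts = np.arange(nbins, dtype=np.int64) * bin_size
    ends = np.minimum(starts + bin_size, L)
    df = pd.DataFrame({
        "start": starts, "end": ends,
        "aligned_read_bases": aligned,
        "mismatched_bases": mismatched,
        "gap_length": gap,
    })
    with np.errstate(invalid="ignore", divide="ignore"):
        df["mismatch_rate"] = np.where(aligned > 0, mismatched / np.maximum(aligned, 1), np.nan)
        df["gap_rate"] = np.where(aligned > 0, gap / np.maximum(aligned, 1), np.nan)
    if ngs_depth is not None:
        nonn = (target_seq != N).astype(np.int64)
        zero = ((ngs_depth == 0) & (target_seq != N)).astype(np.int64)
        nonn_per = np.add.reduceat(nonn, starts)
        zero_per = np.add.reduceat(zero, starts)
        with np.errstate(invalid="ignore", divide="ignore"):
            df["ucr_fraction"] = np.where(nonn_per > 0, zero_per / np.maximum(nonn_per, 1), np.nan)
    else:
        df["ucr_fraction"] = np.nan
    df["partial"] = ends - starts < bin_size
    return df


def classify_high_ucr(bins: pd.DataFrame, threshold: float = 0.9) -> pd.Series:
    """True for high-UCR bins: strictly more than ``threshold`` uncovered.

    Bins with undefined (NaN) ucr_fraction are never high-UCR.
    """
    return bins["ucr_fraction"] > threshold


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n_bins: int
    degenerate: bool


def divergence_ucr_correlation(
    diff_mask: np.ndarray,
    ucr: list[tuple[int, int]],
    n_mask: np.ndarray | None = None,
    blocks: list[tuple[int, int]] | None = None,
    block_min: int = 200_000,
    bin_size: int = 100_000,
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Pearson correlation of per-bin divergence against per-bin UCR ratio.

    ``diff_mask`` marks positions where the assembly differs from the
    reference/truth.  Blocks (default: the whole sequence) of at least
    ``block_min`` bp are cut into ``bin_size`` bins; per bin, divergence is
    diff positions over non-N length and the UCR ratio is UCR bases over bin
    length.  Returns the correlation (flagged degenerate when a variable is
    constant) together with the per-bin table.  Raises on fewer than 3 usable
    bins.
    """
    L = len(diff_mask)
    if blocks is None:
        blocks = [(0, L)]
    if n_mask is None:
        n_mask = np.zeros(L, dtype=bool)
    ucr_mask = interval_mask(ucr, L)
    rows = []
    for bs, be in blocks:
        if be - bs < block_min:
            continue
        for s in range(bs, be, bin_size):
            e = min(s + bin_size, be)
            nonn = int((~n_mask[s:e]).sum())
            if nonn == 0:
                continue
            rows.append((s, e,
                         float(diff_mask[s:e].sum() / nonn),
                         float(ucr_mask[s:e].sum() / (e - s))))
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} usable bins (< 3)")
    table = pd.DataFrame(rows, columns=["start", "end", "divergence", "ucr_ratio"])
    x = table["divergence"].to_numpy()
    y = table["ucr_ratio"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), len(rows), True), table
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(rows), False), table


# -- summaries and writers ----------------------------------------------------

def assembly_summary(
    name: str,
    assembly_seq: np.ndarray,
    depth: np.ndarray,
    n_reads_total: int,
    n_reads_mapped: int,
    thresholds: tuple[int, ...] = (1, 5, 10, 20),
) -> dict:
    """One column of the assembly-comparison table (sizes, mapping, coverage)."""
    n_mask = assembly_seq == N
    nonn = int((~n_mask).sum())
    cov = coverage_at_thresholds(depth, thresholds, n_mask)
    ucr = ucr_intervals(depth, n_mask)
    ucr_len = sum(e - s for s, e in ucr)
    return {
        "assembly": name,
        "size_bp": int(len(assembly_seq)),
        "non_n_bp": nonn,
        "mapped_rate": n_reads_mapped / n_reads_total if n_reads_total else float("nan"),
        "mean_depth": float(depth[~n_mask].mean()) if nonn else float("nan"),
        **{f"coverage_ge_{t}x": cov[t] for t in thresholds},
        "ucr_fraction": ucr_len / nonn if nonn else float("nan"),
        "ucr_bp": int(ucr_len),
    }


def write_ucr_bed(ucr: list[tuple[int, int]], target: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, e in ucr:
            fh.write(f"{target}\t{s}\t{e}\n")


def write_bins_tsv(bins: pd.DataFrame, path: str | Path) -> None:
    bins.to_csv(path, sep="\t", index=False)
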