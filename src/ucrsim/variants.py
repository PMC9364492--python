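"""Pileup-derived site classification: heterozygosity and complete discordance.

Site calling follows the depth-and-allele-frequency rules used when
estimating heterozygosity from accurate reads piled on an assembly: positions
with depth below 5 are set aside; at the rest, the allele frequency (AF) of
the leading non-reference allele — the deletion pseudo-allele participates,
insertions do not create calls — classifies the site:

* ``heterozygous``            0.25 <= AF <= 0.75
* ``homozygous-alt``          AF > 0.75 (but some reads still match the reference)
* ``complete-discordance``    every read carries a non-reference allele
* ``homozygous-ref``          AF < 0.25

Complete discordance is the signature of an assembly base that disagrees with
*all* the evidence — for this analysis, the footprint of correction artifacts
fixed into the consensus.  By default it requires all reads non-reference but
not allele-unanimity; the stricter same-allele variant is available behind a
flag.  AF uses the single most frequent non-reference allele by default
(keeping heterozygous calls biallelic); the summed-non-reference variant is
available for sensitivity analysis.

Genome heterozygosity is the heterozygous-site count over depth-eligible
positions (the all-positions denominator is reportable as well).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .align import Pileup
from .genome import GAP, N

LOW_DEPTH = "low-depth"
HOM_REF = "homozygous-ref"
HET = "heterozygous"
HOM_ALT = "homozygous-alt"
COMPLETE_DISCORDANCE = "complete-discordance"

_ALPHABET = "ACGT-"


@dataclass
class SiteCalls:
    """Result of :func:`call_sites`.

    ``df`` holds one row per emitted site (by default: depth-eligible sites
    with any non-reference support, plus all sites when ``emit_all``), with
    columns target, pos, depth, ref, alt, alt_count, af, alt_is_gap, cls.
    ``eligible_positions`` counts ref-defined positions meeting the depth
    filter — the default heterozygosity denominator.
    """

    df: pd.DataFrame
    eligible_positions: int
    n_low_depth: int
    target_length: int
    min_depth: int

    def positions(self, cls: str) -> np.ndarray:
        return self.df.loc[self.df["cls"] == cls, "pos"].to_numpy()


def call_sites(
    pileup: Pileup,
    min_depth: int = 5,
    af_lo: float = 0.25,
    af_hi: float = 0.75,
    sum_af: bool = False,
    strict_cd: bool = False,
    emit_all: bool = False,
) -> SiteCalls:
    """Classify every pileup column by non-reference allele frequency.

    Positions whose reference base is N are excluded entirely.  ``sum_af``
    switches AF to the summed non-reference frequency; ``strict_cd`` requires
    complete-discordance sites to be allele-unanimous, not merely
    reference-free.
    """
    ref = pileup.ref
    counts = pileup.counts
    depth = counts.sum(axis=1)
    defined = ref != N
    eligible = defined & (depth >= min_depth)
    n_low = int((defined & (depth > 0) & (depth < min_depth)).sum())

    pos_all = np.nonzero(defined & (depth > 0))[0]
    d = depth[pos_all]
    ref_codes = ref[pos_all]
    cnt = counts[pos_all]
    ref_count = cnt[np.arange(len(pos_all)), ref_codes]
    nonref = cnt.copy()
    nonref[np.arange(len(pos_all)), ref_codes] = 0
    lead = nonref.argmax(axis=1)  # ties -> smallest allele code (deterministic)
    lead_count = nonref[np.arange(len(pos_all)), lead]
    nonref_total = nonref.sum(axis=1)
    af = (nonref_total if sum_af else lead_count) / np.maximum(d, 1)

    cls = np.full(len(pos_all), HOM_REF, dtype=object)
    cls[d < min_depth] = LOW_DEPTH
    elig = d >= min_depth
    cd = elig & (ref_count == 0)
    if strict_cd:
        cd &= lead_count == d
    cls[elig & (af >= af_lo) & (af <= af_hi)] = HET
    cls[elig & (af > af_hi)] = HOM_ALT
    cls[cd] = COMPLETE_DISCORDANCE

    emit = np.ones(len(pos_all), dtype=bool) if emit_all else (elig & (nonref_total > 0))
    df = pd.DataFrame({
        "target": pileup.target,
        "pos": pos_all[emit],
        "depth": d[emit],
        "ref": [_ALPHABET[c] for c in ref_codes[emit]],
        "alt": [_ALPHABET[c] for c in lead[emit]],
        "alt_count": lead_count[emit],
        "af": af[emit],
        "alt_is_gap": lead[emit] == GAP,
        "cls": cls[emit],
    })
    return SiteCalls(
        df=df, eligible_positions=int(eligible.sum()), n_low_depth=n_low,
        target_length=len(ref), min_depth=min_depth,
    )


def heterozygosity(calls: SiteCalls,
                   eligible_positions: int | None = None) -> float:
    """Heterozygous-site count over depth-eligible positions.

    Pass ``eligible_positions`` to use a different denominator (e.g. all
    assembly positions).
    """
    denom = calls.eligible_positions if eligible_positions is None else eligible_positions
    if denom == 0:
        raise ValueError("no eligible positions")
    return int((calls.df["cls"] == HET).sum()) / denom


def ucr_complete_discordance_fraction(
    calls: SiteCalls,
    ucr: list[tuple[int, int]],
) -> float:
    """Complete-discordance positions inside UCR over total UCR length.

    UCR has no short-read coverage by definition, so the calls must come from
    long-read or accurate-long-read pileups on the same coordinates.  NaN
    (flagged undefined) when the UCR is empty.
    """
    ucr_len = sum(e - s for s, e in ucr)
    if ucr_len == 0:
        return float("nan")
    cd = calls.positions(COMPLETE_DISCORDANCE)
    inside = _count_in_intervals(cd, ucr)
    return inside / ucr_len


def cd_inside_outside(
    calls: SiteCalls,
    ucr: list[tuple[int, int]],
    non_n_length: int,
) -> tuple[float, float]:
    """(CD density inside UCR, CD density outside) over the non-N assembly."""
    ucr_len = sum(e - s for s, e in ucr)
    cd = calls.positions(COMPLETE_DISCORDANCE)
    inside = _count_in_intervals(cd, ucr)
    outside = len(cd) - inside
    fin = inside / ucr_len if ucr_len else float("nan")
    out_len = non_n_length - ucr_len
    fout = outside / out_len if out_len else float("nan")
    return fin, fout


def _count_in_intervals(pos: np.ndarray, intervals: list[tuple[int, int]]) -> int:
    if len(pos) == 0 or not intervals:
        return 0
    starts = np.array([s for s, _ in intervals])
    ends = np.array([e for _, e in intervals])
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    return int((ok & (pos < ends[np.clip(idx, 0, None)])).sum())


def discordance_split(calls: SiteCalls) -> tuple[float, float]:
    """Among discordant sites, the complete fraction, split mismatch vs gap.

    A site is a mismatch site when its leading non-reference allele is a base
    and a gap site when it is the deletion pseudo-allele.  Returns (complete
    fraction of mismatch sites, complete fraction of gap sites); NaN where a
    class has no sites (flagged undefined).
    """
    df = calls.df[calls.df["alt_count"] > 0]
    out = []
    for is_gap in (False, True):
        sub = df[df["alt_is_gap"] == is_gap]
        if len(sub) == 0:
            out.append(float("nan"))
        else:
            out.append(float((sub["cls"] == COMPLETE_DISCORDANCE).mean()))
    return out[0], out[1]


def write_calls_tsv(calls: SiteCalls, path: str | Path) -> None:
    """Minimal VCF-like TSV (CHROM, POS 1-based, REF, ALT, DP, AF, CLASS)."""
    df = calls.df
    pd.DataFrame({
        "CHROM": df["target"],
        "POS": df["pos"] + 1,
        "REF": df["ref"],
        "ALT": df["alt"],
        "DP": df["depth"],
        "AF": df["af"].round(4),
        "CLASS": df["cls"],
    }).to_csv(path, sep="\t", index=False)
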