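"""Site classification: heterozygosity, complete discordance, splits."""

import numpy as np
import pytest

import ucrsim as u
from ucrsim.align import Pileup
from ucrsim.genome import GAP, N
from ucrsim.variants import (COMPLETE_DISCORDANCE, HET, HOM_ALT, HOM_REF,
                             LOW_DEPTH, _count_in_intervals)


def make_pileup(ref, columns):
    """ref: code array; columns: {pos: {allele_code: count}}."""
    counts = np.zeros((len(ref), 5), dtype=np.int32)
    for pos, alleles in columns.items():
        for a, n in alleles.items():
            counts[pos, a] = n
    return Pileup(target="t", ref=ref, counts=counts,
                  ins_len=np.zeros(len(ref), dtype=np.int64))


class TestCallSites:
    def test_low_depth_regardless_of_alleles(self):
        ref = np.zeros(10, dtype=np.uint8)
        pile = make_pileup(ref, {3: {1: 4}})  # depth 4, all non-ref
        calls = u.call_sites(pile, min_depth=5, emit_all=True)
        row = calls.df[calls.df["pos"] == 3].iloc[0]
        assert row["cls"] == LOW_DEPTH
        assert calls.eligible_positions == 0

    def test_half_alt_is_heterozygous(self):
        ref = np.zeros(10, dtype=np.uint8)
        pile = make_pileup(ref, {2: {0: 5, 1: 5}})
        calls = u.call_sites(pile, min_depth=5)
        row = calls.df.iloc[0]
        assert row["cls"] == HET and row["af"] == pytest.approx(0.5)

    def test_af_band_edges_inclusive(self):
        ref = np.zeros(10, dtype=np.uint8)
        pile = make_pileup(ref, {1: {0: 3, 1: 1},    # AF 0.25
                                 2: {0: 1, 1: 3},    # AF 0.75
                                 3: {0: 1, 1: 4}})   # AF 0.8
        calls = u.call_sites(pile, min_depth=4)
        by_pos = calls.df.set_index("pos")["cls"]
        assert by_pos[1] == HET and by_pos[2] == HET
        assert by_pos[3] == HOM_ALT

    def test_all_reads_non_reference_is_complete_discordance(self):
        ref = np.zeros(10, dtype=np.uint8)
        pile = make_pileup(ref, {4: {1: 8}})
        calls = u.call_sites(pile, min_depth=5)
        assert calls.df.iloc[0]["cls"] == COMPLETE_DISCORDANCE

    def test_strict_cd_requires_allele_unanimity(self):
        ref = np.zeros(10, dtype=np.uint8)
        pile = make_pileup(ref, {4: {1: 4, 2: 4}})  # all non-ref, two alleles
        default = u.call_sites(pile, min_depth=5)
        strict = u.call_sites(pile, min_depth=5, strict_cd=True)
        assert default.df.iloc[0]["cls"] == COMPLETE_DISCORDANCE
        assert strict.df.iloc[0]["cls"] != COMPLETE_DISCORDANCE

    def test_deletion_pseudo_allele_participates(self):
        ref = np.zeros(10, dtype=np.uint8)
        pile = make_pileup(ref, {5: {0: 5, GAP: 5}})
        calls = u.call_sites(pile, min_depth=5)
        row = calls.df.iloc[0]
        assert row["cls"] == HET and row["alt_is_gap"]

    def test_sum_af_variant(self):
        ref = np.zeros(10, dtype=np.uint8)
        # leading non-ref AF = 0.2, summed non-ref AF = 0.4
        pile = make_pileup(ref, {6: {0: 6, 1: 2, 2: 2}})
        lead = u.call_sites(pile, min_depth=5)
        summed = u.call_sites(pile, min_depth=5, sum_af=True)
        assert lead.df.iloc[0]["cls"] == HOM_REF
        assert summed.df.iloc[0]["cls"] == HET

    def test_n_reference_positions_excluded(self):
        ref = np.full(10, N, dtype=np.uint8)
        pile = make_pileup(ref, {2: {1: 9}})
        calls = u.call_sites(pile, min_depth=5, emit_all=True)
        assert len(calls.df) == 0 and calls.eligible_positions == 0

    def test_every_eligible_site_gets_exactly_one_class(self):
        rng = np.random.default_rng(81)
        ref = rng.integers(0, 4, size=300, dtype=np.uint8)
        counts = rng.integers(0, 6, size=(300, 5)).astype(np.int32)
        pile = Pileup("t", ref, counts, np.zeros(300, dtype=np.int64))
        calls = u.call_sites(pile, min_depth=5, emit_all=True)
        depth = counts.sum(axis=1)
        assert len(calls.df) == int((depth > 0).sum())
        assert calls.df["cls"].isin(
            [LOW_DEPTH, HOM_REF, HET, HOM_ALT, COMPLETE_DISCORDANCE]).all()
        eligible = calls.df[calls.df["depth"] >= 5]
        assert (eligible["cls"] != LOW_DEPTH).all()


class TestHeterozygosity:
    def test_simple_arithmetic(self):
        ref = np.zeros(10_000, dtype=np.uint8)
        cols = {p: {0: 5, 1: 5} for p in range(22)}
        cols.update({p: {0: 10} for p in range(22, 10_000)})
        pile = make_pileup(ref, cols)
        calls = u.call_sites(pile, min_depth=5)
        assert u.heterozygosity(calls) == pytest.approx(0.0022)

    def test_no_eligible_positions_rejected(self):
        pile = make_pileup(np.zeros(5, dtype=np.uint8), {})
        calls = u.call_sites(pile)
        with pytest.raises(ValueError):
            u.heterozygosity(calls)

    def test_recovery_from_simulated_diploid(self):
        """Parameter recovery: 0.22% heterozygosity from error-free reads."""
        g = u.make_subgenomes(200_000, 0.0, (5_000, 5_000), seed=82,
                              n_subgenomes=1)
        g = u.add_heterozygosity(g, 0.0022, seed=83)
        reads = u.simulate_long_reads(g, 30, (8_000, 1_000), u.ERROR_FREE,
                                      seed=84)
        recs = u.oracle_place_all(reads, g.subgenomes)
        pile = u.build_pileup(recs, "subA", g.subgenomes["subA"])
        calls = u.call_sites(pile, min_depth=5)
        est = u.heterozygosity(calls)
        assert est == pytest.approx(0.0022, rel=0.25)


class TestUcrCdOverlap:
    def test_simple_fraction(self):
        ref = np.zeros(200, dtype=np.uint8)
        cols = {p: {1: 8} for p in (10, 20, 30, 40, 50)}  # five CD sites
        cols.update({p: {0: 8} for p in range(100, 150)})
        pile = make_pileup(ref, cols)
        calls = u.call_sites(pile, min_depth=5)
        assert u.ucr_complete_discordance_fraction(
            calls, [(0, 100)]) == pytest.approx(0.05)

    def test_empty_ucr_flagged_undefined(self):
        pile = make_pileup(np.zeros(10, dtype=np.uint8), {2: {0: 9}})
        calls = u.call_sites(pile)
        assert np.isnan(u.ucr_complete_discordance_fraction(calls, []))

    def test_inside_outside_split(self):
        ref = np.zeros(1_000, dtype=np.uint8)
        cols = {p: {1: 8} for p in (5, 15, 500)}
        pile = make_pileup(ref, cols)
        calls = u.call_sites(pile, min_depth=5)
        fin, fout = u.cd_inside_outside(calls, [(0, 100)], 1_000)
        assert fin == pytest.approx(2 / 100)
        assert fout == pytest.approx(1 / 900)

    def test_interval_counter_matches_mask(self):
        rng = np.random.default_rng(85)
        iv = [(10, 50), (200, 220), (400, 900)]
        pos = rng.integers(0, 1_000, size=200)
        mask = np.zeros(1_000, dtype=bool)
        for s, e in iv:
            mask[s:e] = True
        assert _count_in_intervals(pos, iv) == int(mask[pos].sum())


class TestDiscordanceSplit:
    def test_no_discordant_sites_flagged(self):
        pile = make_pileup(np.zeros(10, dtype=np.uint8), {1: {0: 9}})
        calls = u.call_sites(pile)
        mm, gap = u.discordance_split(calls)
        assert np.isnan(mm) and np.isnan(gap)

    def test_hand_built_half_complete(self):
        ref = np.zeros(10, dtype=np.uint8)
        pile = make_pileup(ref, {1: {1: 8},            # complete mismatch site
                                 2: {0: 4, 1: 4},      # partial mismatch site
                                 3: {GAP: 8},           # complete gap site
                                 4: {0: 4, GAP: 4}})    # partial gap site
        calls = u.call_sites(pile, min_depth=5)
        mm, gap = u.discordance_split(calls)
        assert mm == pytest.approx(0.5) and gap == pytest.approx(0.5)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(86)
        ref = rng.integers(0, 4, size=500, dtype=np.uint8)
        counts = rng.integers(0, 4, size=(500, 5)).astype(np.int32)
        pile = Pileup("t", ref, counts, np.zeros(500, dtype=np.int64))
        calls = u.call_sites(pile, min_depth=5)
        mm, gap = u.discordance_split(calls)
        mm_sites = mm_cd = gap_sites = gap_cd = 0
        for p in range(500):
            d = counts[p].sum()
            if d < 5:
                continue
            nonref = counts[p].copy()
            nonref[ref[p]] = 0
            if nonref.sum() == 0:
                continue
            lead = int(nonref.argmax())
            complete = counts[p, ref[p]] == 0
            if lead == GAP:
                gap_sites += 1
                gap_cd += complete
            else:
                mm_sites += 1
                mm_cd += complete
        assert mm == pytest.approx(mm_cd / mm_sites)
        assert gap == pytest.approx(gap_cd / gap_sites)


class TestWriter:
    def test_vcf_like_tsv_is_one_based(self, tmp_path):
        ref = np.zeros(10, dtype=np.uint8)
        pile = make_pileup(ref, {4: {0: 5, 1: 5}})
        calls = u.call_sites(pile, min_depth=5)
        u.write_calls_tsv(calls, tmp_path / "calls.tsv")
        lines = (tmp_path / "calls.tsv").read_text().splitlines()
        assert lines[0].split("\t")[:4] == ["CHROM", "POS", "REF", "ALT"]
        assert lines[1].split("\t")[1] == "5"
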