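"""Alignment engine: oracle placement, seed-extend mapper, pileups, SAM."""

import edlib
import numpy as np
import pytest

import ucrsim as u
from ucrsim.align import (MATCH, MISMATCH, DELETION, INSERTION, KmerIndex,
                          write_sam)
from ucrsim.genome import GAP
from ucrsim.reads import ErrorProfile, SimRead


def make_read(rid, sub, start, seq_codes, truth_codes, insertions=None):
    return SimRead(id=rid, subgenome=sub, start=start,
                   end=start + len(truth_codes), strand="+",
                   alleles=seq_codes, truth=truth_codes,
                   insertions=insertions or {})


class TestOraclePlace:
    def test_error_free_read_is_one_match_op(self, tetra_genome,
                                             clean_long_reads):
        r = clean_long_reads[0]
        rec = u.oracle_place(r, tetra_genome.subgenomes)
        ops = rec.ops(tetra_genome.subgenomes[r.subgenome])
        # het-allele draws may introduce isolated mismatches vs the reference
        non_match = [o for o in ops if o[0] != MATCH]
        assert sum(ln for op, ln, _ in ops if op != DELETION) == len(r)
        assert all(op == MISMATCH and ln == 1 for op, ln, _ in non_match)
        assert len(non_match) <= len(r.het_pos)

    def test_single_mismatch_op_structure(self):
        truth = np.zeros(100, dtype=np.uint8)  # poly-A origin
        seq = truth.copy()
        seq[10] = 2
        r = make_read("q", "t", 0, seq, truth)
        rec = u.oracle_place(r, {"t": truth})
        assert rec.ops(truth) == [(MATCH, 10, "A" * 10), (MISMATCH, 1, "G"),
                                  (MATCH, 89, "A" * 89)]

    def test_op_lengths_conserve_query_and_target(self, tetra_genome,
                                                  ont_reads):
        for r in ont_reads[:20]:
            rec = u.oracle_place(r, tetra_genome.subgenomes)
            ops = rec.ops(tetra_genome.subgenomes[r.subgenome])
            q = sum(ln for op, ln, _ in ops if op != DELETION)
            t = sum(ln for op, ln, _ in ops if op != INSERTION)
            assert q == len(r)
            assert t == r.span

    def test_unknown_target_rejected(self, clean_long_reads):
        with pytest.raises(KeyError):
            u.oracle_place(clean_long_reads[0], {"nope": np.zeros(10, np.uint8)})

    def test_edit_count_vs_independent_dp_alignment(self):
        """The ledger edit count can never beat the optimal alignment, and at
        low error rates (where edit collisions are vanishingly rare) the two
        agree exactly."""
        g = u.make_subgenomes(20_000, 0.0, (5_000, 5_000), seed=21,
                              n_subgenomes=1)
        for profile, exact in ((ErrorProfile(0.0015, 0.00025, 0.00025), True),
                               (u.ONT_PROFILE, False)):
            reads = u.simulate_long_reads(g, 3, (2_000, 2_000), profile,
                                          seed=22)
            assert len(reads) >= 20
            for r in reads[:20]:
                ledger_edits = sum(r.n_errors())
                dist = edlib.align(r.forward_sequence,
                                   u.decode(r.truth))["editDistance"]
                assert dist <= ledger_edits
                if exact:
                    assert dist == ledger_edits


@pytest.fixture(scope="module")
def target():
    rng = np.random.default_rng(33)
    return {"t": rng.integers(0, 4, size=2_000, dtype=np.uint8)}


class TestSeedExtend:
    def test_exact_substring_maps_at_origin(self, target):
        index = KmerIndex(target, k=21)
        q = target["t"][300:450].copy()
        recs = u.seed_extend_map(q, index)
        assert recs and recs[0].start == 300 and recs[0].n_mismatch == 0

    def test_mismatch_rate_threshold_is_strict(self, target):
        index = KmerIndex(target, k=21)
        q = target["t"][300:450].copy()
        for i in (5, 50, 100, 140):  # 4 mismatches on 150 bp = 2.7% > 2%
            q[i] = (q[i] + 1) % 4
        assert u.seed_extend_map(q, index) == []
        q2 = target["t"][300:450].copy()
        for i in (5, 50, 100):  # 3 mismatches = 2.0% -> mapped
            q2[i] = (q2[i] + 1) % 4
        recs = u.seed_extend_map(q2, index)
        assert recs and recs[0].n_mismatch == 3

    def test_decisions_match_exhaustive_scan(self, target):
        """On a <= 2 kb target, mapping decisions equal brute force over all
        offsets with the same lowest-coordinate tie rule."""
        index = KmerIndex(target, k=21)
        t = target["t"]
        rng = np.random.default_rng(34)
        for _ in range(40):
            start = int(rng.integers(0, len(t) - 150))
            q = t[start:start + 150].copy()
            n_err = int(rng.integers(0, 6))
            for p in rng.choice(150, size=n_err, replace=False):
                q[p] = (q[p] + int(rng.integers(1, 4))) % 4
            # brute force: best end-to-end placement over every offset
            best_mm, best_s = min(
                (int((t[s:s + 150] != q).sum()), s)
                for s in range(len(t) - 150 + 1))
            recs = u.seed_extend_map(q, index)
            if best_mm / 150 <= 0.02:
                assert recs and recs[0].start == best_s \
                    and recs[0].n_mismatch == best_mm
            else:
                assert recs == []

    def test_error_free_reads_all_map_to_origin(self, tetra_genome):
        reads = u.simulate_accurate_reads(tetra_genome, 0.2, 150, 0.0, seed=35)
        index = KmerIndex(tetra_genome.subgenomes, k=21)
        for r in reads:
            recs = u.seed_extend_map(r, index, keep_secondary=True)
            assert recs
            placements = {(x.target, x.start) for x in recs}
            assert (r.subgenome, r.start) in placements

    def test_tie_break_lowest_vs_hash(self):
        rng = np.random.default_rng(36)
        block = rng.integers(0, 4, size=400, dtype=np.uint8)
        targets = {"a": block.copy(), "b": block.copy()}
        index = KmerIndex(targets, k=21)
        q = block[100:250].copy()
        low = u.seed_extend_map(q, index, keep_secondary=True)
        assert low[0].target == "a" and not low[1].is_primary
        read = SimRead(id="tie_x", subgenome="a", start=100, end=250,
                       strand="+", alleles=q, truth=q.copy())
        h1 = u.seed_extend_map(read, index, tie_break="hash")
        h2 = u.seed_extend_map(read, index, tie_break="hash")
        assert h1[0].target == h2[0].target and h1[0].start == h2[0].start


class TestFilterPrimary:
    def test_idempotent_and_drops_secondary(self):
        a = np.zeros(10, dtype=np.uint8)
        recs = [u.AlignmentRecord("q1", "t", 0, "+", a, is_primary=True),
                u.AlignmentRecord("q1", "t", 5, "+", a, is_primary=False),
                u.AlignmentRecord("q2", "t", 2, "+", a, is_primary=True)]
        once = u.filter_primary(recs)
        assert [r.query_id for r in once] == ["q1", "q2"]
        assert u.filter_primary(once) == once

    def test_sam_flag_0x900_records_dropped(self, tmp_path):
        """Hand-written 6-record SAM: flags 0x100/0x800 are filtered."""
        ref = "ACGTACGTACGTACGTACGTACGTACGTAC"
        sam = tmp_path / "toy.sam"
        lines = ["@HD\tVN:1.6\tSO:coordinate", "@SQ\tSN:t\tLN:30"]
        for name, flag, pos in [("r1", 0, 1), ("r1", 256, 11), ("r2", 16, 3),
                                ("r2", 2048, 21), ("r3", 0, 5), ("r3", 272, 9)]:
            seq = ref[pos - 1:pos + 9]
            lines.append(f"{name}\t{flag}\tt\t{pos}\t60\t10M\t*\t0\t0\t{seq}\tIIIIIIIIII")
        sam.write_text("\n".join(lines) + "\n")
        targets = {"t": u.encode(ref)}
        recs = u.read_sam(sam, targets)
        assert len(recs) == 6
        prim = u.filter_primary(recs)
        assert len(prim) == 3
        assert all(r.is_primary for r in prim)
        assert sorted(r.query_id for r in prim) == ["r1", "r2", "r3"]


class TestPileup:
    def test_single_error_free_read(self):
        rng = np.random.default_rng(40)
        t = rng.integers(0, 4, size=120, dtype=np.uint8)
        r = make_read("q", "t", 0, t[0:100].copy(), t[0:100].copy())
        rec = u.oracle_place(r, {"t": t})
        pile = u.build_pileup([rec], "t", t)
        cols = list(pile.columns())
        assert len(cols) == 100
        for c in cols:
            assert c.depth == 1
            assert c.allele_counts == {c.ref_base: 1}

    def test_mismatch_column_counts(self):
        t = np.zeros(50, dtype=np.uint8)  # all A
        r1 = make_read("q1", "t", 0, t[:20].copy(), t[:20].copy())
        seq2 = t[:20].copy()
        seq2[5] = 2  # G at position 5
        r2 = make_read("q2", "t", 0, seq2, t[:20].copy())
        pile = u.build_pileup([u.oracle_place(r, {"t": t}) for r in (r1, r2)],
                              "t", t)
        assert pile.counts[5, 0] == 1 and pile.counts[5, 2] == 1
        assert pile.depth[5] == 2

    def test_deletion_and_insertion_accounting(self):
        t = np.zeros(30, dtype=np.uint8)
        seq = t[:20].copy()
        seq[7] = GAP
        r = make_read("q", "t", 0, seq, t[:20].copy(), insertions={3: 2})
        pile = u.build_pileup([u.oracle_place(r, {"t": t})], "t", t)
        assert pile.counts[7, GAP] == 1
        assert pile.depth[7] == 1  # deletion still spans the position
        assert pile.ins_len[2] == 1  # attached to the preceding position

    def test_counts_equal_naive_recount(self, tetra_genome, ont_reads):
        """Pileup counts equal a per-read expansion recount on 5 kb."""
        sub = [r for r in ont_reads if r.subgenome == "subA"][:50]
        t = tetra_genome.subgenomes["subA"]
        recs = [u.oracle_place(r, tetra_genome.subgenomes) for r in sub]
        pile = u.build_pileup(recs, "subA", t)
        naive = np.zeros((len(t), 5), dtype=int)
        for r in sub:
            for i in range(r.span):
                naive[r.start + i, r.alleles[i]] += 1
        lo, hi = 10_000, 15_000
        assert np.array_equal(pile.counts[lo:hi], naive[lo:hi])

    def test_base_conservation(self, tetra_genome, ont_reads):
        sub = [r for r in ont_reads if r.subgenome == "subB"][:40]
        recs = [u.oracle_place(r, tetra_genome.subgenomes) for r in sub]
        pile = u.build_pileup(recs, "subB", tetra_genome.subgenomes["subB"])
        total = int(pile.counts[:, :4].sum() + pile.ins_len.sum())
        assert total == sum(r.aligned_query_bases for r in recs)


class TestSamRoundTrip:
    def test_written_sam_reads_back_equivalently(self, tetra_genome,
                                                 ont_reads, tmp_path):
        sub = [r for r in ont_reads if r.subgenome == "subA"][:20]
        recs = [u.oracle_place(r, tetra_genome.subgenomes) for r in sub]
        targets = {"subA": tetra_genome.subgenomes["subA"]}
        write_sam(recs, targets, tmp_path / "x.sam")
        back = u.read_sam(tmp_path / "x.sam", targets)
        assert len(back) == len(recs)
        p1 = u.build_pileup(recs, "subA", targets["subA"])
        p2 = u.build_pileup(back, "subA", targets["subA"])
        assert np.array_equal(p1.counts, p2.counts)
        assert np.array_equal(p1.ins_len, p2.ins_len)
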