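"""End-to-end experiment orchestration and reporting.

The full experiment mirrors the workflow whose artifacts it studies:

1. simulate an allotetraploid genome (block-structured subgenome divergence
   plus within-subgenome heterozygosity) and three read sets — noisy long
   reads, accurate long reads, accurate short reads;
2. self-correct the noisy long reads by overlap clustering + majority vote;
3. build coordinate-preserving consensus assemblies from raw long reads,
   corrected long reads, and accurate long reads; polish the corrected-read
   assembly with the accurate reads;
4. evaluate every assembly: short-read mapping, depth, coverage at
   thresholds, UCR intervals, per-bin discordance, site calls
   (heterozygosity, complete discordance), the UCR/complete-discordance
   overlap, and the divergence-vs-UCR correlation.

Everything is driven by one declarative config whose seed makes the whole
bundle reproducible byte for byte; a manifest records all parameters.
An analysis-only mode runs the evaluation stages on a user-provided
FASTA + SAM/BAM pair instead of simulated data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align, assembly as asm, correction, genome as gen, reads as rd, ucr, variants

logger = logging.getLogger("ucrsim")

RAW = "raw-consensus"
CORRECTED = "corrected-consensus"
CCS = "ccs-consensus"
POLISHED = "polished"


@dataclass
class PipelineConfig:
    """Declarative configuration of a full simulation run.

    Defaults are the study conditions of the analysis: ~5% divergence inside
    divergent blocks, 0.22% heterozygosity, noisy long reads at 17.5%
    mismatch / 7.5% gap and 30-fold coverage, accurate long and short reads
    at 0.2% error.  The subgenome length (300 kb) is the package's default
    problem size for a desk-scale run.
    """

    # genome
    subgenome_length: int = 300_000
    n_subgenomes: int = 2
    divergence: float = 0.05
    conserved_len: int = 5_000
    divergent_len: int = 5_000
    heterozygosity: float = 0.0022
    # reads
    ont_depth: float = 30.0
    ont_mean_len: int = 10_000
    ont_min_len: int = 1_000
    ont_mismatch: float = 0.175
    ont_insertion: float = 0.0375
    ont_deletion: float = 0.0375
    ccs_depth: float = 30.0
    ccs_read_len: int = 12_000
    ccs_error: float = 0.002
    ngs_depth: float = 10.0
    ngs_read_len: int = 150
    ngs_error: float = 0.002
    # correction
    correction: bool = True
    min_overlap: int = 2_000
    min_support: int = 3
    phase_split: bool = False
    # mapping / evaluation
    kmer: int = 21
    max_mismatch_rate: float = 0.02
    tie_break: str = "hash"
    bin_size: int = 100
    high_ucr_threshold: float = 0.9
    min_depth: int = 5
    af_lo: float = 0.25
    af_hi: float = 0.75
    block_min: int = 200_000
    corr_bin: int = 100_000
    seed: int = 42
    write_ledgers: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        bad = set(data) - {f.name for f in dataclasses.fields(cls)}
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def ont_profile(self) -> rd.ErrorProfile:
        return rd.ErrorProfile(self.ont_mismatch, self.ont_insertion, self.ont_deletion)


@dataclass
class PipelineResult:
    """In-memory bundle of a pipeline run (files are written separately)."""

    config: PipelineConfig
    genome: gen.PolyploidGenome
    ont_raw: list
    ont_corrected: list
    ccs_reads: list
    ngs_reads: list
    account: correction.CorrectionAccount | None
    assemblies: dict[str, dict[str, np.ndarray]]
    ngs_eval: dict[str, dict]          # variant -> per-subgenome depth arrays etc.
    summary: pd.DataFrame
    bins: pd.DataFrame                 # per-bin discordance on corrected assembly
    het_estimate: float
    cd_in_ucr: float
    cd_outside_ucr: float
    discordance_split: tuple[float, float]
    correlation: ucr.CorrelationResult
    corr_table: pd.DataFrame


def _seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2^31 derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _ngs_evaluate(variant: str, seqs: dict[str, np.ndarray], ngs_reads, cfg):
    """Map short reads to an assembly variant and profile depth/coverage/UCR."""
    index = align.KmerIndex(seqs, k=cfg.kmer)
    mapped = align.map_reads(ngs_reads, index, cfg.max_mismatch_rate,
                             tie_break=cfg.tie_break)
    per = {}
    rows = []
    for name, seq in seqs.items():
        recs = [r for r in mapped if r.target == name]
        depth = ucr.depth_profile(recs, len(seq))
        n_mask = seq == gen.N
        iv = ucr.ucr_intervals(depth, n_mask)
        per[name] = {"depth": depth, "ucr": iv, "n_mask": n_mask}
        rows.append(ucr.assembly_summary(f"{variant}:{name}", seq, depth,
                                         len(ngs_reads), len(mapped)))
    # genome-wide aggregate over subgenomes
    nonn = sum(r["non_n_bp"] for r in rows)
    agg = {
        "assembly": variant,
        "size_bp": sum(r["size_bp"] for r in rows),
        "non_n_bp": nonn,
        "mapped_rate": len(mapped) / len(ngs_reads) if ngs_reads else float("nan"),
        "mean_depth": sum(r["mean_depth"] * r["non_n_bp"] for r in rows) / nonn,
        **{k: sum(r[k] * r["non_n_bp"] for r in rows) / nonn
           for k in rows[0] if k.startswith("coverage_ge_")},
        "ucr_fraction": sum(r["ucr_bp"] for r in rows) / nonn,
        "ucr_bp": sum(r["ucr_bp"] for r in rows),
    }
    per["_summary_rows"] = rows + [agg]
    per["_n_mapped"] = len(mapped)
    return per


def run_pipeline(config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full simulate -> correct -> assemble -> polish -> evaluate chain."""
    cfg = config or PipelineConfig()
    s_gen, s_het, s_ont, s_ccs, s_ngs = _seeds(cfg.seed, 5)

    logger.info("simulating genome: %d subgenome(s) x %d bp, d=%.3f, h=%.4f",
                cfg.n_subgenomes, cfg.subgenome_length, cfg.divergence,
                cfg.heterozygosity)
    g = gen.make_subgenomes(cfg.subgenome_length, cfg.divergence,
                            (cfg.conserved_len, cfg.divergent_len),
                            seed=s_gen, n_subgenomes=cfg.n_subgenomes)
    if cfg.heterozygosity > 0:
        g = gen.add_heterozygosity(g, cfg.heterozygosity, seed=s_het)

    ont_raw = rd.simulate_long_reads(g, cfg.ont_depth,
                                     (cfg.ont_mean_len, cfg.ont_min_len),
                                     cfg.ont_profile(), seed=s_ont,
                                     id_prefix="ont")
    ccs_reads = rd.simulate_accurate_reads(g, cfg.ccs_depth, cfg.ccs_read_len,
                                           cfg.ccs_error, seed=s_ccs,
                                           id_prefix="ccs")
    ngs_reads = rd.simulate_accurate_reads(g, cfg.ngs_depth, cfg.ngs_read_len,
                                           cfg.ngs_error, seed=s_ngs,
                                           id_prefix="ngs")
    logger.info("simulated reads: %d long, %d accurate-long, %d short",
                len(ont_raw), len(ccs_reads), len(ngs_reads))

    account = None
    if cfg.correction:
        graph = correction.find_overlaps(ont_raw, g, cfg.min_overlap)
        ont_corrected = correction.correct_reads(ont_raw, graph,
                                                 cfg.min_support,
                                                 cfg.phase_split)
        account = correction.correction_accounting(ont_raw, ont_corrected, g)
        logger.info("correction: removed=%d retained=%d introduced=%d",
                    account.removed, account.retained, account.introduced)
    else:
        ont_corrected = ont_raw

    assemblies = {
        RAW: asm.consensus_assembly(ont_raw, g),
        CORRECTED: asm.consensus_assembly(ont_corrected, g),
        CCS: asm.consensus_assembly(ccs_reads, g),
    }
    assemblies[POLISHED] = asm.polish(assemblies[CORRECTED], ccs_reads)

    ngs_eval = {}
    summary_rows = []
    for variant, seqs in assemblies.items():
        ev = _ngs_evaluate(variant, seqs, ngs_reads, cfg)
        ngs_eval[variant] = ev
        summary_rows.extend(ev.pop("_summary_rows"))
        logger.info("evaluated %s: %d short reads mapped", variant,
                    ev.pop("_n_mapped"))
    summary = pd.DataFrame(summary_rows)

    # per-bin discordance of the raw long reads on the corrected assembly,
    # with UCR fractions from the short-read depth
    corr_seqs = assemblies[CORRECTED]
    bins_parts = []
    for name, seq in corr_seqs.items():
        recs = align.oracle_place_all(
            [r for r in ont_raw if r.subgenome == name], corr_seqs)
        b = ucr.bin_discordance(seq, recs, cfg.bin_size,
                                ngs_eval[CORRECTED][name]["depth"])
        b.insert(0, "target", name)
        bins_parts.append(b)
    bins = pd.concat(bins_parts, ignore_index=True)
    bins["high_ucr"] = ucr.classify_high_ucr(bins, cfg.high_ucr_threshold)

    # heterozygosity: accurate long reads piled on their own consensus assembly
    ccs_seqs = assemblies[CCS]
    het_num = het_den = 0
    for name, seq in ccs_seqs.items():
        recs = align.oracle_place_all(
            [r for r in ccs_reads if r.subgenome == name], ccs_seqs)
        pile = align.build_pileup(align.filter_primary(recs), name, seq)
        calls = variants.call_sites(pile, cfg.min_depth, cfg.af_lo, cfg.af_hi)
        het_num += int((calls.df["cls"] == variants.HET).sum())
        het_den += calls.eligible_positions
    het_estimate = het_num / het_den if het_den else float("nan")

    # complete discordance: accurate long reads piled on the corrected assembly
    cd_in_num = cd_out_num = 0.0
    ucr_len_tot = out_len_tot = 0
    mm_sites = gap_sites = mm_cd = gap_cd = 0
    for name, seq in corr_seqs.items():
        recs = align.oracle_place_all(
            [r for r in ccs_reads if r.subgenome == name], corr_seqs)
        pile = align.build_pileup(align.filter_primary(recs), name, seq)
        calls = variants.call_sites(pile, cfg.min_depth, cfg.af_lo, cfg.af_hi)
        iv = ngs_eval[CORRECTED][name]["ucr"]
        nonn = int((seq != gen.N).sum())
        cd = calls.positions(variants.COMPLETE_DISCORDANCE)
        inside = variants._count_in_intervals(cd, iv)
        cd_in_num += inside
        cd_out_num += len(cd) - inside
        ucr_len_tot += sum(e - s for s, e in iv)
        out_len_tot += nonn - sum(e - s for s, e in iv)
        dfm = calls.df[calls.df["alt_count"] > 0]
        for is_gap in (False, True):
            sub = dfm[dfm["alt_is_gap"] == is_gap]
            n_cd = int((sub["cls"] == variants.COMPLETE_DISCORDANCE).sum())
            if is_gap:
                gap_sites += len(sub)
                gap_cd += n_cd
            else:
                mm_sites += len(sub)
                mm_cd += n_cd
    cd_in = cd_in_num / ucr_len_tot if ucr_len_tot else float("nan")
    cd_out = cd_out_num / out_len_tot if out_len_tot else float("nan")
    split = (mm_cd / mm_sites if mm_sites else float("nan"),
             gap_cd / gap_sites if gap_sites else float("nan"))

    # divergence (corrected assembly vs truth) against UCR ratio, large bins
    diff_parts, ucr_parts, nmask_parts, offset = [], [], [], 0
    for name, seq in corr_seqs.items():
        truth = g.subgenomes[name]
        diff_parts.append((seq != truth) & (seq != gen.N))
        nmask_parts.append(seq == gen.N)
        ucr_parts.extend((s + offset, e + offset)
                         for s, e in ngs_eval[CORRECTED][name]["ucr"])
        offset += len(seq)
    diff_mask = np.concatenate(diff_parts)
    n_mask = np.concatenate(nmask_parts)
    blocks = []
    off = 0
    for name, seq in corr_seqs.items():
        blocks.append((off, off + len(seq)))
        off += len(seq)
    corr_res, corr_table = ucr.divergence_ucr_correlation(
        diff_mask, ucr_parts, n_mask, blocks, cfg.block_min, cfg.corr_bin)

    result = PipelineResult(
        config=cfg, genome=g, ont_raw=ont_raw, ont_corrected=ont_corrected,
        ccs_reads=ccs_reads, ngs_reads=ngs_reads, account=account,
        assemblies=assemblies, ngs_eval=ngs_eval, summary=summary, bins=bins,
        het_estimate=het_estimate, cd_in_ucr=cd_in, cd_outside_ucr=cd_out,
        discordance_split=split, correlation=corr_res, corr_table=corr_table,
    )
    if outdir is not None:
        write_bundle(result, outdir)
    return result


def write_bundle(result: PipelineResult, outdir: str | Path) -> None:
    """Write the full report bundle (FASTA/FASTQ/BED/TSV/JSON) to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    g = result.genome
    gen.save_genome(g, out)
    rd.write_fastq(result.ont_raw, out / "ont_raw.fastq")
    rd.write_origins_tsv(result.ont_raw, out / "ont_raw.origins.tsv")
    rd.write_fastq(result.ccs_reads, out / "ccs.fastq")
    rd.write_fastq(result.ngs_reads, out / "ngs.fastq")
    if cfg.write_ledgers:
        rd.write_ledger_tsv(result.ont_raw, out / "ont_raw.ledger.tsv")
    if result.account is not None:
        rd.write_fastq(result.ont_corrected, out / "ont_corrected.fastq")
        result.account.to_json(out / "correction_account.json")
    for variant, seqs in result.assemblies.items():
        gen.write_fasta(seqs, out / f"asm_{variant}.fasta")
        for name in seqs:
            ucr.write_ucr_bed(result.ngs_eval[variant][name]["ucr"], name,
                              out / f"ucr_{variant}_{name}.bed")
    result.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    ucr.write_bins_tsv(result.bins, out / "bins_corrected.tsv")
    result.corr_table.to_csv(out / "divergence_ucr_bins.tsv", sep="\t",
                             index=False)
    report = {
        "het_estimate": result.het_estimate,
        "cd_fraction_in_ucr": result.cd_in_ucr,
        "cd_fraction_outside_ucr": result.cd_outside_ucr,
        "complete_fraction_mismatch_sites": result.discordance_split[0],
        "complete_fraction_gap_sites": result.discordance_split[1],
        "divergence_ucr_pearson_r": result.correlation.r,
        "divergence_ucr_p_value": result.correlation.p_value,
    }
    if result.account is not None:
        report.update({
            "removed_errors": result.account.removed,
            "retained_errors": result.account.retained,
            "introduced_errors": result.account.introduced,
            "introduced_rate": result.account.introduced_rate,
        })
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)


def run_fig7() -> dict:
    """The worked correction examples (tetraploid and diploid), printed."""
    tetra = correction.fig7b_example()
    tetra_clean = correction.fig7b_example(with_errors=False)
    diplo = correction.fig7a_example()
    return {"tetraploid": tetra, "tetraploid_error_free": tetra_clean,
            "diploid": diplo}


def format_fig7_report(res: dict) -> str:
    lines = ["Worked self-correction example (allotetraploid, 12 reads)", ""]
    t = res["tetraploid"]
    lines.append(f"  homozygous SNPs, accurate reads on assembled subgenomes: "
                 f"{t['ccs_homozygous_snp_count']}")
    lines.append(f"  heterozygous SNPs, corrected reads on subgenome A:       "
                 f"{t['corrected_het_snp_count_on_subA']}")
    lines.append("  corrected alleles at the two divergent sites:")
    for rid, al in t["corrected_alleles"].items():
        lines.append(f"    {rid:>4}: site1={al['site1']} site2={al['site2']}")
    tc = res["tetraploid_error_free"]
    lines.append("")
    lines.append("Without the two sequencing errors (clusters tie, reads keep "
                 "their own alleles):")
    lines.append(f"  homozygous SNPs: {tc['ccs_homozygous_snp_count']}, "
                 f"heterozygous SNPs on subgenome A: "
                 f"{tc['corrected_het_snp_count_on_subA']}")
    d = res["diploid"]
    lines.append("")
    lines.append("Diploid panel (error repair and genotype loss):")
    lines.append(f"  homozygous-site alleles after correction:  {d['hom_site_alleles']}")
    lines.append(f"  heterozygous-site alleles after correction: {d['het_site_alleles']}")
    lines.append(f"  sequencing error removed: {d['error_removed']}; "
                 f"minority haplotype lost: {d['genotype_lost']}")
    return "\n".join(lines)


def analyze(fasta: str | Path, sam: str | Path, outdir: str | Path,
            config: PipelineConfig | None = None) -> dict:
    """Analysis-only mode: evaluate a real FASTA + SAM/BAM pair.

    Runs primary filtering, depth/coverage/UCR, per-bin discordance and site
    calling on the provided alignments and writes the same evaluation
    artifacts as the simulated pipeline.
    """
    cfg = config or PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    targets = gen.read_fasta(fasta)
    records = align.filter_primary(align.read_sam(sam, targets))
    report = {}
    bins_parts = []
    rows = []
    for name, seq in targets.items():
        recs = [r for r in records if r.target == name]
        depth = ucr.depth_profile(recs, len(seq))
        n_mask = seq == gen.N
        iv = ucr.ucr_intervals(depth, n_mask)
        ucr.write_ucr_bed(iv, name, out / f"ucr_{name}.bed")
        b = ucr.bin_discordance(seq, recs, cfg.bin_size, depth)
        b.insert(0, "target", name)
        b["high_ucr"] = ucr.classify_high_ucr(b, cfg.high_ucr_threshold)
        bins_parts.append(b)
        pile = align.build_pileup(recs, name, seq)
        calls = variants.call_sites(pile, cfg.min_depth, cfg.af_lo, cfg.af_hi)
        variants.write_calls_tsv(calls, out / f"calls_{name}.tsv")
        rows.append(ucr.assembly_summary(name, seq, depth, len(records),
                                         len(recs)))
        report[name] = {
            "ucr_bp": sum(e - s for s, e in iv),
            "het_sites": int((calls.df["cls"] == variants.HET).sum()),
            "cd_sites": int((calls.df["cls"]
                             == variants.COMPLETE_DISCORDANCE).sum()),
            "eligible_positions": calls.eligible_positions,
        }
    bins = pd.concat(bins_parts, ignore_index=True)
    ucr.write_bins_tsv(bins, out / "bins.tsv")
    pd.DataFrame(rows).to_csv(out / "summary.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
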