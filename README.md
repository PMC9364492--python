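# ucrsim

Simulation and analysis of **self-correction artifacts** in long-read
assemblies of allopolyploid genomes, and of the assembly regions they leave
behind: **UCR** — regions of an assembly with zero short-read (NGS) coverage.

## The problem

Allotetraploid genomes carry two diverged subgenomes (A and B) whose
sequences alternate between *conserved* blocks (locally identical) and
*divergent* blocks (a few percent fixed substitution differences).
Non-hybrid ("self") correction of noisy long reads polishes each read
against the consensus of the reads it overlaps. On an allotetraploid this
backfires: conserved blocks make reads from *both* subgenomes overlap
detectably, so correction clusters become chimeric wherever a conserved
block borders a divergent one. At a subgenome-divergent site the cluster
then carries both fixed alleles at near-equal frequency, and the majority
vote — tipped by coverage fluctuations and sequencing errors — rewrites the
minority subgenome's reads with the other subgenome's allele. These
*introduced* errors harden into the consensus assembly, repel accurate short
reads (which tolerate only ~2% mismatches), and surface as UCR.

`ucrsim` makes this mechanism executable and measurable. It simulates the
genome and reads with complete per-base ground truth, implements
self-correction as overlap clustering + column-wise plurality vote, builds
coordinate-preserving consensus assemblies, and computes the evaluation
statistics in the field's standard form:

* per-base depth profiles and coverage at depth thresholds (≥1/5/10/20×);
* UCR intervals (BED) and high-UCR bin classification (100 bp bins with
  > 90% of bases uncovered);
* per-bin mismatch rate `mismatched bases / aligned read bases` and gap rate
  `gap length / aligned read bases`;
* pileup site calls: a site with depth ≥ 5 is *heterozygous* when the
  leading non-reference allele frequency satisfies 0.25 ≤ AF ≤ 0.75, and a
  *complete discordance* when every covering read is non-reference;
* genome heterozygosity (heterozygous sites / depth-eligible positions) and
  the Pearson correlation of per-bin divergence against per-bin UCR ratio.

Exact **removed / retained / introduced** error accounting is possible
because every simulated read carries an invertible error ledger; counting is
against truth, never estimated.

## Worked example

The twelve-read correction cartoon — two subgenomes sharing a conserved left
block, two divergent sites with alleles A/C (subgenome A) versus G/T
(subgenome B), one sequencing error in each subgenome's reads — runs
self-contained:

```sh
$ ucrsim fig7
Worked self-correction example (allotetraploid, 12 reads)

  homozygous SNPs, accurate reads on assembled subgenomes: 2
  heterozygous SNPs, corrected reads on subgenome A:       1
  corrected alleles at the two divergent sites:
      r1: site1=A site2=T
      ...
     r12: site1=A site2=T
```

The chimeric cluster {r1–r4, r9–r12} votes "A" and "T" the major alleles, so
all eight reads are corrected to A/T: subgenome B loses its G, subgenome A
loses its C. Accurate reads piled on the assembled subgenomes then show one
homozygous SNP on each (total **2**), while corrected reads piled on the true
subgenome-A sequence show **1** heterozygous SNP (AF = 0.5) where the
adjacent-region reads r5–r8 still carry the true "C". Without the two
sequencing errors every cluster column ties, reads keep their own alleles,
and both counts are 0.

## Full pipeline

```sh
ucrsim run-all --seed 42 -o out/          # simulate -> correct -> assemble
                                          # -> polish -> evaluate
ucrsim analyze --fasta asm.fasta --sam aln.sam -o out/   # your own data
```

A run at the default study conditions (two 300 kb subgenomes, 5% divergence
in divergent blocks, 0.22% heterozygosity, long reads at 17.5% mismatch /
7.5% gap, 30×) writes genome + truth tables, read sets, corrected reads with
their correction account, four assembly variants, UCR BEDs, bin tables, site
calls, a coverage summary across variants and `report.json`. A rerun with
the same config is byte-identical.

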