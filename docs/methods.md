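# Methods

## Genome model

An allotetraploid is modeled as two subgenomes of equal length over a
uniform {A,C,G,T} composition. A deterministic block grid alternates
conserved and divergent blocks (defaults 5 kb / 5 kb, starting conserved)
along the whole sequence; inside divergent blocks subgenome B differs from
subgenome A by independent per-base substitutions at rate *d* (default
0.05), so the realized divergence *inside divergent blocks* equals the
requested rate up to binomial noise. Divergence is substitution-only: the
two subgenomes therefore share one coordinate system (position *p* on A is
homologous to *p* on B), which makes the cross-subgenome projection used by
overlap clustering the identity and keeps every downstream statistic exactly
joinable to truth. Within-subgenome heterozygosity adds diploid allele
pairs at per-base rate *h* (default 0.0022) at positions disjoint from
divergent sites (collisions are re-drawn). There is no repeat or indel
divergence model: repeats are a confounder deliberately excluded, and the
divergence anchor concerns substitutions. Coordinates are 0-based,
half-open everywhere; all randomness flows through explicit seeds
(documented default 42) and equal seeds give byte-identical output.

The diploid control used in the mechanism comparison is a single subgenome
with *d* = 0 and *h* = 0. It isolates the correction machinery itself: with
heterozygosity present, majority vote additionally collapses heterozygous
sites (genotype loss, shown by the diploid worked example), a separate and
depth-independent effect that would obscure the depth-scaling of pure
vote errors.

## Read model

Three presets: noisy long reads (mismatch 0.175, insertion 0.0375, deletion
0.0375 — i.e. 17.5% mismatches and 7.5% gaps, the gap total split evenly
between the two indel types since only their sum is anchored), accurate long
reads (12 kb, 0.2% error) and accurate short reads (150 bp, 0.2% error).
Long-read lengths follow a truncated geometric distribution (default mean
10 kb, minimum 1 kb); accurate reads are fixed-length and substitution-only;
all reads are single-end (UCR is a coverage property, pairing adds nothing).
Indels are length-1 events. Each read records its origin, the haplotype
drawn (probability 1/2 per heterozygous site) and an error ledger; removing
the ledger's edits from the read sequence reproduces the haplotype-resolved
origin substring exactly, a property the tests verify both exhaustively on
small sets and against an independent dynamic-programming aligner (edit
distance can only be ≤ the ledger count — distinct injected edits can
compose into cheaper alignments at high rates — with equality at low rates).
Strand is drawn and honored by FASTQ output, but sequences are kept in
target-forward orientation internally so no strand ambiguity reaches any
statistic. Quality scores are not modeled (constant placeholder).

## Placement and mapping

Simulated reads are placed by *oracle alignment* at their true origin — the
operation list falls out of the error ledger — on any coordinate-preserving
target (the truth subgenomes or a consensus assembly of them). Short-read
mapping is a deliberately simple stand-in for a practical aligner: exact
21-mer seeds index the target, each seed proposes an end-to-end gapless
placement, the fewest-mismatch placement wins, and the read maps iff its
mismatch rate is ≤ 2% — the acceptance rule is anchored to the observation
that almost all mapped short reads show ≤ 2% mismatches. This reproduces
the one behavior that matters here (error-dense regions lose short-read
coverage) without affine gaps or quality models. Assembly N positions act
as ambiguity codes (neither match nor mismatch), so reads spanning a
zero-coverage edge are not spuriously rejected. Equal-scoring placements
are tie-broken by lowest target coordinate by default; the pipeline
evaluation instead spreads multireads over their equal-best placements by a
stable hash of the read id — without this, every conserved-block read would
pile onto one subgenome copy and the other copy would look uncovered, which
is an artifact of determinism, not of the data. Both rules are
deterministic; the choice is a one-line config switch.

Pileups follow the mpileup conventions: per-position allele counts with a
deletion pseudo-allele (deletions span positions and count toward depth),
insertions accruing to the preceding consumed position. SAM/BAM ingestion
(analysis-only mode) maps CIGAR M/=/X/I/D/S onto this representation; M is
resolved against the supplied FASTA, so mismatches are exact when the
reference is given.

## Self-correction

Overlap detection (truth mode) connects two reads when their origin
intervals share ≥ 2 kb (`min_overlap`), and, for cross-subgenome pairs, when
the shared span additionally intersects a conserved block — without a
conserved anchor, ~5% divergence keeps real reads from clustering. An
anchor-k-mer mode (≥ 10 shared 15-mers on a consistent diagonal) exists for
low-error sets and cross-checks. Correction is column-wise plurality over
the cluster (the target is a member): columns with ≥ 3 votes
(`min_support`) adopt the majority allele, ties and under-supported columns
keep the target's own base, and an insertion is adopted only when a strict
majority of members covering its junction carries one. `min_support` and
`min_overlap` are stand-in defaults in the range practical correctors use;
the object of study is the mechanism, not any specific tool's parameters.
An off-by-default `phase_split` option restricts clusters to same-subgenome
members — the idealized counterfactual of a divergence-aware corrector —
and removes the introduced-error channel (tested: > 10-fold reduction).

Accounting pairs each raw read with its corrected version and classifies
every position against the read's own haplotype truth: **removed** (raw
error, now correct), **retained** (raw error, still wrong), **introduced**
(raw correct, now wrong); `removed + retained = raw error count` holds
exactly on every run. Insertions are errors by definition (truth has none).
Removed/retained are typed by the raw error, introduced by the corrected
state.

## Assembly and polishing

The consensus assembly is coordinate-preserving: per subgenome and position,
the plurality base over the covering reads, ties resolved by the base of the
earliest read in reference-sorted order, zero-coverage positions emitted as
N. There is no contigging — the phenomenon lives in base-level error
density, and preserving coordinates keeps assemblies joinable to truth.
Corrected reads are deliberately placed at their *original* origin even
where correction moved their content toward the other subgenome: that is the
channel through which correction artifacts harden into the assembly.
Deletion votes thin support but cast no base; a position whose reads are all
deleted is emitted as N. Polishing re-votes every covered position with a
chosen read set, ties keeping the current base (hence polishing with the
assembly's own input is a no-op), and never increases the distance to truth
when the polishing reads are error-free (tested).

## Evaluation statistics

Depth counts reads whose target-consuming operations span a position, capped
at 200 for histogram parity with the usual genomecov invocation. All
denominators exclude N positions. UCR intervals are maximal zero-depth runs
over non-N positions; UCR and covered intervals tile the non-N assembly
exactly. Bin statistics (default 100 bp, last partial bin kept and flagged)
attribute a read base to the bin of its target position, deletion length to
the deleted positions' bins, insertion length to the anchoring position's
bin; mismatch and gap rates divide by aligned read bases and are NaN where
nothing aligned. High-UCR bins are strictly > 90% uncovered (the strict
reading of the two phrasings the source material uses; the other is noted as
ambiguous). When comparing classes, rates are aggregated
(Σ mismatches / Σ aligned) rather than averaged per bin, since per-bin
ratios at near-zero coverage are dominated by noise. The divergence–UCR
association selects blocks ≥ `block_min` (default 200 kb), cuts them into
`corr_bin` bins (default 100 kb), computes per-bin divergence (diff
positions / non-N length) and UCR ratio, and reports Pearson *r* with its
standard t-transform p-value — a single test, no multiplicity correction.
Degenerate inputs (constant variable) are flagged rather than erroring;
fewer than 3 usable bins is an error.

Site calls: positions below depth 5 are set aside; AF is the frequency of
the single most frequent non-reference allele (keeping heterozygous calls
biallelic; a summed-AF variant exists behind a flag), with the deletion
pseudo-allele participating and insertions creating no calls. Heterozygous:
0.25 ≤ AF ≤ 0.75. Complete discordance: all reads non-reference (allele
unanimity not required by default; a strict variant exists behind a flag).
Heterozygosity divides heterozygous calls by depth-eligible positions — the
all-positions denominator is reportable but not the default, since
uncovered positions carry no evidence either way.

## Problem sizes and defaults

The default pipeline config runs two 300 kb subgenomes with long reads at
30×, accurate long reads at 30× and short reads at 10×. The acceptance
script and test suite use 150 kb subgenomes for the mechanism run (with the
correlation bins scaled to 25 kb over ≥ 150 kb blocks so that ≥ 12 bins
exist), a 300 kb diploid control, and 1 Mb genomes for the two
parameter-recovery checks — sizes chosen so that every statistic rests on
thousands of events while a full run completes in about a minute on one
CPU. Sub-read-length coverage ramps at sequence ends are a known artifact
of uniform read-start simulation (real libraries extend past contig ends);
consequently edge positions can be N or thinly covered, and truth
comparisons in the tests condition on ≥ 5× support where that matters.

## What the simulation does and does not show

The generator reproduces the conditions the analysis is about — block-wise
subgenome divergence, realistic error rates, coverage levels — but not
repeats, structural variation, chimeric reads, quality-value information, or
assembler/corrector implementation details (string graphs, partial-order
consensus, quality-aware voting). Passing tests therefore demonstrate the
*mechanism* — chimeric clusters flip minority-subgenome alleles, the flips
concentrate at divergent sites, harden into consensus, and create UCR that
accurate-read polishing repairs — and the correctness of the statistics
computing it. They do not certify the behavior of any particular real-world
assembler, nor reproduce whole-genome magnitudes, which depend on data
volumes far beyond a desk-scale run.
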