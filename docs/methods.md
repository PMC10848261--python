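# Methods

## Scope and model of the data

`emsmut` treats an EMS-mutagenized population as a set of per-line variant
call sets against one reference. Every statistic is a function of four
ingredients: the reference sequence, gene models, per-line (contig, pos,
ref, alt, zygosity) records, and optional per-variant annotations
(hard-filter INFO fields, SIFT scores). The package does not call
variants; it starts where a caller's VCFs end.

### Substitution classes

A substitution and its reverse complement are one event observed from two
strands, so the 12 raw types collapse to 6 classes: two transitions
(GC>AT, AT>GC) and four transversions (GC>TA, GC>CG, AT>CG, AT>TA).
Classification is strand-symmetric by construction and is property-tested
over all 12 cases. A published list of the transversion classes in this
field sometimes includes AT>GC by typo; the four transversions used here
are GC>TA, GC>CG, AT>CG, AT>TA.

### Densities, zygosity, uniqueness

Density is reported as kb of denominator per mutation
(`denominator_bp / n / 1000`). The denominator defaults to the full
reference length including N runs, matching how genome-scale densities
are usually quoted against the assembly size; an N-excluding variant
exists. Zero mutations yield an explicit undefined result. Note that at
genome scale the quoted assembly size is usually rounded, so a published
density can differ in the third decimal from the ratio of its own printed
inputs (950 Mb / 311,101 = 3.054 kb); `mutation_density` reports the
computed value.

A variant key (contig, pos, ref, alt) is *unique within the population*
iff exactly one line carries it, and *novel versus a panel* iff absent
from the union of the panel sets. Zygosity never enters set identity:
subtraction and uniqueness operate per site/allele, matching how parental
subtraction is done in practice.

### Hard filters and parental subtraction

The SNP thresholds (QD < 2, FS > 60, MQ < 40, MQRankSum < −12.5,
ReadPosRankSum < −8) and InDel thresholds (QD < 2, FS > 200,
ReadPosRankSum < −20) follow the GATK hard-filtering convention,
including its treatment of absent annotations: a missing INFO field
passes its criterion (logged). Filtering is idempotent. Parental
subtraction removes the parent's alleles per key; multi-allelic records
are split before any set algebra.

### Sequence context

Windows of ±k (default 20) reference bases are stacked into a
per-position composition matrix. Off-contig positions are marked absent
and excluded from that position's denominator — never fabricated — so
interior denominators equal the window count and edge denominators
shrink. The site-vs-flank GC statistic compares position 0 with the
unweighted mean over all other positions. Windows are taken from the
reference strand; a pyrimidine-centered collapsed mode exists but is off
by default, since the spectrum classes are already strand-collapsed and
reference-strand composition is what a genome browser shows.

### Region and effect classification

Each variant receives exactly one region under the precedence
CDS > UTR > intron > promoter > intergenic, applied across all
overlapping genes; this makes region percentages mutually exclusive and
able to sum to 100. The promoter is a fixed window (default 3000 bp)
immediately 5′ of the gene span, truncated only at contig edges — not
clipped at neighboring genes, because precedence already prevents
double-counting against genic regions.

Coding effects are computed on the transcript strand: the variant's
offset in the spliced CDS is found through the transcription-ordered
segments (descending genomic coordinates on minus-strand genes), the
alternate allele is complemented as needed, and both codons are
translated with the standard code. Class rules: identical amino acids →
synonymous; any non-synonymous change in codon 1 → start_loss; new stop →
stop_gain; lost stop → stop_loss; otherwise missense. start_loss and
stop_loss outrank missense within their codons so the categories match
SIFT4G-style annotation. The classifier is validated two independent
ways: against a full-CDS mutate–translate–diff oracle on every simulated
CDS SNP, and under whole-genome reverse complementation (strand
invariance).

InDels are frameshift iff the ref/alt length difference is not a multiple
of 3. MNPs are rejected with an explicit error; the analysis targets SNPs
and short InDels.

The SIFT deleterious threshold is inclusive (score ≤ 0.05), configurable;
published usage varies between "≤" and "<" and the inclusive reading
follows the methods-style statement of the convention.

### Genetic-code neighborhood model

Each of the 61 sense codons has 9 single-nucleotide variants; the 549
directed changes, labeled synonymous/missense/stop-gain and
transition/transversion, are the substrate for three statistics.

*Theoretical matrix.* For a source amino acid, pool the changes of all
its codons (uniform over codons by default; usage-weighted available) and
report each missense target's share as a percent. The default denominator
excludes synonymous changes and stop-gains: this is the convention under
which every valine codon contributes 6 missense neighbors of which
exactly one is alanine and one glycine, giving Val→Ala = Val→Gly =
100/6 ≈ 16.67% (16.66 when truncated to two decimals — published worked
examples of this quantity truncate rather than round, so tables carry
full precision plus both two-decimal renderings). Both inclusions are
available as flags. For valine the usage weighting provably cannot change
the Ala/Gly entries (each codon contributes one of each), which is kept
as a closed-form test.

*Change-type count.* Brute-force enumeration yields 150 ordered missense
(from, to) types plus 18 amino acids with at least one synonymous
self-change (all but Met and Trp) = 168 accessible types when stops are
excluded — the convention matching amino-acid change atlases that display
self-changes such as L/L and S/S.

*Ratios.* Observed matrices come in two conventions: the display
convention (percent of all changes, self-changes included) and the row
convention (per-source missense shares). Ratios are always formed on the
row convention (`normalize_rows_missense` converts); each amino-acid
change is labeled transition/transversion by the nucleotide changes
realizing it, changes realizable by both are labeled *mixed* and excluded
from the two averages, and an observed change with zero theoretical
expectation reports an infinite ratio excluded from means with a log
entry.

*Mutagenicity.* Within each amino-acid family, observed mutated-codon
counts and usage frequencies are separately normalized to sum to 1;
R = observed/usage per codon. The preferred codon is the family's
most-used codon, ties broken lexicographically for deterministic output.

## The simulator: what it emulates, and what it does not

The generator's defaults are the study conditions of a densely
mutagenized diploid population: density 1/3057 bp, class probabilities
(GC>AT 0.2786, AT>GC 0.2762, remaining mass split equally over the four
transversions), mutated-site GC probability 0.47 on a 37%-GC background,
homozygous fraction 0.167. Sample-size parameters (genome length, gene
count, line count) are scaled to desk size per run; the analysis scripts
use 2 Mb / 60 genes / 6 lines, and the density there is raised to
1/500 bp solely so a 2 Mb genome yields enough CDS hits for codon-level
analyses — the acceptance recomputations use 1/3057 on 10 Mb.

Genomes are i.i.d. bases at the configured GC; genes are non-overlapping
cassettes (UTR5 + one- or two-exon CDS + UTR3) whose CDS starts ATG, ends
with a stop and contains none internally. Sites are drawn without
replacement; the collapsed class plus the site's base determine the
alternate allele deterministically; zygosity is Bernoulli. Each line owns
a random stream derived from (seed, line index), so adding lines never
perturbs existing ones. Within a pair, the second line copies
`shared_fraction` of its partner's SNPs and draws `(1 − shared_fraction)`
of its own Poisson count fresh, so a fraction of 1 yields identical key
sets. Background panels draw sites uniformly with uniform alternate
alleles (no class bias).

**Site pool versus class marginals.** The collapsed class determines
whether the mutated site is G/C, so the site-GC fraction and the six
class marginals cannot be pinned simultaneously: with the default equal
transversion split the G/C classes carry 0.5012 of the mass while the
site-GC target is 0.47. The generator therefore has two modes.
`site_gc_prob=None` draws the class first (class marginals exact; implied
site-GC = G/C-class mass). A numeric `site_gc_prob` (the default, 0.47)
draws the site pool first and the class conditionally within the pool
(site-GC exact; class marginals tilted by pool/mass — e.g. GC>AT
0.2786 × 0.47/0.5012 ≈ 0.261). Class-recovery checks use the first mode,
context-bias checks the second; a run of the full pipeline at defaults
shows the tilted class frequencies, which is why the worked example
prints GC>AT ≈ 26.5%.

The truth table records, per line, every count the downstream modules
recompute — class and raw-type counts, zygosity, per-variant provenance
(fresh/copied/indel), region and coding-effect counts for SNPs, and panel
overlaps. Region and effect truth are computed inside the generator by a
direct linear interval scan and a full-CDS translation diff — deliberately
different code paths from the interval-tree annotation and codon-local
classifier they validate.

Not emulated: recombination and pedigree transmission (M₂→M₄ structure is
reduced to the pairwise-sharing knob), selection against essential genes,
context-dependent mutation rates, sequencing error, and the long-tailed
between-line density dispersion seen in real populations (per-line
overrides exist instead). Passing recovery tests therefore shows the
estimators are correct for data matching the generating model, not that
real populations satisfy that model.

## Numerical and I/O choices

- Coordinates are 1-based inclusive at every public surface (matching
  GFF3/VCF); BED intervals are 0-based half-open as the format defines.
- Percentages are computed in double precision; two-decimal displays use
  round-half-even, with a truncation rendering alongside where published
  worked examples truncate.
- Multi-transcript genes use the first mRNA in file order (gene-level
  analysis; logged). Missing CDS phase is assumed 0 with a warning.
- Codon-usage inputs may be counts or per-thousand frequencies; only
  within-family proportions are used, so the scale cancels.
- Empty inputs yield explicit undefined results (None) rather than NaN
  arithmetic: empty spectrum frequencies, zero-mutation density,
  all-unknown zygosity, empty-line panel uniqueness.
- Sites whose window bases are N (or off-contig) are excluded from
  composition denominators; genomes keep N bases.
- Pipeline stages run in a fixed order with fail-fast error reporting
  naming the stage; reruns on identical inputs are byte-identical, and
  the manifest lists every output with a SHA-256 digest.

## Problem sizes

Unit and property tests run on 200–600 kb genomes with 5–12 genes and
2–3 lines (seconds in total). The recovery recomputations use ~100,000
SNPs for class frequencies (3 binomial SE ≈ 0.45 percentage points on a
27.86% class), ~50,000 windows for site-GC (3 SE ≈ 0.67 points), and a
10 Mb genome at 1/3057 bp for density (λ ≈ 3271; 3 Poisson SE ≈ 0.16 kb).

## Known limitations

- One transcript per gene; no splice-site or UTR-boundary effect classes.
- Promoter windows may overlap neighboring genes' spans; precedence
  resolves annotation but no promoter-vs-gene conflict report is emitted.
- `coding_effect` assumes the reference allele matches the reference
  genome at the site (it errors loudly otherwise); pre-phased or
  back-to-back substitutions in one codon are evaluated per variant, not
  jointly.
- The mutagenicity ratio conditions on the amino-acid family and so says
  nothing about absolute per-codon rates.
- The simulator's InDels are placed uniformly and are not length-calibrated
  to real InDel spectra; they exist to exercise frame classification.
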