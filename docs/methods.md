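# Methods

This note records the models, conventions and design choices behind
`radmut`, in the spirit of a statistical-software methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All internal coordinates are 1-based inclusive, as in VCF and GFF3. BED
export is the single exception (0-based half-open); a 1-bp feature at
position *p* is written `p-1  p`. VCF is read through pysam (FORMAT `AD`
required; multi-allelic records are split into independent biallelic
candidates before filtering), FASTA through Biopython, GFF3 through
gffutils. A VCF contig missing from the genome model is a hard error:
silently dropping calls would corrupt every per-chromosome frequency
downstream.

## The reliable-mutation filter

VAF is computed from allele depths, `alt / (ref + alt)`, never from `DP`,
because the filter is defined on read-count allele frequency; a sample with
no informative reads at a site has VAF 0 (with a warning when an explicit
zero-depth record is present). The retention rule is: exactly one mutant
sample in [`focal_min`=0.25, `focal_max`=1.0] and every other sample —
wild type included, absent samples counting as 0 — at or below
`other_max`=0.10. All boundaries are inclusive on the retaining side: a
site at exactly 25% in the focal line, or exactly 10% in another line, is
kept. Zygosity is homozygous iff VAF ≥ `hom_min`=0.75, again inclusive.
A site in the focal window in two lines is background (shared, pre-existing
divergence), not two mutations. The filter is idempotent, and monotone in
its thresholds (raising `other_max` can only grow the retained set; raising
`focal_min` can only shrink it) — both are property-tested.

## Classification

Variants are trimmed to their minimal representation (shared suffix then
prefix, VCF anchor kept for pure indels) and left-aligned through repeat
tracts when genome sequence is available. Within each line, maximal runs of
single-base substitutions at strictly consecutive positions merge into one
MNV; strict adjacency is required (a 1-bp gap keeps two SBSs), the merged
zygosity is homozygous only if every member is, and the merged VAF is the
member mean. Size classes: net length 0 with span 1 → SBS, span ≥ 2 → MNV;
|length| 1–10 → InDel; |length| > 50 → SV. The 11–50 bp range that these
definitions leave open is surfaced as an explicit `unclassified` bucket
rather than silently lumped, so class totals remain comparable across
treatments.

## Spectra and context

The substitution spectrum is directional on the reference strand (12
classes); G>A and C>T are *not* complement-collapsed, matching how
radiation-mutagenesis studies report them. Ti/Tv is
(A>G + G>A + C>T + T>C) / all others, and is reported as undefined — never
divided — when there are no transversions. For dinucleotide context, a G>A
site is "in context" when either immediate neighbour on the reference
strand is a purine (for C>T, a pyrimidine); the side can be restricted to
5′ or 3′ (`side=` argument, default `either`, chosen because the direction
is ambiguous in the field's usual phrasing), chromosome ends evaluate the
one existing neighbour, and a mismatch between the recorded REF and the
genome base is an error. The complementary strand is deliberately not
consulted; a G>A with only a 3′ pyrimidine neighbour is out of context even
though its reverse-complement reading would qualify. Printed percentages
use two-decimal half-up rounding.

Treatment summaries pool each treatment's lines; per-line class counts are
compared between treatments with an independent-samples *t*-test
(scipy `ttest_ind`; degenerate identical groups return p = 1 rather than a
0/0 statistic). The HF-vs-LF comparison uses Welch's unequal-variance form.

## Windows and HF/LF regions

Windows tile each chromosome from position 1 without overlap (default 1 Mb,
100 kb supported); the last window may be short, and a mutation is binned by
its start position with inclusive boundaries. A window is HF when its
per-bp frequency is at least `hf_multiplier`=4 times the chromosome mean
frequency *and* holds ≥ 2 mutations; LF windows have zero mutations.
Adjacent qualifying windows merge into regions. The 4× multiplier with a
two-mutation floor is this package's operationalization — reported
anomalies in the literature run around 5–6× the chromosome mean — and is
config-exposed rather than hard-coded. Note the criterion is self-relative:
a hotspot spanning a large fraction of a short chromosome inflates the
chromosome mean and can fall below 4× of it. InDel–SBS proximity is the
fraction of InDels with at least one SBS of the same treatment within a
radius (default 10 kb, with a {1, 5, 10, 50} kb sensitivity helper, since
"adjacent" is not quantified in the field).

## Annotation

Features are assigned with a fixed precedence (exon > splice region >
UTR5/UTR3 > intron > upstream > downstream > intergenic) so each mutation
gets exactly one category even where genes overlap; upstream/downstream
windows are 5 kb measured from the transcript ends respecting strand
(the convention of SnpEff-style annotators), splice regions are the 2
intronic bases adjacent to each exon. Coding effects are evaluated on the
coding strand with the standard genetic code, codon-by-codon for
substitutions (MNVs spanning a codon boundary are substituted jointly);
InDels are frameshift when net length is not divisible by 3, else in-frame.
A frameshift counts as functionally affecting the gene only when the
shifted translation reaches a stop before the reference terminus; stop gain
and stop loss always do. The test suite checks the codon-level path against
whole-CDS retranslation and the feature path against a per-base
interval-painting oracle.

## Inheritance model

The selfing chain het → {hom ¼, het ½, lost ¼} with absorbing hom/lost
gives p_het = (½)^(g−1) and, exactly at every generation,
p_hom = p_lost = (1 − p_het)/2. This symmetry is the justification for the
back-estimator M1 = 2·hom + het, which the suite verifies to be unbiased by
forward simulation (200 mutations, g ∈ {4,5,6}, 1,000 replicates, 99%
Monte-Carlo interval). The estimator is exact integer arithmetic. The model
assumes a non-chimeric M1 plant and no selection or segregation distortion;
note that asymptotically half (not a quarter) of mutations fix — the
sometimes-quoted "25% preserved" figure is the single-generation homozygote
gain at first selfing only. Genome length for the per-base rate must be
passed explicitly (sum of the genome model's chromosomes, or an assembled
reference length such as 3.73×10⁸ bp for rice).

## BSA mapping

Segregation is tested with the uncorrected Pearson χ² (1 df) against a
configurable ratio (default 3:1); the continuity-corrected form is not used
because pool sizes in this setting are large and the uncorrected statistic
is the field's convention. A marker is pool-associated when the
recessive-phenotype bulk is fixed for the mutant parent's allele while the
dominant bulk differs; monomorphic markers are skipped with a warning.
Candidates are high-impact mutations (nonsense, stop-lost, frameshift)
within ±2 Mb of the associated marker (radius config-exposed; "around the
marker" is not quantified in practice), sorted by distance. The forward F2
simulator recombines marker alleles away from the causal allele with the
Haldane fraction of physical distance at 2.5×10⁻⁸ Morgans/bp (≈ 400 kb/cM,
a rice-like map density); a pool's consensus is a parental allele only when
every pooled plant is homozygous for it.

## The synthetic-cohort generator

Defaults encode the cohort structure the analysis is designed for: 6 lines,
Poisson(100) mutations per line, type mix (SBS, MNV, InDel, SV) =
(0.62, 0.13, 0.25, 0), Ti/Tv 2.22, deletion fraction 0.83 with a geometric
length profile over 1–10 bp, MNV lengths 2–5 (mostly 2), 50 shared
background variants, generation g = 4, depth 30×. SVs are supported but off
by default, matching cohorts where none are observed. Positions are uniform
except in configured hotspot windows (multiplicative rate — an assumption
for testing, not a claim about the true spatial process); events are kept
≥ 15 bp apart so sites never overlap. SBS alternates realize the configured
Ti/Tv in expectation; InDel/SV truth records are stored left-aligned so
recovered records compare positionally. Zygosity fates come from the
selfing chain; lost mutations remain in the truth (fate `lost`) but are not
emitted. Read support is total depth ~ Poisson(mean_depth) and alt depth ~
Binomial(depth, p) with p = 1 (hom), ½ (het), 0 (absent); background sites
are homozygous in every sample including the wild type. MNVs are emitted as
separate per-base SNV records so the pipeline's merge step is exercised.
Every output is byte-identical under a fixed seed.

What the generator does **not** model: mapping and sequencing error,
strand/mapping-quality bias, chimeric (sectored) M1 plants, linked
selection, read-level artefacts, and realistic genome composition (the
sequence is uniform-random with engineered, stop-free open reading frames).
Passing recovery tests therefore demonstrate correctness of the analysis
logic under the stated statistical model, not robustness to real
sequencing noise. At 30× depth a heterozygous site occasionally samples a
VAF below the 25% bound (probability ≈ 3×10⁻³), which is the model's own
irreducible loss; the recovery tests accordingly require ≥ 95% recovery and
exact agreement on what is recovered, not exact recovery of everything.

## Problem sizes in the test suite

The suite's simulations are sized for tight feedback: the shared cohort
fixture is 6 lines × ~100 mutations on an 8 Mb two-chromosome genome at
30× depth; estimator recovery uses 1,000 replicates of 200 mutations;
hotspot detection uses 100 seeded runs of 200 mutations on 10 Mb; oracle
comparisons use 1,000–10,000 random draws. These sizes give the Monte-Carlo
intervals quoted above while keeping the whole suite under a minute.
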