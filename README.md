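# radmut

Mutation-profile analysis for radiation-mutagenized plant resequencing
cohorts.

When a set of mutant lines derived from mutagenized seed (e.g. carbon-ion
beam or gamma-ray irradiated rice) is whole-genome resequenced together with
the untreated parent, the induced mutations must be separated from shared
ancestral variation, classified, and characterized before any biology can be
read off. `radmut` implements that post-calling analysis as a tested Python
library:

- **Reliable-mutation filtering** — a variant is accepted as an induced,
  line-private mutation only when its variant allele frequency (VAF,
  alt reads / total reads) lies in [25%, 100%] in exactly one mutant line and
  at or below 10% in every other sample including the wild type; VAF ≥ 75%
  is called homozygous. Sites shared across lines or present in the parent
  are set aside as background.
- **Classification** — single-base substitutions (SBS); multi-nucleotide
  variants (MNV: substitutions at strictly consecutive bases, merged into
  one event); insertions/deletions of 1–10 bp (InDel); structural variants
  of >50 bp (SV); events of 11–50 bp are reported in an explicit
  `unclassified` bucket.
- **Spectra** — the 12 directional substitution classes, the
  transition/transversion ratio Ti/Tv, flanking purine/pyrimidine
  dinucleotide context of G>A and C>T transitions, and the signed InDel size
  distribution with deletion excess.
- **Landscape** — per-chromosome mutation frequency, non-overlapping window
  counts (1 Mb or 100 kb), high-frequency (HF) and zero-count low-frequency
  (LF) region detection with a Welch *t* comparison, cross-treatment HF
  overlaps, and InDel–SBS proximity fractions.
- **Annotation** — feature assignment (exon > splice region > UTR > intron >
  upstream > downstream > intergenic, 5 kb flanks) and coding effects
  (silent / missense / nonsense / stop-lost; frameshift vs in-frame InDels,
  with premature-stop retranslation).
- **Inheritance model** — a mutation arises heterozygous in the M1 plant and
  under selfing moves each generation to homozygous (¼), heterozygous (½) or
  lost (¼), so at generation *g*:
  p_het = (½)^(g−1), p_hom = p_lost = (1 − p_het)/2.
  The symmetry p_hom = p_lost justifies back-estimating the M1 mutation
  count from an observed line as **2·n_hom + n_het**, and the per-base
  mutation rate as the cohort mean of that estimate divided by the genome
  length.
- **BSA mapping** — χ² test of F2 phenotype segregation against a Mendelian
  ratio, bulk-pool SSR marker association, and screening of high-impact
  mutations (stop gain/loss, frameshift) around the associated marker.
- **Synthetic cohorts** — a generator producing a toy genome, gene models,
  and a multi-line VCF with binomially sampled allele depths and known
  ground truth, used throughout the test suite for recovery checks.

## Worked example

```bash
python examples/inheritance_model.py
```

prints, for a four-line cohort sequenced at generation M6:

```
per-line M1 estimates (2 x hom + het):
  H404: 93 hom + 16 het -> 202
  H409: 89 hom + 20 het -> 198
  H410: 84 hom + 10 het -> 178
  H411: 74 hom + 15 het -> 163
cohort mean M1 count: 185.25
per-base mutation rate over a 3.73e8 bp genome: 5.0e-07
```

Each line's observed homozygous and heterozygous mutation counts are
combined into an estimate of how many mutations the original M1 plant
carried (lost mutations are assumed as numerous as fixed ones); the cohort
mean divided by the assembled genome size gives the induced per-base
mutation rate.

`examples/run_cohort_analysis.py` generates a six-line synthetic cohort,
runs the filter/classify pipeline, and prints type counts, Ti/Tv, InDel
statistics and detected hotspot windows. `examples/annotate_and_map.py`
annotates a cohort and maps a recessive causal mutation through a simulated
F2 population.

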