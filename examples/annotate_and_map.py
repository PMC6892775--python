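"""Variant-effect annotation and bulked-segregant mapping of a causal mutation.

Annotates a generated cohort's mutations against its gene models (feature
category plus coding effect), then maps a recessive trait in a simulated F2
population: chi-square segregation test, bulk-pool marker association, and
screening of high-impact mutations around the associated marker.
"""

import tempfile

from radmut import (
    CohortConfig,
    annotate_mutations,
    candidates_near_marker,
    chi_square_segregation,
    effect_summary,
    pool_association,
    read_vcf_cohort,
    region_distribution,
    run_pipeline,
    simulate_cohort,
    simulate_f2_mapping,
)

config = CohortConfig(seed=7)
with tempfile.TemporaryDirectory() as workdir:
    genome, genes, truth, paths = simulate_cohort(config, workdir)
    cohort = read_vcf_cohort(paths["vcf"], config.wild_type_id)
    result = run_pipeline(cohort, genome)

annotated = annotate_mutations(result.mutations, genes, genome)
print("feature distribution by mutation class (% of class):")
print(region_distribution(annotated).to_string(index=False))

summary = effect_summary(annotated)
print("\ncoding-effect counts:")
print(summary.effects.to_string(index=False))
print("functionally affected genes per line (stop gain/loss or premature-stop"
      " frameshift):")
for line, gene_ids in summary.affected_genes.items():
    print(f"  {line}: {', '.join(gene_ids)}")

# --- BSA mapping of a recessive locus in a simulated F2 population ---
# Treat one line's premature-stop mutation as the causal locus and place the
# nearest SSR marker 30 kb away, the rest on the other chromosome.
causal_mut = next(am.mutation for am in annotated if am.functionally_affected)
causal = (causal_mut.chrom, causal_mut.pos)
other = "chr2" if causal_mut.chrom == "chr1" else "chr1"
markers = [("RM_near", causal_mut.chrom, causal_mut.pos + 30_000)] + [
    (f"RM{i}", other, 400_000 * i) for i in range(1, 6)
]
table, n_dom, n_rec = simulate_f2_mapping(11, markers, causal)
seg = chi_square_segregation(n_dom, n_rec)
print(f"\nF2 segregation {n_dom}:{n_rec}, chi2 = {seg.chi_square:.2f} vs 3:1 "
      f"({'consistent' if seg.consistent else 'rejected'} at alpha 0.05)")
associated = pool_association(table)
print(f"pool-associated markers: {[m.marker_id for m in associated]}")

# High-impact mutations near the associated marker are the causal candidates.
if associated:
    hits = candidates_near_marker(associated[0], annotated, radius=2_000_000)
    print(f"high-impact candidates within 2 Mb of {associated[0].marker_id}:")
    for am in hits[:5]:
        m = am.mutation
        print(f"  {m.line_id} {m.chrom}:{m.pos} {m.ref}>{m.alt} "
              f"{am.effect} in {am.gene_id}")
    if not hits:
        print("  (none in this cohort draw)")
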