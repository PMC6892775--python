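"""The selfing-transmission model and M1 mutation-count back-estimation.

A mutation arising heterozygous in an M1 plant drifts, generation by
generation of selfing, toward fixation (1/4 per generation), stays
heterozygous (1/2), or is lost (1/4). Because fixation and loss are
symmetric, the original M1 count can be back-estimated from a sequenced
descendant line as 2 x homozygous + heterozygous.
"""

from radmut import (
    cohort_mutation_rate,
    estimate_m1,
    generation_probabilities,
    line_estimate,
    simulate_selfing,
)

print("state probabilities by generation (het / hom / lost):")
for g in range(1, 7):
    s = generation_probabilities(g)
    print(f"  M{g}: {s.p_het:.4f} / {s.p_hom:.4f} / {s.p_lost:.4f}")

# Forward simulation agrees with the closed form.
fates = simulate_selfing(100_000, g=6, seed=1)
print("\nsimulated fates at M6 over 100,000 mutations:")
for fate in ("het", "hom", "lost"):
    print(f"  {fate}: {fates.count(fate) / len(fates):.4f}")

# Back-estimation for a four-line cohort sequenced at M6; the per-base rate
# uses the assembled genome length the calls were made against.
counts = [("H404", 93, 16), ("H409", 89, 20), ("H410", 84, 10), ("H411", 74, 15)]
estimates = [line_estimate(line, hom, het, generation=6) for line, hom, het in counts]
print("\nper-line M1 estimates (2 x hom + het):")
for e in estimates:
    print(f"  {e.line_id}: {e.observed_hom} hom + {e.observed_het} het "
          f"-> {e.estimated_m1}")
mean, rate = cohort_mutation_rate(estimates, genome_length=373_000_000)
print(f"cohort mean M1 count: {mean:.2f}")
print(f"per-base mutation rate over a 3.73e8 bp genome: {rate:.1e}")
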