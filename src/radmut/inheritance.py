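"""Selfing-transmission model and M1 mutation-count back-estimation.

A new mutation arises heterozygous in the M1 plant. Under selfing, each
generation a heterozygous mutation becomes homozygous with probability 1/4,
stays heterozygous with probability 1/2, and is lost with probability 1/4;
homozygous and lost are absorbing. Hence at generation g (M_g):

    p_het  = (1/2)^(g-1)
    p_hom  = p_lost = (1 - p_het) / 2

By the symmetry p_hom = p_lost, the number of mutations lost by drift equals
the number fixed, so the original M1 count is back-estimated from an observed
line as 2 x homozygous + heterozygous. The per-base mutation rate divides the
cohort mean of that estimate by the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class GenerationState:
    generation: int
    p_het: float
    p_hom: float
    p_lost: float


@dataclass(frozen=True)
class M1Estimate:
    line_id: str
    observed_hom: int
    observed_het: int
    estimated_m1: int
    generation: Optional[int] = None


def generation_probabilities(g: int) -> GenerationState:
    """Closed-form het/hom/lost probabilities at generation M_g (g >= 1)."""
    if g < 1:
        raise ValueError(f"generation must be >= 1, got {g}")
    p_het = 0.5 ** (g - 1)
    p_abs = (1.0 - p_het) / 2.0
    return GenerationState(generation=g, p_het=p_het, p_hom=p_abs, p_lost=p_abs)


def simulate_selfing(
    n_mutations: int, g: int, seed: int | np.random.Generator
) -> list[str]:
    """Walk ``n_mutations`` independent mutations through g-1 selfing steps.

    Each starts heterozygous in M1 and per generation moves to homozygous
    (1/4), heterozygous (1/2) or lost (1/4), absorbing at hom/lost. Returns
    one fate per mutation: 'het', 'hom' or 'lost'.
    """
    if g < 1:
        raise ValueError(f"generation must be >= 1, got {g}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # 0 = het, 1 = hom, 2 = lost
    state = np.zeros(n_mutations, dtype=np.int8)
    for _ in range(g - 1):
        het = state == 0
        draws = rng.random(int(het.sum()))
        new = np.zeros(draws.shape, dtype=np.int8)
        new[draws < 0.25] = 1
        new[draws >= 0.75] = 2
        state[het] = new
    names = np.array(["het", "hom", "lost"])
    return list(names[state])


def estimate_m1(observed_hom: int, observed_het: int) -> int:
    """Back-estimate the M1 mutation count: 2 x homozygous + heterozygous."""
    if observed_hom < 0 or observed_het < 0:
        raise ValueError("counts must be non-negative")
    return 2 * observed_hom + observed_het


def line_estimate(
    line_id: str, observed_hom: int, observed_het: int, generation: Optional[int] = None
) -> M1Estimate:
    return M1Estimate(
        line_id=line_id,
        observed_hom=observed_hom,
        observed_het=observed_het,
        estimated_m1=estimate_m1(observed_hom, observed_het),
        generation=generation,
    )


def cohort_mutation_rate(
    estimates: Sequence[M1Estimate], genome_length: int
) -> tuple[float, float]:
    """Mean M1 estimate over lines and the per-base mutation rate.

    ``genome_length`` defaults nowhere: pass the assembled genome size the
    cohort was called against (sum of GenomeModel lengths, or an explicit
    assembly size).
    """
    if not estimates:
        raise ValueError("need at least one line estimate")
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    mean_m1 = sum(e.estimated_m1 for e in estimates) / len(estimates)
    return mean_m1, mean_m1 / genome_length
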