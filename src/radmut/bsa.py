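"""Bulked-segregant mapping of a causal mutation.

Three steps mirror the classical workflow for a monogenic recessive trait:
(1) a chi-square test that the F2 phenotype segregation fits the expected
Mendelian ratio (3:1 by default); (2) association of SSR markers with the
trait by comparing the two bulk pools — the recessive pool should be fixed
for the mutant parent's allele at linked markers while the dominant pool
stays mixed; (3) intersection of high-impact mutations (stop gain/loss,
frameshift) with a window around the associated marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .annotate import AnnotatedMutation

HIGH_IMPACT_EFFECTS = frozenset({"nonsense", "stop_lost", "frameshift"})


@dataclass(frozen=True)
class SegregationResult:
    n_dominant_class: int
    n_recessive_class: int
    expected_ratio: tuple[int, int]
    chi_square: float
    p: float
    consistent: bool  # fits the expected ratio at alpha


@dataclass(frozen=True)
class MarkerGenotypes:
    """Bulk-pool consensus genotypes at one marker.

    Alleles are abstract labels drawn from the two parental states, or
    ``"het"`` for a mixed pool call.
    """

    marker_id: str
    chrom: str
    position: int
    parent1_allele: str  # mutant parent
    parent2_allele: str
    pool_r_allele: str  # recessive-phenotype bulk
    pool_d_allele: str  # dominant-phenotype bulk


def chi_square_segregation(
    n_a: int,
    n_b: int,
    ratio: tuple[int, int] = (3, 1),
    alpha: float = 0.05,
) -> SegregationResult:
    """Pearson chi-square (no continuity correction, 1 df) against a:b.

    ``consistent`` is True when p >= alpha, i.e. the observed counts do not
    reject the expected Mendelian ratio.
    """
    total = n_a + n_b
    if total <= 0:
        raise ValueError("need at least one observation")
    a, b = ratio
    exp_a = total * a / (a + b)
    exp_b = total * b / (a + b)
    if exp_a == 0 or exp_b == 0:
        raise ValueError("expected count of zero; ratio terms must be positive")
    chi2 = (n_a - exp_a) ** 2 / exp_a + (n_b - exp_b) ** 2 / exp_b
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationResult(
        n_dominant_class=n_a,
        n_recessive_class=n_b,
        expected_ratio=ratio,
        chi_square=chi2,
        p=p,
        consistent=p >= alpha,
    )


def pool_association(markers: Sequence[MarkerGenotypes]) -> list[MarkerGenotypes]:
    """Markers whose pools separate: R fixed for the mutant allele, D not.

    Monomorphic markers (identical parental alleles) are skipped with a
    warning — they carry no mapping information.
    """
    associated = []
    for mk in markers:
        if mk.parent1_allele == mk.parent2_allele:
            warnings.warn(f"marker {mk.marker_id} monomorphic between parents; skipped",
                          stacklevel=2)
            continue
        if mk.pool_r_allele == mk.parent1_allele and mk.pool_d_allele != mk.pool_r_allele:
            associated.append(mk)
    return associated


def candidates_near_marker(
    marker: MarkerGenotypes,
    annotated: Sequence[AnnotatedMutation],
    radius: int = 2_000_000,
    line_id: Optional[str] = None,
) -> list[AnnotatedMutation]:
    """High-impact mutations within ``radius`` bp of the marker, nearest first.

    Only stop-gain, stop-loss and frameshift effects qualify; restrict to one
    line with ``line_id`` when the annotation covers a whole cohort.
    """
    hits = [
        am
        for am in annotated
        if am.mutation.chrom == marker.chrom
        and abs(am.mutation.pos - marker.position) <= radius
        and am.effect in HIGH_IMPACT_EFFECTS
        and (line_id is None or am.mutation.line_id == line_id)
    ]
    hits.sort(key=lambda am: abs(am.mutation.pos - marker.position))
    return hits
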