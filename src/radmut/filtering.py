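"""Reliable-mutation filtering by variant allele frequency.

A candidate mutation is kept only when exactly one mutant line supports it at
a VAF between 25% and 100% while every other sample — including the wild type
and samples with no call at the site, which count as 0% — stays at or below
10%. Retained variants with VAF >= 75% are called homozygous, the rest
heterozygous. Sites shared by several lines, or present in the wild type,
are set aside as background (pre-existing divergence from the reference,
not mutagenesis).

All VAF boundaries are inclusive on the retaining side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .model import (
    HETEROZYGOUS,
    HOMOZYGOUS,
    CohortCalls,
    Mutation,
    VariantCall,
)


@dataclass(frozen=True)
class FilterConfig:
    """VAF thresholds of the reliable-mutation filter."""

    focal_min_vaf: float = 0.25
    focal_max_vaf: float = 1.0
    other_max_vaf: float = 0.10
    hom_min_vaf: float = 0.75

    def __post_init__(self) -> None:
        if not (
            0.0
            <= self.other_max_vaf
            < self.focal_min_vaf
            <= self.hom_min_vaf
            <= self.focal_max_vaf
            <= 1.0
        ):
            raise ValueError(
                "thresholds must satisfy 0 <= other_max < focal_min <= hom_min <= focal_max <= 1"
            )


def compute_vaf(call: VariantCall) -> float:
    """Alt-read fraction ``alt / (ref + alt)``; 0.0 at zero total depth.

    The zero-depth case arises for non-focal samples with no informative
    reads; it is defined as 0% (with a warning) so such samples can satisfy
    the cross-sample exclusivity requirement.
    """
    total = call.ref_depth + call.alt_depth
    if total == 0:
        warnings.warn(
            f"zero total depth at {call.chrom}:{call.pos} sample {call.sample_id}; VAF := 0",
            stacklevel=2,
        )
        return 0.0
    return call.alt_depth / total


def call_zygosity(vaf: float, config: FilterConfig = FilterConfig()) -> str:
    """Homozygous iff VAF >= the homozygous threshold (inclusive)."""
    if vaf < config.focal_min_vaf:
        raise ValueError(
            f"VAF {vaf} below focal minimum {config.focal_min_vaf}: not a retained mutation"
        )
    return HOMOZYGOUS if vaf >= config.hom_min_vaf else HETEROZYGOUS


def filter_candidates(
    calls: list[VariantCall],
    samples: list[str],
    wild_type_id: str,
    config: FilterConfig = FilterConfig(),
) -> Optional[Mutation]:
    """Apply the exclusivity filter to all calls at one (chrom,pos,ref,alt) site.

    ``calls`` are every sample's call at the site; samples without a call are
    treated as VAF 0. Returns the retained line-private mutation, or None.
    The wild type counts among the "other samples" and can never be focal.
    """
    if not calls:
        return None
    site = calls[0].site
    if any(c.site != site for c in calls):
        raise ValueError("filter_candidates requires calls grouped by one site")
    vafs = {s: 0.0 for s in samples}
    for c in calls:
        if c.sample_id not in vafs:
            raise ValueError(f"sample {c.sample_id!r} not in cohort sample list")
        vafs[c.sample_id] = compute_vaf(c)

    focal = [
        s
        for s in samples
        if s != wild_type_id and config.focal_min_vaf <= vafs[s] <= config.focal_max_vaf
    ]
    if len(focal) != 1:
        return None
    line = focal[0]
    if any(vafs[s] > config.other_max_vaf for s in samples if s != line):
        return None
    chrom, pos, ref, alt = site
    vaf = vafs[line]
    return Mutation(
        line_id=line,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        vaf=vaf,
        zygosity=call_zygosity(vaf, config),
    )


def remove_background(
    retained: list[Mutation],
    cohort: Optional[CohortCalls] = None,
    config: FilterConfig = FilterConfig(),
) -> tuple[list[Mutation], list[Mutation]]:
    """Split retained mutations into line-private and background sets.

    A (chrom,pos,ref,alt) site attributed to more than one line, or carried by
    the wild type above the cross-sample VAF bound, is background. When
    ``cohort`` is given its wild-type calls are consulted; with per-site
    exclusivity filtering already applied these checks are a safety net, so
    the operation is idempotent.
    """
    by_site: dict[tuple[str, int, str, str], list[Mutation]] = {}
    for m in retained:
        by_site.setdefault(m.site, []).append(m)

    wt_sites: set[tuple[str, int, str, str]] = set()
    if cohort is not None:
        for c in cohort.calls:
            if c.sample_id == cohort.wild_type_id and compute_vaf(c) > config.other_max_vaf:
                wt_sites.add(c.site)

    clean: list[Mutation] = []
    background: list[Mutation] = []
    for site, muts in by_site.items():
        if len({m.line_id for m in muts}) > 1 or site in wt_sites:
            background.extend(muts)
        else:
            clean.extend(muts)
    return clean, background


def filter_cohort(
    cohort: CohortCalls, config: FilterConfig = FilterConfig()
) -> tuple[list[Mutation], list[Mutation]]:
    """Run the site filter plus background removal over a whole cohort.

    Returns (clean line-private mutations, background variants). Background
    here means sites rejected by the exclusivity rule because more than one
    sample carried them above the cross-sample bound — i.e. shared variants —
    recorded once per carrying sample; sites failing only the focal window
    (e.g. VAF below 25% everywhere) are dropped silently.
    """
    clean: list[Mutation] = []
    background: list[Mutation] = []
    for site, calls in sorted(cohort.by_site().items()):
        kept = filter_candidates(calls, cohort.samples, cohort.wild_type_id, config)
        if kept is not None:
            clean.append(kept)
            continue
        # Shared site: >1 sample above other_max, at least one in focal range.
        vafs = {c.sample_id: compute_vaf(c) for c in calls}
        above = [s for s, v in vafs.items() if v > config.other_max_vaf]
        focalish = [
            s
            for s, v in vafs.items()
            if config.focal_min_vaf <= v <= config.focal_max_vaf
        ]
        if len(above) > 1 and focalish:
            chrom, pos, ref, alt = site
            for s in focalish:
                background.append(
                    Mutation(
                        line_id=s,
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        vaf=vafs[s],
                        zygosity=call_zygosity(vafs[s], config),
                    )
                )
    clean, more_background = remove_background(clean, cohort, config)
    background.extend(more_background)
    return clean, background
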