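"""End-to-end convenience wrapper: VCF -> filtered, merged, classified mutations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .classify import TypeRules, prepare_line_mutations
from .filtering import FilterConfig, filter_cohort
from .model import CohortCalls, GenomeModel, Mutation


@dataclass
class PipelineResult:
    mutations: list[Mutation]  # classified, line-private
    background: list[Mutation]

    def for_line(self, line_id: str) -> list[Mutation]:
        return [m for m in self.mutations if m.line_id == line_id]


def run_pipeline(
    cohort: CohortCalls,
    genome: Optional[GenomeModel] = None,
    filter_config: FilterConfig = FilterConfig(),
    rules: TypeRules = TypeRules(),
) -> PipelineResult:
    """Filter a cohort's calls, then normalize/merge/classify per line.

    A VCF contig absent from the genome model is a hard error — silently
    dropping it would corrupt every per-chromosome frequency downstream.
    """
    if genome is not None:
        known = set(genome.names)
        for c in cohort.calls:
            if c.chrom not in known:
                raise ValueError(
                    f"VCF contig {c.chrom!r} absent from genome model; "
                    "frequencies would be miscalculated"
                )
    clean, background = filter_cohort(cohort, filter_config)
    out: list[Mutation] = []
    for line in cohort.mutant_lines:
        line_muts = [m for m in clean if m.line_id == line]
        out.extend(prepare_line_mutations(line_muts, genome, rules))
    out.sort(key=lambda m: (m.chrom, m.pos, m.line_id))
    return PipelineResult(mutations=out, background=background)
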