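"""Variant normalization, MNV merging, and mutation-type classification.

Types follow the size conventions of radiation-mutagenesis resequencing
studies: an insertion/deletion of 1-10 bp is an InDel, more than 50 bp is a
structural variant (SV), and substitutions at strictly consecutive bases are
one multi-nucleotide variant (MNV). The 11-50 bp gap these definitions leave
open is surfaced as an explicit "unclassified" bucket rather than silently
lumped, so class totals stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .model import HOMOZYGOUS, HETEROZYGOUS, GenomeModel, Mutation


@dataclass(frozen=True)
class TypeRules:
    indel_min: int = 1
    indel_max: int = 10
    sv_min: int = 51  # "more than 50 bp"
    mnv_min_run: int = 2

    def __post_init__(self) -> None:
        if self.indel_max >= self.sv_min:
            raise ValueError("indel_max must be below sv_min")


def normalize_variant(m: Mutation, genome: Optional[GenomeModel] = None) -> Mutation:
    """Trim shared REF/ALT padding and left-align indels.

    Shared trailing then leading bases are trimmed, keeping the VCF-style
    leading anchor base for pure insertions/deletions. When ``genome``
    carries sequence, pure indels are shifted left through repeat tracts to a
    canonical position. Raises if REF equals ALT after trimming.
    """
    ref, alt, pos = m.ref, m.alt, m.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise ValueError(f"variant at {m.chrom}:{m.pos} is a no-op after trimming")
    # Drop a remaining shared anchor for equal-length substitutions.
    if len(ref) > 1 and len(alt) == len(ref) and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1

    if genome is not None and genome.sequence is not None:
        is_del = len(alt) == 1 and len(ref) > 1 and ref[0] == alt[0]
        is_ins = len(ref) == 1 and len(alt) > 1 and ref[0] == alt[0]
        if is_del or is_ins:
            allele = ref[1:] if is_del else alt[1:]
            # Shift left while the current anchor base equals the allele's
            # last base (rotation through a repeat tract).
            while pos > 1:
                anchor = genome.fetch(m.chrom, pos, pos)
                if anchor != allele[-1]:
                    break
                allele = anchor + allele[:-1]
                pos -= 1
                new_anchor = genome.fetch(m.chrom, pos, pos)
                if is_del:
                    ref, alt = new_anchor + allele, new_anchor
                else:
                    ref, alt = new_anchor, new_anchor + allele
    return replace(m, pos=pos, ref=ref, alt=alt)


def _is_snv(m: Mutation) -> bool:
    return len(m.ref) == 1 and len(m.alt) == 1


def merge_mnv(mutations: list[Mutation]) -> list[Mutation]:
    """Merge runs of single-base substitutions at consecutive positions.

    Operates within one line: maximal runs of SNVs at strictly adjacent
    positions (pos, pos+1, ...) on the same chromosome become one MNV record
    spanning the run. The merged record is homozygous only if every member
    is; its VAF is the member mean. Other records pass through unchanged.
    Duplicate positions within the line are an error.
    """
    lines = {m.line_id for m in mutations}
    if len(lines) > 1:
        raise ValueError(f"merge_mnv operates within one line, got {sorted(lines)}")
    snvs = sorted((m for m in mutations if _is_snv(m)), key=lambda m: (m.chrom, m.pos))
    others = [m for m in mutations if not _is_snv(m)]

    seen: set[tuple[str, int]] = set()
    for m in snvs:
        key = (m.chrom, m.pos)
        if key in seen:
            raise ValueError(f"duplicate substitution at {m.chrom}:{m.pos} in one line")
        seen.add(key)

    merged: list[Mutation] = []
    run: list[Mutation] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            merged.append(run[0])
        else:
            first = run[0]
            merged.append(
                Mutation(
                    line_id=first.line_id,
                    chrom=first.chrom,
                    pos=first.pos,
                    ref="".join(m.ref for m in run),
                    alt="".join(m.alt for m in run),
                    vaf=sum(m.vaf for m in run) / len(run),
                    zygosity=HOMOZYGOUS
                    if all(m.zygosity == HOMOZYGOUS for m in run)
                    else HETEROZYGOUS,
                )
            )
        run.clear()

    for m in snvs:
        if run and m.chrom == run[-1].chrom and m.pos == run[-1].pos + 1:
            run.append(m)
        else:
            flush()
            run.append(m)
    flush()
    out = merged + others
    out.sort(key=lambda m: (m.chrom, m.pos))
    return out


def classify(m: Mutation, rules: TypeRules = TypeRules()) -> str:
    """Assign SBS / MNV / InDel / SV / unclassified by span and net length."""
    size = abs(m.length)
    if m.length == 0:
        return "SBS" if m.span == 1 else "MNV"
    if rules.indel_min <= size <= rules.indel_max:
        return "InDel"
    if size >= rules.sv_min:
        return "SV"
    return "unclassified"


def classify_all(mutations: list[Mutation], rules: TypeRules = TypeRules()) -> list[Mutation]:
    return [m.with_class(classify(m, rules)) for m in mutations]


def prepare_line_mutations(
    mutations: list[Mutation],
    genome: Optional[GenomeModel] = None,
    rules: TypeRules = TypeRules(),
) -> list[Mutation]:
    """Normalize, MNV-merge and classify one line's filtered mutations."""
    normed = [normalize_variant(m, genome) for m in mutations]
    return classify_all(merge_mnv(normed), rules)
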