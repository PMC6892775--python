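"""Genomic-feature assignment and coding-effect prediction.

Each mutation gets exactly one feature category — coding exon, splice region,
5'/3' UTR, intron, upstream, downstream or intergenic — using a fixed
precedence when several genes overlap the position:

    exon > splice_region > UTR5/UTR3 > intron > upstream > downstream > intergenic

Upstream/downstream windows are measured from the transcript ends respecting
strand (default 5 kb each side). For coding variants the effect is evaluated
on the coding strand with the standard genetic code: silent, missense,
nonsense (stop gained), stop_lost for substitutions; frameshift or
inframe_indel for InDels. A gene is "functionally affected" by stop gain,
stop loss, or a frameshift that introduces a premature stop before the
reference terminus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .model import GeneModel, GenomeModel, Mutation
from .spectrum import round_half_up

FEATURES = (
    "exon",
    "splice_region",
    "UTR5",
    "UTR3",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)

_PRECEDENCE = {
    "exon": 0,
    "splice_region": 1,
    "UTR5": 2,
    "UTR3": 2,
    "intron": 3,
    "upstream": 4,
    "downstream": 5,
    "intergenic": 6,
}

EFFECTS = (
    "missense",
    "nonsense",
    "stop_lost",
    "silent",
    "frameshift",
    "inframe_indel",
    "noncoding",
    "NA",
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnnotationConfig:
    upstream_bp: int = 5_000
    downstream_bp: int = 5_000
    splice_bp: int = 2

    def __post_init__(self) -> None:
        if min(self.upstream_bp, self.downstream_bp, self.splice_bp) <= 0:
            raise ValueError("annotation windows must be positive")


@dataclass
class AnnotatedMutation:
    mutation: Mutation
    feature: str
    gene_id: Optional[str]
    effect: str = "NA"
    functionally_affected: bool = False


def _feature_within_gene(pos: int, gene: GeneModel, config: AnnotationConfig) -> Optional[str]:
    """Feature for a position relative to one gene, or None if out of reach."""
    if gene.tx_start <= pos <= gene.tx_end:
        in_exon = any(s <= pos <= e for s, e in gene.exons)
        if in_exon:
            if not gene.coding:
                return "exon"
            if gene.cds_start <= pos <= gene.cds_end:
                return "exon"
            # Non-coding exon territory: UTR, sided by strand.
            before_cds = pos < gene.cds_start
            if gene.strand == "+":
                return "UTR5" if before_cds else "UTR3"
            return "UTR3" if before_cds else "UTR5"
        # Intronic: splice region if within splice_bp of an exon edge.
        for s, e in gene.exons:
            if 0 < s - pos <= config.splice_bp or 0 < pos - e <= config.splice_bp:
                return "splice_region"
        return "intron"
    if gene.strand == "+":
        if 0 < gene.tx_start - pos <= config.upstream_bp:
            return "upstream"
        if 0 < pos - gene.tx_end <= config.downstream_bp:
            return "downstream"
    else:
        if 0 < pos - gene.tx_end <= config.upstream_bp:
            return "upstream"
        if 0 < gene.tx_start - pos <= config.downstream_bp:
            return "downstream"
    return None


def assign_feature(
    m: Mutation,
    genes: Sequence[GeneModel],
    config: AnnotationConfig = AnnotationConfig(),
) -> tuple[str, Optional[str]]:
    """Best (feature, gene_id) for a mutation's start position.

    When several genes claim the position, the fixed precedence decides; ties
    break on gene id for determinism. A position claimed by no gene is
    intergenic.
    """
    best: tuple[int, str, Optional[str]] = (_PRECEDENCE["intergenic"], "intergenic", None)
    for gene in genes:
        if gene.chrom != m.chrom:
            continue
        feat = _feature_within_gene(m.pos, gene, config)
        if feat is None:
            continue
        key = (_PRECEDENCE[feat], feat, gene.gene_id)
        if key[0] < best[0] or (key[0] == best[0] and best[2] is not None and key[2] < best[2]):
            best = key
    return best[1], best[2]


def _cds_map(gene: GeneModel, genome: GenomeModel) -> tuple[list[int], str]:
    """CDS chromosome positions and sequence, both in transcription order."""
    positions: list[int] = []
    for s, e in gene.cds_intervals():
        positions.extend(range(s, e + 1))
    seq = "".join(genome.sequence[gene.chrom][p - 1] for p in positions)
    if gene.strand == "-":
        positions = positions[::-1]
        seq = _revcomp(seq)
    return positions, seq


def _apply_to_cds(
    m: Mutation, positions: list[int], cds_seq: str, strand: str
) -> str:
    """Apply a variant to the CDS sequence in transcription order."""
    index_of = {p: i for i, p in enumerate(positions)}
    seq = list(cds_seq)
    if m.length == 0:  # substitution (possibly multi-base)
        for offset, base in enumerate(m.alt):
            p = m.pos + offset
            if p in index_of:
                seq[index_of[p]] = base if strand == "+" else base.translate(_COMPLEMENT)
        return "".join(seq)
    if m.length < 0:  # deletion: ref = anchor + deleted bases
        doomed = {m.pos + 1 + i for i in range(-m.length)}
        return "".join(b for p, b in zip(positions, cds_seq) if p not in doomed)
    # Insertion: alt = anchor + inserted bases, between m.pos and m.pos + 1.
    ins = m.alt[len(m.ref):]
    if m.pos not in index_of:
        return cds_seq
    i = index_of[m.pos]
    if strand == "+":
        return cds_seq[: i + 1] + ins + cds_seq[i + 1 :]
    return cds_seq[:i] + _revcomp(ins) + cds_seq[i:]


def predict_effect(
    m: Mutation, genome: GenomeModel, gene: GeneModel
) -> tuple[str, bool]:
    """Effect of a CDS mutation and whether it functionally affects the gene.

    Substitutions are judged codon-by-codon on the coding strand; InDels by
    net length modulo 3, with frameshifts retranslated to test for a
    premature stop. Returns (effect, functionally_affected).
    """
    if not gene.coding:
        return "noncoding", False
    positions, cds_seq = _cds_map(gene, genome)
    if len(cds_seq) % 3 != 0:
        warnings.warn(f"CDS length of {gene.gene_id} not divisible by 3", stacklevel=2)
        return "NA", False
    ref_protein = str(Seq(cds_seq).translate())

    if m.length == 0:
        mut_seq = _apply_to_cds(m, positions, cds_seq, gene.strand)
        index_of = {p: i for i, p in enumerate(positions)}
        codons = sorted(
            {
                index_of[m.pos + off] // 3
                for off in range(len(m.ref))
                if (m.pos + off) in index_of
            }
        )
        if not codons:
            return "NA", False
        effect = "silent"
        for ci in codons:
            ref_codon = cds_seq[3 * ci : 3 * ci + 3]
            alt_codon = mut_seq[3 * ci : 3 * ci + 3]
            ref_aa = str(Seq(ref_codon).translate())
            alt_aa = str(Seq(alt_codon).translate())
            if ref_aa == alt_aa:
                continue
            if ref_aa == "*":
                return "stop_lost", True
            if alt_aa == "*":
                return "nonsense", True
            effect = "missense"
        return effect, False

    if m.length % 3 == 0:
        return "inframe_indel", False
    mut_seq = _apply_to_cds(m, positions, cds_seq, gene.strand)
    mut_protein = str(Seq(mut_seq[: 3 * (len(mut_seq) // 3)]).translate())
    stop_at = mut_protein.find("*")
    ref_stop_at = ref_protein.find("*")
    ref_terminus = ref_stop_at if ref_stop_at >= 0 else len(ref_protein)
    premature = 0 <= stop_at < ref_terminus
    return "frameshift", premature


def annotate_mutations(
    mutations: Iterable[Mutation],
    genes: Sequence[GeneModel],
    genome: Optional[GenomeModel] = None,
    config: AnnotationConfig = AnnotationConfig(),
) -> list[AnnotatedMutation]:
    """Assign features to all mutations, predicting effects where possible."""
    gene_by_id = {g.gene_id: g for g in genes}
    out: list[AnnotatedMutation] = []
    for m in mutations:
        feature, gene_id = assign_feature(m, genes, config)
        am = AnnotatedMutation(mutation=m, feature=feature, gene_id=gene_id)
        if (
            feature == "exon"
            and gene_id is not None
            and genome is not None
            and genome.sequence is not None
        ):
            gene = gene_by_id[gene_id]
            am.effect, am.functionally_affected = predict_effect(m, genome, gene)
        elif feature == "exon" and gene_id is not None and not gene_by_id[gene_id].coding:
            am.effect = "noncoding"
        out.append(am)
    return out


@dataclass
class EffectSummary:
    effects: pd.DataFrame  # treatment x {missense, nonsense, silent} counts + percent
    affected_genes: dict[str, list[str]]  # line -> sorted gene ids


def effect_summary(
    annotated: Sequence[AnnotatedMutation],
    treatment_of: Optional[Mapping[str, str]] = None,
) -> EffectSummary:
    """Coding-effect counts/percentages per treatment plus affected genes per line.

    Percentages are computed from the counts (missense + nonsense + silent
    denominators), not copied from anywhere; lines with no coding mutations
    simply contribute nothing.
    """
    rows: dict[str, dict[str, int]] = {}
    affected: dict[str, set[str]] = {}
    for am in annotated:
        line = am.mutation.line_id
        treatment = treatment_of.get(line, "all") if treatment_of else "all"
        if am.effect in {"missense", "nonsense", "silent"}:
            row = rows.setdefault(treatment, {"missense": 0, "nonsense": 0, "silent": 0})
            row[am.effect] += 1
        if am.functionally_affected and am.gene_id is not None:
            affected.setdefault(line, set()).add(am.gene_id)
    records = []
    for treatment, row in sorted(rows.items()):
        total = sum(row.values())
        rec = {"treatment": treatment, **row, "total": total}
        for eff in ("missense", "nonsense", "silent"):
            rec[f"{eff}_pct"] = round_half_up(100.0 * row[eff] / total, 2) if total else 0.0
        records.append(rec)
    effects = pd.DataFrame(
        records,
        columns=[
            "treatment",
            "missense",
            "nonsense",
            "silent",
            "total",
            "missense_pct",
            "nonsense_pct",
            "silent_pct",
        ],
    )
    return EffectSummary(
        effects=effects,
        affected_genes={line: sorted(g) for line, g in affected.items()},
    )


def region_distribution(
    annotated: Sequence[AnnotatedMutation],
    treatment_of: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Percentage of mutations per feature, split by class and treatment."""
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for am in annotated:
        m = am.mutation
        treatment = treatment_of.get(m.line_id, "all") if treatment_of else "all"
        key = (treatment, m.mclass or "unclassified")
        row = counts.setdefault(key, {f: 0 for f in FEATURES})
        row[am.feature] += 1
    records = []
    for (treatment, mclass), row in sorted(counts.items()):
        total = sum(row.values())
        rec = {"treatment": treatment, "class": mclass, "n": total}
        for f in FEATURES:
            rec[f] = round_half_up(100.0 * row[f] / total, 2) if total else 0.0
        records.append(rec)
    return pd.DataFrame(records, columns=["treatment", "class", "n", *FEATURES])
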