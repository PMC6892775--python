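"""Shared domain types for the mutation-analysis pipeline.

All genomic coordinates in this package are 1-based inclusive, matching VCF
and GFF3. The single exception is BED export, which is 0-based half-open
(see :mod:`radmut.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

DNA_ALPHABET = frozenset("ACGT")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: Mutation classes used throughout: single-base substitution, multi-nucleotide
#: variant (consecutive substituted bases), small insertion/deletion (1-10 bp),
#: structural variant (>50 bp), plus an explicit bucket for the 11-50 bp gap
#: the size definitions leave open.
MUTATION_CLASSES = ("SBS", "MNV", "InDel", "SV", "unclassified")

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"


def _check_dna(s: str, what: str) -> None:
    if not s or not set(s) <= DNA_ALPHABET:
        raise ValueError(f"{what} must be a non-empty uppercase DNA string, got {s!r}")


@dataclass(frozen=True)
class VariantCall:
    """One per-sample called variant with read support.

    ``ref_depth`` and ``alt_depth`` are the allele depths (VCF ``AD``) from
    which the variant allele frequency is computed; ``pos`` is the 1-based
    position of the first REF base.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        _check_dna(self.ref, "ref")
        _check_dna(self.alt, "alt")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("allele depths must be non-negative")

    @property
    def site(self) -> tuple[str, int, str, str]:
        """The (chrom, pos, ref, alt) key identifying the variant allele."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GenomeModel:
    """Chromosome names and lengths, optionally with sequence.

    The declared lengths are the denominator of every per-chromosome and
    genome-wide frequency; sequence is required only for flanking-context and
    coding-effect analyses.
    """

    chromosomes: list[tuple[str, int]]
    sequence: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        if self.sequence is not None:
            for name, length in self.chromosomes:
                seq = self.sequence.get(name)
                if seq is None:
                    raise ValueError(f"sequence missing for chromosome {name}")
                if len(seq) != length:
                    raise ValueError(
                        f"chromosome {name}: declared length {length} != sequence length {len(seq)}"
                    )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of [start, end], 1-based inclusive."""
        if self.sequence is None:
            raise ValueError("GenomeModel carries no sequence")
        if chrom not in self.lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self.sequence[chrom][start - 1 : end]


@dataclass
class GeneModel:
    """A stranded gene (one transcript) with exon/CDS structure.

    ``exons`` are 1-based inclusive (start, end) intervals sorted along the
    chromosome regardless of strand; ``cds_start``/``cds_end`` delimit the
    coding span in chromosome coordinates, or are None for non-coding genes.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon ({s},{e}) inverted in {self.gene_id}")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"exon ({s},{e}) outside transcript span in {self.gene_id}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"exons overlap or unsorted in {self.gene_id}")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"partial CDS interval in {self.gene_id}")
        if self.cds_start is not None:
            if not any(s <= self.cds_start <= e for s, e in self.exons) or not any(
                s <= self.cds_end <= e for s, e in self.exons
            ):
                raise ValueError(f"CDS boundary outside exons in {self.gene_id}")

    @property
    def coding(self) -> bool:
        return self.cds_start is not None

    def cds_intervals(self) -> list[tuple[int, int]]:
        """Exon pieces intersected with the CDS span, in chromosome order."""
        if not self.coding:
            return []
        out = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                out.append((lo, hi))
        return out


@dataclass(frozen=True)
class Mutation:
    """A filtered, line-private mutation with VAF-derived zygosity.

    ``length`` is the net base-count change: insertions positive, deletions
    negative, substitutions zero. ``mclass`` is assigned by the classifier
    (:mod:`radmut.classify`) and is None until then.
    """

    line_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    zygosity: str
    mclass: Optional[str] = None

    def __post_init__(self) -> None:
        _check_dna(self.ref, "ref")
        _check_dna(self.alt, "alt")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.zygosity not in {HOMOZYGOUS, HETEROZYGOUS}:
            raise ValueError(f"bad zygosity {self.zygosity!r}")

    @property
    def length(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def span(self) -> int:
        """Number of reference bases the event covers."""
        return len(self.ref)

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference span."""
        return self.pos + len(self.ref) - 1

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def with_class(self, mclass: str) -> "Mutation":
        return replace(self, mclass=mclass)


@dataclass
class CohortCalls:
    """All per-sample variant calls read from a multi-sample VCF."""

    calls: list[VariantCall]
    samples: list[str]
    wild_type_id: str

    def __post_init__(self) -> None:
        if self.wild_type_id not in self.samples:
            raise ValueError(f"wild-type sample {self.wild_type_id!r} not among samples")

    @property
    def mutant_lines(self) -> list[str]:
        return [s for s in self.samples if s != self.wild_type_id]

    def by_site(self) -> dict[tuple[str, int, str, str], list[VariantCall]]:
        grouped: dict[tuple[str, int, str, str], list[VariantCall]] = {}
        for c in self.calls:
            grouped.setdefault(c.site, []).append(c)
        return grouped
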