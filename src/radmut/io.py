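"""Readers and writers for the standard formats the pipeline touches.

VCF is read through pysam, FASTA through Biopython and GFF3 through gffutils;
results are returned in the package's own containers (:mod:`radmut.model`).
TSV reports use a fixed, documented column order; genomic regions are also
exported as BED (0-based half-open).
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO

from .model import CohortCalls, GeneModel, GenomeModel, Mutation, VariantCall

MUTATION_COLUMNS = [
    "line",
    "chrom",
    "pos",
    "ref",
    "alt",
    "class",
    "length",
    "zygosity",
    "vaf",
]


def read_vcf_cohort(path: str | os.PathLike, wild_type_id: str) -> CohortCalls:
    """Read a multi-sample VCF into per-sample :class:`VariantCall` records.

    Requires the FORMAT ``AD`` field (ref,alt allele depths). Multi-allelic
    records are split into biallelic calls, one per alt allele. A sample emits
    a call for an alt allele when it has at least one supporting read or a
    genotype carrying that allele; samples with zero support emit nothing.

    Raises ``ValueError`` if ``AD`` is missing on a record or the wild-type
    sample is absent from the header.
    """
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        if wild_type_id not in samples:
            raise ValueError(
                f"wild-type sample {wild_type_id!r} absent from VCF header (has {samples})"
            )
        calls: list[VariantCall] = []
        for rec in vcf:
            alts = rec.alts or ()
            for sample in samples:
                sd = rec.samples[sample]
                ad = sd.get("AD")
                if ad is None or all(a is None for a in ad):
                    raise ValueError(
                        f"record {rec.chrom}:{rec.pos} sample {sample}: FORMAT AD missing"
                    )
                gt = sd.get("GT") or ()
                for ai, alt in enumerate(alts, start=1):
                    if alt is None:
                        continue
                    alt_depth = int(ad[ai]) if ai < len(ad) and ad[ai] is not None else 0
                    ref_depth = int(ad[0]) if ad[0] is not None else 0
                    in_gt = ai in {a for a in gt if a is not None}
                    if alt_depth >= 1 or in_gt:
                        calls.append(
                            VariantCall(
                                sample_id=sample,
                                chrom=rec.chrom,
                                pos=rec.pos,
                                ref=rec.ref.upper(),
                                alt=str(alt).upper(),
                                ref_depth=ref_depth,
                                alt_depth=alt_depth,
                            )
                        )
    return CohortCalls(calls=calls, samples=samples, wild_type_id=wild_type_id)


def read_fasta(path: str | os.PathLike) -> GenomeModel:
    """Read a FASTA file into a :class:`GenomeModel` with uppercased sequence."""
    chromosomes: list[tuple[str, int]] = []
    sequence: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in sequence:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        sequence[rec.id] = seq
        chromosomes.append((rec.id, len(seq)))
    return GenomeModel(chromosomes=chromosomes, sequence=sequence)


def read_gff(path: str | os.PathLike) -> list[GeneModel]:
    """Read GFF3 gene models (one :class:`GeneModel` per mRNA).

    Exon and CDS intervals are kept 1-based inclusive as in GFF3. An mRNA
    whose CDS falls outside its exon union is rejected.
    """
    db = gffutils.create_db(
        os.fspath(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not exons:
            exons = [(mrna.start, mrna.end)]
        cds_start = cds_end = None
        if cds:
            cds_start, cds_end = cds[0][0], cds[-1][1]
            for cs, ce in cds:
                if not any(es <= cs and ce <= ee for es, ee in exons):
                    raise ValueError(
                        f"CDS ({cs},{ce}) outside exons for {mrna.id}"
                    )
        genes.append(
            GeneModel(
                gene_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                tx_start=mrna.start,
                tx_end=mrna.end,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return genes


def mutations_to_table(mutations: Iterable[Mutation]) -> pd.DataFrame:
    """Classified-mutation table with the package's fixed column order."""
    rows = [
        {
            "line": m.line_id,
            "chrom": m.chrom,
            "pos": m.pos,
            "ref": m.ref,
            "alt": m.alt,
            "class": m.mclass,
            "length": m.length,
            "zygosity": m.zygosity,
            "vaf": m.vaf,
        }
        for m in mutations
    ]
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def write_mutations_tsv(mutations: Iterable[Mutation], path: str | os.PathLike) -> None:
    mutations_to_table(mutations).to_csv(path, sep="\t", index=False)


def read_mutations_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "line": str})


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def regions_to_bed(
    regions: Sequence[tuple[str, int, int]],
    path: str | os.PathLike,
    names: Optional[Sequence[str]] = None,
) -> None:
    """Write 1-based inclusive (chrom, start, end) regions as BED.

    BED is 0-based half-open, so a 1-bp feature at position p becomes
    ``p-1\tp``.
    """
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(regions):
            fields = [chrom, str(start - 1), str(end)]
            if names is not None:
                fields.append(str(names[i]))
            fh.write("\t".join(fields) + "\n")


def write_tables(
    mutations: Iterable[Mutation],
    out_dir: str | os.PathLike,
    background: Optional[Iterable[Mutation]] = None,
) -> dict[str, str]:
    """Write the standard report tables under ``out_dir``; returns the paths."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {"mutations": os.path.join(out_dir, "mutations.tsv")}
    write_mutations_tsv(mutations, paths["mutations"])
    if background is not None:
        paths["background"] = os.path.join(out_dir, "background.tsv")
        write_mutations_tsv(background, paths["background"])
    return paths
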