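"""Synthetic mutant-cohort generator with known ground truth.

Emulates the statistical structure a radiation-mutagenesis resequencing
analysis assumes: a toy genome with engineered gene models, a cohort of
mutant lines each carrying line-private mutations drawn from configurable
type/spectrum mixtures (SBS transition:transversion mix, InDel length
distribution with deletion excess, consecutive-base MNVs, optional >50 bp
SVs), shared background variants present in every sample including the wild
type, optional hotspot windows with multiplied mutation rates, zygosity
states produced by g generations of selfing, and binomially sampled read
support around the true allele fractions.

MNVs are written to the VCF as separate single-base records at consecutive
positions — the form per-base callers emit — so the analysis pipeline's
merging step is exercised against truth. Every generator output is
deterministic under a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bsa import MarkerGenotypes
from .inheritance import simulate_selfing
from .model import GeneModel, GenomeModel, Mutation
from .classify import normalize_variant

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class CohortConfig:
    """Study conditions the generator emulates.

    Defaults follow the observed cohort structure of radiation-mutagenized
    rice lines: six lines, ~100 mutations per line, a type mix dominated by
    SBSs with a quarter InDels and no SVs, Ti/Tv 2.22, deletion-heavy InDels,
    read depth ~30x, and four generations of selfing before sequencing.
    """

    n_lines: int = 6
    chrom_lengths: list[int] = field(default_factory=lambda: [5_000_000, 3_000_000])
    per_line_mutation_count: float = 100.0  # Poisson mean
    type_mix: tuple[float, float, float, float] = (0.62, 0.13, 0.25, 0.0)  # SBS, MNV, InDel, SV
    titv_ratio: float = 2.22
    indel_deletion_fraction: float = 0.83
    indel_length_distribution: Optional[Sequence[float]] = None  # over 1..10 bp
    mnv_length_distribution: Sequence[float] = (0.70, 0.20, 0.07, 0.03)  # over 2..5 bp
    hotspot_windows: list[tuple[str, int, int, float]] = field(default_factory=list)
    n_background: int = 50
    generations: int = 4  # M_g sampled; g >= 2
    mean_depth: float = 30.0
    seed: int = 0
    genes_per_chrom: int = 15
    wild_type_id: str = "WT"

    def __post_init__(self) -> None:
        if self.generations < 2:
            raise ValueError("generations must be >= 2 (mutations arise in M1)")
        if self.indel_length_distribution is None:
            w = np.array([0.65 ** k for k in range(10)])
            self.indel_length_distribution = tuple(w / w.sum())
        for name, probs in [
            ("type_mix", self.type_mix),
            ("indel_length_distribution", self.indel_length_distribution),
            ("mnv_length_distribution", self.mnv_length_distribution),
        ]:
            arr = np.asarray(probs, dtype=float)
            if (arr < 0).any() or not np.isclose(arr.sum(), 1.0):
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if not 0.0 <= self.indel_deletion_fraction <= 1.0:
            raise ValueError("indel_deletion_fraction must be in [0,1]")
        if self.titv_ratio <= 0 or self.mean_depth <= 0:
            raise ValueError("titv_ratio and mean_depth must be positive")

    @property
    def line_ids(self) -> list[str]:
        return [f"line{i + 1}" for i in range(self.n_lines)]

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass(frozen=True)
class TrueMutation:
    line_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mtype: str  # SBS, MNV, InDel, SV
    fate: str  # het, hom, lost

    @property
    def observable(self) -> bool:
        return self.fate != "lost"

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CohortTruth:
    """Ground truth for recovery testing: per-line mutations + shared background."""

    per_line: dict[str, list[TrueMutation]]
    background: list[tuple[str, int, str, str]]

    def observable(self, line_id: str) -> list[TrueMutation]:
        return [m for m in self.per_line[line_id] if m.observable]

    def all_observable(self) -> list[TrueMutation]:
        return [m for line in self.per_line.values() for m in line if m.observable]


def _engineer_gene(
    seq: list[str], start: int, strand: str, gene_id: str, chrom: str, rng: np.random.Generator
) -> GeneModel:
    """Write a 3-exon coding gene into the sequence and return its model.

    The CDS is built from stop-free random codons plus a terminal stop so
    coding-effect prediction sees a clean open reading frame. Exon pieces
    (chromosome order): 300 / 420 / 303 bp with UTRs of 99 bp at each
    transcript end; introns 500 and 600 bp.
    """
    e1 = (start, start + 299)
    e2 = (start + 800, start + 1219)
    e3 = (start + 1820, start + 2122)
    tx_start, tx_end = e1[0], e3[1]
    cds_start = e1[0] + 99  # 99 bp 5' UTR on the + strand reading
    cds_end = e3[1] - 99
    # CDS pieces: (300-99) + 420 + (303-99) = 201 + 420 + 204 = 825 = 275 codons
    cds_positions: list[int] = []
    for s, e in [e1, e2, e3]:
        lo, hi = max(s, cds_start), min(e, cds_end)
        cds_positions.extend(range(lo, hi + 1))
    n_codons = len(cds_positions) // 3
    codons = []
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(_BASES, 3))
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    coding = "ATG" + "".join(codons[: n_codons - 2]) + "TAA"
    if strand == "-":
        coding = coding.translate(_COMPLEMENT)[::-1]
    for p, base in zip(cds_positions, coding):
        seq[p - 1] = base
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        exons=[e1, e2, e3],
        cds_start=cds_start,
        cds_end=cds_end,
    )


def simulate_genome(config: CohortConfig) -> tuple[GenomeModel, list[GeneModel]]:
    """Uniform-random DNA with regularly tiled, well-separated coding genes.

    Genes are spaced so that each one's 5 kb upstream/downstream flanks are
    free of neighbours by at least twice the flank size, keeping feature
    assignment unambiguous. Raises if a chromosome is too small for the
    requested gene count.
    """
    rng = config.rng(0)
    sequence: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_span = 2_123
    min_spacing = gene_span + 4 * 5_000
    for chrom, length in zip(config.chrom_names, config.chrom_lengths):
        seq = list(rng.choice(_BASES, length))
        if config.genes_per_chrom > 0:
            spacing = length // config.genes_per_chrom
            if spacing < min_spacing:
                raise ValueError(
                    f"{chrom}: length {length} too small for {config.genes_per_chrom} genes "
                    f"(needs >= {min_spacing} bp per gene)"
                )
            for i in range(config.genes_per_chrom):
                start = i * spacing + spacing // 3
                strand = "+" if i % 2 == 0 else "-"
                genes.append(
                    _engineer_gene(seq, start, strand, f"{chrom}_g{i + 1}", chrom, rng)
                )
        sequence[chrom] = "".join(seq)
    genome = GenomeModel(
        chromosomes=list(zip(config.chrom_names, config.chrom_lengths)),
        sequence=sequence,
    )
    return genome, genes


def _position_segments(
    config: CohortConfig, genome: GenomeModel
) -> tuple[list[tuple[str, int, int]], np.ndarray]:
    """Split chromosomes at hotspot boundaries; weight = span x multiplier."""
    lengths = genome.lengths
    for chrom, start, end, _ in config.hotspot_windows:
        if chrom not in lengths or start < 1 or end > lengths[chrom] or start > end:
            raise ValueError(f"hotspot window {chrom}:{start}-{end} outside genome")
    segments: list[tuple[str, int, int]] = []
    weights: list[float] = []
    for chrom, length in genome.chromosomes:
        cuts = sorted(
            (start, end, mult)
            for c, start, end, mult in config.hotspot_windows
            if c == chrom
        )
        cursor = 1
        for start, end, mult in cuts:
            if start > cursor:
                segments.append((chrom, cursor, start - 1))
                weights.append(start - cursor)
            segments.append((chrom, start, end))
            weights.append((end - start + 1) * mult)
            cursor = end + 1
        if cursor <= length:
            segments.append((chrom, cursor, length))
            weights.append(length - cursor + 1)
    w = np.asarray(weights, dtype=float)
    return segments, w / w.sum()


class _Placer:
    """Draws event positions, keeping events apart so sites never overlap."""

    PAD = 15

    def __init__(self, segments, probs, genome: GenomeModel, rng: np.random.Generator):
        self.segments = segments
        self.probs = probs
        self.genome = genome
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def draw(self, span: int) -> tuple[str, int]:
        lengths = self.genome.lengths
        for _ in range(10_000):
            i = self.rng.choice(len(self.segments), p=self.probs)
            chrom, lo, hi = self.segments[i]
            pos = int(self.rng.integers(lo, hi + 1))
            if pos < 2 or pos + span + 1 > lengths[chrom]:
                continue
            cells = {(chrom, (pos + d) // self.PAD) for d in range(-self.PAD, span + self.PAD)}
            if cells & self.used:
                continue
            self.used |= cells
            return chrom, pos
        raise RuntimeError("could not place mutation; genome too crowded")


def _draw_sbs_alt(ref: str, titv: float, rng: np.random.Generator) -> str:
    if rng.random() < titv / (1.0 + titv):
        return _TRANSITION[ref]
    return _TRANSVERSIONS[ref][int(rng.integers(2))]


def simulate_line_mutations(
    config: CohortConfig, genome: GenomeModel
) -> CohortTruth:
    """Draw each line's private mutations plus shared background variants.

    Per line the count is Poisson; positions are uniform except inside
    hotspot windows, whose rates are multiplied; SBS alternates realize the
    configured Ti/Tv in expectation; InDel lengths follow the configured
    distribution with the configured deletion excess; MNVs substitute 2-5
    consecutive bases. Each mutation's zygosity fate at generation g comes
    from the selfing chain; lost mutations stay in the truth with fate
    "lost" but are not observable.
    """
    if genome.sequence is None:
        raise ValueError("simulate_line_mutations needs genome sequence")
    rng = config.rng(1)
    segments, probs = _position_segments(config, genome)
    placer = _Placer(segments, probs, genome, rng)
    indel_lengths = np.arange(1, 11)
    mnv_lengths = np.arange(2, 6)
    per_line: dict[str, list[TrueMutation]] = {}
    for line in config.line_ids:
        n = int(rng.poisson(config.per_line_mutation_count))
        fates = simulate_selfing(n, config.generations, rng)
        muts: list[TrueMutation] = []
        types = rng.choice(4, size=n, p=np.asarray(config.type_mix, dtype=float))
        for k in range(n):
            mtype = ("SBS", "MNV", "InDel", "SV")[types[k]]
            if mtype == "SBS":
                chrom, pos = placer.draw(1)
                ref = genome.fetch(chrom, pos, pos)
                alt = _draw_sbs_alt(ref, config.titv_ratio, rng)
            elif mtype == "MNV":
                length = int(rng.choice(mnv_lengths, p=np.asarray(config.mnv_length_distribution)))
                chrom, pos = placer.draw(length)
                ref = genome.fetch(chrom, pos, pos + length - 1)
                alt = "".join(
                    b for r in ref for b in [_BASES[_BASES != r][int(rng.integers(3))]]
                )
            elif mtype == "InDel":
                length = int(rng.choice(indel_lengths, p=np.asarray(config.indel_length_distribution)))
                deletion = rng.random() < config.indel_deletion_fraction
                if deletion:
                    chrom, pos = placer.draw(length + 1)
                    ref = genome.fetch(chrom, pos, pos + length)
                    alt = ref[0]
                else:
                    chrom, pos = placer.draw(1)
                    ref = genome.fetch(chrom, pos, pos)
                    alt = ref + "".join(rng.choice(_BASES, length))
            else:  # SV: deletion longer than 50 bp
                length = int(rng.integers(51, 201))
                chrom, pos = placer.draw(length + 1)
                ref = genome.fetch(chrom, pos, pos + length)
                alt = ref[0]
            if mtype in {"InDel", "SV"}:
                # Truth is stored in canonical left-aligned form so recovered
                # records compare positionally; the normalizer itself is
                # validated against an independent oracle elsewhere.
                norm = normalize_variant(
                    Mutation(line, chrom, pos, ref, alt, 1.0, "homozygous"), genome
                )
                chrom, pos, ref, alt = norm.chrom, norm.pos, norm.ref, norm.alt
            muts.append(
                TrueMutation(
                    line_id=line, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    mtype=mtype, fate=fates[k],
                )
            )
        per_line[line] = muts

    background: list[tuple[str, int, str, str]] = []
    for _ in range(config.n_background):
        chrom, pos = placer.draw(1)
        ref = genome.fetch(chrom, pos, pos)
        alt = _draw_sbs_alt(ref, config.titv_ratio, rng)
        background.append((chrom, pos, ref, alt))
    return CohortTruth(per_line=per_line, background=background)


def _vcf_records(truth: CohortTruth, config: CohortConfig):
    """(chrom, pos, ref, alt, carriers {line: vaf_p}) rows, sorted."""
    rows: dict[tuple[str, int, str, str], dict[str, float]] = {}
    for line, muts in truth.per_line.items():
        for m in muts:
            if not m.observable:
                continue
            p = 1.0 if m.fate == "hom" else 0.5
            if m.mtype == "MNV":
                for off, (r, a) in enumerate(zip(m.ref, m.alt)):
                    rows.setdefault((m.chrom, m.pos + off, r, a), {})[line] = p
            else:
                rows.setdefault(m.site, {})[line] = p
    samples = config.line_ids + [config.wild_type_id]
    for chrom, pos, ref, alt in truth.background:
        rows.setdefault((chrom, pos, ref, alt), {}).update({s: 1.0 for s in samples})
    order = {c: i for i, c in enumerate(config.chrom_names)}
    return sorted(rows.items(), key=lambda kv: (order[kv[0][0]], kv[0][1], kv[0][2], kv[0][3]))


def emit_cohort_vcf(
    truth: CohortTruth,
    config: CohortConfig,
    genome: GenomeModel,
    path: str | os.PathLike,
) -> None:
    """Write the cohort as a VCF 4.2 with binomially sampled allele depths.

    Per site and sample, total depth is Poisson(mean_depth) and alt depth is
    Binomial(depth, p) with p = 1 for homozygous carriers, 0.5 for
    heterozygous, 0 for non-carriers; background sites are homozygous in
    every sample including the wild type. Same seed, same bytes.
    """
    rng = config.rng(2)
    samples = config.line_ids + [config.wild_type_id]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in genome.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for (chrom, pos, ref, alt), carriers in _vcf_records(truth, config):
            cols = [chrom, str(pos), ".", ref, alt, ".", "PASS", ".", "GT:AD:DP"]
            for s in samples:
                depth = int(rng.poisson(config.mean_depth))
                p = carriers.get(s, 0.0)
                alt_d = int(rng.binomial(depth, p)) if depth else 0
                ref_d = depth - alt_d
                gt = "0/0" if p == 0.0 else ("1/1" if p == 1.0 else "0/1")
                cols.append(f"{gt}:{ref_d},{alt_d}:{depth}")
            fh.write("\t".join(cols) + "\n")


def write_genome_fasta(genome: GenomeModel, path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, _ in genome.chromosomes:
            fh.write(f">{chrom}\n")
            seq = genome.sequence[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genes_gff(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.chrom}\tradmut\t"
            gene_id = g.gene_id
            fh.write(
                f"{base}gene\t{g.tx_start}\t{g.tx_end}\t.\t{g.strand}\t.\tID=gene_{gene_id}\n"
            )
            fh.write(
                f"{base}mRNA\t{g.tx_start}\t{g.tx_end}\t.\t{g.strand}\t.\t"
                f"ID={gene_id};Parent=gene_{gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{base}exon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={gene_id}.exon{i};Parent={gene_id}\n"
                )
            if g.coding:
                for i, (s, e) in enumerate(g.cds_intervals(), 1):
                    fh.write(
                        f"{base}CDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                        f"ID={gene_id}.cds{i};Parent={gene_id}\n"
                    )


def write_truth_tsv(truth: CohortTruth, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("line\tchrom\tpos\tref\talt\ttype\tfate\n")
        for line in sorted(truth.per_line):
            for m in truth.per_line[line]:
                fh.write(
                    f"{m.line_id}\t{m.chrom}\t{m.pos}\t{m.ref}\t{m.alt}\t{m.mtype}\t{m.fate}\n"
                )
        for chrom, pos, ref, alt in truth.background:
            fh.write(f"background\t{chrom}\t{pos}\t{ref}\t{alt}\tSBS\thom\n")


def simulate_cohort(
    config: CohortConfig, out_dir: str | os.PathLike
) -> tuple[GenomeModel, list[GeneModel], CohortTruth, dict[str, str]]:
    """Generate a full cohort and write FASTA + GFF3 + VCF + truth TSV."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    genome, genes = simulate_genome(config)
    truth = simulate_line_mutations(config, genome)
    paths = {
        "fasta": os.path.join(out_dir, "genome.fa"),
        "gff": os.path.join(out_dir, "genes.gff3"),
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_genome_fasta(genome, paths["fasta"])
    write_genes_gff(genes, paths["gff"])
    emit_cohort_vcf(truth, config, genome, paths["vcf"])
    write_truth_tsv(truth, paths["truth"])
    return genome, genes, truth, paths


def simulate_f2_mapping(
    seed: int | np.random.Generator,
    markers: Sequence[tuple[str, str, int]],
    causal: tuple[str, int],
    n_plants: int = 500,
    pool_size: int = 20,
    morgans_per_bp: float = 2.5e-8,
) -> tuple[list[MarkerGenotypes], int, int]:
    """Forward-simulate an F2 mapping population and its bulk pools.

    ``markers`` are (marker_id, chrom, pos); ``causal`` is the recessive
    causal locus. Each F2 plant receives two independent gametes; a gamete's
    marker allele recombines away from its causal-locus allele with the
    Haldane fraction of the physical distance (markers on other chromosomes
    segregate freely). Pools take ``pool_size`` recessive-phenotype and
    dominant-phenotype plants; a pool's consensus call is a parental allele
    only when every pooled plant is homozygous for it, else "het".

    Returns (marker genotype table, n dominant-phenotype, n recessive).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c_chrom, c_pos = causal
    rec_fracs = []
    for _, chrom, pos in markers:
        if chrom == c_chrom:
            d = abs(pos - c_pos) * morgans_per_bp
            rec_fracs.append(0.5 * (1.0 - np.exp(-2.0 * d)))
        else:
            rec_fracs.append(0.5)
    rec_fracs = np.array(rec_fracs)
    # Gamete causal alleles: 1 = mutant parent allele.
    g1 = rng.integers(0, 2, size=n_plants)
    g2 = rng.integers(0, 2, size=n_plants)
    # Marker alleles per gamete: flip away from the causal allele on recombination.
    m1 = np.where(rng.random((n_plants, len(markers))) < rec_fracs, 1 - g1[:, None], g1[:, None])
    m2 = np.where(rng.random((n_plants, len(markers))) < rec_fracs, 1 - g2[:, None], g2[:, None])
    recessive = (g1 == 1) & (g2 == 1)
    n_rec = int(recessive.sum())
    n_dom = n_plants - n_rec
    rec_idx = np.flatnonzero(recessive)[:pool_size]
    dom_idx = np.flatnonzero(~recessive)[:pool_size]

    def pool_call(idx: np.ndarray, j: int) -> str:
        alleles = np.concatenate([m1[idx, j], m2[idx, j]])
        if (alleles == 1).all():
            return "mut"
        if (alleles == 0).all():
            return "wt"
        return "het"

    table = []
    for j, (marker_id, chrom, pos) in enumerate(markers):
        table.append(
            MarkerGenotypes(
                marker_id=marker_id,
                chrom=chrom,
                position=pos,
                parent1_allele="mut",
                parent2_allele="wt",
                pool_r_allele=pool_call(rec_idx, j),
                pool_d_allele=pool_call(dom_idx, j),
            )
        )
    return table, n_dom, n_rec
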