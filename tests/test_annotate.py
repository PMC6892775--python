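"""Feature assignment and coding-effect prediction."""

import numpy as np
import pytest
from Bio.Seq import Seq

from radmut import (
    AnnotationConfig,
    GeneModel,
    GenomeModel,
    annotate_mutations,
    assign_feature,
    effect_summary,
    predict_effect,
    region_distribution,
)
from radmut.annotate import AnnotatedMutation, FEATURES, _PRECEDENCE
from radmut.model import HOMOZYGOUS, Mutation

# A 120-bp chromosome with one + strand gene: tx 11-100, single exon,
# CDS 21-80 translating to MAWKGLQPDNTIVRRTAFL*.
CDS = "ATGGCTTGGAAAGGACTTCAACCAGATAATACCATTGTTCGAAGAACAGCATTCCTGTAA"
SEQ = "G" * 10 + "C" * 10 + CDS + "T" * 20 + "G" * 20
GENOME = GenomeModel([("chr1", 120)], {"chr1": SEQ})
GENE = GeneModel("g1", "chr1", "+", 11, 100, [(11, 100)], 21, 80)

_COMP = str.maketrans("ACGT", "TGCA")
SEQ_M = SEQ.translate(_COMP)[::-1]
GENOME_M = GenomeModel([("chr1", 120)], {"chr1": SEQ_M})
# The mirrored gene: same transcript read off the - strand.
GENE_M = GeneModel("gm", "chr1", "-", 21, 110, [(21, 110)], 41, 100)


def _mut(pos, ref, alt, chrom="chr1"):
    return Mutation("L1", chrom, pos, ref, alt, 1.0, HOMOZYGOUS)


@pytest.mark.parametrize(
    "pos,expected",
    [
        (30, "exon"),  # inside CDS
        (15, "UTR5"),
        (90, "UTR3"),
        (5, "upstream"),
        (110, "downstream"),
    ],
)
def test_feature_positions_plus_strand(pos, expected):
    feature, gene_id = assign_feature(_mut(pos, "A", "G"), [GENE])
    assert feature == expected and gene_id == "g1"


def test_upstream_downstream_respect_strand_and_window():
    g = GeneModel("gx", "chr9", "+", 10_000, 12_000, [(10_000, 12_000)])
    cfg = AnnotationConfig(upstream_bp=5_000, downstream_bp=5_000)
    assert assign_feature(_mut(7_000, "A", "G", "chr9"), [g], cfg)[0] == "upstream"
    assert assign_feature(_mut(16_000, "A", "G", "chr9"), [g], cfg)[0] == "downstream"
    assert assign_feature(_mut(2_000, "A", "G", "chr9"), [g], cfg)[0] == "intergenic"
    gm = GeneModel("gy", "chr9", "-", 10_000, 12_000, [(10_000, 12_000)])
    assert assign_feature(_mut(16_000, "A", "G", "chr9"), [gm], cfg)[0] == "upstream"
    assert assign_feature(_mut(7_000, "A", "G", "chr9"), [gm], cfg)[0] == "downstream"


def test_intron_and_splice_region():
    g = GeneModel("g2", "chr2", "+", 11, 100, [(11, 40), (61, 100)], 21, 91)
    assert assign_feature(_mut(41, "A", "G", "chr2"), [g])[0] == "splice_region"
    assert assign_feature(_mut(42, "A", "G", "chr2"), [g])[0] == "splice_region"
    assert assign_feature(_mut(50, "A", "G", "chr2"), [g])[0] == "intron"
    assert assign_feature(_mut(59, "A", "G", "chr2"), [g])[0] == "splice_region"


@pytest.mark.parametrize(
    "pos,ref,alt,expected,affected",
    [
        (35, "A", "G", "silent", False),  # GGA->GGG wobble
        (29, "G", "A", "nonsense", True),  # TGG->TGA stop gain
        (31, "A", "C", "missense", False),  # AAA->ACA
        (79, "A", "C", "stop_lost", True),  # TAA->TCA terminal stop lost
    ],
)
def test_substitution_effects(pos, ref, alt, expected, affected):
    effect, fa = predict_effect(_mut(pos, ref, alt), GENOME, GENE)
    assert (effect, fa) == (expected, affected)


def test_eight_bp_deletion_causes_frameshift_with_premature_stop():
    ref = SEQ[31:40]  # anchor at 32 plus 8 deleted bases
    m = _mut(32, ref, ref[0])
    effect, affected = predict_effect(m, GENOME, GENE)
    assert (effect, affected) == ("frameshift", True)


def test_inframe_deletion():
    ref = SEQ[29:33]  # anchor at 30 plus 3 deleted bases
    effect, affected = predict_effect(_mut(30, ref, ref[0]), GENOME, GENE)
    assert (effect, affected) == ("inframe_indel", False)


def test_mnv_spanning_codon_boundary_is_evaluated_jointly():
    # pos 32-33: last base of AAA and first of GGA -> AAG (silent) + AGA (missense)
    effect, _ = predict_effect(_mut(32, SEQ[31:33], "GA"), GENOME, GENE)
    assert effect == "missense"


def test_minus_strand_gene_evaluates_on_coding_strand():
    """The mirrored gene gives the same effects at mirrored coordinates."""
    for plus_pos, ref, alt, expected in [
        (35, "A", "G", "silent"),
        (29, "G", "A", "nonsense"),
        (31, "A", "C", "missense"),
    ]:
        pos = 121 - plus_pos
        m = _mut(pos, ref.translate(_COMP), alt.translate(_COMP))
        effect, _ = predict_effect(m, GENOME_M, GENE_M)
        assert effect == expected, f"plus pos {plus_pos}"


def test_cds_not_multiple_of_three_warns_and_returns_na():
    bad = GeneModel("gb", "chr1", "+", 11, 100, [(11, 100)], 21, 79)
    with pytest.warns(UserWarning, match="divisible"):
        effect, _ = predict_effect(_mut(30, "A", "G"), GENOME, bad)
    assert effect == "NA"


def _paint_feature_map(genome, genes, cfg):
    """Independent oracle: paint per-base feature ranks chromosome-wide."""
    rank_of = _PRECEDENCE
    maps = {}
    for chrom, length in genome.chromosomes:
        arr = np.full(length + 1, rank_of["intergenic"], dtype=np.int8)
        for g in genes:
            if g.chrom != chrom:
                continue
            def paint(lo, hi, feat):
                lo, hi = max(1, lo), min(length, hi)
                if lo <= hi:
                    np.minimum.at(arr, np.arange(lo, hi + 1), rank_of[feat])
            if g.strand == "+":
                paint(g.tx_start - cfg.upstream_bp, g.tx_start - 1, "upstream")
                paint(g.tx_end + 1, g.tx_end + cfg.downstream_bp, "downstream")
            else:
                paint(g.tx_end + 1, g.tx_end + cfg.upstream_bp, "upstream")
                paint(g.tx_start - cfg.upstream_bp, g.tx_start - 1, "downstream")
            paint(g.tx_start, g.tx_end, "intron")
            for i, (s, e) in enumerate(g.exons):
                # splice regions are intronic bases flanking an exon
                if i > 0:
                    paint(s - cfg.splice_bp, s - 1, "splice_region")
                if i < len(g.exons) - 1:
                    paint(e + 1, e + cfg.splice_bp, "splice_region")
            for s, e in g.exons:
                if not g.coding:
                    paint(s, e, "exon")
                    continue
                lo, hi = max(s, g.cds_start), min(e, g.cds_end)
                if g.strand == "+":
                    paint(s, min(e, g.cds_start - 1), "UTR5")
                    paint(max(s, g.cds_end + 1), e, "UTR3")
                else:
                    paint(s, min(e, g.cds_start - 1), "UTR3")
                    paint(max(s, g.cds_end + 1), e, "UTR5")
                if lo <= hi:
                    paint(lo, hi, "exon")
        maps[chrom] = arr
    return maps


def test_feature_assignment_matches_interval_paint_oracle(cohort_run):
    genome, genes = cohort_run["genome"], cohort_run["genes"]
    cfg = AnnotationConfig()
    maps = _paint_feature_map(genome, genes, cfg)
    rank_to_feats = {}
    for f, r in _PRECEDENCE.items():
        rank_to_feats.setdefault(r, set()).add(f)
    rng = np.random.default_rng(17)
    for _ in range(2_000):
        chrom, length = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
        pos = int(rng.integers(1, length + 1))
        feature, _ = assign_feature(_mut(pos, "A", "G", chrom), genes, cfg)
        assert feature in rank_to_feats[maps[chrom][pos]], (chrom, pos, feature)


def test_effect_summary_percentages_from_counts():
    annotated = []
    pos = 1
    for effect, n in [("missense", 25), ("nonsense", 0), ("silent", 18)]:
        for _ in range(n):
            m = Mutation("H633", "chr1", pos, "A", "G", 1.0, HOMOZYGOUS, "SBS")
            annotated.append(AnnotatedMutation(m, "exon", "g1", effect))
            pos += 1
    summary = effect_summary(annotated, {"H633": "CIB"})
    row = summary.effects.iloc[0]
    assert row["silent_pct"] == 41.86 and row["missense_pct"] == 58.14
    assert row["total"] == 43


def test_effect_summary_empty_input_no_division():
    summary = effect_summary([])
    assert summary.effects.empty and summary.affected_genes == {}


def test_affected_gene_lists_match_injected_truth():
    rows = []
    m1 = Mutation("L1", "chr1", 29, "G", "A", 1.0, HOMOZYGOUS, "SBS")
    m2 = Mutation("L2", "chr1", 35, "A", "G", 1.0, HOMOZYGOUS, "SBS")
    annotated = annotate_mutations([m1, m2], [GENE], GENOME)
    summary = effect_summary(annotated)
    assert summary.affected_genes == {"L1": ["g1"]}  # nonsense only


def test_region_distribution_rows_sum_to_100():
    muts = [
        Mutation("L1", "chr1", p, "A", "G", 1.0, HOMOZYGOUS, "SBS")
        for p in (5, 15, 30, 110)
    ]
    annotated = annotate_mutations(muts, [GENE], GENOME)
    table = region_distribution(annotated)
    row = table.iloc[0]
    assert sum(row[f] for f in FEATURES) == pytest.approx(100.0, abs=0.05)


def _oracle_effect(m, genome, gene):
    """Whole-CDS retranslation after applying the variant to the chromosome."""
    seq = genome.sequence[m.chrom]
    delta = len(m.alt) - len(m.ref)
    mutated = seq[: m.pos - 1] + m.alt + seq[m.pos - 1 + len(m.ref) :]
    pieces = []
    for s, e in gene.cds_intervals():
        s2 = s + delta if s > m.pos else s
        e2 = e + delta if e > m.pos else e
        pieces.append(mutated[s2 - 1 : e2])
    cds = "".join(pieces)
    ref_cds = "".join(seq[s - 1 : e] for s, e in gene.cds_intervals())
    if gene.strand == "-":
        cds = cds.translate(_COMP)[::-1]
        ref_cds = ref_cds.translate(_COMP)[::-1]
    ref_prot = str(Seq(ref_cds).translate())
    mut_prot = str(Seq(cds[: 3 * (len(cds) // 3)]).translate())
    ref_term = ref_prot.find("*") if "*" in ref_prot else len(ref_prot)
    if delta % 3 != 0:
        stop = mut_prot.find("*")
        return "frameshift", 0 <= stop < ref_term
    if delta != 0:
        return "inframe_indel", False
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, mut_prot)) if a != b]
    if not diffs:
        return "silent", False
    new_stops = [i for i in diffs if mut_prot[i] == "*"]
    lost_stops = [i for i in diffs if ref_prot[i] == "*"]
    if new_stops and (not lost_stops or min(new_stops) < min(lost_stops)):
        return "nonsense", True
    if lost_stops:
        return "stop_lost", True
    return "missense", False


def test_effects_match_whole_cds_retranslation_on_random_variants(cohort_run):
    genome, genes = cohort_run["genome"], cohort_run["genes"]
    coding = [g for g in genes if g.coding]
    rng = np.random.default_rng(23)
    bases = "ACGT"
    for _ in range(300):
        gene = coding[int(rng.integers(len(coding)))]
        s, e = gene.cds_intervals()[int(rng.integers(len(gene.cds_intervals())))]
        pos = int(rng.integers(s + 12, e - 12))
        kind = rng.random()
        seq = genome.sequence[gene.chrom]
        if kind < 0.5:  # SBS
            ref = seq[pos - 1]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
        elif kind < 0.7:  # 2-bp MNV
            ref = seq[pos - 1 : pos + 1]
            alt = "".join(
                bases[(bases.index(b) + int(rng.integers(1, 4))) % 4] for b in ref
            )
        elif kind < 0.85:  # deletion of 1-6 bp
            n = int(rng.integers(1, 7))
            ref = seq[pos - 1 : pos + n]
            alt = ref[0]
        else:  # insertion of 1-6 bp
            ref = seq[pos - 1]
            alt = ref + "".join(bases[int(b)] for b in rng.integers(0, 4, int(rng.integers(1, 7))))
        if ref == alt:
            continue
        m = _mut(pos, ref, alt, gene.chrom)
        got = predict_effect(m, genome, gene)
        assert got == _oracle_effect(m, genome, gene), (gene.gene_id, pos, ref, alt)
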