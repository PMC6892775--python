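"""Per-chromosome frequency, windows, HF/LF regions, proximity analysis."""

import math

import numpy as np
import pytest
from scipy import stats

from radmut import (
    GenomeModel,
    HFRegion,
    WindowProfile,
    chromosome_frequency,
    common_hf_regions,
    compare_hf_lf,
    detect_hf_lf,
    indel_sbs_proximity,
    window_counts,
)
from radmut.landscape import proximity_sensitivity
from radmut.model import HOMOZYGOUS, Mutation


def _mut(pos, chrom="chr1", mclass="SBS", line="L1"):
    return Mutation(line, chrom, pos, "A", "G", 1.0, HOMOZYGOUS, mclass)


def test_chromosome_spacing_and_rate():
    genome = GenomeModel([("chr1", 10_000_000)])
    freq = chromosome_frequency([_mut(p) for p in range(1, 5_000_001, 1_000_000)], genome)
    assert freq["chr1"]["count"] == 5
    assert freq["chr1"]["kb_per_mutation"] == 2_000.0


def test_zero_mutation_chromosome_reports_undefined_spacing():
    genome = GenomeModel([("chr1", 1_000_000)])
    freq = chromosome_frequency([], genome)
    assert freq["chr1"]["kb_per_mutation"] is None
    assert freq["chr1"]["per_bp_rate"] == 0


def test_unknown_chromosome_is_an_error():
    with pytest.raises(ValueError, match="absent"):
        chromosome_frequency([_mut(5, chrom="chrX")], GenomeModel([("chr1", 100)]))


def test_counts_proportional_to_lengths_for_uniform_cohort(cohort_run):
    """Multinomial goodness of fit of per-chromosome counts vs lengths."""
    genome = cohort_run["genome"]
    muts = cohort_run["result"].mutations
    freq = chromosome_frequency(muts, genome)
    counts = [freq[n]["count"] for n in genome.names]
    total_len = genome.total_length
    expected = [sum(counts) * l / total_len for _, l in genome.chromosomes]
    _, p = stats.chisquare(counts, expected)
    assert p > 1e-3


def test_ragged_tail_window():
    genome = GenomeModel([("chr1", 2_500_000)])
    ws = window_counts([], genome, window_size=1_000_000)
    assert [(w.window_start, w.window_end) for w in ws] == [
        (1, 1_000_000),
        (1_000_001, 2_000_000),
        (2_000_001, 2_500_000),
    ]


def test_window_boundary_is_inclusive():
    genome = GenomeModel([("chr1", 2_000_000)])
    ws = window_counts([_mut(1_000_000)], genome, window_size=1_000_000)
    assert ws[0].count == 1 and ws[1].count == 0


def test_window_counts_match_brute_force_binning():
    genome = GenomeModel([("chr1", 3_000_000), ("chr2", 1_500_000)])
    rng = np.random.default_rng(12)
    muts = []
    for chrom, length in genome.chromosomes:
        for p in rng.integers(1, length + 1, 5_000):
            muts.append(_mut(int(p), chrom=chrom))
    ws = window_counts(muts, genome, window_size=100_000)
    brute = {}
    for m in muts:
        brute[(m.chrom, (m.pos - 1) // 100_000)] = brute.get((m.chrom, (m.pos - 1) // 100_000), 0) + 1
    for w in ws:
        assert w.count == brute.get((w.chrom, (w.window_start - 1) // 100_000), 0)
    assert sum(w.count for w in ws) == len(muts)


def _profile(counts, size=1_000_000, chrom="chr4"):
    return [
        WindowProfile(chrom, i * size + 1, (i + 1) * size, c, c / size)
        for i, c in enumerate(counts)
    ]


def test_clear_outlier_window_is_flagged_hf():
    """A 7e-6 window over a 1.2e-6 chromosome mean satisfies the 4x rule."""
    ws = _profile([1, 1, 1, 7, 1, 1, 1, 1, 1, 1])  # mean 1.5e-6, window 7e-6
    regions = detect_hf_lf(ws, hf_multiplier=4.0)
    hf = [r for r in regions if r.label == "HF"]
    assert len(hf) == 1 and hf[0].start == 3_000_001 and hf[0].count == 7
    assert hf[0].frequency >= 4 * hf[0].chromosome_mean_frequency


def test_homogeneous_profile_has_no_hf_no_lf():
    assert detect_hf_lf(_profile([3] * 10)) == []


def test_zero_count_windows_become_lf_and_merge():
    regions = detect_hf_lf(_profile([3, 0, 0, 3, 3, 3, 3, 3, 3, 3]))
    lf = [r for r in regions if r.label == "LF"]
    assert len(lf) == 1 and (lf[0].start, lf[0].end) == (1_000_001, 3_000_000)


def test_detection_is_scale_free():
    counts = [2, 2, 2, 11, 2, 0, 2, 2, 2, 2]
    small = detect_hf_lf(_profile(counts, size=100_000))
    big = detect_hf_lf(_profile(counts, size=1_000_000))
    assert [(r.label, r.count) for r in small] == [(r.label, r.count) for r in big]


def test_hf_false_positive_rate_under_homogeneous_poisson():
    """Without hotspots, <1% of windows are wrongly flagged at multiplier 4."""
    rng = np.random.default_rng(99)
    density = 12.5  # mutations per 1 Mb window, the generator's default order
    n_flagged = 0
    n_windows = 0
    for _ in range(1_000):
        counts = rng.poisson(density, 8)
        ws = _profile(list(counts))
        n_flagged += sum(r.end // 1_000_000 - (r.start - 1) // 1_000_000
                         for r in detect_hf_lf(ws) if r.label == "HF")
        n_windows += 8
    assert n_flagged / n_windows < 0.01


def test_welch_test_separates_groups():
    hf = [HFRegion("c", 1, 10, 5, f, 1e-6, "HF") for f in (5e-6, 6e-6, 7e-6)]
    lf = [HFRegion("c", 1, 10, 0, 0.0, 1e-6, "LF") for _ in range(3)]
    t, p = compare_hf_lf(hf, lf)
    assert p < 0.05 and t > 0


def test_identical_groups_give_p_one():
    hf = [HFRegion("c", 1, 10, 2, 2e-6, 1e-6, "HF") for _ in range(3)]
    assert compare_hf_lf(hf, hf) == (0.0, 1.0)


def test_welch_statistic_matches_textbook_formula():
    x, y = [5.0, 6.0, 7.0], [1.0, 2.0, 6.0]
    hf = [HFRegion("c", 1, 10, 1, v, 0, "HF") for v in x]
    lf = [HFRegion("c", 1, 10, 1, v, 0, "LF") for v in y]
    t, _ = compare_hf_lf(hf, lf)
    mx, my = np.mean(x), np.mean(y)
    vx, vy = np.var(x, ddof=1) / 3, np.var(y, ddof=1) / 3
    assert t == pytest.approx((mx - my) / math.sqrt(vx + vy))


def test_group_of_one_is_an_error():
    hf = [HFRegion("c", 1, 10, 1, 1e-6, 0, "HF")]
    with pytest.raises(ValueError):
        compare_hf_lf(hf, hf * 3)


def test_common_hf_region_quoted_example():
    a = [HFRegion("chr9", 8_000_001, 9_000_000, 5, 5e-6, 1e-6, "HF")]
    b = [HFRegion("chr9", 8_000_001, 9_000_000, 6, 6e-6, 1e-6, "HF")]
    assert common_hf_regions({"CIB": a, "GR": b}) == [("chr9", 8_000_001, 9_000_000)]


def test_disjoint_hf_regions_share_nothing():
    a = [HFRegion("chr1", 1, 100, 5, 5e-6, 1e-6, "HF")]
    b = [HFRegion("chr1", 200, 300, 5, 5e-6, 1e-6, "HF")]
    assert common_hf_regions({"A": a, "B": b}) == []


def test_common_regions_match_brute_force_intersection():
    rng = np.random.default_rng(4)
    def rand_regions(n):
        out = []
        for _ in range(n):
            s = int(rng.integers(1, 900))
            e = s + int(rng.integers(10, 120))
            out.append(HFRegion("chr1", s, e, 2, 1e-5, 1e-6, "HF"))
        return out
    a, b = rand_regions(8), rand_regions(8)
    got = set(common_hf_regions({"A": a, "B": b}))
    brute = set()
    for ra in a:
        for rb in b:
            lo, hi = max(ra.start, rb.start), min(ra.end, rb.end)
            if lo <= hi:
                brute.add(("chr1", lo, hi))
    assert got == brute


def test_indel_accompanied_by_nearby_sbs():
    muts = [_mut(5_000, mclass="InDel"), _mut(9_000, mclass="SBS")]
    assert indel_sbs_proximity(muts, distance=10_000) == 1.0


def test_no_sbs_on_chromosome_gives_zero():
    muts = [_mut(5_000, mclass="InDel"), _mut(9_000, chrom="chr2", mclass="SBS")]
    assert indel_sbs_proximity(muts, distance=10_000) == 0.0


def test_proximity_matches_brute_force_all_pairs():
    rng = np.random.default_rng(21)
    muts = []
    for i in range(1_000):
        chrom = f"chr{1 + i % 3}"
        mclass = "InDel" if rng.random() < 0.3 else "SBS"
        muts.append(_mut(int(rng.integers(1, 2_000_000)), chrom=chrom, mclass=mclass))
    d = 10_000
    got = indel_sbs_proximity(muts, distance=d)
    indels = [m for m in muts if m.mclass == "InDel"]
    hits = sum(
        1
        for ind in indels
        if any(
            m.mclass == "SBS" and m.chrom == ind.chrom and abs(m.pos - ind.pos) <= d
            for m in muts
        )
    )
    assert got == pytest.approx(hits / len(indels))
    sens = proximity_sensitivity(muts)
    assert sens[1_000] <= sens[5_000] <= sens[10_000] <= sens[50_000]
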