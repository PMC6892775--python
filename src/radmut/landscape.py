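"""Genomic mutation landscape: per-chromosome frequency, fixed windows,
high-/low-frequency region detection, and InDel-SBS proximity.

Treatment-level analyses pool the mutations of all of a treatment's lines.
Windows tile each chromosome without overlap starting at position 1; the last
window may be short. A high-frequency (HF) region is a run of windows whose
per-bp mutation frequency is at least ``hf_multiplier`` times the chromosome
mean (and holds at least ``min_count`` mutations); a low-frequency (LF)
region is a run of zero-count windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .model import GenomeModel, Mutation


@dataclass(frozen=True)
class WindowProfile:
    chrom: str
    window_start: int  # 1-based inclusive
    window_end: int  # 1-based inclusive
    count: int
    frequency: float  # mutations per bp
    treatment: Optional[str] = None

    @property
    def size(self) -> int:
        return self.window_end - self.window_start + 1


@dataclass(frozen=True)
class HFRegion:
    chrom: str
    start: int
    end: int
    count: int
    frequency: float
    chromosome_mean_frequency: float
    label: str  # "HF" or "LF"


def _check_chroms(mutations: Iterable[Mutation], genome: GenomeModel) -> None:
    known = set(genome.names)
    for m in mutations:
        if m.chrom not in known:
            raise ValueError(f"mutation chromosome {m.chrom!r} absent from genome model")


def chromosome_frequency(
    mutations: Sequence[Mutation], genome: GenomeModel
) -> dict[str, dict[str, float]]:
    """Per-chromosome count, kb-per-mutation spacing, and per-bp rate.

    Chromosomes with zero mutations report spacing None and rate 0.
    """
    _check_chroms(mutations, genome)
    counts = {name: 0 for name in genome.names}
    for m in mutations:
        counts[m.chrom] += 1
    out: dict[str, dict[str, float]] = {}
    for name, length in genome.chromosomes:
        n = counts[name]
        out[name] = {
            "count": n,
            "kb_per_mutation": (length / 1000) / n if n else None,
            "per_bp_rate": n / length,
        }
    return out


def window_counts(
    mutations: Sequence[Mutation],
    genome: GenomeModel,
    window_size: int = 1_000_000,
    treatment: Optional[str] = None,
) -> list[WindowProfile]:
    """Count mutations in non-overlapping windows tiled from position 1.

    A mutation is binned by its start position; window boundaries are
    1-based inclusive, so position ``window_size`` falls in the first window.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    _check_chroms(mutations, genome)
    per_chrom_counts: dict[str, dict[int, int]] = {name: {} for name in genome.names}
    for m in mutations:
        idx = (m.pos - 1) // window_size
        d = per_chrom_counts[m.chrom]
        d[idx] = d.get(idx, 0) + 1
    windows: list[WindowProfile] = []
    for name, length in genome.chromosomes:
        n_windows = (length + window_size - 1) // window_size
        for i in range(n_windows):
            start = i * window_size + 1
            end = min((i + 1) * window_size, length)
            count = per_chrom_counts[name].get(i, 0)
            windows.append(
                WindowProfile(
                    chrom=name,
                    window_start=start,
                    window_end=end,
                    count=count,
                    frequency=count / (end - start + 1),
                    treatment=treatment,
                )
            )
    return windows


def detect_hf_lf(
    windows: Sequence[WindowProfile],
    hf_multiplier: float = 4.0,
    min_count: int = 2,
) -> list[HFRegion]:
    """Flag high- and low-frequency windows and merge adjacent ones.

    HF: window frequency >= hf_multiplier x chromosome mean frequency and
    count >= min_count. LF: zero-count windows. The chromosome mean is
    total count / chromosome length over the windows provided (one
    treatment's profile).
    """
    by_chrom: dict[str, list[WindowProfile]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    regions: list[HFRegion] = []
    for chrom, ws in by_chrom.items():
        ws = sorted(ws, key=lambda w: w.window_start)
        total = sum(w.count for w in ws)
        length = sum(w.size for w in ws)
        mean_freq = total / length if length else 0.0
        labels = []
        for w in ws:
            if w.count == 0:
                labels.append("LF")
            elif mean_freq > 0 and w.frequency >= hf_multiplier * mean_freq and w.count >= min_count:
                labels.append("HF")
            else:
                labels.append(None)
        i = 0
        while i < len(ws):
            lab = labels[i]
            if lab is None:
                i += 1
                continue
            j = i
            while j + 1 < len(ws) and labels[j + 1] == lab and ws[j + 1].window_start == ws[j].window_end + 1:
                j += 1
            run = ws[i : j + 1]
            count = sum(w.count for w in run)
            size = sum(w.size for w in run)
            regions.append(
                HFRegion(
                    chrom=chrom,
                    start=run[0].window_start,
                    end=run[-1].window_end,
                    count=count,
                    frequency=count / size,
                    chromosome_mean_frequency=mean_freq,
                    label=lab,
                )
            )
            i = j + 1
    return regions


def compare_hf_lf(
    hf: Sequence[HFRegion], lf: Sequence[HFRegion]
) -> tuple[float, float]:
    """Welch two-sample t-test on per-region frequencies (two-sided).

    Returns (t, p). Requires at least two regions per group.
    """
    if len(hf) < 2 or len(lf) < 2:
        raise ValueError("compare_hf_lf needs >= 2 regions per group")
    x = [r.frequency for r in hf]
    y = [r.frequency for r in lf]
    if x == y:
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def common_hf_regions(
    regions_by_treatment: Mapping[str, Sequence[HFRegion]],
) -> list[tuple[str, int, int]]:
    """Intervals where HF regions of every treatment overlap.

    Returns (chrom, start, end) intersections, 1-based inclusive.
    """
    if len(regions_by_treatment) < 2:
        raise ValueError("common_hf_regions needs >= 2 treatments")
    treatment_intervals = []
    for regions in regions_by_treatment.values():
        treatment_intervals.append(
            sorted((r.chrom, r.start, r.end) for r in regions if r.label == "HF")
        )
    current = treatment_intervals[0]
    for other in treatment_intervals[1:]:
        out = []
        for chrom, s1, e1 in current:
            for c2, s2, e2 in other:
                if chrom != c2:
                    continue
                lo, hi = max(s1, s2), min(e1, e2)
                if lo <= hi:
                    out.append((chrom, lo, hi))
        current = sorted(set(out))
    return current


def indel_sbs_proximity(
    mutations: Sequence[Mutation], distance: int = 10_000
) -> float:
    """Fraction of InDels with at least one SBS within ``distance`` bp.

    Mutations are one treatment's pooled, classified records; the SBS may come
    from any line of the treatment but must lie on the same chromosome.
    Returns 0.0 when there are no InDels.
    """
    indels = [m for m in mutations if m.mclass == "InDel"]
    sbs_pos: dict[str, list[int]] = {}
    for m in mutations:
        if m.mclass == "SBS":
            sbs_pos.setdefault(m.chrom, []).append(m.pos)
    if not indels:
        return 0.0
    n_near = 0
    for ind in indels:
        positions = sbs_pos.get(ind.chrom, ())
        if any(abs(p - ind.pos) <= distance for p in positions):
            n_near += 1
    return n_near / len(indels)


def proximity_sensitivity(
    mutations: Sequence[Mutation],
    distances: Sequence[int] = (1_000, 5_000, 10_000, 50_000),
) -> dict[int, float]:
    """InDel-SBS accompaniment fraction over a grid of radii."""
    return {d: indel_sbs_proximity(mutations, d) for d in distances}
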