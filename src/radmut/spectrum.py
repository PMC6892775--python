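"""Substitution spectra, Ti/Tv, flanking-base context, and InDel size statistics.

Spectra are directional on the reference strand (12 classes, A>C ... T>G), not
complement-collapsed, so G>A and C>T are reported separately. Transitions are
A>G, G>A, C>T and T>C; everything else is a transversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .model import PURINES, PYRIMIDINES, GenomeModel, Mutation

BASES = "ACGT"
SUBSTITUTION_CLASSES = tuple(
    f"{r}>{a}" for r in BASES for a in BASES if r != a
)
TRANSITIONS = ("A>G", "G>A", "C>T", "T>C")
TRANSVERSIONS = tuple(c for c in SUBSTITUTION_CLASSES if c not in TRANSITIONS)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, the convention used for printed percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def substitution_spectrum(mutations: Iterable[Mutation]) -> dict[str, int]:
    """Count the 12 directional substitution classes over an SBS list."""
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    for m in mutations:
        if len(m.ref) != 1 or len(m.alt) != 1:
            raise ValueError(
                f"substitution_spectrum takes SBS records only, got {m.ref}>{m.alt} at {m.chrom}:{m.pos}"
            )
        counts[f"{m.ref}>{m.alt}"] += 1
    return counts


def titv_ratio(counts: Mapping[str, int]) -> Optional[float]:
    """Transition/transversion ratio; None (undefined) at zero transversions."""
    ti = sum(counts.get(c, 0) for c in TRANSITIONS)
    tv = sum(counts.get(c, 0) for c in TRANSVERSIONS)
    if tv == 0:
        return None
    return ti / tv


def dinucleotide_context(
    mutations: Iterable[Mutation],
    genome: GenomeModel,
    target_class: str,
    side: str = "either",
) -> tuple[int, int, float]:
    """Fraction of target-class SBSs whose flanking base matches the REF class.

    For G>A, a site is "in context" when the reference base immediately 5' or
    3' of the mutated base is a purine (forming a purine dinucleotide); for
    C>T, analogously with pyrimidines. ``side`` restricts the test to one
    neighbor (``5prime``/``3prime``); chromosome-end sites evaluate only the
    existing neighbor. Returns (n_in_context, n_total, percent).
    """
    if side not in {"either", "5prime", "3prime"}:
        raise ValueError(f"bad side {side!r}")
    ref_base, alt_base = target_class.split(">")
    klass = PURINES if ref_base in PURINES else PYRIMIDINES
    n_total = 0
    n_in = 0
    lengths = genome.lengths
    for m in mutations:
        if (m.ref, m.alt) != (ref_base, alt_base):
            continue
        genome_base = genome.fetch(m.chrom, m.pos, m.pos)
        if genome_base != m.ref:
            raise ValueError(
                f"reference mismatch at {m.chrom}:{m.pos}: genome {genome_base}, record {m.ref}"
            )
        n_total += 1
        neighbors = []
        if side in {"either", "5prime"} and m.pos > 1:
            neighbors.append(genome.fetch(m.chrom, m.pos - 1, m.pos - 1))
        if side in {"either", "3prime"} and m.pos < lengths[m.chrom]:
            neighbors.append(genome.fetch(m.chrom, m.pos + 1, m.pos + 1))
        if any(b in klass for b in neighbors):
            n_in += 1
    percent = 100.0 * n_in / n_total if n_total else 0.0
    return n_in, n_total, percent


@dataclass
class IndelSizeSpectrum:
    counts: dict[int, int]  # signed length -> count
    deletion_fraction: float
    multi_base_deletion_count: int  # deletions of >= 5 bp


def indel_size_spectrum(
    mutations: Iterable[Mutation], multi_base_min: int = 5
) -> IndelSizeSpectrum:
    """Histogram of signed InDel lengths (insertions +, deletions -)."""
    counts: dict[int, int] = {}
    n = 0
    n_del = 0
    n_multi = 0
    for m in mutations:
        if m.length == 0:
            raise ValueError(f"not an InDel: {m.ref}>{m.alt} at {m.chrom}:{m.pos}")
        counts[m.length] = counts.get(m.length, 0) + 1
        n += 1
        if m.length < 0:
            n_del += 1
            if -m.length >= multi_base_min:
                n_multi += 1
    frac = n_del / n if n else 0.0
    return IndelSizeSpectrum(counts=counts, deletion_fraction=frac, multi_base_deletion_count=n_multi)


@dataclass
class TreatmentSummary:
    """Per-line counts/proportions and per-treatment aggregates by class."""

    per_line: pd.DataFrame  # line, treatment, per-class counts, total
    proportions: pd.DataFrame  # line, treatment, per-class percent of line total
    means: pd.DataFrame  # treatment x class mean per-line count
    ttests: pd.DataFrame  # class, treatment pair, t, p

    def mean_ratio(self, mclass: str, numerator: str, denominator: str) -> float:
        num = self.means.loc[numerator, mclass]
        den = self.means.loc[denominator, mclass]
        return num / den


_SUMMARY_CLASSES = ("SBS", "MNV", "InDel", "SV")


def treatment_summary(
    mutations: Iterable[Mutation],
    treatment_of: Mapping[str, str],
    classes: Sequence[str] = _SUMMARY_CLASSES,
) -> TreatmentSummary:
    """Per-line and per-treatment mutation-count summary with t-tests.

    ``treatment_of`` maps every line to its treatment label; a mutation from
    an unmapped line is an error. Per-line class counts are compared between
    each pair of treatments with an independent-samples t-test.
    """
    rows: dict[str, dict[str, int]] = {}
    for m in mutations:
        if m.line_id not in treatment_of:
            raise ValueError(f"line {m.line_id!r} mapped to no treatment")
        row = rows.setdefault(m.line_id, {c: 0 for c in classes})
        if m.mclass is None:
            raise ValueError("mutations must be classified before summarising")
        if m.mclass in row:
            row[m.mclass] += 1
    # Lines with zero mutations still appear.
    for line in treatment_of:
        rows.setdefault(line, {c: 0 for c in classes})

    per_line = pd.DataFrame.from_dict(rows, orient="index").loc[sorted(rows)]
    per_line.insert(0, "treatment", [treatment_of[l] for l in per_line.index])
    per_line["total"] = per_line[list(classes)].sum(axis=1)
    per_line.index.name = "line"

    proportions = per_line[["treatment"]].copy()
    for c in classes:
        with pd.option_context("mode.chained_assignment", None):
            proportions[c] = [
                round_half_up(100.0 * n / t, 2) if t else 0.0
                for n, t in zip(per_line[c], per_line["total"])
            ]

    means = per_line.groupby("treatment")[list(classes) + ["total"]].mean()

    treatments = sorted(set(treatment_of.values()))
    trows = []
    for i, ta in enumerate(treatments):
        for tb in treatments[i + 1 :]:
            a = per_line[per_line["treatment"] == ta]
            b = per_line[per_line["treatment"] == tb]
            for c in list(classes) + ["total"]:
                x, y = a[c].to_numpy(float), b[c].to_numpy(float)
                if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_ind(x, y)
                trows.append(
                    {"class": c, "treatment_a": ta, "treatment_b": tb, "t": float(t), "p": float(p)}
                )
    ttests = pd.DataFrame(trows, columns=["class", "treatment_a", "treatment_b", "t", "p"])
    return TreatmentSummary(per_line=per_line, proportions=proportions, means=means, ttests=ttests)
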