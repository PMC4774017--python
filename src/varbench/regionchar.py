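"""Characterize confidence regions against gene models and annotation tracks:
per-gene high-confidence coverage of exonic bases, exon-position coverage
distributions, repeat-class fractions, and attribution of low-confidence
bases to an ordered catalogue of reasons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_io import GeneModel, GeneSet
from .intervals import RegionSet, normalize

__all__ = [
    "GeneCoverage",
    "LowConfReason",
    "EXON_CLASSES",
    "gene_coverage",
    "exon_classes",
    "exon_position_coverage",
    "repeat_fraction_in_hiconf",
    "lowconf_reasons",
]

EXON_CLASSES = ("first", "second", "middle", "penultimate", "last")


@dataclass(frozen=True)
class GeneCoverage:
    """Exonic-base coverage of one gene by the high-confidence regions."""

    gene: str
    exonic_bases: int
    covered_bases: int
    gene_sets: tuple[str, ...] = ()

    @property
    def fraction(self) -> float:
        return self.covered_bases / self.exonic_bases


@dataclass(frozen=True)
class LowConfReason:
    reason: str
    bases: int
    percentage: float  # of all low-confidence bases


def gene_coverage(
    genes: Sequence[GeneModel],
    gene_sets: Sequence[GeneSet],
    hiconf: RegionSet,
) -> tuple[list[GeneCoverage], list[dict]]:
    """Per-gene exonic-base coverage plus per-gene-set summaries.

    Exons are merged across transcripts of the same symbol before counting,
    so "exonic bases" is a per-gene base count.  Set summaries are
    base-weighted (covered exonic bases / total exonic bases) with the
    gene-averaged mean emitted alongside; counts of fully covered genes and
    genes below 50% are included.
    """
    by_symbol: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_symbol.setdefault(g.name, []).append(g)
    per_gene: list[GeneCoverage] = []
    for symbol in sorted(by_symbol):
        exons = normalize(e for g in by_symbol[symbol] for e in g.exons)
        total = exons.total_length
        if total == 0:
            warnings.warn(f"gene {symbol} has zero exonic bases; excluded")
            continue
        covered = exons.intersect(hiconf).total_length
        memberships = tuple(sorted(gs.name for gs in gene_sets if symbol in gs.members))
        per_gene.append(GeneCoverage(symbol, total, covered, memberships))

    summaries = []
    universe = [("all", {gc.gene for gc in per_gene})] + [
        (gs.name, gs.members) for gs in gene_sets
    ]
    for name, members in universe:
        rows = [gc for gc in per_gene if gc.gene in members]
        if not rows:
            summaries.append(
                {"gene_set": name, "n_genes": 0, "base_weighted_fraction": float("nan"),
                 "gene_mean_fraction": float("nan"), "n_fully_covered": 0, "n_below_half": 0}
            )
            continue
        total = sum(gc.exonic_bases for gc in rows)
        covered = sum(gc.covered_bases for gc in rows)
        summaries.append(
            {
                "gene_set": name,
                "n_genes": len(rows),
                "base_weighted_fraction": covered / total,
                "gene_mean_fraction": sum(gc.fraction for gc in rows) / len(rows),
                "n_fully_covered": sum(1 for gc in rows if gc.fraction == 1.0),
                "n_below_half": sum(1 for gc in rows if gc.fraction < 0.5),
            }
        )
    return per_gene, summaries


def exon_classes(n_exons: int, strand: str) -> list[str]:
    """Class labels for a gene's exons in *genomic* order.

    Ordering is strand-aware (first = 5'-most).  Each exon gets exactly one
    class by the precedence first > last > second > penultimate > middle, so
    short genes partition deterministically: a 2-exon gene is [first, last],
    a 3-exon gene [first, second, last], a 4-exon gene
    [first, second, penultimate, last].
    """
    labels = ["middle"] * n_exons
    # assign in transcription order, precedence high to low
    order: list[tuple[int, str]] = [(0, "first")]
    if n_exons >= 2:
        order.append((n_exons - 1, "last"))
    if n_exons >= 3:
        order.append((1, "second"))
    if n_exons >= 4:
        order.append((n_exons - 2, "penultimate"))
    assigned: set[int] = set()
    for idx, label in order:
        if idx not in assigned:
            labels[idx] = label
            assigned.add(idx)
    if strand == "-":
        labels.reverse()
    return labels


def exon_position_coverage(
    genes: Sequence[GeneModel], hiconf: RegionSet
) -> dict[str, list[float]]:
    """Distribution of per-exon high-confidence coverage fractions by exon
    class (first/second/middle/penultimate/last, 5'-aware)."""
    out: dict[str, list[float]] = {c: [] for c in EXON_CLASSES}
    for g in genes:
        labels = exon_classes(len(g.exons), g.strand)
        for exon, label in zip(g.exons, labels):
            frac = normalize([exon]).covered_fraction(hiconf)
            out[label].append(frac)
    return out


def repeat_fraction_in_hiconf(
    repeat_tracks: Mapping[str, RegionSet], hiconf: RegionSet
) -> dict[str, float | None]:
    """Fraction of each repeat class's bases inside the high-confidence
    regions; ``None`` for an empty class."""
    out = {}
    for cls in sorted(repeat_tracks):
        track = repeat_tracks[cls]
        out[cls] = track.covered_fraction(hiconf) if track.total_length else None
    return out


def lowconf_reasons(
    lowconf: RegionSet,
    reason_tracks: Mapping[str, RegionSet] | Iterable[tuple[str, RegionSet]],
) -> list[LowConfReason]:
    """Attribute every low-confidence base to the first reason track (in the
    given precedence order) that contains it; the remainder is reported as
    "unattributed".  Percentages are over all low-confidence bases."""
    total = lowconf.total_length
    items = (
        list(reason_tracks.items())
        if isinstance(reason_tracks, Mapping)
        else list(reason_tracks)
    )
    remaining = lowconf
    out = []
    for reason, track in items:
        attributed = remaining.intersect(track)
        bases = attributed.total_length
        out.append(
            LowConfReason(reason, bases, 100.0 * bases / total if total else 0.0)
        )
        remaining = remaining.subtract(attributed)
    rest = remaining.total_length
    out.append(
        LowConfReason("unattributed", rest, 100.0 * rest / total if total else 0.0)
    )
    return out
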