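"""Functional classification, gene-set stratified sensitivity with Wilson
95% confidence intervals, false-negative cause attribution, and filter
specificity.

The functional classes mirror the four clinically interesting SNV categories
(non-synonymous, synonymous, splicing, truncating) plus "other" for
everything the simple transcript-based rules do not cover.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from Bio.Seq import Seq
from statsmodels.stats.proportion import proportion_confint

from .core_io import CallSet, GeneModel, GeneSet, VariantRecord
from .errors import DomainError
from .intervals import RegionSet
from .varcomp import MatchResult, normalize_variant, split_multiallelic

__all__ = [
    "FUNCTION_CLASSES",
    "StratumMetric",
    "FnCause",
    "GeneIndex",
    "classify_function",
    "binomial_ci",
    "stratified_sensitivity",
    "attribute_fn_causes",
    "filter_specificity",
    "representative_transcripts",
]

NON_SYNONYMOUS = "non-synonymous"
SYNONYMOUS = "synonymous"
TRUNCATING = "truncating"
SPLICING = "splicing"
OTHER = "other"
FUNCTION_CLASSES = (NON_SYNONYMOUS, SPLICING, SYNONYMOUS, TRUNCATING, OTHER)

#: intronic bases adjacent to an exon boundary that count as splice-site
SPLICE_BP = 2


# ---------------------------------------------------------------------------
# Functional classification


def _complement(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[base]


def _cds_coding_sequence(gene: GeneModel, reference: Mapping[str, str]) -> str:
    """CDS sequence in coding (5'->3') orientation."""
    seq = reference[gene.chrom]
    parts = [seq[r.start : r.end] for r in gene.cds_intervals()]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _coding_index(gene: GeneModel, pos0: int) -> int | None:
    """Map a genomic 0-based position to its index in the coding sequence, or
    ``None`` if it is not a CDS base."""
    offset = 0
    plus_index = None
    for r in gene.cds_intervals():
        if r.start <= pos0 < r.end:
            plus_index = offset + (pos0 - r.start)
            break
        offset += r.length
    if plus_index is None:
        return None
    if gene.strand == "-":
        return gene.cds_length - 1 - plus_index
    return plus_index


def _is_splice_site(gene: GeneModel, pos0: int) -> bool:
    exons = gene.exons
    for i, e in enumerate(exons):
        if i < len(exons) - 1 and e.end <= pos0 < e.end + SPLICE_BP:
            return True
        if i > 0 and e.start - SPLICE_BP <= pos0 < e.start:
            return True
    return False


def classify_function(
    v: VariantRecord, gene: GeneModel, reference: Mapping[str, str]
) -> str:
    """Assign one of the five function classes to a variant on one transcript.

    Rules: an SNV within :data:`SPLICE_BP` bases of an exon-intron boundary on
    the intron side is splicing; a CDS SNV is translated strand-aware through
    the standard genetic code (stop gained -> truncating, amino-acid change ->
    non-synonymous, silent -> synonymous; stop-loss and start-loss count as
    non-synonymous); a frameshift indel overlapping the CDS is truncating;
    everything else is "other".
    """
    span = gene.span
    if v.chrom != gene.chrom or not (span.start <= v.start0 < span.end):
        raise DomainError(
            f"variant {v.chrom}:{v.pos} outside gene {gene.name} span"
        )
    alt = v.alts[0]
    if len(v.ref) == 1 == len(alt):
        pos0 = v.start0
        if _is_splice_site(gene, pos0):
            return SPLICING
        if not gene.is_coding:
            return OTHER
        idx = _coding_index(gene, pos0)
        if idx is None:
            return OTHER
        cds = _cds_coding_sequence(gene, reference)
        base = alt if gene.strand == "+" else _complement(alt)
        codon_i = idx // 3
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        if len(codon) < 3:
            return OTHER
        new_codon = codon[: idx % 3] + base + codon[idx % 3 + 1 :]
        aa_old = str(Seq(codon).translate())
        aa_new = str(Seq(new_codon).translate())
        if aa_new == aa_old:
            return SYNONYMOUS
        if aa_new == "*":
            return TRUNCATING
        return NON_SYNONYMOUS
    # indel
    if gene.is_coding:
        overlaps_cds = any(
            v.start0 < r.end and v.end0 > r.start for r in gene.cds_intervals()
        )
        if overlaps_cds and (len(v.ref) - len(alt)) % 3 != 0:
            return TRUNCATING
    return OTHER


# ---------------------------------------------------------------------------
# Wilson interval


def binomial_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score 95% (by default) interval for a binomial proportion.

    For x = n the lower bound takes the closed form n/(n+z^2); bounds are
    clipped to [0, 1].
    """
    if n < 1:
        raise DomainError("binomial_ci requires n >= 1")
    if not 0 <= x <= n:
        raise DomainError(f"x={x} outside [0, {n}]")
    low, high = proportion_confint(x, n, alpha=1 - level, method="wilson")
    return (max(0.0, float(low)), min(1.0, float(high)))


# ---------------------------------------------------------------------------
# Gene lookup


class GeneIndex:
    """Per-chromosome lookup from position to the overlapping gene models."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._by_chrom: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(
                (g.span.start, g.span.end, g)
            )
        self._max_len: dict[str, int] = {}
        for chrom, items in self._by_chrom.items():
            items.sort(key=lambda t: t[0])
            self._max_len[chrom] = max(e - s for s, e, _ in items)

    def overlapping(self, chrom: str, pos0: int) -> list[GeneModel]:
        items = self._by_chrom.get(chrom)
        if not items:
            return []
        starts = [s for s, _, _ in items]
        i = bisect_right(starts, pos0)
        out = []
        j = i - 1
        limit = self._max_len[chrom]
        while j >= 0 and items[j][0] >= pos0 - limit:
            s, e, g = items[j]
            if s <= pos0 < e:
                out.append(g)
            j -= 1
        return out


def representative_transcripts(genes: Iterable[GeneModel]) -> dict[str, GeneModel]:
    """One transcript per gene symbol: the longest CDS, ties broken by
    transcript id."""
    best: dict[str, GeneModel] = {}
    for g in sorted(genes, key=lambda g: (-g.cds_length, g.transcript_id)):
        best.setdefault(g.name, g)
    return best


# ---------------------------------------------------------------------------
# Stratified sensitivity


@dataclass(frozen=True)
class StratumMetric:
    """One Table-1-style cell: counts, sensitivity and its Wilson 95% CI."""

    function: str  # a function class or "whole-genome"
    gene_set: str
    tp: int
    fn: int
    sensitivity: float | None
    ci_low: float | None
    ci_high: float | None

    def to_row(self) -> dict:
        return {
            "function": self.function,
            "gene_set": self.gene_set,
            "sensitivity": math.nan if self.sensitivity is None else self.sensitivity,
            "ci_low": math.nan if self.ci_low is None else self.ci_low,
            "ci_high": math.nan if self.ci_high is None else self.ci_high,
            "tp": self.tp,
            "fn": self.fn,
        }


def _metric(function: str, gene_set: str, tp: int, fn: int, level: float) -> StratumMetric:
    n = tp + fn
    if n == 0:
        return StratumMetric(function, gene_set, 0, 0, None, None, None)
    low, high = binomial_ci(tp, n, level)
    return StratumMetric(function, gene_set, tp, fn, tp / n, low, high)


def stratified_sensitivity(
    match: MatchResult,
    gene_models: Sequence[GeneModel],
    gene_sets: Sequence[GeneSet],
    reference: Mapping[str, str],
    level: float = 0.95,
) -> list[StratumMetric]:
    """Sensitivity per (function class x gene set) over truth variants inside
    the high-confidence regions, plus a whole-genome row.

    A truth variant contributes to a cell when it falls inside a gene whose
    symbol belongs to the set; variants outside every gene model appear only
    in the whole-genome row.  One transcript per gene symbol is used (longest
    CDS).
    """
    reps = representative_transcripts(gene_models)
    index = GeneIndex(reps.values())
    counts: dict[tuple[str, str], list[int]] = {}  # (function, set) -> [tp, fn]
    whole = [0, 0]
    for row in match.truth_rows(in_region_only=True):
        hit = 0 if row.match_class == "TP" else 1
        whole[hit] += 1
        v = row.variant
        for gene in index.overlapping(v.chrom, v.start0):
            try:
                fclass = classify_function(v, gene, reference)
            except DomainError:
                continue
            for gs in gene_sets:
                if gene.name in gs.members:
                    counts.setdefault((fclass, gs.name), [0, 0])[hit] += 1
    out = []
    for fclass in FUNCTION_CLASSES:
        for gs in gene_sets:
            tp, fn = counts.get((fclass, gs.name), (0, 0))
            out.append(_metric(fclass, gs.name, tp, fn, level))
    out.append(_metric("whole-genome", "N/A", whole[0], whole[1], level))
    return out


# ---------------------------------------------------------------------------
# False-negative cause attribution


@dataclass(frozen=True)
class FnCause:
    """Non-exclusive causes attributed to one false-negative truth variant."""

    variant: VariantRecord
    causes: frozenset[str]
    filter_labels: frozenset[str] = frozenset()


FILTERED = "filtered"
LOW_COVERAGE = "low_coverage"
HIGH_GC = "high_gc"
UNEXPLAINED = "unexplained"


def attribute_fn_causes(
    fnvs: Sequence[VariantRecord],
    query_raw: CallSet | Sequence[VariantRecord],
    depth_source: Mapping[tuple[str, int], int] | Callable[[str, int], int | None],
    reference: Mapping[str, str],
    gc_window: int = 100,
    repeat_tracks: Mapping[str, RegionSet] | None = None,
    depth_threshold: int = 10,
    gc_threshold: float = 0.75,
) -> tuple[list[FnCause], dict[str, float]]:
    """Attribute causes to each false-negative variant.

    Causes are assigned non-exclusively: ``filtered`` when a raw query call
    with the same normalized key carries a non-empty filter set;
    ``low_coverage`` when read depth at the site is below ``depth_threshold``;
    ``high_gc`` when the reference GC fraction in the centered ``gc_window``
    exceeds ``gc_threshold``; ``repeat_class:<name>`` per containing repeat
    track; ``unexplained`` when nothing applies.  Returns the per-variant
    causes and the summary fraction of FNVs per cause.
    """
    records = query_raw.records if isinstance(query_raw, CallSet) else list(query_raw)
    filtered_keys: dict[tuple, frozenset[str]] = {}
    for rec in records:
        if not rec.filters:
            continue
        for piece in split_multiallelic(rec):
            norm = normalize_variant(piece, reference)
            filtered_keys[(norm.chrom, norm.pos, norm.ref, norm.alts[0])] = rec.filters

    def depth_at(chrom: str, pos: int) -> int | None:
        if callable(depth_source):
            return depth_source(chrom, pos)
        return depth_source.get((chrom, pos))

    results: list[FnCause] = []
    totals: dict[str, int] = {}
    for v in fnvs:
        causes: set[str] = set()
        labels = filtered_keys.get((v.chrom, v.pos, v.ref, v.alts[0]), frozenset())
        if labels:
            causes.add(FILTERED)
        d = depth_at(v.chrom, v.pos)
        if d is not None and d < depth_threshold:
            causes.add(LOW_COVERAGE)
        seq = reference[v.chrom]
        half = gc_window // 2
        lo = max(0, v.start0 - half)
        win = seq[lo : lo + gc_window]
        if win and (win.count("G") + win.count("C")) / len(win) > gc_threshold:
            causes.add(HIGH_GC)
        if repeat_tracks:
            for cls in sorted(repeat_tracks):
                if repeat_tracks[cls].contains(v.chrom, v.pos):
                    causes.add(f"repeat_class:{cls}")
        if not causes:
            causes.add(UNEXPLAINED)
        for c in causes:
            totals[c] = totals.get(c, 0) + 1
        results.append(FnCause(v, frozenset(causes), labels))
    n = len(results)
    summary = {c: totals[c] / n for c in sorted(totals)} if n else {}
    return results, summary


# ---------------------------------------------------------------------------
# Filter specificity


def filter_specificity(
    query_raw: CallSet | Sequence[VariantRecord],
    match: MatchResult,
    reference: Mapping[str, str],
) -> list[dict]:
    """For each filter-label combination on raw query calls: how many sites
    carry it and what fraction of them are false positives (the filtered
    allele is absent from the truth set).  Aggregate rows cover any single
    filter, multiple filters, and all filtered sites.
    """
    truth_keys = {
        (r.variant.chrom, r.variant.pos, r.variant.ref, r.variant.alts[0])
        for r in match.rows
        if r.role == "truth"
    }
    records = query_raw.records if isinstance(query_raw, CallSet) else list(query_raw)
    combos: dict[frozenset, list[int]] = {}  # combo -> [n, n_fp]
    single = [0, 0]
    multiple = [0, 0]
    overall = [0, 0]
    for rec in records:
        if not rec.filters:
            continue
        fp = True
        for piece in split_multiallelic(rec):
            norm = normalize_variant(piece, reference)
            if (norm.chrom, norm.pos, norm.ref, norm.alts[0]) in truth_keys:
                fp = False
        bucket = combos.setdefault(rec.filters, [0, 0])
        for b in (bucket, overall, single if len(rec.filters) == 1 else multiple):
            b[0] += 1
            b[1] += int(fp)
    rows = []
    for combo in sorted(combos, key=lambda c: (len(c), sorted(c))):
        n, n_fp = combos[combo]
        rows.append(
            {
                "filters": ";".join(sorted(combo)),
                "n_sites": n,
                "fraction_fp": n_fp / n,
            }
        )
    for label, (n, n_fp) in (
        ("any single filter", single),
        ("multiple filters", multiple),
        ("all filtered", overall),
    ):
        rows.append(
            {
                "filters": label,
                "n_sites": n,
                "fraction_fp": n_fp / n if n else math.nan,
            }
        )
    return rows
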