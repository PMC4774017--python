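"""Haplotype-aware comparison of a query call set against a truth call set.

Truth variants inside the high-confidence regions are classified TP or FNV
(false negative variant); query variants inside the regions are TP or QV
(questionable variant); everything else is OUTSIDE and excluded from metrics.
Nearby variants are clustered and compared by exhaustive diploid haplotype
reconstruction, so equivalent representations of complex variants (e.g. two
phased SNVs vs one MNV) match.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Mapping, Sequence

from .core_io import CallSet, Region, VariantRecord
from .errors import ClusterTooComplexError, ConsistencyError
from .intervals import RegionSet

__all__ = [
    "MatchClass",
    "MatchRow",
    "MatchResult",
    "normalize_variant",
    "split_multiallelic",
    "haplotype_match",
    "classify",
]

TP = "TP"
FNV = "FNV"
QV = "QV"
OUTSIDE = "OUTSIDE"

#: the four per-variant classes emitted by :func:`classify`
MatchClass = (TP, FNV, QV, OUTSIDE)

#: maximum heterozygous sites per cluster for the exhaustive matcher
MAX_HET_PER_CLUSTER = 12


# ---------------------------------------------------------------------------
# Representation normalization


def split_multiallelic(v: VariantRecord) -> list[VariantRecord]:
    """Split a multi-allelic record into one record per ALT allele.

    The genotype is re-expressed against each single ALT; allele indices that
    refer to a *different* ALT become 0 (reference) in that record.
    """
    if len(v.alts) <= 1:
        return [v]
    out = []
    for i, alt in enumerate(v.alts, start=1):
        gt = None
        if v.genotype is not None:
            gt = tuple(
                None if a is None else (1 if a == i else 0) for a in v.genotype
            )
        out.append(replace(v, alts=(alt,), genotype=gt))
    return out


def normalize_variant(v: VariantRecord, reference: Mapping[str, str]) -> VariantRecord:
    """Canonicalize a variant: trim shared leading/trailing bases (keeping at
    least one base for indels) and left-align indels against the reference
    until no further shift is possible.  SNVs pass through unchanged.

    Raises :class:`ConsistencyError` if the REF allele disagrees with the
    reference sequence.
    """
    if v.chrom not in reference:
        raise ConsistencyError(f"chromosome {v.chrom!r} absent from reference")
    seq = reference[v.chrom]
    if seq[v.start0 : v.end0] != v.ref:
        raise ConsistencyError(
            f"{v.chrom}:{v.pos} REF {v.ref!r} does not match reference "
            f"{seq[v.start0:v.end0]!r}"
        )
    if len(v.alts) != 1:
        # multi-allelic: only trim bases shared by REF and every ALT
        ref, alts, pos = v.ref, list(v.alts), v.pos
        while len(ref) > 1 and all(len(a) > 1 and a[-1] == ref[-1] for a in alts):
            ref = ref[:-1]
            alts = [a[:-1] for a in alts]
        while len(ref) > 1 and all(len(a) > 1 and a[0] == ref[0] for a in alts):
            ref = ref[1:]
            alts = [a[1:] for a in alts]
            pos += 1
        return replace(v, pos=pos, ref=ref, alts=tuple(alts))
    pos, ref, alt = v.pos, v.ref, v.alts[0]
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if ref[-1] == alt[-1] and (len(ref) == 1 or len(alt) == 1) and pos > 1:
            prev = seq[pos - 2]
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise ConsistencyError(f"{v.chrom}:{v.pos} REF equals ALT after trimming")
    return replace(v, pos=pos, ref=ref, alts=(alt,))


# ---------------------------------------------------------------------------
# Haplotype matching


def _het(v: VariantRecord) -> bool:
    gt = _gt(v)
    return gt[0] != gt[1]


def _gt(v: VariantRecord) -> tuple[int, int]:
    # half-calls (./1) are treated as heterozygous with a reference side
    if v.genotype is None:
        return (0, 1)
    a, b = v.genotype
    return (0 if a is None else a, 0 if b is None else b)


def _apply_edits(window_seq: str, w_start0: int, edits: list[tuple[int, int, str]]) -> str | None:
    """Splice (start0, end0, alt) edits into the window sequence; ``None`` if
    edits overlap (unreconstructable haplotype)."""
    edits = sorted(edits)
    out = []
    cur = w_start0
    for s, e, alt in edits:
        if s < cur:
            return None
        out.append(window_seq[cur - w_start0 : s - w_start0])
        out.append(alt)
        cur = e
    out.append(window_seq[cur - w_start0 :])
    return "".join(out)


def _haplotype_pairs(
    records: Sequence[VariantRecord], window: Region, reference: Mapping[str, str]
) -> set[tuple[str, str]]:
    """All reconstructable unordered haplotype-sequence pairs over the window
    for every phasing assignment of the het records."""
    window_seq = reference[window.chrom][window.start : window.end]
    hets = [v for v in records if _het(v)]
    homs = [v for v in records if not _het(v)]
    if len(hets) > MAX_HET_PER_CLUSTER:
        raise ClusterTooComplexError(
            f"{window.chrom}:{window.start}-{window.end}: "
            f"{len(hets)} heterozygous sites exceed the cap of {MAX_HET_PER_CLUSTER}"
        )

    def edit(v: VariantRecord, allele: int) -> tuple[int, int, str] | None:
        if allele == 0:
            return None
        return (v.start0, v.end0, v.alts[allele - 1])

    hom_edits = []
    for v in homs:
        a, _ = _gt(v)
        hom_edits.append(edit(v, a))
    pairs: set[tuple[str, str]] = set()
    for bits in product((0, 1), repeat=len(hets)):
        hap_edits: tuple[list, list] = ([], [])
        for e in hom_edits:
            if e is not None:
                hap_edits[0].append(e)
                hap_edits[1].append(e)
        ok = True
        for v, bit in zip(hets, bits):
            a, b = _gt(v)
            for hap, allele in ((bit, a), (1 - bit, b)):
                e = edit(v, allele)
                if e is not None:
                    hap_edits[hap].append(e)
        seqs = []
        for h in (0, 1):
            s = _apply_edits(window_seq, window.start, hap_edits[h])
            if s is None:
                ok = False
                break
            seqs.append(s)
        if ok:
            pairs.add(tuple(sorted(seqs)))
    return pairs


def haplotype_match(
    truth_subset: Sequence[VariantRecord],
    query_subset: Sequence[VariantRecord],
    window: Region,
    reference: Mapping[str, str],
) -> bool:
    """True iff some phasing of the truth records and some phasing of the
    query records reconstruct the same unordered pair of window haplotype
    sequences.  Exhaustive over 2^h phasings of the het records."""
    for v in list(truth_subset) + list(query_subset):
        if v.chrom != window.chrom or v.start0 < window.start or v.end0 > window.end:
            raise ConsistencyError(
                f"variant {v.chrom}:{v.pos} outside matching window"
            )
    tp = _haplotype_pairs(truth_subset, window, reference)
    qp = _haplotype_pairs(query_subset, window, reference)
    return bool(tp & qp)


# ---------------------------------------------------------------------------
# Classification


@dataclass(frozen=True)
class MatchRow:
    """Classification of one (normalized, single-ALT) variant record."""

    variant: VariantRecord
    role: str  # "truth" | "query"
    match_class: str  # TP | FNV | QV | OUTSIDE
    genotype_match: bool | None = None
    edge_flag: bool = False
    partner: str | None = None  # id of the matched record on the other side
    cluster_id: int | None = None

    @property
    def vid(self) -> str:
        v = self.variant
        return f"{self.role}:{v.chrom}:{v.pos}:{v.ref}>{v.alts[0]}"


@dataclass
class MatchResult:
    """Per-variant classifications plus the filtered query records that were
    excluded from matching (kept for false-negative cause attribution)."""

    rows: list[MatchRow] = field(default_factory=list)
    filtered_query: list[VariantRecord] = field(default_factory=list)

    def count(self, role: str, match_class: str) -> int:
        return sum(1 for r in self.rows if r.role == role and r.match_class == match_class)

    @property
    def tp(self) -> int:
        """True positives on the truth side (Table-1 numerator)."""
        return self.count("truth", TP)

    @property
    def fnv(self) -> int:
        return self.count("truth", FNV)

    @property
    def qv(self) -> int:
        return self.count("query", QV)

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fnv
        return None if denom == 0 else self.tp / denom

    def truth_rows(self, in_region_only: bool = True) -> list[MatchRow]:
        return [
            r
            for r in self.rows
            if r.role == "truth" and (not in_region_only or r.match_class != OUTSIDE)
        ]

    def genotype_discordant(self) -> list[MatchRow]:
        """Allele-level matches called with the wrong genotype: counted as TP
        for sensitivity but reported as questionable-genotype diagnostics."""
        return [
            r
            for r in self.rows
            if r.role == "query" and r.match_class == TP and r.genotype_match is False
        ]

    def fnv_records(self) -> list[VariantRecord]:
        return [r.variant for r in self.rows if r.role == "truth" and r.match_class == FNV]

    def to_rows(self) -> list[dict]:
        out = []
        for r in sorted(self.rows, key=lambda r: (r.variant.chrom, r.variant.pos, r.role)):
            v = r.variant
            out.append(
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alts[0],
                    "role": r.role,
                    "class": r.match_class,
                    "genotype_match": "" if r.genotype_match is None else str(r.genotype_match),
                    "edge_flag": str(r.edge_flag),
                    "filters": ";".join(sorted(v.filters)),
                    "partner": r.partner or "",
                }
            )
        return out


def _prepare(records: Iterable[VariantRecord], reference) -> list[VariantRecord]:
    out = []
    for v in records:
        for piece in split_multiallelic(v):
            out.append(normalize_variant(piece, reference))
    return sorted(out, key=lambda v: (v.chrom, v.pos, v.ref, v.alts))


def _genotypes_equal(a: VariantRecord, b: VariantRecord) -> bool:
    return tuple(sorted(_gt(a))) == tuple(sorted(_gt(b)))


def classify(
    query: CallSet,
    truth: CallSet,
    hiconf: RegionSet,
    reference: Mapping[str, str],
    edge_bp: int = 50,
    cluster_gap: int = 50,
    genotype_strict: bool = False,
) -> MatchResult:
    """Classify every truth and query variant.

    Non-PASS query records are excluded from matching (they surface again in
    FN-cause attribution).  Matching is exact on (chrom, pos, ref, alt) after
    normalization, then haplotype-aware within clusters of variants at most
    ``cluster_gap`` bases apart.  ``edge_bp`` controls the inside-edge flag:
    a variant within ``edge_bp`` bases of a high-confidence boundary (i.e.
    edge_distance <= edge_bp - 1) is flagged.

    With ``genotype_strict`` an exact allele match with discordant genotype
    is not a TP: the truth record becomes FNV and the query record QV.
    """
    truth_norm = _prepare(truth.records, reference)
    query_all = _prepare(query.records, reference)
    query_pass = [v for v in query_all if not v.filters]
    filtered = [v for v in query_all if v.filters]

    sides = {"truth": truth_norm, "query": query_pass}
    in_region: dict[str, list[VariantRecord]] = {"truth": [], "query": []}
    rows: list[MatchRow] = []
    for role, recs in sides.items():
        for v in recs:
            if hiconf.contains(v.chrom, v.pos):
                in_region[role].append(v)
            else:
                rows.append(MatchRow(v, role, OUTSIDE))

    # exact matching on the normalized key
    def keyed(recs):
        d: dict[tuple, list[VariantRecord]] = {}
        for v in recs:
            d.setdefault((v.chrom, v.pos, v.ref, v.alts[0]), []).append(v)
        return d

    tk, qk = keyed(in_region["truth"]), keyed(in_region["query"])
    matched: dict[int, tuple[VariantRecord, bool]] = {}  # id(variant) -> (partner, gt_ok)
    for key in tk:
        if key not in qk:
            continue
        for tv, qv in zip(tk[key], qk[key]):
            gt_ok = _genotypes_equal(tv, qv)
            if genotype_strict and not gt_ok:
                continue
            matched[id(tv)] = (qv, gt_ok)
            matched[id(qv)] = (tv, gt_ok)

    # cluster all in-region variants; haplotype-match clusters that still
    # contain unmatched records on both sides
    tagged = [(v, "truth") for v in in_region["truth"]] + [
        (v, "query") for v in in_region["query"]
    ]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].pos, t[0].ref, t[0].alts))
    clusters: list[list[tuple[VariantRecord, str]]] = []
    for item in tagged:
        v = item[0]
        if (
            clusters
            and clusters[-1][-1][0].chrom == v.chrom
            and v.start0 - max(u.end0 for u, _ in clusters[-1]) <= cluster_gap
        ):
            clusters[-1].append(item)
        else:
            clusters.append([item])

    hap_matched: set[int] = set()
    for ci, cluster in enumerate(clusters):
        unmatched = [(v, role) for v, role in cluster if id(v) not in matched]
        if not unmatched:
            continue
        t_side = [v for v, role in cluster if role == "truth"]
        q_side = [v for v, role in cluster if role == "query"]
        if not t_side or not q_side:
            continue
        chrom = cluster[0][0].chrom
        lo = max(0, min(v.start0 for v, _ in cluster) - 1)
        hi = min(len(reference[chrom]), max(v.end0 for v, _ in cluster) + 1)
        if haplotype_match(t_side, q_side, Region(chrom, lo, hi), reference):
            for v, _ in cluster:
                hap_matched.add(id(v))

    cluster_of = {
        id(v): ci for ci, cluster in enumerate(clusters) for v, _ in cluster
    }
    for role, recs in in_region.items():
        for v in recs:
            dist = hiconf.edge_distance(v.chrom, v.pos)
            edge = dist is not None and dist <= edge_bp - 1
            ci = cluster_of.get(id(v))
            if id(v) in matched:
                partner, gt_ok = matched[id(v)]
                rows.append(
                    MatchRow(v, role, TP, gt_ok, edge,
                             f"{('query' if role == 'truth' else 'truth')}:"
                             f"{partner.chrom}:{partner.pos}:{partner.ref}>{partner.alts[0]}",
                             ci)
                )
            elif id(v) in hap_matched:
                rows.append(MatchRow(v, role, TP, True, edge, f"cluster:{ci}", ci))
            else:
                rows.append(
                    MatchRow(v, role, FNV if role == "truth" else QV, None, edge, None, ci)
                )
    return MatchResult(rows=rows, filtered_query=filtered)
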