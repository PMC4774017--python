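"""Detection of platform-consistent systematic-error sites.

A systematic-error site is a benchmark homozygous-reference position where
*all* datasets of one sequencing platform, or more than two of them, call a
variant (with quality above a permissive threshold).  Detected sites are then
intersected allele-aware with database variant lists: a database record only
matches when its alternative allele agrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core_io import CallSet, VariantRecord
from .errors import DomainError
from .intervals import RegionSet
from .varcomp import normalize_variant, split_multiallelic

__all__ = ["PlatformPanel", "SystematicErrorSite", "detect", "db_intersect"]


@dataclass
class PlatformPanel:
    """All call sets produced from one sequencing technology."""

    platform: str
    datasets: list[CallSet]

    def __post_init__(self) -> None:
        if not self.datasets:
            raise DomainError(f"platform {self.platform!r} has zero datasets")
        labels = [d.source_label for d in self.datasets]
        if len(set(labels)) != len(labels):
            raise DomainError(
                f"platform {self.platform!r}: dataset source_labels not unique"
            )


@dataclass
class SystematicErrorSite:
    chrom: str
    pos: int
    ref: str
    alt: str  # majority alt over evidence calls; ties -> lexicographic smallest
    alts: tuple[str, ...]  # all observed alts
    platforms: frozenset[str]
    n_evidence: int
    db_hits: dict[str, bool] = field(default_factory=dict)

    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.ref)


def _evidence_calls(
    callset: CallSet,
    homref: RegionSet,
    min_qual: float,
    reference: Mapping[str, str] | None,
):
    """Yield normalized single-ALT records that constitute evidence for an
    incorrect genotype: a call whose genotype contains a non-reference allele
    (or any call when no genotype was emitted) with qual > min_qual at a
    benchmark hom-ref position."""
    for rec in callset.records:
        if rec.qual is None or rec.qual <= min_qual:
            continue
        if rec.genotype is not None and not any(a for a in rec.genotype if a):
            continue
        for piece in split_multiallelic(rec):
            v = normalize_variant(piece, reference) if reference else piece
            if homref.contains(v.chrom, v.pos):
                yield v


def detect(
    benchmark_homref: RegionSet,
    panels: Sequence[PlatformPanel],
    min_qual: float = 2,
    reference: Mapping[str, str] | None = None,
) -> list[SystematicErrorSite]:
    """Find sites flagged by at least one platform.

    A platform flags a site when the number of its datasets with evidence
    equals the platform's dataset count ("all"), or exceeds two.  Supplying
    ``reference`` left-aligns evidence calls first, so homopolymer indels in
    shifted representations collapse to one site.
    """
    # (chrom,pos,ref) -> platform -> dataset label -> alt list
    evidence: dict[tuple, dict[str, dict[str, list[str]]]] = {}
    for panel in panels:
        for ds in panel.datasets:
            for v in _evidence_calls(ds, benchmark_homref, min_qual, reference):
                site = evidence.setdefault((v.chrom, v.pos, v.ref), {})
                site.setdefault(panel.platform, {}).setdefault(
                    ds.source_label, []
                ).append(v.alts[0])

    n_datasets = {p.platform: len(p.datasets) for p in panels}
    out = []
    for key in sorted(evidence):
        chrom, pos, ref = key
        flagged = set()
        alts: list[str] = []
        n_ev = 0
        for platform, per_ds in evidence[key].items():
            n = len(per_ds)
            if n == n_datasets[platform] or n > 2:
                flagged.add(platform)
                for ds_alts in per_ds.values():
                    alts.extend(ds_alts)
                n_ev += n
        if not flagged:
            continue
        assert benchmark_homref.contains(chrom, pos)
        tally: dict[str, int] = {}
        for a in alts:
            tally[a] = tally.get(a, 0) + 1
        best = max(tally.values())
        majority = sorted(a for a, c in tally.items() if c == best)[0]
        out.append(
            SystematicErrorSite(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=majority,
                alts=tuple(sorted(set(alts))),
                platforms=frozenset(flagged),
                n_evidence=n_ev,
            )
        )
    return out


def db_intersect(
    sites: Sequence[SystematicErrorSite],
    databases: Mapping[str, CallSet],
    reference: Mapping[str, str] | None = None,
) -> tuple[dict[str, int], list[SystematicErrorSite]]:
    """Allele-aware intersection of systematic-error sites with database
    variant lists.

    A site matches a database record iff chrom, normalized position, REF and
    at least one ALT agree.  Returns Table-2-shaped counts: total sites,
    per-database counts, and a deduplicated "any_database" total; sites come
    back annotated with per-database hit booleans.
    """
    db_keys: dict[str, dict[tuple, set[str]]] = {}
    for label in sorted(databases):
        keyed: dict[tuple, set[str]] = {}
        for rec in databases[label].records:
            for piece in split_multiallelic(rec):
                v = normalize_variant(piece, reference) if reference else piece
                keyed.setdefault((v.chrom, v.pos, v.ref), set()).add(v.alts[0])
        db_keys[label] = keyed

    counts = {"total_sites": len(sites)}
    any_hit = 0
    for site in sites:
        hit_any = False
        for label, keyed in db_keys.items():
            alts = keyed.get(site.key(), set())
            hit = bool(alts & set(site.alts))
            site.db_hits[label] = hit
            hit_any = hit_any or hit
        any_hit += int(hit_any)
    counts["any_database"] = any_hit
    for label in db_keys:
        counts[label] = sum(1 for s in sites if s.db_hits.get(label))
    return counts, list(sites)
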