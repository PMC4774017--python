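"""Per-position k-mer uniqueness and mismatch-tolerant alignability tracks.

A position is *unique* at k when the k-mer starting there occurs at exactly
one genomic location (forward strand, matching how the classic browser
tracks were built); it is *alignable* at (k, m) when no second location lies
within Hamming distance m (gapless).  K-mers containing N are never unique
or alignable: undefined sequence cannot certify uniqueness, and an N is
counted as a mismatch against every base including another N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError
from .intervals import RegionSet
from .core_io import Region, VariantRecord

__all__ = [
    "UniquenessTrack",
    "VariantContext",
    "exact_uniqueness",
    "alignability",
    "variant_context",
    "percentage",
    "track_to_regions",
]


@dataclass
class UniquenessTrack:
    """Boolean per-position flags: True iff the k-mer starting at that
    position has exactly one genomic location under the track's mode."""

    k: int
    mode: str  # "exact" | "mismatch(m)"
    flags: dict[str, np.ndarray]

    def at(self, chrom: str, pos0: int) -> bool | None:
        """Flag at a 0-based position; ``None`` when out of track range."""
        arr = self.flags.get(chrom)
        if arr is None or not 0 <= pos0 < len(arr):
            return None
        return bool(arr[pos0])

    def fraction_true(self, within: RegionSet | None = None) -> float:
        """Fraction of valid (in-range) positions flagged unique, optionally
        restricted to a region set."""
        num = denom = 0
        for chrom in sorted(self.flags):
            arr = self.flags[chrom]
            valid = len(arr) - self.k + 1
            if valid <= 0:
                continue
            if within is None:
                num += int(arr[:valid].sum())
                denom += valid
            else:
                mask = np.zeros(valid, dtype=bool)
                for r in within:
                    if r.chrom == chrom:
                        mask[r.start : min(r.end, valid)] = True
                num += int((arr[:valid] & mask).sum())
                denom += int(mask.sum())
        if denom == 0:
            raise DomainError("no valid positions for fraction_true")
        return num / denom


def _validate_k(reference: Mapping[str, str], k: int) -> None:
    if k < 1:
        raise DomainError("k must be >= 1")
    if not reference or k > max(len(s) for s in reference.values()):
        raise DomainError(f"k={k} exceeds the longest chromosome")


def exact_uniqueness(reference: Mapping[str, str], k: int = 35) -> UniquenessTrack:
    """Exact k-mer uniqueness: position p is True iff its k-mer occurs once
    among all forward-strand k-mer start positions genome-wide and contains
    no N."""
    _validate_k(reference, k)
    counts: dict[str, int] = {}
    for chrom in reference:
        seq = reference[chrom]
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
    flags = {}
    for chrom in reference:
        seq = reference[chrom]
        arr = np.zeros(len(seq), dtype=bool)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer and counts[kmer] == 1:
                arr[i] = True
        flags[chrom] = arr
    return UniquenessTrack(k=k, mode="exact", flags=flags)


_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(
    reference: Mapping[str, str],
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, int]]]:
    """Concatenate chromosomes into one int32 array.  Each N and each
    inter-chromosome separator base gets a distinct negative code so it
    mismatches everything (including other Ns); the returned boolean mask
    marks separator positions so windows spanning a chromosome junction can
    be excluded outright."""
    chroms = sorted(reference)
    pieces = []
    sep_pieces = []
    spans = []
    cursor = 0
    sentinel = -1
    for chrom in chroms:
        seq = reference[chrom]
        arr = np.empty(len(seq), dtype=np.int32)
        for i, b in enumerate(seq):
            code = _BASE_CODES.get(b)
            if code is None:
                code = sentinel
                sentinel -= 1
            arr[i] = code
        pieces.append(arr)
        sep_pieces.append(np.zeros(len(seq), dtype=bool))
        spans.append((chrom, cursor, cursor + len(seq)))
        cursor += len(seq)
        pieces.append(np.arange(sentinel - 200, sentinel, dtype=np.int32))
        sep_pieces.append(np.ones(200, dtype=bool))
        sentinel -= 201
        cursor += 200
    if not pieces:
        return np.array([], np.int32), np.array([], bool), spans
    return np.concatenate(pieces[:-1]), np.concatenate(sep_pieces[:-1]), spans


def alignability(
    reference: Mapping[str, str],
    k: int = 100,
    max_mismatch: int = 2,
    window: int | None = None,
) -> UniquenessTrack:
    """Mismatch-tolerant uniqueness: position p is True iff no *other*
    genomic location matches its k-mer within Hamming distance
    ``max_mismatch`` (gapless comparison, forward strand).

    The scan is quadratic in genome length; ``window`` bounds the shift
    between compared locations (a banded scan) for larger genomes, at the
    cost of missing distant near-duplicates.  ``max_mismatch=0`` reproduces
    :func:`exact_uniqueness`.
    """
    _validate_k(reference, k)
    if max_mismatch < 0:
        raise DomainError("max_mismatch must be >= 0")
    arr, sep, spans = _encode(reference)
    L = len(arr)
    n_starts = L - k + 1
    multi = np.zeros(max(n_starts, 0), dtype=bool)
    if n_starts > 0:
        cs = np.concatenate(([0], np.cumsum(sep.astype(np.int32))))
        in_genome = (cs[k:] - cs[:-k]) == 0  # window stays within one chromosome
    max_shift = L - k if window is None else min(window, L - k)
    for d in range(1, max_shift + 1):
        neq = (arr[d:] != arr[:-d]).astype(np.int32)
        if len(neq) < k:
            break
        c = np.concatenate(([0], np.cumsum(neq)))
        mism = c[k:] - c[:-k]  # mism[i] = Hamming(kmer_i, kmer_{i+d})
        n_pairs = len(mism)
        hit = (mism <= max_mismatch) & in_genome[:n_pairs] & in_genome[d : d + n_pairs]
        idx = np.nonzero(hit)[0]
        multi[idx] = True
        multi[idx + d] = True
    flags = {}
    for chrom, lo, hi in spans:
        n = hi - lo
        out = np.zeros(n, dtype=bool)
        valid = n - k + 1
        if valid > 0:
            seq = reference[chrom]
            ok = ~multi[lo : lo + valid]
            # positions whose k-mer contains N are never alignable
            n_pos = np.array([c == "N" for c in seq], dtype=np.int32)
            cn = np.concatenate(([0], np.cumsum(n_pos)))
            has_n = (cn[k:] - cn[:-k]) > 0
            out[:valid] = ok & ~has_n
        flags[chrom] = out
    return UniquenessTrack(k=k, mode=f"mismatch({max_mismatch})", flags=flags)


# ---------------------------------------------------------------------------
# Variant context (Table-4 semantics)


@dataclass(frozen=True)
class VariantContext:
    variant: VariantRecord
    in_hiconf: bool
    unique35: bool | None
    alignable100: bool | None
    subset: str | None = None


def percentage(numerator: int, denominator: int) -> float:
    """Report a count as a percentage, rounded to 2 decimals (the printed
    convention of the context summaries)."""
    if denominator <= 0:
        raise DomainError("percentage requires a positive denominator")
    return round(100.0 * numerator / denominator, 2)


def variant_context(
    variants: Sequence[VariantRecord],
    hiconf: RegionSet,
    track35: UniquenessTrack,
    track100: UniquenessTrack,
    subsets: Mapping[int, str] | None = None,
) -> tuple[list[VariantContext], list[dict]]:
    """Annotate each variant with its genomic-context flags (inside the
    high-confidence regions; starts a unique 35-mer; starts an alignable
    100-mer) and summarize the percentage true per flag, overall and per
    subset label.  Flags are looked up at the variant's 0-based start."""
    contexts = []
    for i, v in enumerate(variants):
        contexts.append(
            VariantContext(
                variant=v,
                in_hiconf=hiconf.contains(v.chrom, v.pos),
                unique35=track35.at(v.chrom, v.start0),
                alignable100=track100.at(v.chrom, v.start0),
                subset=subsets.get(i) if subsets else None,
            )
        )
    groups: list[tuple[str, list[VariantContext]]] = [("all", contexts)]
    if subsets:
        for label in sorted({s for s in subsets.values()}):
            groups.append((label, [c for c in contexts if c.subset == label]))
    rows = []
    for label, group in groups:
        n = len(group)
        if n == 0:
            continue
        rows.append(
            {
                "subset": label,
                "n": n,
                "pct_in_hiconf": percentage(sum(c.in_hiconf for c in group), n),
                "pct_unique35": percentage(sum(bool(c.unique35) for c in group), n),
                "pct_alignable100": percentage(sum(bool(c.alignable100) for c in group), n),
            }
        )
    return contexts, rows


def track_to_regions(track: UniquenessTrack) -> list[Region]:
    """Runs of True positions as BED-style regions (for export)."""
    out = []
    for chrom in sorted(track.flags):
        arr = track.flags[chrom]
        if not arr.any():
            continue
        diff = np.diff(arr.astype(np.int8), prepend=0, append=0)
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        out.extend(Region(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out
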