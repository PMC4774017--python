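"""Domain types and readers/writers for the standard formats the pipeline touches.

Coordinate conventions follow each format's native one and are converted at
exactly one boundary: :class:`Region` is 0-based half-open (BED), while
:class:`VariantRecord.pos` is 1-based (VCF).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

from .errors import FormatError

__all__ = [
    "Region",
    "VariantRecord",
    "GeneModel",
    "GeneSet",
    "CallSet",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_fasta",
    "write_fasta",
    "read_gene_set",
    "write_report",
]

_DNA = frozenset("ACGTN")


@dataclass(frozen=True, order=True)
class Region:
    """Half-open genomic interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise FormatError("Region chrom must be non-empty")
        if self.start < 0:
            raise FormatError(f"Region start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise FormatError(
                f"Region end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VariantRecord:
    """One small-variant call.

    ``pos`` is the 1-based position of the first REF base.  ``filters`` is the
    set of failing filter labels; an empty set means PASS.  ``genotype`` is a
    pair of allele indices (0 = REF, ``None`` for the missing side of a
    half-call) or ``None`` when no genotype was emitted.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    filters: frozenset[str] = frozenset()
    genotype: tuple[int | None, int | None] | None = None
    depth: int | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"VariantRecord pos must be >= 1, got {self.pos}")
        if not self.ref or not set(self.ref) <= _DNA:
            raise FormatError(f"bad REF allele {self.ref!r}")
        for alt in self.alts:
            if not alt or not set(alt) <= _DNA:
                raise FormatError(f"bad ALT allele {alt!r}")
        if self.genotype is not None:
            for a in self.genotype:
                if a is not None and not 0 <= a <= len(self.alts):
                    raise FormatError(
                        f"genotype index {a} out of range for {len(self.alts)} alt(s)"
                    )
        if self.depth is not None and self.depth < 0:
            raise FormatError("depth must be non-negative")

    @property
    def start0(self) -> int:
        """0-based start of the REF allele."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end of the REF allele."""
        return self.pos - 1 + len(self.ref)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_half_call(self) -> bool:
        return self.genotype is not None and any(a is None for a in self.genotype)

    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        return (self.chrom, self.pos, self.ref, self.alts)


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: ordered exons plus optional CDS bounds (0-based
    half-open, BED-like).  ``cds_start``/``cds_end`` are ``None`` for
    non-coding transcripts.  Exons are kept in genomic order regardless of
    strand."""

    name: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Region, ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise FormatError(f"gene {self.name}: no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise FormatError(
                    f"gene {self.name}: exons overlap or are unsorted"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise FormatError(f"gene {self.name}: partial CDS bounds")
        if self.cds_start is not None:
            if not (self.exons[0].start <= self.cds_start < self.cds_end <= self.exons[-1].end):
                raise FormatError(f"gene {self.name}: CDS outside exon span")

    @property
    def span(self) -> Region:
        return Region(self.chrom, self.exons[0].start, self.exons[-1].end)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def cds_intervals(self) -> list[Region]:
        """Exon pieces inside the CDS bounds, genomic order."""
        if not self.is_coding:
            return []
        out = []
        for e in self.exons:
            s, t = max(e.start, self.cds_start), min(e.end, self.cds_end)
            if t > s:
                out.append(Region(self.chrom, s, t))
        return out

    @property
    def cds_length(self) -> int:
        return sum(r.length for r in self.cds_intervals())


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (e.g. a clinical reporting panel)."""

    name: str
    members: frozenset[str]


@dataclass
class CallSet:
    """All calls for one sample from one source, sorted by (chrom, pos)."""

    sample_id: str
    records: list[VariantRecord] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos, r.ref, r.alts))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# VCF


def _check_alt(alt: str, where: str) -> None:
    if alt.startswith("<") or "[" in alt or "]" in alt or alt == "*":
        raise FormatError(
            f"{where}: symbolic/breakend ALT {alt!r} is not supported "
            "(structural variants are outside the benchmark scope)"
        )


def read_vcf(path: str | Path, sample: str | None = None) -> CallSet:
    """Read a VCF 4.x file into a :class:`CallSet`.

    Only CHROM/POS/REF/ALT/QUAL/FILTER plus one sample's GT and DP are
    interpreted.  ``PASS`` and ``.`` map to an empty filter set.  Sites-only
    files yield records without genotype/depth.
    """
    path = str(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            vf = pysam.VariantFile(path)
        except (ValueError, OSError) as exc:
            raise FormatError(f"{path}: cannot parse VCF header: {exc}") from exc
        samples = list(vf.header.samples)
        if sample is None:
            if len(samples) > 1:
                raise FormatError(
                    f"{path}: multi-sample VCF, name one of {samples}"
                )
            sample = samples[0] if samples else ""
        elif sample not in samples:
            raise KeyError(f"{path}: sample {sample!r} not in {samples}")

        records: list[VariantRecord] = []
        lineno = len(str(vf.header).rstrip("\n").split("\n"))
        try:
            for rec in vf:
                lineno += 1
                records.append(_convert_record(rec, sample, path, lineno))
        except (ValueError, OSError) as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: malformed VCF line {lineno}: {exc}") from exc
        finally:
            vf.close()
    return CallSet(sample_id=sample, records=records, source_label=path)


def _convert_record(rec, sample: str, path: str, lineno: int) -> VariantRecord:
    where = f"{path}: line {lineno}"
    alts = tuple(rec.alts or ())
    if not alts:
        raise FormatError(f"{where}: record without ALT allele")
    for alt in alts:
        _check_alt(alt, where)
    filters = frozenset(k for k in rec.filter.keys() if k != "PASS")
    genotype = None
    depth = None
    if sample:
        fmt = rec.samples[sample]
        gt = fmt.get("GT")
        if gt is not None and gt != (None,) and len(gt) > 0:
            if len(gt) == 1:
                gt = (gt[0], gt[0])
            genotype = (gt[0], gt[1])
            if genotype == (None, None):
                genotype = None
        dp = fmt.get("DP")
        if dp is not None:
            depth = int(dp)
    try:
        return VariantRecord(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref.upper(),
            alts=tuple(a.upper() for a in alts),
            # htslib stores QUAL as float32; round away its representation noise
            qual=None if rec.qual is None else round(float(rec.qual), 3),
            filters=filters,
            genotype=genotype,
            depth=depth,
            sample_id=sample,
        )
    except FormatError as exc:
        raise FormatError(f"{where}: {exc}") from exc


def write_vcf(
    callset: CallSet,
    path: str | Path,
    contigs: Mapping[str, int] | Sequence[str] | None = None,
    sites_only: bool = False,
) -> None:
    """Write a CallSet as an uncompressed VCF 4.2 file.

    All filter labels appearing in the records are declared in the header so
    the file round-trips through htslib without edits.
    """
    labels = sorted({f for r in callset.records for f in r.filters})
    lines = ["##fileformat=VCFv4.2", f"##source=varbench"]
    if contigs is not None:
        if isinstance(contigs, Mapping):
            for name in contigs:
                lines.append(f"##contig=<ID={name},length={contigs[name]}>")
        else:
            for name in contigs:
                lines.append(f"##contig=<ID={name}>")
    else:
        for name in sorted({r.chrom for r in callset.records}):
            lines.append(f"##contig=<ID={name}>")
    for lab in labels:
        lines.append(f'##FILTER=<ID={lab},Description="{lab}">')
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if not sites_only:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
        header += f"\tFORMAT\t{callset.sample_id or 'SAMPLE'}"
    lines.append(header)
    for r in callset.records:
        qual = "." if r.qual is None else f"{r.qual:g}"
        filt = ";".join(sorted(r.filters)) if r.filters else "PASS"
        row = [r.chrom, str(r.pos), ".", r.ref, ",".join(r.alts), qual, filt, "."]
        if not sites_only:
            if r.genotype is None:
                gt = "./."
            else:
                gt = "/".join("." if a is None else str(a) for a in r.genotype)
            dp = "." if r.depth is None else str(r.depth)
            row += ["GT:DP", f"{gt}:{dp}"]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Region]:
    """Read a BED3+ file into sorted Regions.  Overlaps are preserved as
    given; merging is a separate operation (:func:`varbench.intervals.normalize`)."""
    regions = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {i}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: non-integer bounds") from exc
            if end <= start or start < 0:
                raise FormatError(
                    f"{path}: line {i}: bad interval [{start}, {end})"
                )
            regions.append(Region(parts[0], start, end))
    return sorted(regions)


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# Gene models (refFlat-style)

_REFFLAT_COLS = (
    "geneName",
    "name",
    "chrom",
    "strand",
    "exonCount",
    "exonStarts",
    "exonEnds",
    "cdsStart",
    "cdsEnd",
)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-style tab table (columns: geneName, name, chrom, strand,
    exonCount, exonStarts, exonEnds, cdsStart, cdsEnd; exon bounds are
    comma-separated 0-based half-open).  ``cdsStart == cdsEnd`` (or ``.``)
    marks a non-coding transcript."""
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}: line {i}: expected 9 columns")
            gname, tid, chrom, strand, n, starts_s, ends_s, cs, ce = parts[:9]
            starts = [int(x) for x in starts_s.rstrip(",").split(",") if x]
            ends = [int(x) for x in ends_s.rstrip(",").split(",") if x]
            if len(starts) != int(n) or len(ends) != int(n):
                raise FormatError(
                    f"{path}: line {i}: exonCount {n} inconsistent with bound lists"
                )
            exons = tuple(Region(chrom, s, e) for s, e in zip(starts, ends))
            cds_start = cds_end = None
            if cs not in (".", "") and ce not in (".", "") and int(cs) != int(ce):
                cds_start, cds_end = int(cs), int(ce)
            try:
                genes.append(
                    GeneModel(gname, tid, chrom, strand, exons, cds_start, cds_end)
                )
            except FormatError as exc:
                raise FormatError(f"{path}: line {i}: {exc}") from exc
    return sorted(genes, key=lambda g: (g.chrom, g.span.start, g.name))


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_REFFLAT_COLS) + "\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.span.start, g.name)):
            starts = ",".join(str(e.start) for e in g.exons) + ","
            ends = ",".join(str(e.end) for e in g.exons) + ","
            cs = "." if g.cds_start is None else str(g.cds_start)
            ce = "." if g.cds_end is None else str(g.cds_end)
            fh.write(
                "\t".join(
                    [g.name, g.transcript_id, g.chrom, g.strand,
                     str(len(g.exons)), starts, ends, cs, ce]
                )
                + "\n"
            )


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list; the set name defaults to the
    file stem."""
    path = Path(path)
    members = frozenset(
        line.strip() for line in path.read_text().splitlines() if line.strip()
    )
    return GeneSet(name or path.stem, members)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into a mapping chrom -> uppercased sequence string."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Reports

#: column-name driven numeric formatting, so every writer is deterministic
_DEFAULT_FORMATS: tuple[tuple[str, str], ...] = (
    ("sensitivity", "{:.3f}"),
    ("ci_", "{:.3f}"),
    ("percent", "{:.2f}"),
    ("pct", "{:.2f}"),
    ("fraction", "{:.4f}"),
)


def _format_value(col: str, value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if value != value:  # NaN
            return "NA"
        low = col.lower()
        for key, fmt in _DEFAULT_FORMATS:
            if key in low:
                return fmt.format(value)
        return f"{value:.6g}"
    return str(value)


def write_report(rows, path: str | Path, format: str = "tsv", header_comment: str | None = None) -> None:
    """Write a list of dict rows (or a DataFrame) as TSV or JSON with stable
    column order and fixed numeric formatting (sensitivities/CI bounds 3
    decimals, percentages 2 decimals)."""
    if hasattr(rows, "to_dict"):  # DataFrame
        rows = rows.to_dict(orient="records")
    rows = list(rows)
    if format == "json":
        def _clean(v):
            return None if (isinstance(v, float) and v != v) else v
        payload = [{k: _clean(v) for k, v in row.items()} for row in rows]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=False)
            fh.write("\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    cols: list[str] = []
    for row in rows:
        for k in row:
            if k not in cols:
                cols.append(k)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_format_value(c, row.get(c)) for c in cols) + "\n")
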