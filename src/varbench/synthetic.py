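"""Seeded generator for every input the benchmarking pipeline consumes.

The bundle emulates, at desk scale, the structure of a diploid truth set
benchmarked against high-confidence regions: a random reference with planted
difficult features, genes with valid reading frames, truth variants planted
per functional stratum, a query call set derived from the truth by applying
configured error modes (filter removal, low-coverage misses, genotype errors,
MNV re-representation, strand-bias false calls), per-platform panels with
planted systematic-error sites, and database variant lists.  Ground-truth
bookkeeping tables accompany every planted fact and serve as test oracles via
:func:`expected_metrics`, which recounts them without touching pipeline code.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right, insort
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    CallSet,
    GeneModel,
    GeneSet,
    Region,
    VariantRecord,
    write_bed,
    write_fasta,
    write_gene_models,
    write_vcf,
)
from .errors import GenerationError
from .intervals import RegionSet, normalize
from .syserr import PlatformPanel

__all__ = ["SimConfig", "TruthBundle", "generate", "expected_metrics", "ExpectedMetrics"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = {"TAA", "TAG", "TGA"}
_CODON_TABLE = {}
for _a in "TCAG":
    for _b in "TCAG":
        for _c in "TCAG":
            _CODON_TABLE[_a + _b + _c] = None  # filled below
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _codon in enumerate(_CODON_TABLE):
    _CODON_TABLE[_codon] = _AA[_i]


def _translate(codon: str) -> str:
    return _CODON_TABLE[codon]


@dataclass
class SimConfig:
    """All knobs of the generator; identical seed + config gives a
    byte-identical bundle."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000

    # low-confidence structure: fraction of the genome excluded and the
    # precedence-ordered reason mix (the bookkeeping is exact by construction)
    lowconf_fraction: float = 0.12
    reason_fractions: dict = field(
        default_factory=lambda: {
            "dbVar_SV": 0.47,
            "RepSeqSTR": 0.34,
            "segdup": 0.15,
            "simple_repeat": 0.04,
        }
    )
    lowconf_margin: int = 20  # padding kept around planted sequence features
    segment_size: tuple = (500, 3000)

    # repeat-annotation tracks (do not alter the sequence)
    repeat_classes: dict = field(
        default_factory=lambda: {
            "SINE": (60, 120, 350),  # (count, min_len, max_len)
            "LINE": (20, 400, 1200),
            "low_complexity": (15, 60, 200),
        }
    )

    # GC-rich windows (sequence rewritten to ~90% G+C)
    n_gc_windows: int = 12
    gc_window_length: int = 160

    # gene models
    n_genes: int = 80
    exon_count: tuple = (2, 8)
    exon_length: tuple = (120, 280)
    intron_length: tuple = (200, 800)
    acmg_size: int = 8
    clinvar_omim_size: int = 24
    sv_overlap_gene_fraction: float = 0.25  # genes deliberately straddling SV segments

    # truth variants
    stratum_counts: dict = field(
        default_factory=lambda: {
            "non-synonymous": 300,
            "synonymous": 300,
            "truncating": 50,
            "splicing": 40,
            "intergenic": 2300,
        }
    )
    n_mnv_pairs: int = 30
    het_fraction: float = 0.67
    outside_fraction: float = 0.05  # of intergenic variants planted out of region
    min_variant_spacing: int = 60

    # error modes
    stratum_sensitivity: dict = field(
        default_factory=lambda: {
            "non-synonymous": 0.95,
            "synonymous": 0.95,
            "truncating": 0.95,
            "splicing": 0.90,
            "intergenic": 0.95,
        }
    )
    miss_filtered_fraction: float = 0.6
    gc_miss_fraction: float = 0.3  # of low-coverage intergenic misses in GC windows
    repeat_miss_fraction: float = 0.3  # of filtered intergenic misses inside SINEs
    filter_weights: dict = field(
        default_factory=lambda: {
            "Q20": 0.30,
            "MQ": 0.20,
            "badReads": 0.15,
            "hp10": 0.10,
            "SC": 0.10,
            "strandBias": 0.15,
        }
    )
    multi_filter_fraction: float = 0.2
    genotype_error_rate: float = 0.02
    mnv_shuffle_rate: float = 0.5
    n_false_positives: int = 40
    fp_filtered_fraction: float = 0.5
    fp_edge_fraction: float = 0.4  # of unfiltered FPs placed near an inside edge
    mean_depth: float = 30.0

    # platform panels / systematic errors
    platforms: dict = field(default_factory=lambda: {"HiSeq": 3, "PGM": 4})
    n_systematic_sites: int = 25
    n_subthreshold_sites: int = 10
    n_lowqual_sites: int = 3
    database_fractions: dict = field(
        default_factory=lambda: {"dbSNP": 0.5, "ClinVar": 0.12}
    )
    n_db_decoys: int = 8

    edge_margin: int = 1000  # chromosome ends kept clear of features

    def validate(self) -> None:
        rates = [
            self.lowconf_fraction,
            self.miss_filtered_fraction,
            self.genotype_error_rate,
            self.mnv_shuffle_rate,
            self.fp_filtered_fraction,
            self.het_fraction,
            self.outside_fraction,
            *self.stratum_sensitivity.values(),
        ]
        if any(not 0 <= r <= 1 for r in rates):
            raise GenerationError("all rates must lie in [0, 1]")
        if any(c < 0 for c in self.stratum_counts.values()):
            raise GenerationError("stratum counts must be >= 0")
        if abs(sum(self.reason_fractions.values()) - 1.0) > 1e-9:
            raise GenerationError("reason fractions must sum to 1")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise GenerationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("segment_size", "exon_count", "exon_length", "intron_length"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "repeat_classes" in data:
            data["repeat_classes"] = {
                k: tuple(v) for k, v in data["repeat_classes"].items()
            }
        return cls(**data)


# ---------------------------------------------------------------------------
# placement helpers


class _Occupancy:
    """Per-chromosome reserved intervals with overlap checks."""

    def __init__(self):
        self._iv: dict[str, list[tuple[int, int]]] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        lst = self._iv.get(chrom, [])
        i = bisect_right(lst, (start, start))
        if i > 0 and lst[i - 1][1] > start:
            return False
        if i < len(lst) and lst[i][0] < end:
            return False
        return True

    def reserve(self, chrom: str, start: int, end: int) -> None:
        insort(self._iv.setdefault(chrom, []), (start, end))


class _Spacing:
    """Sorted positions per chromosome with a minimum-distance check."""

    def __init__(self, min_dist: int):
        self.min_dist = min_dist
        self._pos: dict[str, list[int]] = {}

    def ok(self, chrom: str, pos0: int, span: int = 1) -> bool:
        lst = self._pos.get(chrom, [])
        i = bisect_left(lst, pos0)
        if i > 0 and pos0 - lst[i - 1] < self.min_dist:
            return False
        if i < len(lst) and lst[i] - (pos0 + span - 1) < self.min_dist:
            return False
        return True

    def add(self, chrom: str, pos0: int) -> None:
        insort(self._pos.setdefault(chrom, []), pos0)


@dataclass
class TruthBundle:
    """Everything the pipeline needs, plus ground-truth bookkeeping."""

    config: SimConfig
    reference: dict[str, str]
    truth: CallSet
    query: CallSet  # raw: includes filtered records
    hiconf: RegionSet
    lowconf: RegionSet
    reason_tracks: dict[str, RegionSet]  # precedence order
    repeat_tracks: dict[str, RegionSet]
    genes: list[GeneModel]
    gene_sets: list[GeneSet]
    depth: dict[tuple[str, int], int]  # (chrom, 1-based pos) -> depth
    homref: RegionSet
    panels: list[PlatformPanel]
    databases: dict[str, CallSet]
    bookkeeping: dict[str, pd.DataFrame]

    def write(self, outdir) -> None:
        """Write the bundle as plain-text standard formats plus TSV
        bookkeeping."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        contigs = {c: len(s) for c, s in sorted(self.reference.items())}
        write_fasta(dict(sorted(self.reference.items())), out / "reference.fa")
        write_vcf(self.truth, out / "truth.vcf", contigs)
        write_vcf(self.query, out / "query.vcf", contigs)
        write_bed(self.hiconf, out / "hiconf.bed")
        write_bed(self.homref, out / "homref.bed")
        (out / "reasons").mkdir(exist_ok=True)
        for reason, track in self.reason_tracks.items():
            write_bed(track, out / "reasons" / f"{reason}.bed")
        (out / "repeats").mkdir(exist_ok=True)
        for cls, track in self.repeat_tracks.items():
            write_bed(track, out / "repeats" / f"{cls}.bed")
        write_gene_models(self.genes, out / "genes.refflat")
        (out / "genesets").mkdir(exist_ok=True)
        for gs in self.gene_sets:
            (out / "genesets" / f"{gs.name}.txt").write_text(
                "\n".join(sorted(gs.members)) + "\n"
            )
        with open(out / "depth.tsv", "w") as fh:
            fh.write("chrom\tpos\tdepth\n")
            for (chrom, pos), d in sorted(self.depth.items()):
                fh.write(f"{chrom}\t{pos}\t{d}\n")
        (out / "panels").mkdir(exist_ok=True)
        for panel in self.panels:
            pdir = out / "panels" / panel.platform
            pdir.mkdir(exist_ok=True)
            for ds in panel.datasets:
                write_vcf(ds, pdir / f"{ds.source_label}.vcf", contigs)
        (out / "databases").mkdir(exist_ok=True)
        for label, cs in self.databases.items():
            write_vcf(cs, out / "databases" / f"{label}.vcf", contigs, sites_only=True)
        (out / "bookkeeping").mkdir(exist_ok=True)
        for name, df in self.bookkeeping.items():
            df.to_csv(out / "bookkeeping" / f"{name}.tsv", sep="\t", index=False)
        self.config.to_yaml(out / "config.yaml")


# ---------------------------------------------------------------------------
# generation


def _weighted_choice(rng, weights: Mapping[str, float]) -> str:
    labels = sorted(weights)
    w = np.array([weights[k] for k in labels], dtype=float)
    return labels[int(rng.choice(len(labels), p=w / w.sum()))]


def _depth_normal(rng, mean: float) -> int:
    # negative-binomial-like integer depth, floored at 10 so only planted
    # low-coverage sites cross the <10 rule
    r = 10
    p = r / (r + mean)
    return max(10, int(rng.negative_binomial(r, p)))


def generate(config: SimConfig | None = None) -> TruthBundle:
    """Build a complete synthetic bundle from a seeded configuration."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    seqs = {c: rng.integers(0, 4, cfg.chrom_length).astype(np.uint8) for c in chroms}
    # occ_all tracks every reserved feature; occ_nosv omits the SV-reason
    # low-confidence segments so genes may deliberately straddle them
    occ_all = _Occupancy()
    occ_nosv = _Occupancy()
    genome_len = cfg.n_chromosomes * cfg.chrom_length

    def rand_pos(span: int) -> tuple[str, int]:
        chrom = chroms[int(rng.integers(len(chroms)))]
        lo = cfg.edge_margin
        hi = cfg.chrom_length - cfg.edge_margin - span
        if hi <= lo:
            raise GenerationError("chromosomes too short for the configuration")
        return chrom, int(rng.integers(lo, hi))

    def place(span: int, gap: int = 100, tries: int = 4000, sv: bool = False) -> tuple[str, int]:
        for _ in range(tries):
            chrom, start = rand_pos(span)
            if occ_all.free(chrom, start - gap, start + span + gap):
                occ_all.reserve(chrom, start, start + span)
                if not sv:
                    occ_nosv.reserve(chrom, start, start + span)
                return chrom, start
        raise GenerationError(f"could not place a {span} bp feature")

    # ---- low-confidence segments with exact per-reason base counts --------
    total_lowconf = int(round(cfg.lowconf_fraction * genome_len))
    seg_rows = []
    sv_segments: list[Region] = []
    for reason in cfg.reason_fractions:  # insertion order = precedence
        remaining = int(round(cfg.reason_fractions[reason] * total_lowconf))
        while remaining > 0:
            lo, hi = cfg.segment_size
            size = int(rng.integers(lo, hi + 1))
            if remaining - size < lo:
                size = remaining
            chrom, start = place(size, gap=150, sv=(reason == "dbVar_SV"))
            seg_rows.append(
                {"chrom": chrom, "start": start, "end": start + size, "reason": reason}
            )
            if reason == "dbVar_SV":
                sv_segments.append(Region(chrom, start, start + size))
            remaining -= size
    seg_df = pd.DataFrame(seg_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    lowconf = normalize(
        Region(r.chrom, r.start, r.end) for r in seg_df.itertuples()
    )
    whole = normalize(Region(c, 0, cfg.chrom_length) for c in chroms)
    hiconf = whole.subtract(lowconf)
    reason_tracks = {
        reason: normalize(
            Region(r.chrom, r.start, r.end)
            for r in seg_df.itertuples()
            if r.reason == reason
        )
        for reason in cfg.reason_fractions
    }

    # plant hard-to-sequence motifs inside STR segments (with margin) so the
    # excluded sequence really is repetitive
    m = cfg.lowconf_margin
    for r in seg_df.itertuples():
        if r.reason == "RepSeqSTR" and r.end - r.start > 2 * m + 30:
            s, e = r.start + m, r.end - m
            if rng.random() < 0.5:  # homopolymer
                seqs[r.chrom][s:e] = seqs[r.chrom][s]
            else:  # tandem repeat
                unit = rng.integers(0, 4, int(rng.integers(2, 7))).astype(np.uint8)
                reps = np.tile(unit, (e - s) // len(unit) + 1)[: e - s]
                seqs[r.chrom][s:e] = reps
        elif r.reason == "segdup" and r.end - r.start > 2 * m + 50:
            s, e = r.start + m, r.end - m
            src_chrom, src = rand_pos(e - s)
            seqs[r.chrom][s:e] = seqs[src_chrom][src : src + (e - s)]

    # ---- repeat-annotation tracks (sequence untouched) --------------------
    repeat_tracks: dict[str, RegionSet] = {}
    repeat_regions: dict[str, list[Region]] = {}
    for cls in sorted(cfg.repeat_classes):
        count, lo, hi = cfg.repeat_classes[cls]
        regs = []
        for _ in range(count):
            span = int(rng.integers(lo, hi + 1))
            chrom, start = rand_pos(span)
            regs.append(Region(chrom, start, start + span))
        repeat_regions[cls] = regs
        repeat_tracks[cls] = normalize(regs)

    # ---- GC-rich windows (fully in high-confidence space) -----------------
    gc_windows: list[Region] = []
    for _ in range(cfg.n_gc_windows):
        for _try in range(4000):
            chrom, start = rand_pos(cfg.gc_window_length)
            end = start + cfg.gc_window_length
            if occ_all.free(chrom, start - 100, end + 100) and hiconf.contains(
                chrom, start + 1
            ) and hiconf.contains(chrom, end):
                occ_all.reserve(chrom, start, end)
                occ_nosv.reserve(chrom, start, end)
                draw = rng.random(cfg.gc_window_length)
                gc = rng.integers(0, 2, cfg.gc_window_length)  # C or G
                bases = np.where(draw < 0.9, 1 + gc, 3 * rng.integers(0, 2, cfg.gc_window_length))
                seqs[chrom][start:end] = bases.astype(np.uint8)
                gc_windows.append(Region(chrom, start, end))
                break
        else:
            raise GenerationError("could not place a GC window")

    # ---- genes -------------------------------------------------------------
    genes: list[GeneModel] = []
    gene_meta: dict[str, dict] = {}
    n_straddle = int(round(cfg.sv_overlap_gene_fraction * cfg.n_genes))
    for gi in range(cfg.n_genes):
        n_ex = int(rng.integers(cfg.exon_count[0], cfg.exon_count[1] + 1))
        ex_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, n_ex)
        in_lens = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, max(n_ex - 1, 0))
        span = int(ex_lens.sum() + in_lens.sum())
        placed = False
        for _try in range(6000):
            if gi < n_straddle and sv_segments and _try < 2000:
                seg = sv_segments[int(rng.integers(len(sv_segments)))]
                offset = int(rng.integers(span // 4, 3 * span // 4 + 1))
                chrom, start = seg.chrom, seg.start - offset
                if start < cfg.edge_margin or start + span > cfg.chrom_length - cfg.edge_margin:
                    continue
            else:
                chrom, start = rand_pos(span)
            if occ_nosv.free(chrom, start - 150, start + span + 150):
                occ_all.reserve(chrom, start, start + span)
                occ_nosv.reserve(chrom, start, start + span)
                placed = True
                break
        if not placed:
            raise GenerationError("could not place a gene")
        exons = []
        cursor = start
        for j in range(n_ex):
            exons.append(Region(chrom, cursor, cursor + int(ex_lens[j])))
            cursor += int(ex_lens[j]) + (int(in_lens[j]) if j < n_ex - 1 else 0)
        strand = "+" if rng.random() < 0.5 else "-"
        cds_start = exons[0].start + int(rng.integers(10, min(40, exons[0].length - 10)))
        cds_end = exons[-1].end - int(rng.integers(10, min(40, exons[-1].length - 10)))
        gene = GeneModel(
            name=f"GENE{gi + 1:03d}",
            transcript_id=f"T{gi + 1:03d}",
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
            cds_start=cds_start,
            cds_end=cds_end,
        )
        cds_len = gene.cds_length
        trim = cds_len % 3
        if trim:
            cds_end -= trim
            gene = GeneModel(
                gene.name, gene.transcript_id, chrom, strand, tuple(exons), cds_start, cds_end
            )
            cds_len = gene.cds_length
        # write a valid reading frame into the CDS bases
        n_codons = cds_len // 3
        codons = ["ATG"]
        non_stop = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")
        for _ in range(n_codons - 2):
            codons.append(non_stop[int(rng.integers(len(non_stop)))])
        codons.append(sorted(_STOPS)[int(rng.integers(3))])
        coding = "".join(codons)
        genomic = coding if strand == "+" else "".join(
            _COMP[b] for b in reversed(coding)
        )
        g_arr = np.frombuffer(genomic.encode(), dtype=np.uint8)
        code_of = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            code_of[b] = i
        g_codes = code_of[g_arr]
        offset = 0
        coding_genomic = []  # genomic pos0 of each coding index (plus-orientation)
        for r in gene.cds_intervals():
            seqs[chrom][r.start : r.end] = g_codes[offset : offset + r.length]
            coding_genomic.extend(range(r.start, r.end))
            offset += r.length
        if strand == "-":
            coding_genomic = coding_genomic[::-1]
        genes.append(gene)
        gene_meta[gene.name] = {
            "gene": gene,
            "coding": coding,
            "coding_genomic": coding_genomic,
        }

    gene_names = [g.name for g in genes]
    acmg = sorted(rng.choice(gene_names, size=cfg.acmg_size, replace=False))
    rest = [g for g in gene_names if g not in set(acmg)]
    extra = sorted(
        rng.choice(rest, size=max(cfg.clinvar_omim_size - cfg.acmg_size, 0), replace=False)
    )
    gene_sets = [
        GeneSet("ACMG56", frozenset(acmg)),
        GeneSet("ClinVarOMIM", frozenset(acmg) | frozenset(extra)),
        GeneSet("AllCoding", frozenset(gene_names)),
    ]
    gene_spans = normalize(g.span for g in genes)

    # ---- reference is now final: freeze numpy codes 0..3 to ACGT strings ---
    _to_bases = bytes.maketrans(bytes(range(4)), b"ACGT")
    reference = {c: seqs[c].tobytes().translate(_to_bases).decode() for c in chroms}

    def base_at(chrom: str, pos0: int) -> str:
        return reference[chrom][pos0]

    spacing = _Spacing(cfg.min_variant_spacing)

    def other_base(ref: str) -> str:
        choices = sorted(set("ACGT") - {ref})
        return choices[int(rng.integers(3))]

    # ---- truth variants ----------------------------------------------------
    var_rows: list[dict] = []
    vid = 0

    def genotype() -> tuple[int, int]:
        return (0, 1) if rng.random() < cfg.het_fraction else (1, 1)

    def add_variant(chrom, pos0, ref, alt, stratum, gene, in_region, mnv_pair=-1):
        nonlocal vid
        vid += 1
        gt = genotype() if mnv_pair < 0 else (0, 1)
        var_rows.append(
            {
                "id": vid,
                "chrom": chrom,
                "pos": pos0 + 1,
                "ref": ref,
                "alt": alt,
                "gt": "/".join(map(str, gt)),
                "stratum": stratum,
                "gene": gene,
                "in_region": in_region,
                "mnv_pair": mnv_pair,
            }
        )
        spacing.add(chrom, pos0)

    coding_strata = {"synonymous", "non-synonymous", "truncating"}
    # plant the most constrained strata first (stop-gain sites are scarce)
    stratum_order = ["truncating", "splicing", "synonymous", "non-synonymous", "intergenic"]
    for stratum in [s for s in stratum_order if s in cfg.stratum_counts] + sorted(
        set(cfg.stratum_counts) - set(stratum_order)
    ):
        count = cfg.stratum_counts[stratum]
        if stratum in coding_strata:
            # shuffled exhaustive scan over every internal codon so dense
            # configurations use the full capacity deterministically
            pool = [
                (name, ci)
                for name in gene_names
                for ci in range(1, len(gene_meta[name]["coding"]) // 3 - 1)
            ]
            planted = 0
            for oi in rng.permutation(len(pool)):
                if planted >= count:
                    break
                name, ci = pool[int(oi)]
                meta = gene_meta[name]
                gene, coding, cg = meta["gene"], meta["coding"], meta["coding_genomic"]
                codon = coding[ci * 3 : ci * 3 + 3]
                for p in (int(x) for x in rng.permutation(3)):
                    idx = ci * 3 + p
                    pos0 = cg[idx]
                    if not hiconf.contains(gene.chrom, pos0 + 1):
                        continue
                    if not spacing.ok(gene.chrom, pos0):
                        continue
                    cands = []
                    for b in "ACGT":
                        if b == codon[p]:
                            continue
                        new = codon[:p] + b + codon[p + 1 :]
                        aa_old, aa_new = _translate(codon), _translate(new)
                        if stratum == "synonymous" and aa_new == aa_old and aa_new != "*":
                            cands.append(b)
                        elif stratum == "non-synonymous" and aa_new != aa_old and "*" not in (aa_old, aa_new):
                            cands.append(b)
                        elif stratum == "truncating" and aa_new == "*" and aa_old != "*":
                            cands.append(b)
                    if not cands:
                        continue
                    coding_alt = cands[int(rng.integers(len(cands)))]
                    if gene.strand == "+":
                        ref, alt = codon[p], coding_alt
                    else:
                        ref, alt = _COMP[codon[p]], _COMP[coding_alt]
                    assert base_at(gene.chrom, pos0) == ref
                    add_variant(gene.chrom, pos0, ref, alt, stratum, gene.name, True)
                    planted += 1
                    break
            if planted < count:
                raise GenerationError(f"cannot plant {count} {stratum} variants")
        elif stratum == "splicing":
            planted = 0
            attempts = 0
            while planted < count:
                attempts += 1
                if attempts > 200 * count + 1000:
                    raise GenerationError("cannot plant splicing variants")
                gene = genes[int(rng.integers(len(genes)))]
                if len(gene.exons) < 2:
                    continue
                bi = int(rng.integers(len(gene.exons) - 1))
                donor = rng.random() < 0.5
                off = int(rng.integers(1, 3))
                if donor:
                    pos0 = gene.exons[bi].end + off - 1
                else:
                    pos0 = gene.exons[bi + 1].start - off
                if not hiconf.contains(gene.chrom, pos0 + 1):
                    continue
                if not spacing.ok(gene.chrom, pos0):
                    continue
                ref = base_at(gene.chrom, pos0)
                add_variant(gene.chrom, pos0, ref, other_base(ref), "splicing", gene.name, True)
                planted += 1
        elif stratum == "intergenic":
            n_outside = int(round(cfg.outside_fraction * count))
            planted_out = 0
            attempts = 0
            while planted_out < n_outside:
                attempts += 1
                if attempts > 200 * count + 1000:
                    raise GenerationError("cannot plant out-of-region variants")
                if not sv_segments:
                    break
                seg = sv_segments[int(rng.integers(len(sv_segments)))]
                pos0 = int(rng.integers(seg.start + 5, seg.end - 5))
                if gene_spans.contains(seg.chrom, pos0 + 1):
                    continue
                if not spacing.ok(seg.chrom, pos0):
                    continue
                ref = base_at(seg.chrom, pos0)
                add_variant(seg.chrom, pos0, ref, other_base(ref), "intergenic", "", False)
                planted_out += 1
            planted = planted_out
            attempts = 0
            while planted < count:
                attempts += 1
                if attempts > 200 * count + 1000:
                    raise GenerationError("cannot plant intergenic variants")
                chrom, pos0 = rand_pos(1)
                if gene_spans.contains(chrom, pos0 + 1):
                    continue
                if not hiconf.contains(chrom, pos0 + 1):
                    continue
                if not spacing.ok(chrom, pos0):
                    continue
                ref = base_at(chrom, pos0)
                add_variant(chrom, pos0, ref, other_base(ref), "intergenic", "", True)
                planted += 1

    # adjacent phased SNV pairs (complex-representation material)
    pair_id = 0
    attempts = 0
    while pair_id < cfg.n_mnv_pairs:
        attempts += 1
        if attempts > 200 * cfg.n_mnv_pairs + 1000:
            raise GenerationError("cannot plant MNV pairs")
        chrom, pos0 = rand_pos(2)
        if gene_spans.contains(chrom, pos0 + 1) or gene_spans.contains(chrom, pos0 + 2):
            continue
        if not (hiconf.contains(chrom, pos0 + 1) and hiconf.contains(chrom, pos0 + 2)):
            continue
        if not (spacing.ok(chrom, pos0, span=2)):
            continue
        pair_id += 1
        for off in (0, 1):
            ref = base_at(chrom, pos0 + off)
            add_variant(chrom, pos0 + off, ref, other_base(ref), "intergenic", "", True,
                        mnv_pair=pair_id)

    variants = pd.DataFrame(var_rows)

    # ---- query fates -------------------------------------------------------
    fates = []
    gt_err = []
    pair_fate: dict[int, str] = {}
    pair_shuffle: dict[int, bool] = {}
    for row in variants.itertuples():
        sens = cfg.stratum_sensitivity[row.stratum]
        if row.mnv_pair > 0:
            if row.mnv_pair not in pair_fate:
                if rng.random() < sens:
                    pair_fate[row.mnv_pair] = "called"
                    pair_shuffle[row.mnv_pair] = rng.random() < cfg.mnv_shuffle_rate
                else:
                    pair_fate[row.mnv_pair] = (
                        "filtered" if rng.random() < cfg.miss_filtered_fraction else "lowcov"
                    )
                    pair_shuffle[row.mnv_pair] = False
            fates.append(pair_fate[row.mnv_pair])
            gt_err.append(False)
            continue
        if not row.in_region or rng.random() < sens:
            fates.append("called")
            gt_err.append(rng.random() < cfg.genotype_error_rate)
        else:
            fates.append(
                "filtered" if rng.random() < cfg.miss_filtered_fraction else "lowcov"
            )
            gt_err.append(False)
    variants["fate"] = fates
    variants["genotype_error"] = gt_err

    # relocate a share of intergenic misses into GC windows / SINE elements so
    # cause attribution has planted signal (positions move; fates stay)
    sine_regions = [
        r
        for r in repeat_regions.get("SINE", [])
        if hiconf.contains(r.chrom, r.start + r.length // 2 + 1)
    ]

    def relocate(mask_index, candidates, interior: int):
        for i in mask_index:
            for _try in range(500):
                reg = candidates[int(rng.integers(len(candidates)))]
                if reg.length <= 2 * interior + 2:
                    continue
                pos0 = int(rng.integers(reg.start + interior, reg.end - interior))
                chrom = reg.chrom
                if gene_spans.contains(chrom, pos0 + 1):
                    continue
                if not hiconf.contains(chrom, pos0 + 1):
                    continue
                if not spacing.ok(chrom, pos0):
                    continue
                ref = base_at(chrom, pos0)
                variants.loc[i, "chrom"] = chrom
                variants.loc[i, "pos"] = pos0 + 1
                variants.loc[i, "ref"] = ref
                variants.loc[i, "alt"] = other_base(ref)
                spacing.add(chrom, pos0)
                break

    inter = variants[(variants.stratum == "intergenic") & (variants.mnv_pair < 0)]
    lowcov_idx = inter.index[inter.fate == "lowcov"]
    n_gc = int(round(cfg.gc_miss_fraction * len(lowcov_idx)))
    if gc_windows and n_gc:
        relocate(lowcov_idx[:n_gc], gc_windows, interior=55)
    filt_idx = inter.index[inter.fate == "filtered"]
    n_rep = int(round(cfg.repeat_miss_fraction * len(filt_idx)))
    if sine_regions and n_rep:
        relocate(filt_idx[:n_rep], sine_regions, interior=5)

    # ---- filters, depths ---------------------------------------------------
    def draw_filters() -> frozenset[str]:
        if rng.random() < cfg.multi_filter_fraction:
            first = _weighted_choice(rng, cfg.filter_weights)
            rest = {k: v for k, v in cfg.filter_weights.items() if k != first}
            return frozenset({first, _weighted_choice(rng, rest)})
        return frozenset({_weighted_choice(rng, cfg.filter_weights)})

    depth: dict[tuple[str, int], int] = {}
    filters_col = []
    for row in variants.itertuples():
        key = (row.chrom, int(row.pos))
        if row.fate == "lowcov":
            depth[key] = int(rng.integers(2, 10))
        else:
            depth[key] = _depth_normal(rng, cfg.mean_depth)
        filters_col.append(";".join(sorted(draw_filters())) if row.fate == "filtered" else "")
    variants["filters"] = filters_col
    # members of a filtered MNV pair share one filter draw (one filtered event)
    for pid, grp in variants[variants.mnv_pair > 0].groupby("mnv_pair"):
        if (grp.fate == "filtered").any():
            variants.loc[grp.index, "filters"] = grp.filters.iloc[0]
    variants["depth"] = [depth[(r.chrom, int(r.pos))] for r in variants.itertuples()]

    # ---- false positives ---------------------------------------------------
    fp_rows = []
    n_filtered_fp = int(round(cfg.fp_filtered_fraction * cfg.n_false_positives))
    hic_regions = [r for r in hiconf if r.length > 300]
    for fi in range(cfg.n_false_positives):
        is_filtered = fi < n_filtered_fp
        near_edge = (not is_filtered) and (
            rng.random() < cfg.fp_edge_fraction
        )
        for _try in range(4000):
            if near_edge:
                reg = hic_regions[int(rng.integers(len(hic_regions)))]
                pos0 = reg.start + int(rng.integers(0, 50))
                chrom = reg.chrom
            else:
                chrom, pos0 = rand_pos(1)
                if not hiconf.contains(chrom, pos0 + 1):
                    continue
            if gene_spans.contains(chrom, pos0 + 1):
                continue
            if not spacing.ok(chrom, pos0):
                continue
            break
        else:
            raise GenerationError("cannot place false positives")
        spacing.add(chrom, pos0)
        ref = base_at(chrom, pos0)
        if is_filtered:
            labels = frozenset({"strandBias"}) if rng.random() < 0.7 else frozenset(
                {"strandBias", _weighted_choice(rng, {k: v for k, v in cfg.filter_weights.items() if k != "strandBias"})}
            )
        else:
            labels = frozenset()
        key = (chrom, pos0 + 1)
        depth[key] = _depth_normal(rng, cfg.mean_depth)
        fp_rows.append(
            {
                "id": fi + 1,
                "chrom": chrom,
                "pos": pos0 + 1,
                "ref": ref,
                "alt": other_base(ref),
                "filters": ";".join(sorted(labels)),
                "edge_planted": near_edge,
                "depth": depth[key],
            }
        )
    fps = pd.DataFrame(fp_rows)

    # realized context annotations for the bookkeeping oracle
    def gc_frac_at(chrom: str, pos0: int, window: int = 100) -> float:
        half = window // 2
        lo = max(0, pos0 - half)
        win = reference[chrom][lo : lo + window]
        return (win.count("G") + win.count("C")) / len(win)

    variants["gc_frac"] = [
        gc_frac_at(r.chrom, int(r.pos) - 1) for r in variants.itertuples()
    ]
    variants["repeat_classes"] = [
        ";".join(
            sorted(
                cls
                for cls, track in repeat_tracks.items()
                if track.contains(r.chrom, int(r.pos))
            )
        )
        for r in variants.itertuples()
    ]

    # ---- truth & query call sets ------------------------------------------
    truth_records = []
    for row in variants.itertuples():
        gt = tuple(int(x) for x in row.gt.split("/"))
        truth_records.append(
            VariantRecord(row.chrom, int(row.pos), row.ref, (row.alt,), 50.0,
                          frozenset(), gt, None, "TRUTH")
        )
    truth = CallSet("TRUTH", truth_records, "synthetic-truth")

    query_records = []
    done_pairs: set[int] = set()
    by_pair: dict[int, list] = {}
    for row in variants.itertuples():
        if row.mnv_pair > 0:
            by_pair.setdefault(row.mnv_pair, []).append(row)
    for row in variants.itertuples():
        key = (row.chrom, int(row.pos))
        qual = round(float(rng.uniform(30, 60)), 1)
        if row.fate == "lowcov":
            continue
        if row.mnv_pair > 0:
            if row.mnv_pair in done_pairs:
                continue
            done_pairs.add(row.mnv_pair)
            pair = sorted(by_pair[row.mnv_pair], key=lambda r: r.pos)
            if row.fate == "called" and pair_shuffle[row.mnv_pair]:
                a, b = pair
                query_records.append(
                    VariantRecord(a.chrom, int(a.pos), a.ref + b.ref, (a.alt + b.alt,),
                                  qual, frozenset(), (0, 1), depth[(a.chrom, int(a.pos))], "QUERY")
                )
                continue
            labels = frozenset(pair[0].filters.split(";")) if row.fate == "filtered" else frozenset()
            for r in pair:
                query_records.append(
                    VariantRecord(r.chrom, int(r.pos), r.ref, (r.alt,), qual,
                                  labels - {""}, (0, 1), depth[(r.chrom, int(r.pos))], "QUERY")
                )
            continue
        gt = tuple(int(x) for x in row.gt.split("/"))
        if row.genotype_error:
            gt = (1, 1) if gt == (0, 1) else (0, 1)
        labels = frozenset(l for l in row.filters.split(";") if l)
        query_records.append(
            VariantRecord(row.chrom, int(row.pos), row.ref, (row.alt,), qual,
                          labels, gt, depth[key], "QUERY")
        )
    for row in fps.itertuples():
        labels = frozenset(l for l in row.filters.split(";") if l)
        qual = round(float(rng.uniform(30, 60)), 1)
        query_records.append(
            VariantRecord(row.chrom, int(row.pos), row.ref, (row.alt,), qual,
                          labels, (0, 1), int(row.depth), "QUERY")
        )
    query = CallSet("QUERY", query_records, "synthetic-query")

    # ---- benchmark hom-ref space and platform panels -----------------------
    buffers = normalize(
        Region(r.chrom, max(0, int(r.pos) - 11), int(r.pos) + 10)
        for frame in (variants, fps)
        for r in frame.itertuples()
    )
    homref = hiconf.subtract(buffers)

    platform_names = sorted(cfg.platforms)
    ds_labels = {
        p: [f"{p}_ds{i + 1}" for i in range(cfg.platforms[p])] for p in platform_names
    }
    panel_calls: dict[str, dict[str, list[VariantRecord]]] = {
        p: {d: [] for d in ds_labels[p]} for p in platform_names
    }
    sys_rows = []

    def homref_site() -> tuple[str, int]:
        for _try in range(4000):
            chrom, pos0 = rand_pos(1)
            if not homref.contains(chrom, pos0 + 1):
                continue
            if not spacing.ok(chrom, pos0):
                continue
            spacing.add(chrom, pos0)
            return chrom, pos0
        raise GenerationError("cannot place hom-ref panel sites")

    def inject(chrom, pos0, platform, n_datasets, qual_range):
        labels = ds_labels[platform]
        chosen = sorted(rng.choice(labels, size=n_datasets, replace=False))
        ref = base_at(chrom, pos0)
        alt = other_base(ref)
        for lab in chosen:
            q = round(float(rng.uniform(*qual_range)), 1)
            panel_calls[platform][lab].append(
                VariantRecord(chrom, pos0 + 1, ref, (alt,), q, frozenset(), (0, 1),
                              _depth_normal(rng, cfg.mean_depth), lab)
            )
        return alt, len(chosen)

    for si in range(cfg.n_systematic_sites):
        chrom, pos0 = homref_site()
        platform = platform_names[int(rng.integers(len(platform_names)))]
        d = cfg.platforms[platform]
        n_ev = d if d <= 3 else int(rng.integers(3, d + 1))
        alt, n_used = inject(chrom, pos0, platform, n_ev, (3, 60))
        sys_rows.append(
            {
                "chrom": chrom,
                "pos": pos0 + 1,
                "ref": base_at(chrom, pos0),
                "alt": alt,
                "platform": platform,
                "n_evidence": n_used,
                "kind": "systematic",
            }
        )
    for _ in range(cfg.n_subthreshold_sites):
        chrom, pos0 = homref_site()
        eligible = [p for p in platform_names if cfg.platforms[p] >= 3]
        platform = eligible[int(rng.integers(len(eligible)))]
        alt, n_used = inject(chrom, pos0, platform, 2, (3, 60))
        sys_rows.append(
            {"chrom": chrom, "pos": pos0 + 1, "ref": base_at(chrom, pos0),
             "alt": alt, "platform": platform, "n_evidence": n_used, "kind": "subthreshold"}
        )
    for _ in range(cfg.n_lowqual_sites):
        chrom, pos0 = homref_site()
        platform = platform_names[int(rng.integers(len(platform_names)))]
        alt, n_used = inject(chrom, pos0, platform, cfg.platforms[platform], (0, 2))
        sys_rows.append(
            {"chrom": chrom, "pos": pos0 + 1, "ref": base_at(chrom, pos0),
             "alt": alt, "platform": platform, "n_evidence": n_used, "kind": "lowqual"}
        )
    syserr_df = pd.DataFrame(sys_rows)

    panels = [
        PlatformPanel(
            p,
            [CallSet(lab, panel_calls[p][lab], lab) for lab in ds_labels[p]],
        )
        for p in platform_names
    ]

    # ---- databases ---------------------------------------------------------
    sys_only = syserr_df[syserr_df.kind == "systematic"].reset_index(drop=True)
    databases: dict[str, CallSet] = {}
    for label in sorted(cfg.database_fractions):
        syserr_df[f"in_{label}"] = False
    for label in sorted(cfg.database_fractions):
        n_hit = int(round(cfg.database_fractions[label] * len(sys_only)))
        hit_rows = rng.choice(len(sys_only), size=n_hit, replace=False)
        recs = []
        hit_positions = set()
        for i in sorted(hit_rows):
            r = sys_only.iloc[int(i)]
            recs.append(VariantRecord(r.chrom, int(r.pos), r.ref, (r.alt,), None,
                                      frozenset(), None, None, ""))
            hit_positions.add((r.chrom, int(r.pos)))
        mask = [
            (row.kind == "systematic") and ((row.chrom, int(row.pos)) in hit_positions)
            for row in syserr_df.itertuples()
        ]
        syserr_df[f"in_{label}"] = mask
        databases[label] = recs  # decoys/background added below

    # decoys: database entries at systematic sites with a *different* alt
    first_db = sorted(cfg.database_fractions)[0]
    decoy_rows = rng.choice(len(sys_only), size=min(cfg.n_db_decoys, len(sys_only)), replace=False)
    for i in sorted(decoy_rows):
        r = sys_only.iloc[int(i)]
        wrong = sorted(set("ACGT") - {r.ref, r.alt})[0]
        if not syserr_df.loc[
            (syserr_df.chrom == r.chrom) & (syserr_df.pos == int(r.pos)), f"in_{first_db}"
        ].any():
            databases[first_db].append(
                VariantRecord(r.chrom, int(r.pos), r.ref, (wrong,), None, frozenset(), None, None, "")
            )
    # background entries at ordinary positions
    for label in sorted(databases):
        for _ in range(5):
            chrom, pos0 = rand_pos(1)
            ref = base_at(chrom, pos0)
            databases[label].append(
                VariantRecord(chrom, pos0 + 1, ref, (other_base(ref),), None,
                              frozenset(), None, None, "")
            )
        databases[label] = CallSet("", databases[label], label)

    gene_rows = [
        {
            "name": g.name,
            "transcript": g.transcript_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "n_exons": len(g.exons),
            "span_start": g.span.start,
            "span_end": g.span.end,
            "cds_start": g.cds_start,
            "cds_end": g.cds_end,
            "exon_starts": ",".join(str(e.start) for e in g.exons),
            "exon_ends": ",".join(str(e.end) for e in g.exons),
            "in_ACMG56": g.name in gene_sets[0].members,
            "in_ClinVarOMIM": g.name in gene_sets[1].members,
        }
        for g in genes
    ]

    bookkeeping = {
        "variants": variants,
        "false_positives": fps,
        "lowconf_segments": seg_df,
        "systematic_sites": syserr_df,
        "genes": pd.DataFrame(gene_rows),
    }
    return TruthBundle(
        config=cfg,
        reference=reference,
        truth=truth,
        query=query,
        hiconf=hiconf,
        lowconf=lowconf,
        reason_tracks=reason_tracks,
        repeat_tracks=repeat_tracks,
        genes=genes,
        gene_sets=gene_sets,
        depth=depth,
        homref=homref,
        panels=panels,
        databases=databases,
        bookkeeping=bookkeeping,
    )


# ---------------------------------------------------------------------------
# bookkeeping oracle


@dataclass
class ExpectedMetrics:
    """Reference tables recomputed by direct counting over the bookkeeping
    (independent of the pipeline operations)."""

    whole_genome: tuple[int, int]  # (tp, fn) over in-region truth variants
    strata: dict[str, tuple[int, int]]  # planted stratum -> (tp, fn)
    per_geneset: dict[tuple[str, str], tuple[int, int]]  # (stratum, set) -> (tp, fn)
    fn_cause_fractions: dict[str, float]
    qv_count: int
    genotype_error_count: int
    lowconf_percentages: dict[str, float]
    gene_fractions: dict[str, tuple[int, int]]  # gene -> (exonic, covered)
    geneset_base_weighted: dict[str, float]
    syserr_sites: set[tuple[str, int]]
    syserr_db_counts: dict[str, int]
    filter_combos: dict[frozenset, tuple[int, int]]  # combo -> (n, n_fp)


def expected_metrics(bundle: TruthBundle) -> ExpectedMetrics:
    cfg = bundle.config
    variants = bundle.bookkeeping["variants"]
    fps = bundle.bookkeeping["false_positives"]
    segs = bundle.bookkeeping["lowconf_segments"]
    sysdf = bundle.bookkeeping["systematic_sites"]

    in_reg = variants[variants.in_region]
    called = in_reg.fate == "called"
    whole = (int(called.sum()), int((~called).sum()))
    strata = {
        s: (
            int((called & (in_reg.stratum == s)).sum()),
            int((~called & (in_reg.stratum == s)).sum()),
        )
        for s in sorted(in_reg.stratum.unique())
    }
    per_geneset: dict[tuple[str, str], tuple[int, int]] = {}
    for gs in bundle.gene_sets:
        members = gs.members
        sel = in_reg.gene.isin(members)
        for s in sorted(in_reg.stratum.unique()):
            if s == "intergenic":
                continue
            mask = sel & (in_reg.stratum == s)
            per_geneset[(s, gs.name)] = (
                int((called & mask).sum()),
                int((~called & mask).sum()),
            )

    fn = in_reg[~called]
    n_fn = len(fn)
    fn_cause = {}
    if n_fn:
        fn_cause["filtered"] = float((fn.fate == "filtered").mean())
        fn_cause["low_coverage"] = float((fn.depth < 10).mean())
        fn_cause["high_gc"] = float((fn.gc_frac > 0.75).mean())
        for cls in sorted(bundle.repeat_tracks):
            fn_cause[f"repeat_class:{cls}"] = float(
                fn.repeat_classes.fillna("").str.split(";").apply(lambda L: cls in L).mean()
            )

    qv_count = int((fps.filters.fillna("") == "").sum())
    genotype_error_count = int((in_reg.genotype_error & called).sum())

    total_low = int((segs.end - segs.start).sum())
    lowconf_pct = {
        reason: 100.0 * int((segs[segs.reason == reason].end - segs[segs.reason == reason].start).sum()) / total_low
        for reason in cfg.reason_fractions
    }

    # per-base gene coverage using boolean masks (brute force, no interval code)
    hic_mask = {
        c: np.ones(len(bundle.reference[c]), dtype=bool) for c in bundle.reference
    }
    for r in segs.itertuples():
        hic_mask[r.chrom][r.start : r.end] = False
    gene_fracs: dict[str, tuple[int, int]] = {}
    for g in bundle.genes:
        exonic = sum(e.length for e in g.exons)
        covered = int(sum(hic_mask[g.chrom][e.start : e.end].sum() for e in g.exons))
        gene_fracs[g.name] = (exonic, covered)
    geneset_bw = {}
    for gs in bundle.gene_sets:
        rows = [gene_fracs[n] for n in sorted(gs.members)]
        tot = sum(e for e, _ in rows)
        cov = sum(c for _, c in rows)
        geneset_bw[gs.name] = cov / tot if tot else float("nan")

    sys_only = sysdf[sysdf.kind == "systematic"]
    sys_sites = {(r.chrom, int(r.pos)) for r in sys_only.itertuples()}
    db_counts = {"total_sites": len(sys_sites)}
    any_mask = np.zeros(len(sys_only), dtype=bool)
    for label in sorted(cfg.database_fractions):
        col = sys_only[f"in_{label}"].to_numpy(dtype=bool)
        db_counts[label] = int(col.sum())
        any_mask |= col
    db_counts["any_database"] = int(any_mask.sum())

    filter_combos: dict[frozenset, list[int]] = {}
    for frame, is_fp in ((variants[variants.filters.fillna("") != ""], False),
                         (fps[fps.filters.fillna("") != ""], True)):
        for r in frame.itertuples():
            combo = frozenset(r.filters.split(";"))
            entry = filter_combos.setdefault(combo, [0, 0])
            entry[0] += 1
            entry[1] += int(is_fp)

    return ExpectedMetrics(
        whole_genome=whole,
        strata=strata,
        per_geneset=per_geneset,
        fn_cause_fractions=fn_cause,
        qv_count=qv_count,
        genotype_error_count=genotype_error_count,
        lowconf_percentages=lowconf_pct,
        gene_fractions=gene_fracs,
        geneset_base_weighted=geneset_bw,
        syserr_sites=sys_sites,
        syserr_db_counts=db_counts,
        filter_combos={k: tuple(v) for k, v in filter_combos.items()},
    )
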