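"""Functional classification, Wilson intervals, stratified sensitivity,
FN-cause attribution and filter specificity."""

import numpy as np
import pytest
from Bio.Seq import Seq

from varbench.core_io import CallSet, GeneModel, GeneSet, Region, VariantRecord
from varbench.errors import DomainError
from varbench.stratify import (
    attribute_fn_causes,
    binomial_ci,
    classify_function,
    filter_specificity,
    stratified_sensitivity,
)
from varbench.synthetic import expected_metrics, generate
from varbench.varcomp import classify
from conftest import compact_config


def snv(pos, ref, alt, chrom="chr1"):
    return VariantRecord(chrom, pos, ref, (alt,), genotype=(0, 1))


@pytest.fixture(scope="module")
def plus_gene():
    # one exon 10..40, CDS 10..40: ATG + 8 codons + TAA written below
    cds = "ATG" + "TAC" + "CTG" + "GAA" + "TTT" + "GGG" + "CCC" + "AAA" + "TCT" + "TAA"
    seq = "T" * 10 + cds + "T" * 60
    return {"chr1": seq}, GeneModel("GP", "T1", "chr1", "+",
                                    (Region("chr1", 10, 40),), 10, 40)


class TestClassifyFunction:
    def test_stop_gain_is_truncating(self, plus_gene):
        ref, gene = plus_gene
        # codon 2 is TAC (Tyr) at pos0 13..15; C->A gives TAA (stop)
        assert classify_function(snv(16, "C", "A"), gene, ref) == "truncating"

    def test_synonymous_leucine(self, plus_gene):
        ref, gene = plus_gene
        # codon 3 CTG -> CTA, both Leu; third base at pos0 18
        assert classify_function(snv(19, "G", "A"), gene, ref) == "synonymous"

    def test_nonsynonymous(self, plus_gene):
        ref, gene = plus_gene
        # codon 4 GAA (Glu) -> GCA (Ala)
        assert classify_function(snv(21, "A", "C"), gene, ref) == "non-synonymous"

    def test_frameshift_indel_truncating(self, plus_gene):
        ref, gene = plus_gene
        v = VariantRecord("chr1", 20, ref["chr1"][19:21], (ref["chr1"][19],),
                          genotype=(0, 1))
        assert classify_function(v, gene, ref) == "truncating"

    def test_outside_gene_raises(self, plus_gene):
        ref, gene = plus_gene
        with pytest.raises(DomainError):
            classify_function(snv(5, "T", "A"), gene, ref)

    def test_splice_site_within_two_bases(self):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        gene = GeneModel("GS", "T1", "chr1", "+",
                         (Region("chr1", 10, 40), Region("chr1", 80, 110)), None, None)
        ref = {"chr1": seq}
        for pos0 in (40, 41, 78, 79):  # intron side of both boundaries
            r = seq[pos0]
            a = "A" if r != "A" else "C"
            assert classify_function(snv(pos0 + 1, r, a), gene, ref) == "splicing"
        # 3 bases in: no longer splicing
        r = seq[42]
        assert classify_function(snv(43, r, "A" if r != "A" else "C"), gene, ref) == "other"

    def test_agrees_with_whole_cds_translation_oracle(self, bundle, rng):
        """For random CDS SNVs on generated genes (both strands), the class
        must agree with translating the full CDS before and after the edit."""
        genes = [g for g in bundle.genes]
        checked = 0
        while checked < 1000:
            g = genes[int(rng.integers(len(genes)))]
            ivs = g.cds_intervals()
            iv = ivs[int(rng.integers(len(ivs)))]
            pos0 = int(rng.integers(iv.start, iv.end))
            ref_base = bundle.reference[g.chrom][pos0]
            alt = "ACGT"[("ACGT".index(ref_base) + 1 + int(rng.integers(3))) % 4]
            got = classify_function(snv(pos0 + 1, ref_base, alt, g.chrom), g,
                                    bundle.reference)
            # oracle: translate the whole CDS with and without the variant
            seq = bundle.reference[g.chrom]
            edited = seq[:pos0] + alt + seq[pos0 + 1:]
            def protein(source):
                cds = "".join(source[r.start:r.end] for r in ivs)
                if g.strand == "-":
                    cds = str(Seq(cds).reverse_complement())
                return str(Seq(cds).translate())
            p_old, p_new = protein(seq), protein(edited)
            if p_new == p_old:
                exp = "synonymous"
            elif "*" in p_new[:-1] and "*" not in p_old[:-1]:
                exp = "truncating"
            else:
                exp = "non-synonymous"
            assert got == exp, (g.name, g.strand, pos0, ref_base, alt)
            checked += 1


class TestBinomialCi:
    @pytest.mark.parametrize(
        "x,n,lo,hi",
        [
            (7, 7, 0.646, 1.000),
            (43, 47, 0.801, 0.966),
            (47, 47, 0.924, 1.000),
        ],
    )
    def test_wilson_bounds_3dp(self, x, n, lo, hi):
        low, high = binomial_ci(x, n)
        assert round(low, 3) == lo and round(high, 3) == hi

    def test_all_success_closed_form(self):
        z = 1.959963984540054
        for n in (5, 7, 20, 47):
            low, high = binomial_ci(n, n)
            assert low == pytest.approx(n / (n + z * z), abs=5e-4)
            assert high == 1.0

    def test_zero_success_symmetry(self):
        z = 1.959963984540054
        low, high = binomial_ci(0, 10)
        assert low == 0.0
        assert high == pytest.approx(z * z / (10 + z * z), abs=5e-4)

    def test_n_zero_rejected(self):
        with pytest.raises(DomainError):
            binomial_ci(0, 0)

    def test_coverage_property(self):
        """Over 2000 simulated binomial draws (n=50, p=0.7) the Wilson 95%
        interval contains p in 93-97% of draws."""
        rng = np.random.default_rng(123)
        draws = rng.binomial(50, 0.7, size=2000)
        hits = 0
        for x in draws:
            lo, hi = binomial_ci(int(x), 50)
            hits += lo <= 0.7 <= hi
        assert 0.93 <= hits / 2000 <= 0.97


class TestStratifiedSensitivity:
    def test_stratum_counts_match_bookkeeping(self, bundle, expected, match):
        metrics = stratified_sensitivity(match, bundle.genes, bundle.gene_sets,
                                         bundle.reference)
        by_key = {(m.function, m.gene_set): m for m in metrics}
        for (stratum, gs), (tp, fn) in expected.per_geneset.items():
            m = by_key[(stratum, gs)]
            assert (m.tp, m.fn) == (tp, fn), (stratum, gs)
        wg = by_key[("whole-genome", "N/A")]
        assert (wg.tp, wg.fn) == expected.whole_genome

    def test_all_tp_stratum_of_seven(self):
        # seven all-TP truth rows inside one gene give Wilson(7,7) bounds
        gene = GeneModel("G1", "T", "chr1", "+", (Region("chr1", 10, 40),), 10, 40)
        from varbench.varcomp import MatchResult, MatchRow
        cds = "ATG" + "GAA" * 8 + "TAA"
        ref = {"chr1": "T" * 10 + cds + "T" * 20}
        rows = [MatchRow(snv(14 + 3 * i, "A", "C"), "truth", "TP") for i in range(7)]
        m = MatchResult(rows=rows)
        out = stratified_sensitivity(m, [gene], [GeneSet("S", frozenset({"G1"}))], ref)
        cell = {(x.function, x.gene_set): x for x in out}[("non-synonymous", "S")]
        assert cell.tp == 7 and cell.sensitivity == 1.0
        assert round(cell.ci_low, 3) == 0.646 and cell.ci_high == 1.0

    def test_empty_stratum_missing_sensitivity(self, bundle, match):
        metrics = stratified_sensitivity(match, bundle.genes, bundle.gene_sets,
                                         bundle.reference)
        empty = [m for m in metrics if m.tp + m.fn == 0]
        assert empty and all(m.sensitivity is None for m in empty)


class TestFnCauses:
    def test_planted_cause_fractions_recovered(self, bundle, expected, match):
        _, summary = attribute_fn_causes(
            match.fnv_records(), bundle.query, bundle.depth, bundle.reference,
            repeat_tracks=bundle.repeat_tracks,
        )
        for cause, frac in expected.fn_cause_fractions.items():
            assert summary.get(cause, 0.0) == pytest.approx(frac, abs=1e-9), cause

    def test_filtered_and_lowcov_rules(self):
        ref = {"chr1": "ACGTACGTACGTACGTACGT"}
        fnv = [snv(5, "A", "G"), snv(13, "A", "G")]
        raw = CallSet("Q", [VariantRecord("chr1", 5, "A", ("G",), 40.0,
                                          frozenset({"strandBias"}), (0, 1), 30)])
        causes, summary = attribute_fn_causes(
            fnv, raw, {("chr1", 5): 30, ("chr1", 13): 5}, ref)
        by_pos = {c.variant.pos: c.causes for c in causes}
        assert "filtered" in by_pos[5]
        assert "low_coverage" in by_pos[13]
        assert summary["filtered"] == 0.5 and summary["low_coverage"] == 0.5

    def test_high_gc_window(self):
        # 100 bp centered window with 80 G/C bases -> 0.80 > 0.75
        seq = "AT" * 30 + "GC" * 40 + "AT" * 30
        ref = {"chr1": seq}
        fnv = [snv(100, seq[99], "A" if seq[99] != "A" else "T")]
        _, summary = attribute_fn_causes(fnv, CallSet("Q", []), {}, ref)
        assert summary.get("high_gc") == 1.0


class TestFilterSpecificity:
    def test_planted_combo_fractions(self, bundle, expected, match):
        rows = filter_specificity(bundle.query, match, bundle.reference)
        got = {r["filters"]: (r["n_sites"], r["fraction_fp"]) for r in rows}
        for combo, (n, n_fp) in expected.filter_combos.items():
            key = ";".join(sorted(combo))
            assert got[key][0] == n
            assert got[key][1] == pytest.approx(n_fp / n)

    def test_pure_false_filter_is_fully_fp(self, tiny_truth_and_fp_world):
        query, match_res, ref = tiny_truth_and_fp_world
        rows = filter_specificity(query, match_res, ref)
        got = {r["filters"]: r for r in rows}
        assert got["X"]["fraction_fp"] == 1.0
        assert got["Y"]["fraction_fp"] == 0.0

    def test_unfiltered_callset_gives_empty_table(self):
        ref = {"chr1": "ACGTACGT"}
        from varbench.varcomp import MatchResult
        rows = filter_specificity(CallSet("Q", []), MatchResult(), ref)
        combos = [r for r in rows if r["filters"] not in
                  ("any single filter", "multiple filters", "all filtered")]
        assert combos == []


@pytest.fixture()
def tiny_truth_and_fp_world():
    rng = np.random.default_rng(9)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    ref = {"chr1": seq}
    from varbench.intervals import normalize as rsn
    hiconf = rsn([Region("chr1", 0, 2000)])

    def mk(pos, filters=frozenset()):
        r = seq[pos - 1]
        return VariantRecord("chr1", pos, r, ("A" if r != "A" else "C",),
                             40.0, filters, (0, 1), 30)

    truth_records = [mk(p) for p in range(100, 1000, 100)]
    truth = CallSet("T", truth_records)
    # filter X only on planted false calls; filter Y only on true variants
    query_records = [mk(p, frozenset({"X"})) for p in range(1100, 1400, 100)]
    query_records += [mk(100, frozenset({"Y"}))]
    query_records += truth_records[1:]
    query = CallSet("Q", query_records)
    m = classify(query, truth, hiconf, ref)
    return query, m, ref


def test_parameter_recovery_across_seeds():
    """Planted per-stratum sensitivities are recovered: the Wilson 95%
    interval of the estimate contains the planted rate in >= 90% of
    (seed x stratum) cells over 20 seeds."""
    cells = hits = 0
    for seed in range(20):
        cfg = compact_config(seed=100 + seed)
        bundle = generate(cfg)
        exp = expected_metrics(bundle)
        m = classify(bundle.query, bundle.truth, bundle.hiconf, bundle.reference)
        # pipeline counts must equal bookkeeping counts exactly
        assert (m.tp, m.fnv) == exp.whole_genome
        for stratum, (tp, fn) in exp.strata.items():
            p_planted = cfg.stratum_sensitivity[stratum]
            lo, hi = binomial_ci(tp, tp + fn)
            cells += 1
            hits += lo <= p_planted <= hi
    assert hits / cells >= 0.90
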