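"""Variant normalization, haplotype matching and TP/FNV/QV classification."""

import numpy as np
import pytest

from varbench.core_io import CallSet, Region, VariantRecord
from varbench.errors import ClusterTooComplexError, ConsistencyError
from varbench.intervals import normalize as rs_normalize
from varbench.synthetic import generate
from varbench.varcomp import (
    classify,
    haplotype_match,
    normalize_variant,
    split_multiallelic,
)
from conftest import compact_config


def V(pos, ref, alt, gt=(0, 1), chrom="chr1", **kw):
    return VariantRecord(chrom, pos, ref, (alt,) if isinstance(alt, str) else alt,
                         genotype=gt, **kw)


# ---------------------------------------------------------------------------
# normalization


def oracle_leftmost_minimal(seq: str, pos: int, ref: str, alt: str):
    """Independent oracle: enumerate every equivalent irreducible
    (pos, ref, alt) triple by sequence equality and take the leftmost (then
    shortest)."""
    mutated = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
    tail_gain = len(mutated) - len(seq)
    cands = []
    for p in range(1, len(seq) + 1):
        for rl in range(1, 8):
            if p - 1 + rl > len(seq):
                break
            r = seq[p - 1 : p - 1 + rl]
            al = rl + tail_gain
            if al < 1:
                continue
            a = mutated[p - 1 : p - 1 + al]
            if seq[: p - 1] + a + seq[p - 1 + rl :] != mutated:
                continue
            if r == a:
                continue
            if len(r) > 1 and len(a) > 1 and (r[0] == a[0] or r[-1] == a[-1]):
                continue  # reducible
            if len(r) == 1 or len(a) == 1:
                if r[-1] == a[-1] and p > 1:
                    continue  # still left-shiftable
            cands.append((p, r, a))
    return min(cands, key=lambda t: (t[0], len(t[1])))


class TestNormalizeVariant:
    def test_snv_unchanged(self):
        ref = {"chr1": "GCAAAT"}
        v = V(3, "A", "G")
        assert normalize_variant(v, ref) == v

    def test_homopolymer_deletion_left_aligned(self):
        # deletion of one A from the run in GCAAAT shifts to pos 2, CA>C
        ref = {"chr1": "GCAAAT"}
        out = normalize_variant(V(4, "AA", "A"), ref)
        assert (out.pos, out.ref, out.alts) == (2, "CA", ("C",))

    def test_mnv_trimmed_to_snv(self):
        ref = {"chr1": "T" * 9 + "ATG" + "T" * 5}
        out = normalize_variant(V(10, "ATG", "ATC"), ref)
        assert (out.pos, out.ref, out.alts) == (12, "G", ("C",))

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            normalize_variant(V(1, "T", "G"), {"chr1": "GCAAAT"})

    def test_matches_exhaustive_oracle_on_random_indels(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        # make runs so left-alignment actually shifts
        seq = seq[:30] + "AAAAA" + seq[35:60] + "TGTGTGTG" + seq[68:]
        ref = {"chr1": seq}
        n_checked = 0
        for _ in range(300):
            pos = int(rng.integers(2, len(seq) - 10))
            if rng.random() < 0.5:  # deletion
                dlen = int(rng.integers(1, 4))
                v = V(pos, seq[pos - 1 : pos + dlen], seq[pos - 1])
            else:  # insertion
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(1, 4))))
                v = V(pos, seq[pos - 1], seq[pos - 1] + ins)
            got = normalize_variant(v, ref)
            exp = oracle_leftmost_minimal(seq, v.pos, v.ref, v.alts[0])
            assert (got.pos, got.ref, got.alts[0]) == exp
            n_checked += 1
        assert n_checked == 300


def test_split_multiallelic_genotype_remap():
    v = V(5, "A", ("G", "T"), gt=(1, 2))
    a, b = split_multiallelic(v)
    assert a.alts == ("G",) and a.genotype == (1, 0)
    assert b.alts == ("T",) and b.genotype == (0, 1)


# ---------------------------------------------------------------------------
# haplotype matching


class TestHaplotypeMatch:
    REF = {"chr1": "T" * 99 + "AT" + "C" * 99}  # pos 100='A', 101='T'
    WIN = Region("chr1", 90, 110)

    def test_phased_snv_pair_equals_mnv(self):
        truth = [V(100, "A", "G"), V(101, "T", "C")]
        query = [V(100, "AT", "GC")]
        assert haplotype_match(truth, query, self.WIN, self.REF)

    def test_identical_records_match(self):
        truth = [V(100, "A", "G", gt=(1, 1))]
        assert haplotype_match(truth, list(truth), self.WIN, self.REF)

    def test_het_vs_hom_alt_is_genotype_mismatch(self):
        truth = [V(100, "A", "G", gt=(0, 1))]
        query = [V(100, "A", "G", gt=(1, 1))]
        assert not haplotype_match(truth, query, self.WIN, self.REF)

    def test_trans_pair_differs_from_mnv(self):
        # hom SNVs force cis; MNV on one haplotype cannot represent two homs
        truth = [V(100, "A", "G", gt=(1, 1)), V(101, "T", "C", gt=(0, 1))]
        query = [V(100, "AT", "GC", gt=(0, 1))]
        assert not haplotype_match(truth, query, self.WIN, self.REF)

    def test_het_cap_raises(self):
        ref = {"chr1": "ACGTACGTACGTACGTACGTACGTACGT"}
        truth = [V(p, ref["chr1"][p - 1], "ACGT"[(("ACGT".index(ref["chr1"][p - 1])) + 1) % 4])
                 for p in range(2, 15)]
        with pytest.raises(ClusterTooComplexError):
            haplotype_match(truth, truth, Region("chr1", 0, 20), ref)

    def test_representation_invariance_random_clusters(self, rng):
        """Any phased SNV pair re-encoded as its cis MNV must match; breaking
        one allele must not."""
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        ref = {"chr1": seq}
        for _ in range(50):
            p = int(rng.integers(10, 280))
            r1, r2 = seq[p - 1], seq[p]
            a1 = "ACGT"[("ACGT".index(r1) + 1 + int(rng.integers(3))) % 4]
            a2 = "ACGT"[("ACGT".index(r2) + 1 + int(rng.integers(3))) % 4]
            if a1 == r1 or a2 == r2:
                continue
            truth = [V(p, r1, a1), V(p + 1, r2, a2)]
            window = Region("chr1", p - 5, p + 6)
            assert haplotype_match(truth, [V(p, r1 + r2, a1 + a2)], window, ref)
            wrong = "ACGT"[("ACGT".index(a2) + 1) % 4]
            bad = a1 + (wrong if wrong != r2 else "ACGT"[("ACGT".index(a2) + 2) % 4])
            if bad[1] != r2 and bad != a1 + a2:
                assert not haplotype_match(truth, [V(p, r1 + r2, bad)], window, ref)


# ---------------------------------------------------------------------------
# classification


@pytest.fixture(scope="module")
def tiny_world():
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
    ref = {"chr1": seq}
    hiconf = rs_normalize([Region("chr1", 100, 4500)])
    records = []
    for p in range(200, 4400, 150):
        r = seq[p - 1]
        records.append(V(p, r, "ACGT"[("ACGT".index(r) + 1) % 4]))
    truth = CallSet("T", records)
    return ref, hiconf, truth


class TestClassify:
    def test_identity_gives_full_sensitivity(self, tiny_world):
        ref, hiconf, truth = tiny_world
        m = classify(CallSet("Q", list(truth.records)), truth, hiconf, ref)
        assert m.sensitivity == 1.0 and m.qv == 0 and m.fnv == 0

    def test_dropped_truth_becomes_fnv(self, tiny_world):
        ref, hiconf, truth = tiny_world
        query = CallSet("Q", truth.records[:-3])
        m = classify(query, truth, hiconf, ref)
        assert m.fnv == 3 and m.tp == len(truth.records) - 3

    def test_filtered_query_excluded_from_matching(self, tiny_world):
        ref, hiconf, truth = tiny_world
        from dataclasses import replace

        query_records = [replace(truth.records[0], filters=frozenset({"Q20"}))]
        query_records += truth.records[1:]
        m = classify(CallSet("Q", query_records), truth, hiconf, ref)
        assert m.fnv == 1 and len(m.filtered_query) == 1

    def test_outside_region_excluded(self, tiny_world):
        ref, hiconf, truth = tiny_world
        extra = V(4800, ref["chr1"][4799], "A" if ref["chr1"][4799] != "A" else "C")
        m = classify(CallSet("Q", list(truth.records) + [extra]), truth, hiconf, ref)
        assert m.qv == 0
        assert m.count("query", "OUTSIDE") == 1

    def test_genotype_discordant_is_tp_with_diagnostic(self, tiny_world):
        ref, hiconf, truth = tiny_world
        from dataclasses import replace

        query_records = [replace(truth.records[0], genotype=(1, 1))]
        query_records += truth.records[1:]
        m = classify(CallSet("Q", query_records), truth, hiconf, ref)
        assert m.fnv == 0 and m.qv == 0
        assert len(m.genotype_discordant()) == 1

    def test_genotype_strict_demotes_discordant(self, tiny_world):
        ref, hiconf, truth = tiny_world
        from dataclasses import replace

        query_records = [replace(truth.records[0], genotype=(1, 1))]
        query_records += truth.records[1:]
        m = classify(CallSet("Q", query_records), truth, hiconf, ref,
                     genotype_strict=True)
        assert m.fnv == 1 and m.qv == 1

    def test_edge_flag_within_50bp(self, tiny_world):
        ref, hiconf, truth = tiny_world
        m = classify(CallSet("Q", list(truth.records)), truth, hiconf, ref)
        for row in m.rows:
            d = hiconf.edge_distance(row.variant.chrom, row.variant.pos)
            if d is not None:
                assert row.edge_flag == (d <= 49)


def test_partition_identities_on_synthetic_run():
    bundle = generate(compact_config(seed=17))
    m = classify(bundle.query, bundle.truth, bundle.hiconf, bundle.reference)
    truth_in = sum(1 for r in m.rows if r.role == "truth" and r.match_class != "OUTSIDE")
    query_in = sum(1 for r in m.rows if r.role == "query" and r.match_class != "OUTSIDE")
    assert truth_in == m.tp + m.fnv
    assert query_in == m.count("query", "TP") + m.qv


def test_planted_fnv_count_recovered(bundle, expected, match):
    assert (match.tp, match.fnv) == expected.whole_genome
    assert match.qv == expected.qv_count
    assert len(match.genotype_discordant()) == expected.genotype_error_count
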