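"""K-mer uniqueness / alignability tracks against brute-force oracles, and
variant-context summaries."""

import numpy as np
import pytest

from varbench.core_io import Region, VariantRecord
from varbench.errors import DomainError
from varbench.intervals import normalize
from varbench.uniqueness import (
    alignability,
    exact_uniqueness,
    percentage,
    track_to_regions,
    variant_context,
)


def rand_ref(rng, length, chrom="chr1"):
    return {chrom: "".join("ACGT"[i] for i in rng.integers(0, 4, length))}


def oracle_flags(reference, k, max_mismatch=None):
    """O(L^2 k) scan: a position is flagged iff no other genomic location
    matches its k-mer (exactly, or within the Hamming distance); k-mers with
    N are never flagged and N mismatches everything."""
    items = sorted(reference.items())
    kmers = [(c, i) for c, s in items for i in range(len(s) - k + 1)]
    flags = {c: np.zeros(len(s), dtype=bool) for c, s in items}
    ref = dict(items)

    def dist(c1, i1, c2, i2):
        a, b = ref[c1][i1:i1 + k], ref[c2][i2:i2 + k]
        return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")

    for c, i in kmers:
        if "N" in ref[c][i:i + k]:
            continue
        limit = 0 if max_mismatch is None else max_mismatch
        multi = any(
            dist(c, i, c2, j) <= limit
            for c2, j in kmers
            if (c, i) != (c2, j)
        )
        flags[c][i] = not multi
    return flags


class TestExactUniqueness:
    def test_random_sequence_all_unique(self, rng):
        ref = rand_ref(rng, 200)
        track = exact_uniqueness(ref, 35)
        assert track.flags["chr1"][: 200 - 34].all()
        assert not track.flags["chr1"][200 - 34 :].any()  # out of k-mer range

    def test_identical_chromosomes_nothing_unique(self, rng):
        ref = rand_ref(rng, 150)
        ref["chr2"] = ref["chr1"]
        track = exact_uniqueness(ref, 35)
        assert not track.flags["chr1"].any() and not track.flags["chr2"].any()

    def test_copied_block_matches_brute_force(self, rng):
        seq = rand_ref(rng, 2000)["chr1"]
        seq = seq[:800] + seq[100:200] + seq[900:]  # copy a 100 bp block
        ref = {"chr1": seq}
        track = exact_uniqueness(ref, 35)
        exp = oracle_flags(ref, 35)
        assert np.array_equal(track.flags["chr1"], exp["chr1"])

    def test_kmer_with_n_never_unique(self):
        ref = {"chr1": "ACGTACGTNNACGTACGTAT"}
        track = exact_uniqueness(ref, 5)
        for i in range(len(ref["chr1"]) - 4):
            if "N" in ref["chr1"][i : i + 5]:
                assert not track.flags["chr1"][i]

    def test_k_longer_than_chromosome_rejected(self):
        with pytest.raises(DomainError):
            exact_uniqueness({"chr1": "ACGT"}, 10)

    def test_monotone_in_k(self, rng):
        seq = rand_ref(rng, 600)["chr1"]
        seq = seq[:300] + seq[50:90] + seq[340:]  # plant a repeat
        ref = {"chr1": seq}
        t_small = exact_uniqueness(ref, 20)
        t_big = exact_uniqueness(ref, 30)
        valid = len(seq) - 30 + 1
        assert np.all(t_big.flags["chr1"][:valid] >= t_small.flags["chr1"][:valid])


class TestAlignability:
    def test_divergent_copies_alignable(self, rng):
        seq = rand_ref(rng, 1200)["chr1"]
        block = list(seq[100:200])
        for p in (10, 50, 90):  # 3 mismatches
            block[p] = "A" if block[p] != "A" else "C"
        seq = seq[:600] + "".join(block) + seq[700:]
        track = alignability({"chr1": seq}, 100, 2)
        assert track.flags["chr1"][100] and track.flags["chr1"][600]

    def test_identical_copies_not_alignable(self, rng):
        seq = rand_ref(rng, 1200)["chr1"]
        seq = seq[:600] + seq[100:200] + seq[700:]
        track = alignability({"chr1": seq}, 100, 2)
        assert not track.flags["chr1"][100] and not track.flags["chr1"][600]

    def test_hamming_ladder_matches_brute_force(self, rng):
        """Planted near-duplicates at Hamming distance 0..3 agree with the
        O(L^2 k) oracle position by position."""
        seq = list(rand_ref(rng, 1000)["chr1"])
        src = seq[100:140]
        for target, n_mm in ((300, 0), (450, 1), (600, 2), (750, 3)):
            copy = list(src)
            for p in range(n_mm):
                q = 5 + 11 * p
                copy[q] = "A" if copy[q] != "A" else "C"
            seq[target : target + 40] = copy
        ref = {"chr1": "".join(seq)}
        track = alignability(ref, 40, 2)
        exp = oracle_flags(ref, 40, max_mismatch=2)
        assert np.array_equal(track.flags["chr1"], exp["chr1"])

    def test_multi_chromosome_brute_force(self, rng):
        ref = rand_ref(rng, 300)
        ref["chr2"] = ref["chr1"][40:180] + rand_ref(rng, 100, "x")["x"]
        track = alignability(ref, 30, 2)
        exp = oracle_flags(ref, 30, max_mismatch=2)
        for c in ref:
            assert np.array_equal(track.flags[c], exp[c]), c

    def test_zero_mismatch_equals_exact(self, rng):
        seq = rand_ref(rng, 800)["chr1"]
        seq = seq[:400] + seq[100:160] + seq[460:]
        ref = {"chr1": seq}
        a = alignability(ref, 35, 0)
        e = exact_uniqueness(ref, 35)
        assert np.array_equal(a.flags["chr1"], e.flags["chr1"])

    def test_windowed_scan_matches_full_when_wide_enough(self, rng):
        seq = rand_ref(rng, 600)["chr1"]
        seq = seq[:300] + seq[50:100] + seq[350:]
        ref = {"chr1": seq}
        full = alignability(ref, 30, 2)
        banded = alignability(ref, 30, 2, window=600)
        assert np.array_equal(full.flags["chr1"], banded.flags["chr1"])


class TestVariantContext:
    def test_percentage_printed_convention(self):
        assert percentage(12138, 15735) == 77.14
        assert percentage(998, 1212) == 82.34
        with pytest.raises(DomainError):
            percentage(1, 0)

    def test_all_in_hiconf_is_100(self, rng):
        ref = rand_ref(rng, 500)
        hic = normalize([Region("chr1", 0, 500)])
        t35 = exact_uniqueness(ref, 35)
        t100 = alignability(ref, 100, 2)
        variants = [VariantRecord("chr1", p, ref["chr1"][p - 1],
                                  ("A" if ref["chr1"][p - 1] != "A" else "C",))
                    for p in range(10, 300, 37)]
        ctx, rows = variant_context(variants, hic, t35, t100)
        assert rows[0]["pct_in_hiconf"] == 100.00
        assert all(c.in_hiconf for c in ctx)

    def test_planted_flags_summarized(self, rng):
        seq = rand_ref(rng, 800)["chr1"]
        seq = seq[:400] + seq[100:150] + seq[450:]  # 50 bp exact duplication
        ref = {"chr1": seq}
        hic = normalize([Region("chr1", 0, 300)])
        t35 = exact_uniqueness(ref, 35)
        t100 = alignability(ref, 100, 2)
        variants = [
            VariantRecord("chr1", 101, seq[100], ("A" if seq[100] != "A" else "C",)),
            VariantRecord("chr1", 700, seq[699], ("A" if seq[699] != "A" else "C",)),
        ]
        ctx, rows = variant_context(variants, hic, t35, t100)
        assert ctx[0].in_hiconf and not ctx[0].unique35  # inside the duplication
        assert not ctx[1].in_hiconf
        assert rows[0]["pct_in_hiconf"] == 50.0

    def test_out_of_range_flagged_missing(self, rng):
        ref = rand_ref(rng, 100)
        t = exact_uniqueness(ref, 35)
        v = VariantRecord("chrX", 5, "A", ("C",))
        ctx, _ = variant_context([v], normalize([]), t, t)
        assert ctx[0].unique35 is None


def test_track_to_regions_round_trip(rng):
    ref = rand_ref(rng, 300)
    track = exact_uniqueness(ref, 35)
    total = sum(r.length for r in track_to_regions(track))
    assert total == int(track.flags["chr1"].sum())
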