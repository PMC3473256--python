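"""Superlocus construction, verdict classification and somatic output."""

import dataclasses

import numpy as np
import pytest

from twindiff import calldiff
from twindiff.core import CallSet, DataError, KnownVariantSet, ReferenceGenome, VariantCall
from twindiff.calldiff import (
    Superlocus,
    build_superloci,
    classify_superlocus,
    compare_callsets,
    somatic_output,
    stats_from_counts,
    superlocus_stats,
)

from oracles import classify_oracle, partition_oracle, random_callset_pair


def _cs(calls, sample="s"):
    return CallSet(sample_id=sample, calls=list(calls))


def _snp(ref, contig, pos, het=True, alt=None, qual=50.0):
    b = ref.fetch(contig, pos, pos + 1)
    if alt is None:
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[b]
    a1, a2 = (b, alt) if het else (alt, alt)
    return VariantCall(contig, pos, pos + 1, "snp", a1, a2, qual)


class TestBuildSuperloci:
    def test_distant_snps_stay_separate(self, tiny_ref):
        a = _cs([_snp(tiny_ref, "chr1", 5), _snp(tiny_ref, "chr1", 45)])
        b = _cs([], "t")
        sls = build_superloci(a, b, tiny_ref, merge_gap=20)
        assert len(sls) == 2

    def test_nearby_calls_merge(self, tiny_ref):
        # SNP and a 2 bp deletion 5 bp downstream, merge gap 20 -> one superlocus
        snp = _snp(tiny_ref, "chr1", 10)
        dele = VariantCall("chr1", 16, 18, "del", "", "")
        sls = build_superloci(_cs([snp, dele]), _cs([], "t"), tiny_ref, merge_gap=20)
        assert len(sls) == 1
        assert (sls[0].begin, sls[0].end) == (10, 18)

    def test_partition_matches_quadratic_closure_oracle(self):
        """On 200 random call-set pairs the superlocus partition equals the
        transitive closure of the proximity relation computed by brute force."""
        rng = np.random.default_rng(20)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
        ref = ReferenceGenome({"c": seq}, {"c": "autosome"})
        for trial in range(200):
            merge_gap = int(rng.integers(0, 15))
            calls_a, calls_b = random_callset_pair(rng, ref)
            variants = [
                c
                for c in calls_a + calls_b
                if c.vartype not in ("ref", "no-call")
            ]
            sls = build_superloci(
                _cs(calls_a), _cs(calls_b, "t"), ref, merge_gap=merge_gap
            )
            spans = [(c.begin, c.end) for c in variants]
            expected = partition_oracle(spans, merge_gap)
            got_groups = []
            for sl in sls:
                members = {
                    i
                    for i, c in enumerate(variants)
                    if c in sl.calls_a or c in sl.calls_b
                }
                got_groups.append(members)
            assert sorted(map(sorted, got_groups)) == sorted(
                map(sorted, expected)
            ), f"trial {trial}"

    def test_unsorted_callset_rejected(self, tiny_ref):
        a = _cs([_snp(tiny_ref, "chr1", 5), _snp(tiny_ref, "chr1", 45)])
        a.calls.reverse()  # violate the sorted contract after construction
        with pytest.raises(DataError):
            build_superloci(a, _cs([], "t"), tiny_ref)


class TestClassifySuperlocus:
    def classify(self, ref, calls_a, calls_b, merge_gap=20):
        records = compare_callsets(
            _cs(calls_a, "a"), _cs(calls_b, "b"), ref, merge_gap=merge_gap
        )
        assert len(records) == 1
        return records[0].verdict

    def test_haplotype_labels_carry_no_meaning(self, tiny_ref):
        b = tiny_ref.fetch("chr1", 10, 11)
        alt = "A" if b != "A" else "G"
        v1 = VariantCall("chr1", 10, 11, "snp", b, alt, 50)
        v2 = VariantCall("chr1", 10, 11, "snp", alt, b, 50)
        assert self.classify(tiny_ref, [v1], [v2]) == "identical"

    def test_cis_trans_het_pair_is_phase_mismatch(self, tiny_ref):
        ref = tiny_ref
        b1, b2 = ref.fetch("chr1", 10, 11), ref.fetch("chr1", 14, 15)
        alt1 = "A" if b1 != "A" else "G"
        alt2 = "A" if b2 != "A" else "G"
        cis = [
            VariantCall("chr1", 10, 11, "snp", alt1, b1, 50),
            VariantCall("chr1", 14, 15, "snp", alt2, b2, 50),
        ]
        trans = [
            VariantCall("chr1", 10, 11, "snp", alt1, b1, 50),
            VariantCall("chr1", 14, 15, "snp", b2, alt2, 50),
        ]
        assert self.classify(ref, cis, trans) == "phase-mismatch"
        assert self.classify(ref, cis, list(cis)) == "identical"

    def test_variant_over_reference_is_only_a(self, tiny_ref):
        assert self.classify(tiny_ref, [_snp(tiny_ref, "chr1", 10)], []) == "onlyA"

    def test_variant_over_nocall_is_consistent(self, tiny_ref):
        v = _snp(tiny_ref, "chr1", 10)
        nc = VariantCall("chr1", 8, 13, "no-call", None, None)
        assert self.classify(tiny_ref, [v], [nc]) == "consistent"

    def test_conflicting_hom_calls_mismatch(self, tiny_ref):
        b = tiny_ref.fetch("chr1", 10, 11)
        alts = [x for x in "ACGT" if x != b]
        v1 = VariantCall("chr1", 10, 11, "snp", alts[0], alts[0], 50)
        v2 = VariantCall("chr1", 10, 11, "snp", alts[1], alts[1], 50)
        assert self.classify(tiny_ref, [v1], [v2]) == "mismatch"

    def test_equivalent_indel_representations_match(self, tiny_ref):
        # tiny_ref starts ACGTACGTTGCAGG: positions 8-9 are TG...; build a
        # homopolymer-free check with a 2 bp repeat instead
        ref = ReferenceGenome({"c": "TTACACACGG"}, {"c": "autosome"})
        # deleting AC at 2 or at 4 leaves the same sequence
        d1 = VariantCall("c", 2, 4, "del", "", "")
        d2 = VariantCall("c", 4, 6, "del", "", "")
        assert self.classify(ref, [d1], [d2], merge_gap=5) == "identical"

    def test_oversized_superlocus_degrades_to_mismatch(self, tiny_ref):
        sl = Superlocus(
            "chr1",
            0,
            20,
            calls_a=[_snp(tiny_ref, "chr1", 5)],
            calls_b=[_snp(tiny_ref, "chr1", 5)],
        )
        with pytest.warns(RuntimeWarning):
            rec = classify_superlocus(sl, tiny_ref, max_span=10)
        assert rec.verdict == "mismatch"

    def test_agrees_with_enumeration_oracle(self):
        """Randomized superloci classified identically to the exhaustive
        phase/completion-enumeration oracle (small instances)."""
        rng = np.random.default_rng(7)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
        ref = ReferenceGenome({"c": seq}, {"c": "autosome"})
        checked = 0
        while checked < 150:
            calls_a, calls_b = random_callset_pair(rng, ref)
            sls = build_superloci(_cs(calls_a), _cs(calls_b, "t"), ref, merge_gap=10)
            for sl in sls:
                expected = classify_oracle(sl, ref)
                got = classify_superlocus(sl, ref).verdict
                assert got == expected, (sl, got, expected)
                checked += 1

    def test_swapping_inputs_swaps_only_verdicts(self, bundle_noreads):
        b = bundle_noreads
        fwd = superlocus_stats(compare_callsets(b.genomic, b.cellline, b.ref))
        rev = superlocus_stats(compare_callsets(b.cellline, b.genomic, b.ref))
        assert fwd["counts"]["onlyA"] == rev["counts"]["onlyB"]
        assert fwd["counts"]["onlyB"] == rev["counts"]["onlyA"]
        for same in ("identical", "mismatch", "phase-mismatch", "consistent"):
            assert fwd["counts"][same] == rev["counts"][same]


class TestSuperlocusStats:
    def test_self_comparison_is_all_identical(self, bundle_noreads):
        b = bundle_noreads
        stats = superlocus_stats(compare_callsets(b.genomic, b.genomic, b.ref))
        counts = stats["counts"]
        assert counts["onlyA"] == counts["onlyB"] == counts["mismatch"] == 0
        assert counts["phase-mismatch"] == 0
        assert stats["identical_fraction"] == 1.0

    def test_identical_fraction_from_reported_counts(self):
        """Genome-scale verdict counts give an identical fraction of 0.9930
        (the fraction derived from the counts, not a forced headline figure)."""
        stats = stats_from_counts(
            {"identical": 3_782_487, "onlyA": 15_364, "onlyB": 11_435}
        )
        assert stats["identical_fraction"] == pytest.approx(0.9930, abs=5e-5)

    def test_empty_records_give_null_fraction(self):
        stats = superlocus_stats([])
        assert all(v == 0 for v in stats["counts"].values())
        assert stats["identical_fraction"] is None


class TestSomaticOutput:
    def test_tumor_het_snp_over_normal_ref(self, tiny_ref):
        tumor = _cs([_snp(tiny_ref, "chr1", 10)], "t")
        out = somatic_output(_cs([], "n"), tumor, tiny_ref)
        assert len(out) == 1 and out[0].fully_called

    def test_tumor_variant_over_normal_nocall_flagged(self, tiny_ref):
        nc = VariantCall("chr1", 8, 13, "no-call", None, None)
        out = somatic_output(
            _cs([nc], "n"), _cs([_snp(tiny_ref, "chr1", 10)], "t"), tiny_ref
        )
        assert len(out) == 1 and not out[0].fully_called

    def test_identical_callsets_yield_no_candidates(self, bundle_noreads):
        b = bundle_noreads
        assert somatic_output(b.cellline, b.cellline, b.ref) == []

    def test_shared_variant_not_a_candidate(self, tiny_ref):
        v = _snp(tiny_ref, "chr1", 10)
        out = somatic_output(_cs([v], "n"), _cs([v], "t"), tiny_ref)
        assert out == []


class TestNovelty:
    def test_known_candidate_not_novel(self, tiny_ref):
        v = _snp(tiny_ref, "chr1", 10)
        cand = calldiff.SomaticCandidate(variant=v, fully_called=True)
        known = KnownVariantSet.from_keys(v.key(tiny_ref))
        (out,) = calldiff.annotate_novelty([cand], known, tiny_ref)
        assert out.novel is False

    def test_empty_known_set_makes_all_novel(self, tiny_ref):
        v = _snp(tiny_ref, "chr1", 10)
        cand = calldiff.SomaticCandidate(variant=v, fully_called=True)
        (out,) = calldiff.annotate_novelty(
            [cand], KnownVariantSet.from_keys([]), tiny_ref
        )
        assert out.novel is True
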