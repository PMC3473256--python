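"""Functional classification and the QC metrics report."""

import dataclasses

import numpy as np
import pytest

from twindiff.core import (
    CallSet,
    GeneModel,
    KnownVariantSet,
    ReferenceGenome,
    VariantCall,
    revcomp,
)
from twindiff.metrics import (
    MetricsReport,
    build_metrics_report,
    classify_variant,
    coverage_summary,
    derived_ratios,
    gene_overlap_report,
    het_hom_ratio,
    novel_rate,
    report_table,
    tstv_ratio,
)


def _gene_ref(cds: str, flank: str = "TTTTTTTTTT", strand: str = "+"):
    """Reference with one gene whose CDS is ``cds`` starting at position 10."""
    seq = flank + (cds if strand == "+" else revcomp(cds)) + flank
    ref = ReferenceGenome({"c": seq}, {"c": "autosome"})
    gm = GeneModel("g1", "c", strand, [(10, 10 + len(cds))])
    return ref, gm


class TestClassifyVariant:
    def test_stop_gained_is_nonsense(self):
        # codon TAC -> TAA by a third-position C->A change
        ref, gm = _gene_ref("ATGTACAAATAG")
        v = VariantCall("c", 15, 16, "snp", "C", "A")
        assert classify_variant(v, gm, ref) == "nonsense"

    def test_met_to_ile_is_missense(self):
        # codon ATG -> ATA
        ref, gm = _gene_ref("ATGTACAAATAG")
        v = VariantCall("c", 12, 13, "snp", "G", "A")
        assert classify_variant(v, gm, ref) == "missense"

    def test_third_position_wobble_is_synonymous(self):
        # AAA -> AAG, both lysine
        ref, gm = _gene_ref("ATGAAATAG")
        v = VariantCall("c", 15, 16, "snp", "A", "G")
        assert classify_variant(v, gm, ref) == "synonymous"

    def test_stop_lost_is_nonstop(self):
        # TAG -> TGG (stop -> Trp)
        ref, gm = _gene_ref("ATGAAATAG")
        v = VariantCall("c", 17, 18, "snp", "A", "G")
        assert classify_variant(v, gm, ref) == "nonstop"

    def test_frame_rules_for_indels(self):
        ref, gm = _gene_ref("ATGAAACCCTAG")
        in_frame = VariantCall("c", 13, 16, "del", "", "")
        shift = VariantCall("c", 13, 15, "del", "", "")
        assert classify_variant(in_frame, gm, ref) == "frame-preserving"
        assert classify_variant(shift, gm, ref) == "frame-shifting"
        ins = VariantCall("c", 13, 13, "ins", "AT", "AT")
        assert classify_variant(ins, gm, ref) == "frame-shifting"

    def test_variant_outside_cds_is_noncoding(self):
        ref, gm = _gene_ref("ATGAAATAG")
        v = VariantCall("c", 2, 3, "snp", "T", "A")
        assert classify_variant(v, gm, ref) == "noncoding"

    def test_minus_strand_classification(self):
        # the same nonsense change seen from the minus strand
        ref, gm = _gene_ref("ATGTACAAATAG", strand="-")
        # CDS position 15 on the plus-strand gene maps to the complement here
        cds = "ATGTACAAATAG"
        # find the genomic position of the codon-3 base: CDS offset 5
        genomic_pos = 10 + (len(cds) - 1 - 5)
        base = ref.fetch("c", genomic_pos, genomic_pos + 1)
        v = VariantCall("c", genomic_pos, genomic_pos + 1, "snp", base, revcomp("A"))
        assert classify_variant(v, gm, ref) == "nonsense"

    def test_strand_consistency(self):
        """Reverse-complementing the reference and gene model leaves every
        class unchanged."""
        rng = np.random.default_rng(3)
        cds = "ATG" + "".join(
            np.random.default_rng(4).choice(["AAA", "CCC", "GAT", "TGC", "TAC"], 20)
        ) + "TAG"
        ref, gm = _gene_ref(cds)
        length = len(ref.contigs["c"])
        flipped_ref = ReferenceGenome(
            {"c": revcomp(ref.contigs["c"])}, {"c": "autosome"}
        )
        b0, e0 = gm.cds_intervals[0]
        flipped_gm = GeneModel(
            "g1", "c", "-", [(length - e0, length - b0)]
        )
        for pos in range(10, 10 + len(cds)):
            base = ref.fetch("c", pos, pos + 1)
            for alt in "ACGT":
                if alt == base:
                    continue
                v = VariantCall("c", pos, pos + 1, "snp", base, alt)
                fpos = length - pos - 1
                fv = VariantCall(
                    "c", fpos, fpos + 1, "snp", revcomp(base), revcomp(alt)
                )
                assert classify_variant(v, gm, ref) == classify_variant(
                    fv, flipped_gm, flipped_ref
                )

    def test_equal_length_sub_translated(self):
        # AAA CCC -> AAG GGC in one 4 bp substitution: protein KP -> KG
        ref, gm = _gene_ref("ATGAAACCCTAG")
        v = VariantCall("c", 15, 19, "sub", "GGGC", "GGGC")
        assert classify_variant(v, gm, ref) in ("missense", "nonsense")


class TestSimpleStats:
    def test_tstv_hand_count(self):
        assert tstv_ratio([("A", "G"), ("C", "T"), ("A", "C")]) == 2.0

    def test_all_transitions_guarded(self):
        assert tstv_ratio([("A", "G"), ("G", "A")]) is None

    def test_simulated_tstv_matches_closed_form(self, bundle_noreads):
        """ts probability 0.68 gives ts/tv ~ 0.68/0.32 = 2.125."""
        b = bundle_noreads
        report = build_metrics_report(b.genomic, [], b.ref, b.known)
        assert report.tstv == pytest.approx(0.68 / 0.32, rel=0.12)

    def test_novel_rate_hand_count(self, tiny_ref):
        calls = []
        for pos in range(0, 40, 2):
            base = tiny_ref.fetch("chr1", pos, pos + 1)
            alt = "A" if base != "A" else "C"
            calls.append(VariantCall("chr1", pos, pos + 1, "snp", base, alt))
        known = KnownVariantSet.from_keys(
            k for c in calls[:19] for k in c.key(tiny_ref)
        )
        assert novel_rate(calls, known, tiny_ref) == pytest.approx(1 / 20)

    def test_all_het_ratio_is_null(self, tiny_ref):
        base = tiny_ref.fetch("chr1", 4, 5)
        alt = "A" if base != "A" else "C"
        calls = [VariantCall("chr1", 4, 5, "snp", base, alt)]
        assert het_hom_ratio(calls, "snp", tiny_ref) is None


class TestDerivedRatios:
    def test_ratios_recompute_from_counts(self):
        report = MetricsReport(
            sample_id="genomic",
            total_counts={"snp": 3_346_813, "ins": 187_392, "del": 204_807},
            class_counts={
                "synonymous_snp": 9_778,
                "missense_snp": 9_329,
                "nonsense_snp": 90,
                "nonstop_snp": 13,
                "frameshift_ins": 121,
                "frameshift_del": 108,
                "frameshift_sub": 17,
                "preserve_ins": 113,
                "preserve_del": 107,
                "preserve_sub": 258,
            },
        )
        r = derived_ratios(report)
        assert r.frameshift_preserve_ratio == pytest.approx((121 + 108 + 17) / (113 + 107 + 258))
        assert r.nonsyn_syn_ratio == pytest.approx(9_329 / 9_778)
        assert r.ins_del_ratio == pytest.approx(187_392 / 204_807)
        assert r.indel_snp_ratio == pytest.approx((187_392 + 204_807) / 3_346_813)

    def test_zero_denominator_gives_null(self):
        r = derived_ratios(MetricsReport(sample_id="x"))
        assert r.frameshift_preserve_ratio is None
        assert r.nonsyn_syn_ratio is None

    def test_report_internally_consistent(self, bundle_noreads):
        """Every derived ratio in a generated report recomputes exactly from
        the counts in the same report."""
        b = bundle_noreads
        r = build_metrics_report(b.genomic, b.genes, b.ref, b.known)
        cc, tc = r.class_counts, r.total_counts
        fs = cc["frameshift_ins"] + cc["frameshift_del"] + cc["frameshift_sub"]
        fp = cc["preserve_ins"] + cc["preserve_del"] + cc["preserve_sub"]
        if fp:
            assert r.frameshift_preserve_ratio == fs / fp
        if cc["synonymous_snp"]:
            assert r.nonsyn_syn_ratio == cc["missense_snp"] / cc["synonymous_snp"]
        assert r.ins_del_ratio == tc["ins"] / tc["del"]
        assert r.indel_snp_ratio == (tc["ins"] + tc["del"]) / tc["snp"]
        assert (
            r.fully_called_fraction
            + r.partially_called_fraction
            + r.nocalled_fraction
        ) == pytest.approx(1.0, abs=1e-9)

    def test_table_has_two_sample_columns(self, bundle_noreads):
        b = bundle_noreads
        reports = [
            build_metrics_report(cs, b.genes, b.ref, b.known)
            for cs in (b.genomic, b.cellline)
        ]
        table = report_table(reports)
        assert list(table.columns) == ["genomic", "cellline"]
        assert table.loc["SNP total count", "genomic"] > 0


class TestCoverageSummary:
    def test_fraction_at_depth(self):
        cs = coverage_summary({30: 10, 40: 60, 50: 30})
        assert cs.fraction_at_least(40) == pytest.approx(0.9)
        assert cs.fraction_at_least(0) == 1.0

    def test_uniform_depth(self):
        cs = coverage_summary(np.full(100, 40))
        assert cs.fraction_at_least(40) == 1.0


class TestGeneOverlap:
    def test_identical_inputs_full_overlap(self):
        items = [("g1", "missense", 5), ("g2", "frame-shifting", 9)]
        out = gene_overlap_report(items, list(items))
        assert out["overlap_fraction"] == 1.0
        assert out["flagged_genes"] == []

    def test_disjoint_inputs_zero_overlap(self):
        out = gene_overlap_report(
            [("g1", "missense", 5)], [("g2", "missense", 7)]
        )
        assert out["overlap_fraction"] == 0.0
        assert out["per_class"]["missense"]["only_a"] == ["g1"]

    def test_position_discrepancy_flagged(self):
        out = gene_overlap_report(
            [("g1", "missense", 5)], [("g1", "missense", 9)]
        )
        assert out["flagged_genes"] == ["g1"]

    def test_cellline_only_coding_snps_flag_only_b_genes(self, bundle_noreads):
        """Cell-line-private coding somatic SNPs appear as only-B genes."""
        from twindiff.metrics import classify_against_genes

        b = bundle_noreads
        somatic = set(b.truth.somatic_keys)

        def classes(cs):
            out = []
            for c in cs.variant_calls(b.ref):
                cls, gid = classify_against_genes(c, b.genes, b.ref)
                if gid is not None:
                    out.append((gid, cls, c.begin))
            return out

        ca, cb = classes(b.genomic), classes(b.cellline)
        report = gene_overlap_report(ca, cb)
        # genes hit only in the cell line by a somatic missense SNP must be
        # reported as only_b for that class
        somatic_coding = set()
        for c in b.cellline.variant_calls(b.ref):
            if set(c.key(b.ref)) & somatic:
                cls, gid = classify_against_genes(c, b.genes, b.ref)
                if cls == "missense":
                    somatic_coding.add(gid)
        genes_a_missense = {g for g, cls, _ in ca if cls == "missense"}
        expected_only_b = somatic_coding - genes_a_missense
        assert expected_only_b <= set(report["per_class"]["missense"]["only_b"])
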