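"""Twin-genome simulator: determinism, rate calibration, truth labelling."""

import dataclasses

import numpy as np
import pytest

from twindiff import calldiff
from twindiff.core import ConfigError
from twindiff.simulate import (
    SimulationConfig,
    derive_twin_callsets,
    simulate_bundle,
    simulate_individual,
    simulate_reference,
    simulate_unmapped_reads,
    write_bundle,
)


def _small_cfg(**over):
    base = dict(
        contigs={"chr1": 100_000, "EBV": 40_000},
        contig_class={"chr1": "autosome", "EBV": "viral"},
        seed=5,
        no_call_fraction=0.0,
        somatic_snp_count=0,
        n_genes=3,
        cellline_haploid_losses=0,
        cellline_deletions=0,
        loss_length=20_000,
    )
    base.update(over)
    return SimulationConfig(**base)


class TestReference:
    def test_contig_set_and_classes(self):
        cfg = SimulationConfig(seed=2)
        ref = simulate_reference(cfg)
        assert set(ref.contigs) == set(cfg.contigs)
        assert all(len(ref.contigs[c]) == n for c, n in cfg.contigs.items())

    def test_same_seed_identical_sequences(self):
        cfg = SimulationConfig(seed=9)
        assert simulate_reference(cfg).contigs == simulate_reference(cfg).contigs

    def test_base_composition_near_uniform(self):
        ref = simulate_reference(SimulationConfig(seed=2))
        seq = ref.contigs["chr1"]
        n = len(seq)
        # 3 sigma binomial bound around 25% per base
        sigma = np.sqrt(n * 0.25 * 0.75)
        for base in "ACGT":
            assert abs(seq.count(base) - 0.25 * n) < 3.5 * sigma

    def test_zero_contigs_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(contigs={}, contig_class={})


class TestGermline:
    def test_snp_count_within_poisson_bound(self):
        """SNP rate 1e-3 on 100 kb places ~100 SNPs (within 4*sqrt(lambda))."""
        cfg = _small_cfg(ins_rate=0.0, del_rate=0.0, sub_rate=0.0)
        ref = simulate_reference(cfg)
        template = simulate_individual(ref, cfg)
        lam = 1e-3 * 100_000
        assert abs(len(template.calls) - lam) < 4 * np.sqrt(lam)

    def test_zero_rates_give_variant_free_individual(self):
        cfg = _small_cfg(snp_rate=0.0, ins_rate=0.0, del_rate=0.0, sub_rate=0.0)
        ref = simulate_reference(cfg)
        assert simulate_individual(ref, cfg).calls == []

    def test_het_hom_ratio_matches_het_fraction(self, bundle_noreads):
        """Het fraction 0.61 gives a het/hom SNP ratio near 0.61/0.39."""
        b = bundle_noreads
        snps = [c for c in b.genomic.calls if c.vartype == "snp" and c.is_fully_called()]
        het = sum(1 for c in snps if c.allele1 != c.allele2)
        hom = len(snps) - het
        assert het / hom == pytest.approx(0.61 / 0.39, abs=0.25)

    def test_overlap_free_placement(self, bundle_noreads):
        for cs in (bundle_noreads.genomic, bundle_noreads.cellline):
            prev_end = {}
            for c in cs.calls:
                assert c.begin >= prev_end.get(c.contig, 0) or c.begin == c.end
                prev_end[c.contig] = max(prev_end.get(c.contig, 0), c.end)


class TestTwinDerivation:
    def test_noise_counts_within_poisson_bound(self, default_cfg, bundle_noreads):
        """~1 error per 150 kb: expected FP count on the non-viral genome."""
        lam = default_cfg.technical_error_rate * default_cfg.nonviral_length()
        for sample in ("genomic", "cellline"):
            n = len(bundle_noreads.truth.noise_keys[sample])
            assert abs(n - lam) <= 4 * np.sqrt(lam) + 1

    def test_noiseless_twins_are_identical(self):
        cfg = _small_cfg(
            technical_error_rate=0.0, fn_rate=0.0, half_call_rate=0.0
        )
        ref = simulate_reference(cfg)
        template = simulate_individual(ref, cfg)
        genomic, cellline, truth = derive_twin_callsets(template, ref, cfg)
        assert [c for c in genomic.calls] == [c for c in cellline.calls]
        assert truth.difference_keys() == set()

    def test_noise_quality_stochastically_lower(self, bundle_noreads):
        b = bundle_noreads
        noise = set(b.truth.noise_keys["cellline"])
        qn = [
            c.var_quality
            for c in b.cellline.calls
            if c.vartype not in ("ref", "no-call") and set(c.key(b.ref)) & noise
        ]
        qt = [
            c.var_quality
            for c in b.cellline.calls
            if c.vartype == "snp" and not (set(c.key(b.ref)) & noise)
        ]
        assert np.median(qn) < np.median(qt)

    def test_every_difference_is_labelled(self, bundle_noreads):
        """calldiff on the twin call sets finds no unlabelled difference."""
        b = bundle_noreads
        diff_keys = b.truth.difference_keys()
        records = calldiff.compare_callsets(b.genomic, b.cellline, b.ref)
        for r in records:
            if r.verdict in ("onlyA", "onlyB", "mismatch", "phase-mismatch"):
                sl = r.superlocus
                keys = {
                    k
                    for c in sl.calls_a + sl.calls_b
                    if c.vartype not in ("ref", "no-call")
                    for k in c.key(b.ref)
                }
                assert keys & diff_keys, (r.verdict, sl)

    def test_somatic_snps_absent_from_known_set(self, bundle_noreads):
        b = bundle_noreads
        assert not set(b.truth.somatic_keys) & b.known.keys

    def test_mito_amplification_in_coverage(self, bundle_noreads):
        b = bundle_noreads
        for sample, expected in (("genomic", 1.0), ("cellline", 9.0)):
            cov = b.coverage[sample]
            chrm = cov[cov["contig"] == "chrM"]["relativeCoverage"].mean()
            assert chrm == pytest.approx(expected, rel=0.05)
        segs = [s for s in b.segments["cellline"] if s.contig == "chrM"]
        assert len(segs) == 1 and segs[0].ploidy == 18

    def test_excess_somatic_count_rejected(self):
        cfg = _small_cfg(somatic_snp_count=50_000)
        ref = simulate_reference(cfg)
        template = simulate_individual(ref, cfg)
        with pytest.raises(ConfigError):
            derive_twin_callsets(template, ref, cfg)


class TestReads:
    def test_viral_depth_matches_copies(self, default_cfg, bundle):
        """copies=2 at 40X autosomal depth gives ~80X viral depth."""
        viral_len = default_cfg.contigs["EBV"]
        viral_bases = sum(
            len(r.seq) for r in bundle.reads["cellline"] if "viral" in r.id
        )
        assert viral_bases / viral_len == pytest.approx(80.0, rel=0.1)

    def test_genomic_sample_has_no_viral_reads(self, bundle):
        assert all("viral" not in r.id for r in bundle.reads["genomic"])

    def test_read_length_exceeding_viral_genome_rejected(self):
        cfg = _small_cfg(read_length=90_000)
        ref = simulate_reference(cfg)
        with pytest.raises(ConfigError):
            simulate_unmapped_reads(ref, cfg, "cellline")


class TestDeterminism:
    def test_same_seed_byte_identical_bundle(self, tmp_path):
        import filecmp
        import os

        cfg = _small_cfg(somatic_snp_count=20)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_bundle(simulate_bundle(cfg), str(d1))
        write_bundle(simulate_bundle(cfg), str(d2))
        names = os.listdir(d1)
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert not mismatch and not errors
        assert len(match) == len(names)

    def test_different_seeds_differ(self):
        a = simulate_bundle(_small_cfg(seed=5), with_reads=False)
        b = simulate_bundle(_small_cfg(seed=6), with_reads=False)
        assert a.ref.contigs != b.ref.contigs
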