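"""End-to-end orchestration of the twin-genome comparison, plus the
regional-distribution and validation-bound statistics.

``run_pipeline`` executes, on a simulated twin bundle: variant diff
(SuperlocusStats), reciprocal somatic analyses (CT: cell line as tumor, GT:
genomic DNA as tumor) with calibrated SomaticScores and novelty annotation,
CNV diffing, junction diffing with the panel-frequency filter, the QC
metrics report, viral screening, and the regional distribution of filtered
candidates — and returns one JSON-serialisable report. The SomaticScore
calibration is built from an independent simulation (a fixed substream of
the pipeline seed), never from the data being scored.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import calldiff, metrics, structural, viral
from .core import ConfigError, DataError, ReferenceGenome
from .simulate import SimulationConfig, simulate_bundle, write_bundle

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    merge_gap: int = calldiff.DEFAULT_MERGE_GAP
    somatic_score_cutoff: float = 0.5
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS
    cnv_params: structural.CnvMatchParams = field(
        default_factory=structural.CnvMatchParams
    )
    junction_params: structural.JunctionDiffParams = field(
        default_factory=structural.JunctionDiffParams
    )
    regional_bin_size: int = 200_000
    telomere_fraction: float = 0.05
    kmer_size: int = 31
    # external Sanger-style validation results, if any: (n_tested, n_confirmed)
    validation: Optional[tuple[int, int]] = None
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)


@dataclass
class ValidationOutcome:
    n_tested: int
    n_confirmed: int
    ci_method: str
    upper_bound: float


def validation_bound(
    n_tested: int,
    n_confirmed: int,
    method: str = "clopper-pearson",
    level: float = 0.95,
) -> ValidationOutcome:
    """Upper confidence bound for the true-difference fraction after a
    validation experiment confirming ``n_confirmed`` of ``n_tested``
    candidates.

    Methods: ``clopper-pearson`` (exact two-sided; for zero confirmations the
    upper bound is 1 - (alpha/2)^(1/n)), ``clopper-pearson-one-sided``
    (1 - alpha^(1/n) at zero confirmations), and ``wilson`` (score interval).
    """
    if n_tested <= 0:
        raise DataError("n_tested must be positive")
    if not (0 <= n_confirmed <= n_tested):
        raise DataError("n_confirmed must lie in [0, n_tested]")
    alpha = 1.0 - level
    k, n = n_confirmed, n_tested
    if method == "clopper-pearson":
        upper = 1.0 if k == n else float(sstats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    elif method == "clopper-pearson-one-sided":
        upper = 1.0 if k == n else float(sstats.beta.ppf(1 - alpha, k + 1, n - k))
    elif method == "wilson":
        if k == n:
            return ValidationOutcome(n, k, method, 1.0)
        p = k / n
        z = float(sstats.norm.ppf(1 - alpha / 2))
        denom = 1 + z * z / n
        centre = p + z * z / (2 * n)
        half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
        upper = float(min(1.0, (centre + half) / denom))
    else:
        raise ConfigError(f"unknown method {method!r}")
    return ValidationOutcome(
        n_tested=n, n_confirmed=k, ci_method=method, upper_bound=upper
    )


@dataclass
class RegionalDistribution:
    table: pd.DataFrame  # contig, bin_begin, bin_end, count, near_contig_end
    chi2: Optional[float]
    p_value: Optional[float]


def regional_distribution(
    positions: Sequence[tuple[str, int]],
    contig_lengths: dict[str, int],
    bin_size: int = 200_000,
    telomere_fraction: float = 0.05,
) -> RegionalDistribution:
    """Bin candidate positions across the genome and test uniformity.

    Each bin is flagged when it lies within ``telomere_fraction`` of its
    contig's length from either contig end (a telomere/centromere surrogate
    for synthetic contigs). The chi-square statistic compares observed bin
    counts with expectations proportional to bin length.
    """
    if bin_size <= 0:
        raise ConfigError("bin_size must be positive")
    rows = []
    for contig, length in contig_lengths.items():
        n_bins = max(1, -(-length // bin_size))
        for i in range(n_bins):
            b = i * bin_size
            e = min(length, (i + 1) * bin_size)
            near_end = b < telomere_fraction * length or e > (1 - telomere_fraction) * length
            rows.append([contig, b, e, 0, near_end])
    index = {
        (r[0], r[1] // bin_size): i for i, r in enumerate(rows)
    }
    for contig, pos in positions:
        if contig not in contig_lengths:
            raise DataError(f"position on unknown contig {contig!r}")
        rows[index[(contig, pos // bin_size)]][3] += 1
    table = pd.DataFrame(
        rows, columns=["contig", "bin_begin", "bin_end", "count", "near_contig_end"]
    )
    total = int(table["count"].sum())
    if total == 0:
        return RegionalDistribution(table=table, chi2=None, p_value=None)
    lengths = (table["bin_end"] - table["bin_begin"]).to_numpy(dtype=float)
    expected = total * lengths / lengths.sum()
    chi2, p = sstats.chisquare(table["count"].to_numpy(dtype=float), expected)
    return RegionalDistribution(table=table, chi2=float(chi2), p_value=float(p))


# ---------------------------------------------------------------------------
# the pipeline


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def build_calibration(
    cfg: PipelineConfig, n_somatic: int = 2_000
) -> calldiff.Calibration:
    """Calibrate the SomaticScore on an independent labelled simulation."""
    sim = dataclasses.replace(
        cfg.simulation,
        seed=(cfg.seed * 7919 + 101) % (2**31),
        somatic_snp_count=n_somatic,
    )
    bundle = simulate_bundle(sim, with_reads=False)
    candidates = calldiff.somatic_output(
        bundle.genomic,
        bundle.cellline,
        bundle.ref,
        merge_gap=cfg.merge_gap,
        normal_ref_quality=sim.normal_ref_quality,
    )
    return calldiff.Calibration.from_labelled(
        candidates, set(bundle.truth.somatic_keys), bundle.ref
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full twin-comparison pipeline on a simulated bundle.

    Returns the report dict; when ``cfg.outdir`` is set, also writes the
    simulated inputs, per-stage outputs, ``report.json`` and ``report.md``.
    """
    report: dict = {"seed": cfg.seed}

    bundle = _stage("simulate")(simulate_bundle)(cfg.simulation)
    ref = bundle.ref
    if cfg.outdir:
        write_bundle(bundle, os.path.join(cfg.outdir, "inputs"))

    calibration = _stage("calibrate")(build_calibration)(cfg)

    @_stage("diff")
    def do_diff():
        records = calldiff.compare_callsets(
            bundle.genomic, bundle.cellline, ref, merge_gap=cfg.merge_gap
        )
        return calldiff.superlocus_stats(records)

    report["superlocus_stats"] = do_diff()
    logger.info("verdict counts: %s", report["superlocus_stats"]["counts"])

    @_stage("somatic")
    def do_somatic():
        sweep = calldiff.ct_gt_sweep(
            bundle.genomic,
            bundle.cellline,
            ref,
            calibration,
            cutoffs=list(cfg.cutoffs),
            merge_gap=cfg.merge_gap,
        )
        for direction in ("ct_candidates", "gt_candidates"):
            calldiff.annotate_novelty(sweep[direction], bundle.known, ref)
        x = cfg.somatic_score_cutoff
        survivors = [
            c
            for c in sweep["ct_candidates"]
            if c.fully_called and c.somatic_score >= x
        ]
        gt_survivors = [
            c
            for c in sweep["gt_candidates"]
            if c.fully_called and c.somatic_score >= x
        ]
        return sweep, survivors, gt_survivors

    sweep, ct_survivors, gt_survivors = do_somatic()
    report["somatic"] = {
        "sweep": sweep["sweep"],
        "cutoff": cfg.somatic_score_cutoff,
        "ct_at_cutoff": len(ct_survivors),
        "gt_at_cutoff": len(gt_survivors),
        "ct_snp_at_cutoff": sum(
            1 for c in ct_survivors if c.variant.vartype == "snp"
        ),
        "gt_snp_at_cutoff": sum(
            1 for c in gt_survivors if c.variant.vartype == "snp"
        ),
        "ct_novel_fraction": (
            sum(1 for c in ct_survivors if c.novel) / len(ct_survivors)
            if ct_survivors
            else None
        ),
        "ct_novel_by_class": calldiff.novel_fraction_by_class(ct_survivors),
    }

    @_stage("cnvdiff")
    def do_cnv():
        out = {}
        for refs, others, label in (
            ("cellline", "genomic", "cellline_as_reference"),
            ("genomic", "cellline", "genomic_as_reference"),
        ):
            diffs = structural.cnv_diff(
                bundle.segments[refs], bundle.segments[others], cfg.cnv_params
            )
            out[label] = [
                {
                    "contig": d.ref_segment.contig,
                    "begin": d.ref_segment.begin,
                    "end": d.ref_segment.end,
                    "ploidy": d.ref_segment.ploidy,
                    "kind": d.kind,
                    "other_ploidy": (
                        d.other_segment.ploidy if d.other_segment else None
                    ),
                }
                for d in diffs
            ]
        return out

    report["cnv_differences"] = do_cnv()

    @_stage("junctiondiff")
    def do_junctions():
        params = cfg.junction_params
        fg = structural.filter_junctions_by_panel(
            bundle.junctions["genomic"], params.panel_frequency_cutoff
        )
        fc = structural.filter_junctions_by_panel(
            bundle.junctions["cellline"], params.panel_frequency_cutoff
        )
        unique_c = structural.junction_diff(fc, fg, params)
        unique_g = structural.junction_diff(fg, fc, params)
        nonviral_lengths = {
            c: l
            for c, l in cfg.simulation.contigs.items()
            if cfg.simulation.contig_class[c] != "viral"
        }
        return {
            "unique_to_cellline": [dataclasses.asdict(j) for j in unique_c],
            "unique_to_genomic": [dataclasses.asdict(j) for j in unique_g],
            "bins_cellline": {
                c: v.tolist()
                for c, v in structural.bin_junctions(fc, nonviral_lengths)[
                    "bins"
                ].items()
            },
        }

    report["junctions"] = do_junctions()

    @_stage("metrics")
    def do_metrics():
        reports = [
            metrics.build_metrics_report(cs, bundle.genes, ref, bundle.known)
            for cs in (bundle.genomic, bundle.cellline)
        ]
        table = metrics.report_table(reports)
        if cfg.outdir:
            os.makedirs(cfg.outdir, exist_ok=True)
            table.to_csv(os.path.join(cfg.outdir, "metrics.tsv"), sep="\t")
        overlap = metrics.gene_overlap_report(
            _gene_classes(bundle.genomic, bundle.genes, ref),
            _gene_classes(bundle.cellline, bundle.genes, ref),
        )
        return {
            "table": {
                sample: {
                    row: (None if pd.isna(v) else v)
                    for row, v in table[sample].items()
                }
                for sample in table.columns
            },
            "gene_overlap": overlap,
        }

    report["metrics"] = do_metrics()

    @_stage("viral")
    def do_viral():
        viral_contig = cfg.simulation.viral_contig
        idx = viral.build_index(ref.contigs[viral_contig], k=cfg.kmer_size)
        out = {}
        for sample in ("genomic", "cellline"):
            res = viral.screen_reads(bundle.reads[sample], idx)
            out[sample] = {
                "viral_reads": res.viral_reads,
                "total_reads": res.total_reads,
                "viral_depth": res.viral_depth,
                "copies": viral.copy_number(
                    res.viral_depth, cfg.simulation.autosomal_depth
                ),
            }
        # screen long insertions and junction transition sequences for viral
        # content among cell-line-unique calls
        seqs = [
            c.variant.allele1 or c.variant.allele2 or ""
            for c in ct_survivors
            if c.variant.vartype in ("ins", "sub")
        ]
        seqs += [
            j["transition_seq"]
            for j in report["junctions"]["unique_to_cellline"]
            if j["transition_seq"]
        ]
        hits = viral.screen_sequences(seqs, idx)
        out["nonreference_sequences"] = {
            "screened": len(hits),
            "viral_hits": sum(1 for h in hits if h.hit),
        }
        return out

    report["viral"] = do_viral()

    @_stage("regional")
    def do_regional():
        # uniformity is judged over diploid territory: the sex chromosome
        # carries no diploid calls in this model and would bias the test
        nonviral_lengths = {
            c: l
            for c, l in cfg.simulation.contigs.items()
            if cfg.simulation.contig_class[c] not in ("viral", "sexchrom")
        }
        rd = regional_distribution(
            [(c.variant.contig, c.variant.begin) for c in ct_survivors],
            nonviral_lengths,
            bin_size=cfg.regional_bin_size,
            telomere_fraction=cfg.telomere_fraction,
        )
        return {
            "chi2": rd.chi2,
            "p_value": rd.p_value,
            "n_bins": len(rd.table),
            "near_end_count": int(
                rd.table.loc[rd.table["near_contig_end"], "count"].sum()
            ),
        }

    report["regional_distribution"] = do_regional()

    if cfg.validation is not None:
        n_tested, n_confirmed = cfg.validation
        report["validation"] = {
            m: dataclasses.asdict(validation_bound(n_tested, n_confirmed, m))
            for m in ("clopper-pearson", "clopper-pearson-one-sided", "wilson")
        }

    if cfg.outdir:
        os.makedirs(cfg.outdir, exist_ok=True)
        with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        with open(os.path.join(cfg.outdir, "report.md"), "w") as fh:
            fh.write(render_markdown(report))
    return report


def _gene_classes(cs, genes, ref):
    out = []
    for c in cs.variant_calls(ref):
        cls, gene_id = metrics.classify_against_genes(c, genes, ref)
        if gene_id is not None:
            out.append((gene_id, cls, c.begin))
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def render_markdown(report: dict) -> str:
    """Human-readable summary of a pipeline report."""
    lines = ["# Twin-genome comparison report", ""]
    sls = report["superlocus_stats"]
    lines.append("## Variant concordance (superloci)")
    for verdict, n in sls["counts"].items():
        lines.append(f"- {verdict}: {n}")
    frac = sls["identical_fraction"]
    lines.append(
        f"- identical fraction: {frac:.4f}" if frac is not None else
        "- identical fraction: n/a"
    )
    lines.append("")
    som = report["somatic"]
    lines.append("## Somatic analysis (CT = cell line as tumor, GT = genomic as tumor)")
    lines.append("| cutoff | CT | GT | CT/GT |")
    lines.append("|---|---|---|---|")
    for row in som["sweep"]:
        ratio = "inf" if row["ct_gt_ratio"] is None else f"{row['ct_gt_ratio']:.2f}"
        lines.append(f"| {row['cutoff']:.1f} | {row['ct']} | {row['gt']} | {ratio} |")
    lines.append("")
    lines.append(
        f"At cutoff {som['cutoff']}: CT={som['ct_at_cutoff']} "
        f"(SNPs: {som['ct_snp_at_cutoff']}), GT={som['gt_at_cutoff']} "
        f"(SNPs: {som['gt_snp_at_cutoff']}); "
        f"novel fraction among CT survivors: {som['ct_novel_fraction']}"
    )
    lines.append("")
    lines.append("## CNV differences")
    for label, diffs in report["cnv_differences"].items():
        lines.append(f"- {label}: {len(diffs)} difference(s)")
        for d in diffs:
            lines.append(
                f"    - {d['contig']}:{d['begin']}-{d['end']} ploidy {d['ploidy']} "
                f"({d['kind']}, other ploidy {d['other_ploidy']})"
            )
    lines.append("")
    lines.append("## Junctions")
    jx = report["junctions"]
    lines.append(f"- unique to cell line: {len(jx['unique_to_cellline'])}")
    lines.append(f"- unique to genomic: {len(jx['unique_to_genomic'])}")
    lines.append("")
    lines.append("## Viral screen")
    for sample in ("genomic", "cellline"):
        v = report["viral"][sample]
        lines.append(
            f"- {sample}: {v['viral_reads']}/{v['total_reads']} viral reads, "
            f"depth {v['viral_depth']:.1f}, copies {v['copies']:.2f}"
        )
    nr = report["viral"]["nonreference_sequences"]
    lines.append(
        f"- non-reference sequences screened: {nr['screened']}, "
        f"viral hits: {nr['viral_hits']}"
    )
    lines.append("")
    rd = report["regional_distribution"]
    lines.append("## Regional distribution of CT survivors")
    p = rd["p_value"]
    lines.append(
        f"- chi-square uniformity p = {p:.3f}" if p is not None else
        "- chi-square uniformity p = n/a (no candidates)"
    )
    if "validation" in report:
        lines.append("")
        lines.append("## Validation bound")
        for method, v in report["validation"].items():
            lines.append(
                f"- {method}: upper bound {v['upper_bound']:.4f} "
                f"({v['n_confirmed']}/{v['n_tested']} confirmed)"
            )
    lines.append("")
    return "\n".join(lines)
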