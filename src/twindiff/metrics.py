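"""Functional variant classification and sequencing QC metrics.

Variants are classified against one canonical coding transcript per gene:

* SNPs inside a CDS are translated on the coding strand with the standard
  codon table — ``synonymous``, ``missense`` (amino acid change),
  ``nonsense`` (stop gained), or ``nonstop`` (stop lost).
* Length-changing variants touching a CDS are ``frame-shifting`` when the
  net length change is not a multiple of 3, else ``frame-preserving``.
  Equal-length block substitutions fully inside a CDS are additionally
  resolved by translation, but counted in the frame-preserving rows of the
  metrics report.
* Variants outside every CDS are ``noncoding``.

The metrics report mirrors the usual whole-genome QC table: per-type counts,
het/hom ratios, ts/tv, novel rates, called-fraction triple, per-class coding
locus counts, and the derived ratios, each recomputable from the report's
own counts. The "nonsyn/syn SNP ratio" is implemented as missense /
synonymous (despite the name, the conventional quotient excludes nonsense
and nonstop loci).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from Bio.Seq import Seq

from .core import (
    CallSet,
    DataError,
    GeneModel,
    KnownVariantSet,
    ReferenceGenome,
    VariantCall,
)

FUNCTIONAL_CLASSES = (
    "synonymous",
    "missense",
    "nonsense",
    "nonstop",
    "frame-shifting",
    "frame-preserving",
    "noncoding",
)

_SNP_SEVERITY = ("nonsense", "nonstop", "missense", "synonymous")

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ---------------------------------------------------------------------------
# classification


def _translate(seq: str) -> str:
    return str(Seq(seq[: len(seq) - len(seq) % 3]).translate())


def _protein_effect(ref_protein: str, alt_protein: str) -> str:
    if alt_protein == ref_protein:
        return "synonymous"
    ref_stop = ref_protein.find("*")
    alt_stop = alt_protein.find("*")
    ref_stop = len(ref_protein) if ref_stop < 0 else ref_stop
    alt_stop = len(alt_protein) if alt_stop < 0 else alt_stop
    if alt_stop < ref_stop:
        return "nonsense"
    if alt_stop > ref_stop:
        return "nonstop"
    return "missense"


def _overlaps_cds(v: VariantCall, gm: GeneModel) -> bool:
    for b, e in gm.cds_intervals:
        if v.begin < e and v.end > b:
            return True
        if v.vartype == "ins" and b <= v.begin <= e:
            # an insertion at a CDS boundary lands inside the transcript
            if b < v.begin < e:
                return True
    return False


def _cds_with_replacement(
    gm: GeneModel, ref: ReferenceGenome, v: VariantCall, allele: str
) -> Optional[str]:
    """Rebuild the coding sequence with the variant applied, or None when the
    variant pokes outside the CDS intervals (boundary-spanning)."""
    intervals = sorted(gm.cds_intervals)
    covering = [
        (b, e) for b, e in intervals if b <= v.begin and v.end <= e
    ]
    if not covering:
        return None
    b, e = covering[0]
    parts = []
    for ib, ie in intervals:
        seg = ref.fetch(gm.contig, ib, ie)
        if (ib, ie) == (b, e):
            seg = (
                ref.fetch(gm.contig, ib, v.begin)
                + allele
                + ref.fetch(gm.contig, v.end, ie)
            )
        parts.append(seg)
    seq = "".join(parts)
    if gm.strand == "-":
        from .core import revcomp

        seq = revcomp(seq)
    return seq[gm.phase :]


def classify_variant(
    v: VariantCall, gm: GeneModel, ref: ReferenceGenome
) -> str:
    """Functional class of a variant against one gene model.

    For het calls whose two non-reference alleles classify differently, the
    most severe class is returned (nonsense > nonstop > missense >
    synonymous for SNPs; frame-shifting > frame-preserving for indels).
    """
    if v.contig != gm.contig:
        raise DataError("variant and gene model are on different contigs")
    alts = v.alt_alleles(ref)
    if not alts or not _overlaps_cds(v, gm):
        return "noncoding"
    span_len = v.end - v.begin

    if v.vartype == "snp":
        classes = set()
        ref_cds = gm.coding_sequence(ref)
        ref_protein = _translate(ref_cds)
        for allele in set(alts):
            alt_cds = _cds_with_replacement(gm, ref, v, allele)
            if alt_cds is None:
                return "noncoding"
            classes.add(_protein_effect(ref_protein, _translate(alt_cds)))
        for cls in _SNP_SEVERITY:
            if cls in classes:
                return cls
        return "synonymous"

    # length effects for ins/del/sub
    net_changes = [len(a) - span_len for a in alts]
    if any(n % 3 != 0 for n in net_changes):
        return "frame-shifting"
    if v.vartype == "sub" and all(len(a) == span_len for a in alts):
        ref_cds = gm.coding_sequence(ref)
        classes = set()
        for allele in set(alts):
            alt_cds = _cds_with_replacement(gm, ref, v, allele)
            if alt_cds is None:
                return "frame-preserving"  # boundary-spanning, length neutral
            classes.add(_protein_effect(_translate(ref_cds), _translate(alt_cds)))
        for cls in _SNP_SEVERITY:
            if cls in classes:
                return cls
        return "synonymous"
    return "frame-preserving"


def classify_against_genes(
    v: VariantCall, genes: Sequence[GeneModel], ref: ReferenceGenome
) -> tuple[str, Optional[str]]:
    """Classify against the first gene whose CDS the variant touches.

    Returns ``(functional_class, gene_id)``; ``("noncoding", None)`` when no
    gene is hit.
    """
    for gm in genes:
        if gm.contig != v.contig:
            continue
        cls = classify_variant(v, gm, ref)
        if cls != "noncoding":
            return cls, gm.gene_id
    return "noncoding", None


# ---------------------------------------------------------------------------
# simple QC statistics


def tstv_ratio(pairs: Iterable[tuple[str, str]]) -> Optional[float]:
    """Transitions / transversions over (ref_base, alt_base) pairs.

    ``None`` (with no crash) when there are no transversions.
    """
    ts = tv = 0
    for r, a in pairs:
        if r == a:
            continue
        if (r, a) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ts / tv


def snp_ref_alt_pairs(
    calls: Iterable[VariantCall], ref: ReferenceGenome
) -> list[tuple[str, str]]:
    pairs = []
    for c in calls:
        if c.vartype != "snp":
            continue
        r = ref.fetch(c.contig, c.begin, c.end)
        for a in c.alt_alleles(ref):
            pairs.append((r, a))
            break  # one pair per locus
    return pairs


def het_hom_ratio(
    calls: Iterable[VariantCall], vartype: str, ref: ReferenceGenome
) -> Optional[float]:
    """Het/hom ratio among fully-called variants of one type."""
    het = hom = 0
    for c in calls:
        if c.vartype != vartype or not c.is_fully_called() or not c.is_variant(ref):
            continue
        if c.allele1 != c.allele2:
            het += 1
        else:
            hom += 1
    if hom == 0:
        return None
    return het / hom


def novel_rate(
    calls: Iterable[VariantCall],
    known: KnownVariantSet,
    ref: ReferenceGenome,
    vartype: Optional[str] = None,
) -> Optional[float]:
    """Fraction of variants absent from the known-variant catalogue."""
    total = novel = 0
    for c in calls:
        if vartype is not None and c.vartype != vartype:
            continue
        if not c.is_variant(ref):
            continue
        total += 1
        if not known.contains_call(c, ref):
            novel += 1
    if total == 0:
        return None
    return novel / total


# ---------------------------------------------------------------------------
# the metrics report


@dataclass
class MetricsReport:
    """Table-1-style QC summary for one sample."""

    sample_id: str
    total_counts: dict[str, int] = field(default_factory=dict)
    het_hom_ratios: dict[str, Optional[float]] = field(default_factory=dict)
    tstv: Optional[float] = None
    novel_rates: dict[str, Optional[float]] = field(default_factory=dict)
    fully_called_fraction: float = 1.0
    partially_called_fraction: float = 0.0
    nocalled_fraction: float = 0.0
    class_counts: dict[str, int] = field(default_factory=dict)
    frameshift_preserve_ratio: Optional[float] = None
    nonsyn_syn_ratio: Optional[float] = None
    ins_del_ratio: Optional[float] = None
    indel_snp_ratio: Optional[float] = None
    coding_indel_ratio: Optional[float] = None
    coding_snp_fraction: Optional[float] = None
    coding_indel_fraction: Optional[float] = None

    def validate(self) -> None:
        total = (
            self.fully_called_fraction
            + self.partially_called_fraction
            + self.nocalled_fraction
        )
        if abs(total - 1.0) > 1e-9:
            raise DataError("called fractions must sum to 1")


_CLASS_KEYS = (
    "synonymous_snp",
    "missense_snp",
    "nonsense_snp",
    "nonstop_snp",
    "frameshift_ins",
    "frameshift_del",
    "frameshift_sub",
    "preserve_ins",
    "preserve_del",
    "preserve_sub",
)


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den else None


def derived_ratios(report: MetricsReport) -> MetricsReport:
    """Fill in every derived ratio from the report's own counts."""
    cc = {k: report.class_counts.get(k, 0) for k in _CLASS_KEYS}
    tc = report.total_counts
    fs = cc["frameshift_ins"] + cc["frameshift_del"] + cc["frameshift_sub"]
    fp = cc["preserve_ins"] + cc["preserve_del"] + cc["preserve_sub"]
    report.frameshift_preserve_ratio = _ratio(fs, fp)
    report.nonsyn_syn_ratio = _ratio(cc["missense_snp"], cc["synonymous_snp"])
    report.ins_del_ratio = _ratio(tc.get("ins", 0), tc.get("del", 0))
    report.indel_snp_ratio = _ratio(
        tc.get("ins", 0) + tc.get("del", 0), tc.get("snp", 0)
    )
    coding_ins = cc["frameshift_ins"] + cc["preserve_ins"]
    coding_del = cc["frameshift_del"] + cc["preserve_del"]
    coding_snp = (
        cc["synonymous_snp"] + cc["missense_snp"] + cc["nonsense_snp"] + cc["nonstop_snp"]
    )
    report.coding_indel_ratio = _ratio(coding_ins, coding_del)
    report.coding_snp_fraction = _ratio(coding_snp, tc.get("snp", 0))
    report.coding_indel_fraction = _ratio(
        coding_ins + coding_del, tc.get("ins", 0) + tc.get("del", 0)
    )
    return report


def build_metrics_report(
    cs: CallSet,
    genes: Sequence[GeneModel],
    ref: ReferenceGenome,
    known: KnownVariantSet,
) -> MetricsReport:
    """Compute the full QC report for one call set."""
    variants = cs.variant_calls(ref)
    report = MetricsReport(
        sample_id=cs.sample_id,
        fully_called_fraction=cs.fully_called_fraction,
        partially_called_fraction=cs.partially_called_fraction,
        nocalled_fraction=cs.nocalled_fraction,
    )
    for vt in ("snp", "ins", "del", "sub"):
        group = [c for c in variants if c.vartype == vt]
        report.total_counts[vt] = len(group)
        report.het_hom_ratios[vt] = het_hom_ratio(group, vt, ref)
        report.novel_rates[vt] = novel_rate(group, known, ref, vt)
    report.tstv = tstv_ratio(snp_ref_alt_pairs(variants, ref))

    counts = {k: 0 for k in _CLASS_KEYS}
    for c in variants:
        cls, _ = classify_against_genes(c, genes, ref)
        if cls == "noncoding":
            continue
        if c.vartype == "snp":
            counts[f"{cls}_snp"] += 1
        else:
            in_frame = cls in ("frame-preserving", *_SNP_SEVERITY)
            prefix = "preserve" if in_frame else "frameshift"
            counts[f"{prefix}_{c.vartype}"] += 1
    report.class_counts = counts
    return derived_ratios(report)


TABLE_ROWS = [
    ("SNP Transitions/transversions", lambda r: r.tstv),
    ("SNP het/hom ratio", lambda r: r.het_hom_ratios.get("snp")),
    ("INS het/hom ratio", lambda r: r.het_hom_ratios.get("ins")),
    ("DEL het/hom ratio", lambda r: r.het_hom_ratios.get("del")),
    ("SUB het/hom ratio", lambda r: r.het_hom_ratios.get("sub")),
    ("SNP total count", lambda r: r.total_counts.get("snp")),
    ("INS total count", lambda r: r.total_counts.get("ins")),
    ("DEL total count", lambda r: r.total_counts.get("del")),
    ("SUB total count", lambda r: r.total_counts.get("sub")),
    ("SNP novel rate", lambda r: r.novel_rates.get("snp")),
    ("INS novel rate", lambda r: r.novel_rates.get("ins")),
    ("DEL novel rate", lambda r: r.novel_rates.get("del")),
    ("SUB novel rate", lambda r: r.novel_rates.get("sub")),
    ("Fully called genome fraction", lambda r: r.fully_called_fraction),
    ("Partially called genome fraction", lambda r: r.partially_called_fraction),
    ("No-called genome fraction", lambda r: r.nocalled_fraction),
    ("Synonymous SNP loci", lambda r: r.class_counts.get("synonymous_snp")),
    ("Missense SNP loci", lambda r: r.class_counts.get("missense_snp")),
    ("Nonsense SNP loci", lambda r: r.class_counts.get("nonsense_snp")),
    ("Nonstop SNP loci", lambda r: r.class_counts.get("nonstop_snp")),
    ("Frame-shifting INS loci", lambda r: r.class_counts.get("frameshift_ins")),
    ("Frame-shifting DEL loci", lambda r: r.class_counts.get("frameshift_del")),
    ("Frame-shifting SUB loci", lambda r: r.class_counts.get("frameshift_sub")),
    ("Frame-preserving INS loci", lambda r: r.class_counts.get("preserve_ins")),
    ("Frame-preserving DEL loci", lambda r: r.class_counts.get("preserve_del")),
    ("Frame-preserving SUB loci", lambda r: r.class_counts.get("preserve_sub")),
    ("Frame-shifting/preserving ratio", lambda r: r.frameshift_preserve_ratio),
    ("Nonsyn/syn SNP ratio", lambda r: r.nonsyn_syn_ratio),
    ("Insertion/deletions ratio", lambda r: r.ins_del_ratio),
    ("Ins + del/SNP ratio", lambda r: r.indel_snp_ratio),
    ("Coding insertion/deletions ratio", lambda r: r.coding_indel_ratio),
    ("Coding SNP/all SNP ratio", lambda r: r.coding_snp_fraction),
    ("Coding (ins + del)/all (ins + del) ratio", lambda r: r.coding_indel_fraction),
]


def report_table(reports: Sequence[MetricsReport]):
    """Two-column (or n-column) QC table as a pandas DataFrame."""
    import pandas as pd

    data = {r.sample_id: [fn(r) for _, fn in TABLE_ROWS] for r in reports}
    return pd.DataFrame(data, index=[name for name, _ in TABLE_ROWS])


# ---------------------------------------------------------------------------
# coverage summary


@dataclass
class CoverageSummary:
    histogram: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.histogram.values())

    def fraction_at_least(self, depth: int) -> float:
        if self.total == 0:
            raise DataError("empty coverage track")
        covered = sum(n for d, n in self.histogram.items() if d >= depth)
        return covered / self.total


def coverage_summary(
    track: Union[Mapping[int, int], Sequence[int], np.ndarray],
) -> CoverageSummary:
    """Depth histogram from per-base/per-window depths (array or mapping
    depth -> base count)."""
    if isinstance(track, Mapping):
        hist = {int(d): int(n) for d, n in track.items()}
    else:
        arr = np.asarray(track)
        if arr.size == 0:
            return CoverageSummary(histogram={})
        values, counts = np.unique(arr.astype(int), return_counts=True)
        hist = dict(zip(values.tolist(), counts.tolist()))
    if any(d < 0 for d in hist):
        raise DataError("depths must be non-negative")
    return CoverageSummary(histogram=hist)


# ---------------------------------------------------------------------------
# per-gene overlap of non-synonymous variant classes


NONSYN_CLASSES = ("missense", "nonsense", "nonstop", "frameshift")


def _canonical_class(cls: str) -> Optional[str]:
    if cls in ("missense", "nonsense", "nonstop"):
        return cls
    if cls == "frame-shifting":
        return "frameshift"
    return None


def gene_overlap_report(
    classes_a: Iterable[tuple[str, str, int]],
    classes_b: Iterable[tuple[str, str, int]],
) -> dict:
    """Per-class shared/unique affected genes for two samples.

    Inputs are iterables of ``(gene_id, functional_class, position)``; only
    the non-synonymous classes (missense, nonsense, nonstop, frameshift)
    participate. Shared genes whose variant positions differ between the two
    samples are flagged for manual review.
    """

    def collect(items):
        genes: dict[str, dict[str, set[int]]] = {}
        for gene_id, cls, pos in items:
            canon = _canonical_class(cls)
            if canon is None:
                continue
            genes.setdefault(canon, {}).setdefault(gene_id, set()).add(pos)
        return genes

    ga, gb = collect(classes_a), collect(classes_b)
    per_class = {}
    all_a: set[str] = set()
    all_b: set[str] = set()
    flagged: set[str] = set()
    for cls in NONSYN_CLASSES:
        in_a = set(ga.get(cls, {}))
        in_b = set(gb.get(cls, {}))
        all_a |= in_a
        all_b |= in_b
        shared = in_a & in_b
        for g in shared:
            if ga[cls][g] != gb[cls][g]:
                flagged.add(g)
        per_class[cls] = {
            "shared": sorted(shared),
            "only_a": sorted(in_a - in_b),
            "only_b": sorted(in_b - in_a),
        }
    union = all_a | all_b
    overlap_fraction = len(all_a & all_b) / len(union) if union else None
    return {
        "per_class": per_class,
        "overlap_fraction": overlap_fraction,
        "n_genes": len(union),
        "flagged_genes": sorted(flagged),
    }
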