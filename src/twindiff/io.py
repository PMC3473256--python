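"""Readers and writers for every on-disk format the pipeline touches.

Two call-set dialects are supported:

``cgi-var-tsv``
    The package's native, lossless dialect, modelled on CGI-style var files:
    tab-separated columns ``contig begin end vartype allele1 allele2
    varQuality`` with 0-based half-open coordinates. A no-called haplotype
    allele is written ``?``; a deleted allele is the empty string. Header
    comment lines carry the sample id and the called-fraction triple, so a
    write/read round trip is the identity on valid call sets.

``vcf-subset``
    A minimal single-sample VCF (CHROM/POS/ID/REF/ALT/QUAL/FILTER/FORMAT=GT)
    read and written through :mod:`pysam`. Genotypes are written phased
    (``|``) because haplotype phase is meaningful to the comparison engine.
    This dialect cannot represent no-call *region* records or the
    called-fraction metadata; writing a call set containing no-call region
    records in this dialect is an error. Records whose called alleles are
    all reference (e.g. a half-called het whose called haplotype matches the
    reference) also lose their original vartype label, since VCF carries no
    such column — they read back as ``ref`` records.

All other formats are simple TSV (segments, coverage windows, junctions,
known variants), FASTA/FASTQ via Bio.SeqIO, and a GFF3 subset (CDS features
grouped by Parent) via gffutils.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    CallSet,
    DataError,
    GeneModel,
    Junction,
    KnownVariantSet,
    ParseError,
    PloidySegment,
    ReferenceGenome,
    VariantCall,
)

DIALECTS = ("cgi-var-tsv", "vcf-subset")

_VAR_COLUMNS = ["contig", "begin", "end", "vartype", "allele1", "allele2", "varQuality"]
_NOCALL_TOKEN = "?"

SEGMENT_COLUMNS = ["contig", "begin", "end", "relativeCoverage", "ploidy", "ploidyScore"]
COVERAGE_COLUMNS = ["contig", "begin", "end", "relativeCoverage"]
JUNCTION_COLUMNS = [
    "leftContig",
    "leftPos",
    "leftStrand",
    "rightContig",
    "rightPos",
    "rightStrand",
    "transitionSeq",
    "support",
    "panelFrequency",
]
KNOWN_COLUMNS = ["contig", "begin", "vartype", "allele"]


def _float_repr(v) -> str:
    """Lossless float serialisation for TSV round trips."""
    return repr(float(v))


# ---------------------------------------------------------------------------
# call sets


def read_callset(
    path: str, dialect: str, ref: Optional[ReferenceGenome] = None
) -> CallSet:
    """Read a call set in the named dialect.

    If ``ref`` is given, contigs and spans are validated against it and a
    reference-mismatch :class:`DataError` is raised on disagreement.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "cgi-var-tsv":
        cs = _read_cgi_var(path)
    else:
        cs = _read_vcf(path)
    if ref is not None:
        cs.validate_against(ref)
    return cs


def write_callset(
    cs: CallSet, path: str, dialect: str, ref: Optional[ReferenceGenome] = None
) -> None:
    """Write a call set; the emitted file re-reads to an equal call set."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "cgi-var-tsv":
        _write_cgi_var(cs, path)
    else:
        if ref is None:
            raise ValueError("vcf-subset output requires the reference genome")
        _write_vcf(cs, path, ref)


def _read_cgi_var(path: str) -> CallSet:
    sample_id = os.path.splitext(os.path.basename(path))[0]
    fractions = {"fully": 1.0, "partially": 0.0, "nocalled": 0.0}
    calls: list[VariantCall] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    key = key.strip()
                    if key == "sample_id":
                        sample_id = value.strip()
                    elif key in (
                        "fully_called_fraction",
                        "partially_called_fraction",
                        "nocalled_fraction",
                    ):
                        fractions[key.split("_")[0]] = float(value)
                continue
            fields = line.split("\t")
            if fields[: len(_VAR_COLUMNS)] == _VAR_COLUMNS or fields[0] == "contig":
                header_seen = True
                continue
            if len(fields) != len(_VAR_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(_VAR_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            try:
                contig, begin, end, vartype, a1, a2, qual = fields
                call = VariantCall(
                    contig=contig,
                    begin=int(begin),
                    end=int(end),
                    vartype=vartype,
                    allele1=None if a1 == _NOCALL_TOKEN else a1,
                    allele2=None if a2 == _NOCALL_TOKEN else a2,
                    var_quality=float(qual),
                )
            except (ValueError, DataError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            calls.append(call)
    if not header_seen and not calls:
        raise ParseError(f"{path}: no header line found")
    return CallSet(
        sample_id=sample_id,
        calls=calls,
        fully_called_fraction=fractions["fully"],
        partially_called_fraction=fractions["partially"],
        nocalled_fraction=fractions["nocalled"],
    )


def _write_cgi_var(cs: CallSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sample_id={cs.sample_id}\n")
        fh.write(f"#fully_called_fraction={cs.fully_called_fraction!r}\n")
        fh.write(f"#partially_called_fraction={cs.partially_called_fraction!r}\n")
        fh.write(f"#nocalled_fraction={cs.nocalled_fraction!r}\n")
        fh.write("\t".join(_VAR_COLUMNS) + "\n")
        for c in cs.calls:
            a1 = _NOCALL_TOKEN if c.allele1 is None else c.allele1
            a2 = _NOCALL_TOKEN if c.allele2 is None else c.allele2
            fh.write(
                f"{c.contig}\t{c.begin}\t{c.end}\t{c.vartype}\t{a1}\t{a2}\t"
                f"{c.var_quality!r}\n"
            )


def _vcf_record_to_call(rec, path: str) -> Optional[VariantCall]:
    sample = rec.samples[0]
    gt = sample.get("GT", (None, None))
    if gt is None:
        gt = (None, None)
    if len(gt) != 2:
        raise ParseError(f"{path}: non-diploid genotype at {rec.chrom}:{rec.pos}")
    alleles = list(rec.alleles)
    ref_allele = alleles[0]
    begin = rec.start
    # trim the shared leading anchor base used for indel anchoring
    alts = alleles[1:]
    trim = 0
    if any(len(a) != len(ref_allele) for a in alts) and alts:
        if all(a and a[0] == ref_allele[0] for a in alts):
            trim = 1
    ref_seq = ref_allele[trim:]
    begin += trim
    end = begin + len(ref_seq)

    def hap(code: Optional[int]) -> Optional[str]:
        if code is None:
            return None
        return alleles[code][trim:]

    a1, a2 = hap(gt[0]), hap(gt[1])
    called = [a for a in (a1, a2) if a is not None]
    non_ref = [a for a in called if a != ref_seq]
    if not non_ref:
        if not called:
            vartype = "no-call"
        else:
            vartype = "ref"
    elif len(ref_seq) == 1 and all(len(a) == 1 for a in called):
        vartype = "snp"
    elif len(ref_seq) == 0:
        vartype = "ins"
    elif all(a == "" for a in non_ref):
        vartype = "del"
    else:
        vartype = "sub"
    if vartype == "no-call" and len(ref_seq) <= 1:
        # single-position missing genotype; representable as a 1 bp no-call
        return VariantCall(rec.chrom, begin, end, "no-call", None, None,
                           rec.qual or 0.0)
    try:
        return VariantCall(rec.chrom, begin, end, vartype, a1, a2, rec.qual or 0.0)
    except DataError as exc:
        raise ParseError(f"{path}: record at {rec.chrom}:{rec.pos}: {exc}") from exc


def _read_vcf(path: str) -> CallSet:
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise ParseError(f"{path}: expected exactly one sample, got {samples}")
        contigs = set(vf.header.contigs)
        calls = []
        for rec in vf:
            if contigs and rec.chrom not in contigs:
                raise DataError(f"{path}: contig {rec.chrom!r} not in header")
            call = _vcf_record_to_call(rec, path)
            if call is not None:
                calls.append(call)
    return CallSet(sample_id=samples[0], calls=calls)


def _call_to_vcf_alleles(c: VariantCall, ref: ReferenceGenome):
    """Return (pos0, ref_allele, alts, gt) in VCF anchored representation."""
    span = ref.fetch(c.contig, c.begin, c.end)
    needs_anchor = c.vartype in ("ins", "del") or (
        c.vartype == "sub"
        and any(len(a) != len(span) for a in c.called_alleles())
    )
    if needs_anchor:
        if c.begin == 0:
            raise DataError(
                f"cannot anchor {c.vartype} at {c.contig}:0 for VCF output"
            )
        anchor = ref.fetch(c.contig, c.begin - 1, c.begin)
        pos0 = c.begin - 1
        ref_allele = anchor + span
        haps = [None if a is None else anchor + a for a in c.alleles]
    else:
        pos0 = c.begin
        ref_allele = span
        haps = list(c.alleles)
    alts: list[str] = []
    gt: list[Optional[int]] = []
    for h in haps:
        if h is None:
            gt.append(None)
        elif h == ref_allele:
            gt.append(0)
        else:
            if h not in alts:
                alts.append(h)
            gt.append(alts.index(h) + 1)
    return pos0, ref_allele, alts, tuple(gt)


def _write_vcf(cs: CallSet, path: str, ref: ReferenceGenome) -> None:
    header = pysam.VariantHeader()
    for name, seq in ref.contigs.items():
        header.contigs.add(name, length=len(seq))
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(cs.sample_id)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for c in cs.calls:
            if c.vartype == "no-call" and c.end - c.begin > 1:
                raise DataError(
                    "vcf-subset cannot represent no-call region records; "
                    "use the cgi-var-tsv dialect"
                )
            pos0, ref_allele, alts, gt = _call_to_vcf_alleles(c, ref)
            rec = vf.new_record(
                contig=c.contig,
                start=pos0,
                alleles=tuple([ref_allele] + alts) if alts else (ref_allele, "."),
                qual=c.var_quality,
                filter="PASS",
            )
            rec.stop = pos0 + len(ref_allele)
            rec.samples[cs.sample_id]["GT"] = gt
            rec.samples[cs.sample_id].phased = True
            vf.write(rec)


# ---------------------------------------------------------------------------
# segments, coverage windows, junctions


def read_segments(path: str) -> list[PloidySegment]:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        PloidySegment(
            contig=str(r.contig),
            begin=int(r.begin),
            end=int(r.end),
            relative_coverage=float(r.relativeCoverage),
            ploidy=int(r.ploidy),
            ploidy_score=float(r.ploidyScore),
        )
        for r in df.itertuples()
    ]


def write_segments(segments: Iterable[PloidySegment], path: str) -> None:
    df = pd.DataFrame(
        [
            (s.contig, s.begin, s.end, s.relative_coverage, s.ploidy, s.ploidy_score)
            for s in segments
        ],
        columns=SEGMENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format=_float_repr)


def read_coverage_windows(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = set(COVERAGE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df[COVERAGE_COLUMNS]


def write_coverage_windows(df: pd.DataFrame, path: str) -> None:
    df[COVERAGE_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_float_repr)


def read_junctions(path: str) -> list[Junction]:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                     float_precision="round_trip")
    missing = set(JUNCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        Junction(
            left_contig=str(r.leftContig),
            left_pos=int(r.leftPos),
            left_strand=str(r.leftStrand),
            right_contig=str(r.rightContig),
            right_pos=int(r.rightPos),
            right_strand=str(r.rightStrand),
            transition_seq=str(r.transitionSeq),
            support=int(r.support),
            panel_frequency=float(r.panelFrequency),
        )
        for r in df.itertuples()
    ]


def write_junctions(junctions: Iterable[Junction], path: str) -> None:
    df = pd.DataFrame(
        [
            (
                j.left_contig,
                j.left_pos,
                j.left_strand,
                j.right_contig,
                j.right_pos,
                j.right_strand,
                j.transition_seq,
                j.support,
                j.panel_frequency,
            )
            for j in junctions
        ],
        columns=JUNCTION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format=_float_repr)


# ---------------------------------------------------------------------------
# gene models (GFF3 subset: CDS features grouped by Parent)


def read_genemodel(path: str) -> list[GeneModel]:
    """Parse CDS features from a GFF3 file into gene models.

    GFF3 is 1-based closed; intervals are converted to 0-based half-open.
    The ``phase`` of the transcription-first CDS feature becomes the model's
    first-codon phase.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    by_gene: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
        if not parents:
            raise ParseError(f"{path}: CDS feature without Parent or ID")
        by_gene.setdefault(parents[0], []).append(feat)
    models = []
    for gene_id, feats in by_gene.items():
        strands = {f.strand for f in feats}
        contigs = {f.seqid for f in feats}
        if len(strands) != 1 or len(contigs) != 1:
            raise DataError(f"gene {gene_id}: inconsistent strand or contig")
        strand = strands.pop()
        intervals = sorted((f.start - 1, f.end) for f in feats)
        if strand == "-":
            intervals = intervals[::-1]
        first = feats[0]
        ordered = sorted(feats, key=lambda f: f.start, reverse=(strand == "-"))
        phase = ordered[0].frame
        phase = int(phase) if phase not in (None, ".") else 0
        models.append(
            GeneModel(
                gene_id=gene_id,
                contig=contigs.pop(),
                strand=strand,
                cds_intervals=intervals,
                phase=phase,
            )
        )
    models.sort(key=lambda g: (g.contig, g.genomic_span()))
    return models


def write_genemodel(models: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            b, e = g.genomic_span()
            fh.write(
                f"{g.contig}\ttwindiff\tgene\t{b + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (ib, ie) in enumerate(g.cds_intervals):
                phase = g.phase if i == 0 else _running_phase(g, i)
                fh.write(
                    f"{g.contig}\ttwindiff\tCDS\t{ib + 1}\t{ie}\t.\t{g.strand}\t"
                    f"{phase}\tID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


def _running_phase(g: GeneModel, index: int) -> int:
    consumed = sum(e - b for b, e in g.cds_intervals[:index]) - g.phase
    return (3 - consumed % 3) % 3


# ---------------------------------------------------------------------------
# sequences, reads, known variants


def read_fasta(
    path: str, contig_class: Optional[dict[str, str]] = None
) -> ReferenceGenome:
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in contigs:
            raise ParseError(f"{path}: duplicate contig {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ParseError(f"{path}: no FASTA records")
    return ReferenceGenome(contigs=contigs, contig_class=dict(contig_class or {}))


def write_fasta(ref: ReferenceGenome, path: str, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in ref.contigs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_reads(path: str) -> list[SeqRecord]:
    fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
    return list(SeqIO.parse(path, fmt))


def write_reads(reads: Iterable[SeqRecord], path: str) -> None:
    fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
    with open(path, "w") as fh:
        SeqIO.write(reads, fh, fmt)


def read_known_set(path: str) -> KnownVariantSet:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                     float_precision="round_trip")
    missing = set(KNOWN_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    keys = {
        (str(r.contig), int(r.begin), str(r.vartype), str(r.allele))
        for r in df.itertuples()
    }
    return KnownVariantSet.from_keys(keys)


def write_known_set(known: KnownVariantSet, path: str) -> None:
    rows = sorted(known.keys)
    df = pd.DataFrame(rows, columns=KNOWN_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format=_float_repr)
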