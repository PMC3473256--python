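"""Domain types and coordinate conventions.

All coordinates inside the package are 0-based half-open intervals on a
named contig. Conversion to and from 1-based formats (VCF, GFF3) happens
only at the I/O boundary (:mod:`twindiff.io`).

Variant representation follows the CGI var-file style:

* ``snp``   — one reference base replaced by one alternate base.
* ``ins``   — zero-length reference span (``begin == end``); the inserted
  sequence is carried by the non-reference allele.
* ``del``   — non-empty reference span; the deleted (non-reference) allele
  is the empty string.
* ``sub``   — block substitution: a non-empty reference span replaced by an
  arbitrary sequence (possibly of equal length).
* ``ref``   — explicitly reference-called span.
* ``no-call`` — span where neither haplotype could be called.

``allele1`` and ``allele2`` are the sequences of the two haplotypes over the
record's reference span; ``None`` marks a no-call on that haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_N = frozenset("ACGTN")

VARTYPES = ("snp", "ins", "del", "sub", "ref", "no-call")
CONTIG_CLASSES = ("autosome", "sexchrom", "mito", "viral")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class TwindiffError(Exception):
    """Base class for package errors."""


class ConfigError(TwindiffError):
    """Invalid configuration or parameters."""


class DataError(TwindiffError):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """Malformed input file; carries file and line context where known."""


@dataclass
class ReferenceGenome:
    """An in-memory reference: ordered contig name -> upper-case sequence.

    ``contig_class`` assigns each contig one of ``autosome``, ``sexchrom``,
    ``mito`` or ``viral``.
    """

    contigs: dict[str, str]
    contig_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise DataError(f"contig {name!r} has empty sequence")
            if not set(seq) <= DNA_ALPHABET_N:
                bad = sorted(set(seq) - DNA_ALPHABET_N)
                raise DataError(f"contig {name!r} contains non-DNA characters {bad}")
        for name, cls in self.contig_class.items():
            if name not in self.contigs:
                raise DataError(f"contig_class references unknown contig {name!r}")
            if cls not in CONTIG_CLASSES:
                raise DataError(f"unknown contig class {cls!r} for {name!r}")

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, begin: int, end: int) -> str:
        if contig not in self.contigs:
            raise DataError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if not (0 <= begin <= end <= len(seq)):
            raise DataError(
                f"span {contig}:{begin}-{end} outside contig of length {len(seq)}"
            )
        return seq[begin:end]

    def contigs_of_class(self, cls: str) -> list[str]:
        return [c for c in self.contigs if self.contig_class.get(c) == cls]


@dataclass
class VariantCall:
    """One per-sample call over a reference span (see module docstring)."""

    contig: str
    begin: int
    end: int
    vartype: str
    allele1: Optional[str]
    allele2: Optional[str]
    var_quality: float = 0.0

    def __post_init__(self) -> None:
        if self.vartype not in VARTYPES:
            raise DataError(f"unknown vartype {self.vartype!r}")
        if not (0 <= self.begin <= self.end):
            raise DataError(f"invalid span {self.begin}-{self.end}")
        if self.var_quality < 0:
            raise DataError("var_quality must be non-negative")
        for a in (self.allele1, self.allele2):
            if a is not None and not set(a) <= DNA_ALPHABET:
                raise DataError(f"allele {a!r} contains non-DNA characters")
        if self.vartype == "snp":
            if self.end - self.begin != 1:
                raise DataError("snp must span exactly one base")
            for a in self.called_alleles():
                if len(a) != 1:
                    raise DataError("snp alleles must have length 1")
        if self.vartype == "ins" and self.begin != self.end:
            raise DataError("ins must have a zero-length reference span")
        if self.vartype == "del":
            # non-reference alleles must be empty; the only other legal
            # allele is the reference span itself (het deletion)
            for a in self.called_alleles():
                if a != "" and len(a) != self.end - self.begin:
                    raise DataError("del non-reference alleles must be empty")
        if self.vartype == "no-call" and (
            self.allele1 is not None or self.allele2 is not None
        ):
            raise DataError("no-call records carry no called alleles")

    @property
    def alleles(self) -> tuple[Optional[str], Optional[str]]:
        return (self.allele1, self.allele2)

    def called_alleles(self) -> list[str]:
        return [a for a in (self.allele1, self.allele2) if a is not None]

    def is_fully_called(self) -> bool:
        return self.allele1 is not None and self.allele2 is not None

    def alt_alleles(self, ref: "ReferenceGenome") -> list[str]:
        """Called alleles differing from the reference span (duplicates kept)."""
        span = ref.fetch(self.contig, self.begin, self.end)
        return [a for a in self.called_alleles() if a != span]

    def is_variant(self, ref: "ReferenceGenome") -> bool:
        """True if some called allele differs from the reference span."""
        if self.vartype in ("ref", "no-call"):
            return False
        return bool(self.alt_alleles(ref))

    def key(self, ref: "ReferenceGenome") -> list[tuple[str, int, str, str]]:
        """Normalized identity keys, one per distinct non-reference allele."""
        norm = left_normalize(self, ref)
        span = ref.fetch(norm.contig, norm.begin, norm.end)
        keys = []
        for a in norm.called_alleles():
            if a != span:
                k = (norm.contig, norm.begin, norm.vartype, a)
                if k not in keys:
                    keys.append(k)
        return keys


def left_normalize(call: VariantCall, ref: ReferenceGenome) -> VariantCall:
    """Left-align an insertion or deletion against the reference.

    The record is shifted one base leftwards while the reference base before
    the span equals the last base of the variable sequence (the inserted
    sequence for ``ins``, the deleted reference span for ``del``). For a het
    insertion both non-empty alleles must rotate on the same base for the
    shift to apply. SNPs, block substitutions and no-calls are returned
    unchanged: their placement is not representation-ambiguous in this model.
    """
    if call.vartype == "del":
        seq = ref.contigs[call.contig]
        begin, end = call.begin, call.end
        while begin > 0 and seq[begin - 1] == seq[end - 1]:
            begin -= 1
            end -= 1
        if begin == call.begin:
            return call
        return replace(call, begin=begin, end=end)
    if call.vartype == "ins":
        seq = ref.contigs[call.contig]
        begin = call.begin
        alts = [a for a in call.called_alleles() if a != ""]
        if not alts:
            return call
        shifted = list(alts)
        while begin > 0 and all(a and seq[begin - 1] == a[-1] for a in shifted):
            shifted = [seq[begin - 1] + a[:-1] for a in shifted]
            begin -= 1
        if begin == call.begin:
            return call

        def _map(a: Optional[str]) -> Optional[str]:
            if a is None or a == "":
                return a
            return shifted[alts.index(a)]

        return replace(
            call,
            begin=begin,
            end=begin,
            allele1=_map(call.allele1),
            allele2=_map(call.allele2),
        )
    return call


@dataclass
class CallSet:
    """All calls of one sample, sorted by (contig, begin, end).

    The three called-fraction fields describe how much of the genome was
    fully, partially or not called; they must sum to 1.
    """

    sample_id: str
    calls: list[VariantCall]
    fully_called_fraction: float = 1.0
    partially_called_fraction: float = 0.0
    nocalled_fraction: float = 0.0

    def __post_init__(self) -> None:
        total = (
            self.fully_called_fraction
            + self.partially_called_fraction
            + self.nocalled_fraction
        )
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"called fractions sum to {total!r}, expected 1")
        self.sort()
        self._validate_overlap()

    def sort(self) -> None:
        self.calls.sort(key=lambda c: (c.contig, c.begin, c.end))

    def _validate_overlap(self) -> None:
        prev: Optional[VariantCall] = None
        for c in self.calls:
            if prev is not None and prev.contig == c.contig:
                if c.begin < prev.end or (
                    c.begin == prev.end == c.end == prev.begin
                ):
                    raise DataError(
                        f"overlapping calls at {c.contig}:{prev.begin}-{prev.end} "
                        f"and {c.contig}:{c.begin}-{c.end}"
                    )
            prev = c

    def validate_against(self, ref: ReferenceGenome) -> None:
        for c in self.calls:
            if c.contig not in ref.contigs:
                raise DataError(f"call on unknown contig {c.contig!r}")
            if c.end > ref.length(c.contig):
                raise DataError(
                    f"call {c.contig}:{c.begin}-{c.end} beyond contig end"
                )

    def variant_calls(self, ref: ReferenceGenome) -> list[VariantCall]:
        return [c for c in self.calls if c.is_variant(ref)]


@dataclass
class PloidySegment:
    """A run of equal integer ploidy, with a confidence score."""

    contig: str
    begin: int
    end: int
    relative_coverage: float
    ploidy: int
    ploidy_score: float

    def __post_init__(self) -> None:
        if self.begin >= self.end:
            raise DataError("segment must have positive length")
        if self.ploidy < 0 or self.ploidy_score < 0 or self.relative_coverage < 0:
            raise DataError("ploidy, score and coverage must be non-negative")


@dataclass
class Junction:
    """A chromosomal rearrangement breakpoint joining two reference arms.

    ``transition_seq`` is sequence at the breakpoint absent from the
    reference; ``support`` counts discordant read pairs (the junction score);
    ``panel_frequency`` is the fraction of a sequencing panel's genomes in
    which the same junction was seen (high values suggest platform artifacts).
    """

    left_contig: str
    left_pos: int
    left_strand: str
    right_contig: str
    right_pos: int
    right_strand: str
    transition_seq: str = ""
    support: int = 0
    panel_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.left_strand not in "+-" or self.right_strand not in "+-":
            raise DataError("strands must be '+' or '-'")
        if self.support < 0:
            raise DataError("support must be non-negative")
        if not (0.0 <= self.panel_frequency <= 1.0):
            raise DataError("panel_frequency must lie in [0, 1]")
        if self.transition_seq and not set(self.transition_seq) <= DNA_ALPHABET_N:
            raise DataError("transition_seq contains non-DNA characters")

    def is_deletion_like(self) -> bool:
        return (
            self.left_contig == self.right_contig
            and self.left_strand == "+"
            and self.right_strand == "+"
            and self.right_pos > self.left_pos
        )

    def span(self) -> Optional[int]:
        if self.left_contig != self.right_contig:
            return None
        return abs(self.right_pos - self.left_pos)


@dataclass
class GeneModel:
    """One canonical coding transcript: ordered CDS intervals on a strand.

    ``cds_intervals`` are 0-based half-open reference intervals listed in
    transcription order (descending reference coordinate on the minus
    strand). ``phase`` is the number of bases to skip at the start of the
    first interval before the first complete codon.
    """

    gene_id: str
    contig: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise DataError("strand must be '+' or '-'")
        if not self.cds_intervals:
            raise DataError(f"gene {self.gene_id}: no CDS intervals")
        ivs = self.cds_intervals
        for b, e in ivs:
            if b >= e:
                raise DataError(f"gene {self.gene_id}: empty CDS interval")
        genomic = sorted(ivs)
        for (b1, e1), (b2, e2) in zip(genomic, genomic[1:]):
            if b2 < e1:
                raise DataError(f"gene {self.gene_id}: overlapping CDS intervals")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(ivs) != expected:
            raise DataError(
                f"gene {self.gene_id}: CDS intervals not in transcription order"
            )
        if self.cds_length() % 3 != 0:
            raise DataError(
                f"gene {self.gene_id}: CDS length {self.cds_length()} "
                "not divisible by 3"
            )

    def cds_length(self) -> int:
        return sum(e - b for b, e in self.cds_intervals)

    def genomic_span(self) -> tuple[int, int]:
        return (
            min(b for b, _ in self.cds_intervals),
            max(e for _, e in self.cds_intervals),
        )

    def coding_sequence(self, ref: ReferenceGenome) -> str:
        parts = [ref.fetch(self.contig, b, e) for b, e in sorted(self.cds_intervals)]
        seq = "".join(parts)
        if self.strand == "-":
            seq = revcomp(seq)
        return seq[self.phase :]

    def cds_coordinate(self, pos: int) -> Optional[int]:
        """Map a genomic position to a coding-sequence offset, or None."""
        offset = 0
        intervals = sorted(self.cds_intervals)
        if self.strand == "+":
            for b, e in intervals:
                if b <= pos < e:
                    return offset + (pos - b) - self.phase
                offset += e - b
        else:
            for b, e in intervals[::-1]:
                if b <= pos < e:
                    return offset + (e - 1 - pos) - self.phase
                offset += e - b
        return None


@dataclass(frozen=True)
class KnownVariantSet:
    """A catalogue of previously observed variants (dbSNP surrogate).

    Keys are left-normalized ``(contig, begin, vartype, alt_allele)`` tuples.
    """

    keys: frozenset[tuple[str, int, str, str]]

    @classmethod
    def from_keys(cls, keys: Iterable[tuple[str, int, str, str]]) -> "KnownVariantSet":
        return cls(frozenset(keys))

    def contains_call(self, call: VariantCall, ref: ReferenceGenome) -> bool:
        """True if every non-reference allele of the call is catalogued."""
        ks = call.key(ref)
        if not ks:
            return False
        return all(k in self.keys for k in ks)

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self.keys
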