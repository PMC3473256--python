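"""k-mer screening of unmapped reads and non-reference sequences against a
viral (EBV-surrogate) genome.

A canonical k-mer index of the viral contig replaces read alignment: a read
is classified viral when at least ``min_hit_fraction`` of its k-mers occur
in the index (canonical = lexicographic minimum of a k-mer and its reverse
complement, so read orientation does not matter). Viral depth is the total
length of viral-classified reads divided by the viral genome length, and
the episome copy number estimate is viral depth / autosomal depth.

Sequences shorter than k (insertions and junction transition sequences down
to the 9 nt screening floor) are screened by exact substring search against
the viral contig and its reverse complement instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .core import ConfigError, DataError, DNA_ALPHABET, revcomp

logger = logging.getLogger(__name__)

DEFAULT_K = 31


@dataclass
class KmerIndex:
    """Canonical k-mer -> positions on the viral contig."""

    k: int
    sequence: str
    index: dict[str, list[int]] = field(default_factory=dict)
    skipped_n_kmers: int = 0

    def lookup(self, kmer: str) -> list[int]:
        return self.index.get(_canonical(kmer), [])


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def build_index(viral_seq: str, k: int = DEFAULT_K) -> KmerIndex:
    """Index every k-mer of the viral contig (k odd; N-containing k-mers are
    skipped and counted)."""
    if k % 2 == 0:
        raise ConfigError("k must be odd (canonical k-mers must be unambiguous)")
    viral_seq = viral_seq.upper()
    if len(viral_seq) < k:
        raise ConfigError(
            f"viral contig length {len(viral_seq)} shorter than k={k}"
        )
    idx = KmerIndex(k=k, sequence=viral_seq)
    skipped = 0
    for i in range(len(viral_seq) - k + 1):
        kmer = viral_seq[i : i + k]
        if not set(kmer) <= DNA_ALPHABET:
            skipped += 1
            continue
        idx.index.setdefault(_canonical(kmer), []).append(i)
    idx.skipped_n_kmers = skipped
    if skipped:
        logger.info("skipped %d N-containing k-mers while indexing", skipped)
    return idx


def _read_seq(read) -> tuple[str, str]:
    """Accept (id, seq) pairs, Bio SeqRecords, or bare strings."""
    if isinstance(read, tuple):
        return read[0], str(read[1]).upper()
    if hasattr(read, "seq"):
        return getattr(read, "id", ""), str(read.seq).upper()
    return "", str(read).upper()


@dataclass
class ScreenResult:
    classifications: list[tuple[str, bool, float]]  # (read id, viral?, hit fraction)
    viral_reads: int
    total_reads: int
    viral_bases: int
    viral_depth: float


def screen_reads(
    reads: Iterable, idx: KmerIndex, min_hit_fraction: float = 0.5
) -> ScreenResult:
    """Classify reads as viral/non-viral and estimate viral depth."""
    if not (0.0 < min_hit_fraction <= 1.0):
        raise ConfigError("min_hit_fraction must lie in (0, 1]")
    rows = []
    viral_reads = 0
    viral_bases = 0
    total = 0
    for read in reads:
        rid, seq = _read_seq(read)
        total += 1
        if len(seq) < idx.k:
            raise DataError(
                f"read {rid!r} shorter than k={idx.k}; cannot screen"
            )
        n_kmers = len(seq) - idx.k + 1
        hits = sum(
            1 for i in range(n_kmers) if idx.lookup(seq[i : i + idx.k])
        )
        frac = hits / n_kmers
        is_viral = frac >= min_hit_fraction
        if is_viral:
            viral_reads += 1
            viral_bases += len(seq)
        rows.append((rid, is_viral, frac))
    depth = viral_bases / len(idx.sequence)
    return ScreenResult(
        classifications=rows,
        viral_reads=viral_reads,
        total_reads=total,
        viral_bases=viral_bases,
        viral_depth=depth,
    )


def copy_number(viral_depth: float, autosomal_depth: float) -> float:
    """Episome copies per diploid genome-equivalent: depth ratio."""
    if autosomal_depth <= 0:
        raise DataError("autosomal depth must be positive")
    return viral_depth / autosomal_depth


@dataclass
class SequenceHit:
    sequence: str
    hit: bool
    method: str  # "kmer" | "substring"
    detail: Optional[str] = None


def screen_sequences(
    seqs: Sequence[str], idx: KmerIndex, min_len: int = 9
) -> list[SequenceHit]:
    """Screen non-reference sequences (long insertions, junction transition
    sequences) for viral content.

    Sequences shorter than ``min_len`` (default 9: the > 8 nt gate) are
    skipped. Sequences of at least k are screened by k-mer lookup; shorter
    ones by exact substring search on both strands.
    """
    both_strands = idx.sequence + "#" + revcomp(idx.sequence)
    out: list[SequenceHit] = []
    for s in seqs:
        s = s.upper()
        if len(s) < min_len:
            continue
        if len(s) >= idx.k:
            hit = any(
                idx.lookup(s[i : i + idx.k])
                for i in range(len(s) - idx.k + 1)
            )
            out.append(SequenceHit(sequence=s, hit=hit, method="kmer"))
        else:
            hit = s in both_strands
            out.append(SequenceHit(sequence=s, hit=hit, method="substring"))
    return out
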