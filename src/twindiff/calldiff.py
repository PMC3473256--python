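"""Haplotype-aware comparison of two call sets from the same individual.

The engine groups nearby variant calls from both samples into *superloci*,
reconstructs the two haplotype sequences of each sample over every
superlocus, and classifies each superlocus with one verdict:

``identical``
    Both samples fully called; the two haplotype sequence multisets are
    equal (a het called as (C,T) in one sample and (T,C) in the other is
    identical — haplotype labels carry no meaning across samples).
``consistent``
    At least one haplotype segment is no-called, and some completion of the
    no-called stretches makes the samples identical.
``onlyA`` / ``onlyB``
    One sample is fully reference-called over the superlocus while the
    other carries a variant.
``phase-mismatch``
    Both samples fully called with the same alleles at the same loci, but
    no arrangement of whole haplotypes matches — the alleles are phased
    differently (e.g. two het SNPs cis in one sample, trans in the other).
``mismatch``
    Both samples make calls that cannot be reconciled.
``ploidy-mismatch``
    Reserved for differing local ploidy; never produced under the diploid
    model (the compared genomes come from the same individual).

The somatic path (:func:`somatic_output`, :func:`score_somatic`) mirrors a
tumor/normal comparison: every tumor variant whose superlocus is
reference-called in the normal sample becomes a candidate, and each
candidate receives a SomaticScore in [0, 1], calibrated so that filtering
at score >= x retains a fraction 1 - x of true somatic variants
(sensitivity = 1 - x).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import (
    CallSet,
    DataError,
    KnownVariantSet,
    ReferenceGenome,
    VariantCall,
    left_normalize,
)

logger = logging.getLogger(__name__)

DEFAULT_MERGE_GAP = 20
MAX_SUPERLOCUS_SPAN = 10_000
MAX_SUPERLOCUS_VARIANTS = 12

VERDICTS = (
    "identical",
    "consistent",
    "onlyA",
    "onlyB",
    "mismatch",
    "phase-mismatch",
    "ploidy-mismatch",
)


@dataclass
class Superlocus:
    contig: str
    begin: int
    end: int
    calls_a: list[VariantCall] = field(default_factory=list)
    calls_b: list[VariantCall] = field(default_factory=list)


@dataclass
class ComparisonRecord:
    superlocus: Superlocus
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise DataError(f"unknown verdict {self.verdict!r}")


@dataclass
class SomaticCandidate:
    """A tumor-only variant with its superlocus context and score."""

    variant: VariantCall
    fully_called: bool
    normal_ref_quality: float = 60.0
    somatic_score: Optional[float] = None
    novel: Optional[bool] = None


# ---------------------------------------------------------------------------
# superlocus construction


def build_superloci(
    a: CallSet,
    b: CallSet,
    ref: ReferenceGenome,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[Superlocus]:
    """Group variant calls of both samples into maximal superloci.

    Two variant spans belong to the same superlocus when they are within
    ``merge_gap`` bp of each other (transitive closure). Reference-called
    territory between superloci is excluded; no-call records of either
    sample that intersect a superlocus span are attached (clipped) so the
    classifier can see them.
    """
    for cs in (a, b):
        if any(
            c2.begin < c1.begin
            for c1, c2 in zip(cs.calls, cs.calls[1:])
            if c1.contig == c2.contig
        ):
            raise DataError(f"call set {cs.sample_id} is not sorted")

    seeds: list[tuple[str, int, int, int, VariantCall]] = []
    for sample_idx, cs in enumerate((a, b)):
        for c in cs.calls:
            if c.vartype in ("ref", "no-call"):
                continue
            seeds.append((c.contig, c.begin, c.end, sample_idx, c))
    seeds.sort(key=lambda t: (t[0], t[1], t[2]))

    superloci: list[Superlocus] = []
    current: Optional[Superlocus] = None
    for contig, begin, end, sample_idx, call in seeds:
        if (
            current is not None
            and contig == current.contig
            and begin - current.end <= merge_gap
        ):
            current.end = max(current.end, end)
        else:
            current = Superlocus(contig=contig, begin=begin, end=end)
            superloci.append(current)
        (current.calls_a if sample_idx == 0 else current.calls_b).append(call)

    _attach_nocalls(superloci, a, 0)
    _attach_nocalls(superloci, b, 1)
    return superloci


def _attach_nocalls(superloci: list[Superlocus], cs: CallSet, which: int) -> None:
    nocalls = [c for c in cs.calls if c.vartype == "no-call"]
    if not nocalls:
        return
    by_contig: dict[str, list[VariantCall]] = {}
    for c in nocalls:
        by_contig.setdefault(c.contig, []).append(c)
    for sl in superloci:
        for nc in by_contig.get(sl.contig, ()):
            if nc.begin < sl.end and nc.end > sl.begin:
                clipped = replace(
                    nc, begin=max(nc.begin, sl.begin), end=min(nc.end, sl.end)
                )
                target = sl.calls_a if which == 0 else sl.calls_b
                target.append(clipped)
                target.sort(key=lambda c: (c.begin, c.end))


# ---------------------------------------------------------------------------
# haplotype reconstruction

_WILD = object()  # matches any DNA string (a no-called haplotype stretch)


def _haplotype_pattern(
    ref: ReferenceGenome,
    contig: str,
    begin: int,
    end: int,
    calls: Sequence[VariantCall],
    hap: int,
) -> tuple:
    """One haplotype over [begin, end) as a tuple of chars and wildcards."""
    out: list = []
    cursor = begin
    for c in sorted(calls, key=lambda c: (c.begin, c.end)):
        if c.begin < cursor:
            raise DataError(
                f"overlapping calls in superlocus {contig}:{begin}-{end}"
            )
        out.extend(ref.fetch(contig, cursor, c.begin))
        allele = c.allele1 if hap == 0 else c.allele2
        if c.vartype == "no-call" or allele is None:
            out.append(_WILD)
        else:
            out.extend(allele)
        cursor = c.end
    out.extend(ref.fetch(contig, cursor, end))
    return tuple(out)


def _is_concrete(pattern: tuple) -> bool:
    return _WILD not in pattern


def _as_string(pattern: tuple) -> str:
    return "".join(pattern)


def _patterns_compatible(pa: tuple, pb: tuple, cap: int = 25_000_000) -> bool:
    """True iff some DNA string matches both patterns.

    Patterns are sequences of literal characters and wildcards, a wildcard
    matching any (possibly empty) DNA string. Decided by memoized two-pointer
    recursion; sizes are bounded by the superlocus span cap.
    """
    if _is_concrete(pa) and _is_concrete(pb):
        return pa == pb
    # trim common concrete prefix/suffix to shrink the DP
    i = 0
    while i < len(pa) and i < len(pb) and pa[i] is not _WILD and pb[i] is not _WILD:
        if pa[i] != pb[i]:
            return False
        i += 1
    ja, jb = len(pa), len(pb)
    while (
        ja > i and jb > i and pa[ja - 1] is not _WILD and pb[jb - 1] is not _WILD
    ):
        if pa[ja - 1] != pb[jb - 1]:
            return False
        ja -= 1
        jb -= 1
    pa, pb = pa[i:ja], pb[i:jb]
    if len(pa) * len(pb) > cap:
        warnings.warn(
            "superlocus pattern comparison exceeded the size cap; "
            "treating as incompatible",
            RuntimeWarning,
            stacklevel=2,
        )
        return False

    na, nb = len(pa), len(pb)
    # forward reachability over (x, y) pointer states; every transition
    # strictly increases x + y, so a visited set suffices
    stack = [(0, 0)]
    seen = {(0, 0)}
    while stack:
        x, y = stack.pop()
        if x == na and y == nb:
            return True
        nxt = []
        if x < na and pa[x] is _WILD:
            nxt.append((x + 1, y))  # wildcard produces nothing further
            if y < nb:
                nxt.append((x, y + 1))  # wildcard absorbs from the other side
        if y < nb and pb[y] is _WILD:
            nxt.append((x, y + 1))
            if x < na:
                nxt.append((x + 1, y))
        if (
            x < na
            and y < nb
            and pa[x] is not _WILD
            and pb[y] is not _WILD
            and pa[x] == pb[y]
        ):
            nxt.append((x + 1, y + 1))
        for state in nxt:
            if state not in seen:
                seen.add(state)
                stack.append(state)
    return False


# ---------------------------------------------------------------------------
# classification


def _sample_state(
    sl: Superlocus, calls: Sequence[VariantCall], ref: ReferenceGenome
):
    pats = tuple(
        _haplotype_pattern(ref, sl.contig, sl.begin, sl.end, calls, hap)
        for hap in (0, 1)
    )
    fully = all(_is_concrete(p) for p in pats)
    has_var = any(c.is_variant(ref) for c in calls)
    return pats, fully, has_var


def _pairing_equal(pa: tuple, pb: tuple) -> bool:
    a1, a2 = map(_as_string, pa)
    b1, b2 = map(_as_string, pb)
    return (a1 == b1 and a2 == b2) or (a1 == b2 and a2 == b1)


def _swap_equal(
    sl: Superlocus, ref: ReferenceGenome, pats_b: tuple
) -> bool:
    """Can re-phasing individual het calls of sample A match sample B?"""
    hets = [
        i
        for i, c in enumerate(sl.calls_a)
        if c.vartype not in ("ref", "no-call") and c.allele1 != c.allele2
    ]
    calls = list(sl.calls_a)
    for mask in range(1, 1 << len(hets)):
        trial = list(calls)
        for bit, idx in enumerate(hets):
            if mask >> bit & 1:
                c = trial[idx]
                trial[idx] = replace(c, allele1=c.allele2, allele2=c.allele1)
        pats = tuple(
            _haplotype_pattern(ref, sl.contig, sl.begin, sl.end, trial, hap)
            for hap in (0, 1)
        )
        if _pairing_equal(pats, pats_b):
            return True
    return False


def classify_superlocus(
    sl: Superlocus,
    ref: ReferenceGenome,
    max_span: int = MAX_SUPERLOCUS_SPAN,
    max_variants: int = MAX_SUPERLOCUS_VARIANTS,
) -> ComparisonRecord:
    """Classify one superlocus (see the module docstring for verdicts).

    Superloci larger than ``max_span`` bp or carrying more than
    ``max_variants`` variant records are classified conservatively as
    ``mismatch`` with a warning, to bound haplotype enumeration.
    """
    n_var = sum(
        1
        for c in sl.calls_a + sl.calls_b
        if c.vartype not in ("ref", "no-call")
    )
    if sl.end - sl.begin > max_span or n_var > max_variants:
        warnings.warn(
            f"superlocus {sl.contig}:{sl.begin}-{sl.end} with {n_var} variants "
            "exceeds enumeration bounds; classified as mismatch",
            RuntimeWarning,
            stacklevel=2,
        )
        return ComparisonRecord(sl, "mismatch")

    pats_a, full_a, var_a = _sample_state(sl, sl.calls_a, ref)
    pats_b, full_b, var_b = _sample_state(sl, sl.calls_b, ref)

    if full_a and full_b:
        if _pairing_equal(pats_a, pats_b):
            return ComparisonRecord(sl, "identical")
        if not var_b:
            return ComparisonRecord(sl, "onlyA")
        if not var_a:
            return ComparisonRecord(sl, "onlyB")
        if _swap_equal(sl, ref, pats_b):
            return ComparisonRecord(sl, "phase-mismatch")
        return ComparisonRecord(sl, "mismatch")

    if full_b and not var_b and var_a:
        return ComparisonRecord(sl, "onlyA")
    if full_a and not var_a and var_b:
        return ComparisonRecord(sl, "onlyB")
    for xa, xb in (((0, 1), (0, 1)), ((0, 1), (1, 0))):
        if _patterns_compatible(pats_a[xa[0]], pats_b[xb[0]]) and _patterns_compatible(
            pats_a[xa[1]], pats_b[xb[1]]
        ):
            return ComparisonRecord(sl, "consistent")
    return ComparisonRecord(sl, "mismatch")


def compare_callsets(
    a: CallSet,
    b: CallSet,
    ref: ReferenceGenome,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[ComparisonRecord]:
    """Build superloci for two call sets and classify all of them."""
    return [
        classify_superlocus(sl, ref)
        for sl in build_superloci(a, b, ref, merge_gap=merge_gap)
    ]


def superlocus_stats(records: Iterable[ComparisonRecord]) -> dict:
    """Verdict counts plus the identical fraction.

    The identical fraction has denominator identical + onlyA + onlyB +
    mismatch + phase-mismatch; ``consistent`` superloci (not fully called)
    are excluded, mirroring the SuperlocusStats report. Superloci are
    counted, not individual variant records. ``None`` when the denominator
    is zero.
    """
    counts = {v: 0 for v in VERDICTS}
    for r in records:
        counts[r.verdict] += 1
    return stats_from_counts(counts)


def stats_from_counts(counts: dict) -> dict:
    full = {v: int(counts.get(v, 0)) for v in VERDICTS}
    denom = (
        full["identical"]
        + full["onlyA"]
        + full["onlyB"]
        + full["mismatch"]
        + full["phase-mismatch"]
    )
    fraction = full["identical"] / denom if denom else None
    return {"counts": full, "identical_fraction": fraction}


# ---------------------------------------------------------------------------
# somatic output and scoring


def somatic_output(
    normal: CallSet,
    tumor: CallSet,
    ref: ReferenceGenome,
    merge_gap: int = DEFAULT_MERGE_GAP,
    normal_ref_quality: float = 60.0,
) -> list[SomaticCandidate]:
    """All tumor variants whose superlocus is reference-called in normal.

    A candidate is flagged ``fully_called=False`` — and excluded from
    downstream counting — when the normal sample has a no-call over the
    superlocus or the tumor variant itself is only half-called.
    Superloci where the normal sample carries its own variant are shared or
    discordant loci, not somatic candidates, and yield nothing.
    """
    superloci = build_superloci(normal, tumor, ref, merge_gap=merge_gap)
    out: list[SomaticCandidate] = []
    for sl in superloci:
        normal_has_var = any(c.is_variant(ref) for c in sl.calls_a)
        if normal_has_var:
            continue
        normal_fully = all(
            c.vartype != "no-call" and c.is_fully_called() for c in sl.calls_a
        )
        for c in sl.calls_b:
            if not c.is_variant(ref):
                continue
            out.append(
                SomaticCandidate(
                    variant=c,
                    fully_called=normal_fully and c.is_fully_called(),
                    normal_ref_quality=normal_ref_quality,
                )
            )
    return out


def raw_confidence(candidate: SomaticCandidate) -> float:
    """Joint log-probability that the tumor variant call and the normal
    reference call are both correct, from their phred qualities."""
    qt = candidate.variant.var_quality
    qn = candidate.normal_ref_quality
    total = 0.0
    for q in (qt, qn):
        p_err = 10.0 ** (-q / 10.0)
        if p_err >= 1.0:
            return -np.inf
        total += np.log1p(-p_err)
    return total


class Calibration:
    """Empirical quantile map from raw confidence to SomaticScore.

    Built from simulator-labelled true somatic candidates: the score of a
    new candidate is the fraction of calibration candidates with lower raw
    confidence, so scores of true somatic variants are uniform on [0, 1]
    and thresholding at x retains a fraction 1 - x of them.
    """

    def __init__(self, raw_values: Sequence[float]):
        arr = np.sort(np.asarray(list(raw_values), dtype=float))
        if arr.size == 0:
            raise DataError("calibration requires at least one labelled variant")
        self._raw = arr
        self._quantiles = (np.arange(arr.size) + 0.5) / arr.size

    @classmethod
    def from_labelled(
        cls,
        candidates: Sequence[SomaticCandidate],
        true_keys: set,
        ref: ReferenceGenome,
    ) -> "Calibration":
        raws = [
            raw_confidence(c)
            for c in candidates
            if c.fully_called and any(k in true_keys for k in c.variant.key(ref))
        ]
        return cls(raws)

    def score(self, raw: float) -> float:
        return float(
            np.interp(raw, self._raw, self._quantiles, left=0.0, right=1.0)
        )

    def to_table(self) -> np.ndarray:
        return np.column_stack([self._raw, self._quantiles])


def score_somatic(
    candidate: SomaticCandidate, calibration: Calibration
) -> SomaticCandidate:
    if candidate.variant.var_quality is None:
        raise DataError("candidate variant lacks var_quality; cannot score")
    candidate.somatic_score = calibration.score(raw_confidence(candidate))
    return candidate


def score_candidates(
    candidates: Iterable[SomaticCandidate], calibration: Calibration
) -> list[SomaticCandidate]:
    return [score_somatic(c, calibration) for c in candidates]


def annotate_novelty(
    candidates: Iterable[SomaticCandidate],
    known: KnownVariantSet,
    ref: ReferenceGenome,
) -> list[SomaticCandidate]:
    """Flag each candidate novel iff absent from the known-variant set."""
    out = []
    for c in candidates:
        c.novel = not known.contains_call(c.variant, ref)
        out.append(c)
    return out


def novel_fraction_by_class(
    candidates: Sequence[SomaticCandidate],
) -> dict[str, Optional[float]]:
    result: dict[str, Optional[float]] = {}
    for vt in ("snp", "ins", "del", "sub"):
        group = [c for c in candidates if c.variant.vartype == vt]
        if not group:
            result[vt] = None
        else:
            result[vt] = sum(1 for c in group if c.novel) / len(group)
    return result


def ct_gt_sweep(
    genomic: CallSet,
    cellline: CallSet,
    ref: ReferenceGenome,
    calibration: Calibration,
    cutoffs: Sequence[float],
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> dict:
    """Reciprocal somatic analyses at a series of score cutoffs.

    CT treats the cell line as the tumor sample; GT treats the genomic DNA
    as the tumor sample and estimates technical noise. Returns per-cutoff
    counts of fully-called candidates with score >= cutoff in each
    direction, plus their CT/GT ratio (None when the GT count is zero).
    """
    if any(not (0.0 <= x <= 1.0) for x in cutoffs):
        raise DataError("cutoffs must lie in [0, 1]")
    ct = score_candidates(
        somatic_output(genomic, cellline, ref, merge_gap=merge_gap), calibration
    )
    gt = score_candidates(
        somatic_output(cellline, genomic, ref, merge_gap=merge_gap), calibration
    )
    rows = []
    for x in cutoffs:
        n_ct = sum(1 for c in ct if c.fully_called and c.somatic_score >= x)
        n_gt = sum(1 for c in gt if c.fully_called and c.somatic_score >= x)
        rows.append(
            {
                "cutoff": float(x),
                "ct": n_ct,
                "gt": n_gt,
                "ct_gt_ratio": (n_ct / n_gt) if n_gt else None,
            }
        )
    return {"ct_candidates": ct, "gt_candidates": gt, "sweep": rows}
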