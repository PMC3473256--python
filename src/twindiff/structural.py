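"""CNV/ploidy comparison and junction diffing.

Ploidy is estimated per 2 kb coverage window as ``round(2 * relative
coverage)`` (relative coverage is the ratio to the autosomal median, so a
diploid region sits at 1.0). Adjacent windows with equal ploidy merge into
segments; each segment gets a confidence score that grows with segment
length and with the distance of its mean coverage from the nearest
competing ploidy's expectation:

    ploidy_score = sqrt(n_windows) * |mean_cov - nearest_alt_ploidy / 2| / sigma

Only the ordering of the score matters for the ``> 40`` reporting gate.

CNV differences: every non-diploid segment of the reference sample whose
score exceeds ``min_ploidy_score`` is looked up in the other sample; a match
requires both endpoints to fall within ``endpoint_window`` (2 kb) of the
reference segment's endpoints. Unmatched segments and matched segments with
differing ploidy are reported.

Junction diffing follows the junctiondiff rule: an A-junction is unique iff
its support reaches ``score_threshold_a``, it is not a deletion-like event
shorter than ``min_deletion_length``, and no B-junction with support >=
``score_threshold_b`` is compatible (same contigs and strands on both arms,
both coordinate differences <= ``max_distance``). Junctions seen in
``panel_frequency_cutoff`` (75%) or more of a sequencing panel are removed
beforehand as likely platform artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import DataError, Junction, PloidySegment

WINDOW_SIZE = 2_000


@dataclass
class CnvMatchParams:
    min_ploidy_score: float = 40.0
    endpoint_window: int = 2_000

    def __post_init__(self) -> None:
        if self.min_ploidy_score < 0 or self.endpoint_window < 0:
            raise DataError("CNV match parameters must be non-negative")


@dataclass
class JunctionDiffParams:
    score_threshold_a: int = 10
    score_threshold_b: int = 0
    max_distance: int = 200
    min_deletion_length: int = 500
    panel_frequency_cutoff: float = 0.75

    def __post_init__(self) -> None:
        if min(
            self.score_threshold_a,
            self.score_threshold_b,
            self.max_distance,
            self.min_deletion_length,
        ) < 0:
            raise DataError("junction diff thresholds must be non-negative")
        if not (0.0 <= self.panel_frequency_cutoff <= 1.0):
            raise DataError("panel_frequency_cutoff must lie in [0, 1]")


@dataclass
class CnvDifference:
    """A reference-sample CNV segment absent or discordant in the other sample."""

    ref_segment: PloidySegment
    other_segment: Optional[PloidySegment]
    kind: str  # "unmatched" | "ploidy-differs"


def estimate_ploidy(
    windows: pd.DataFrame,
    sigma: float = 0.03,
    window_size: int = WINDOW_SIZE,
) -> list[PloidySegment]:
    """Merge per-window relative coverages into scored ploidy segments.

    ``windows`` must have columns contig/begin/end/relativeCoverage, sorted
    and tiling each contig. ``sigma`` is the per-window coverage noise scale
    used in the score.
    """
    required = {"contig", "begin", "end", "relativeCoverage"}
    if not required <= set(windows.columns):
        raise DataError(f"coverage windows missing columns {sorted(required)}")
    if (windows["relativeCoverage"] < 0).any():
        raise DataError("negative relative coverage")
    segments: list[PloidySegment] = []
    for contig, grp in windows.groupby("contig", sort=False):
        grp = grp.sort_values("begin")
        cov = grp["relativeCoverage"].to_numpy(dtype=float)
        begins = grp["begin"].to_numpy(dtype=int)
        ends = grp["end"].to_numpy(dtype=int)
        ploidy = np.maximum(np.rint(2.0 * cov), 0).astype(int)
        start = 0
        for i in range(1, len(cov) + 1):
            boundary = (
                i == len(cov)
                or ploidy[i] != ploidy[start]
                or begins[i] != ends[i - 1]
            )
            if boundary:
                seg_cov = cov[start:i]
                segments.append(
                    _make_segment(
                        str(contig),
                        int(begins[start]),
                        int(ends[i - 1]),
                        seg_cov,
                        int(ploidy[start]),
                        sigma,
                    )
                )
                start = i
    return segments


def _make_segment(
    contig: str, begin: int, end: int, cov: np.ndarray, ploidy: int, sigma: float
) -> PloidySegment:
    mean_cov = float(np.mean(cov))
    alts = [p for p in (ploidy - 1, ploidy + 1) if p >= 0]
    d = min(abs(mean_cov - alt / 2.0) for alt in alts)
    score = float(np.sqrt(len(cov)) * d / sigma)
    return PloidySegment(
        contig=contig,
        begin=begin,
        end=end,
        relative_coverage=mean_cov,
        ploidy=ploidy,
        ploidy_score=score,
    )


def cnv_diff(
    refsegs: Sequence[PloidySegment],
    other: Sequence[PloidySegment],
    params: CnvMatchParams = CnvMatchParams(),
    baseline_ploidy: int = 2,
) -> list[CnvDifference]:
    """Assess reference-sample CNV calls in the other sample.

    Only reference segments with ``ploidy != baseline_ploidy`` and
    ``ploidy_score > min_ploidy_score`` (strictly greater) are assessed.
    """
    by_contig: dict[str, list[PloidySegment]] = {}
    for s in other:
        by_contig.setdefault(s.contig, []).append(s)
    out: list[CnvDifference] = []
    for rs in refsegs:
        if rs.ploidy == baseline_ploidy or rs.ploidy_score <= params.min_ploidy_score:
            continue
        best: Optional[PloidySegment] = None
        best_offset = None
        for os_ in by_contig.get(rs.contig, ()):
            db = abs(os_.begin - rs.begin)
            de = abs(os_.end - rs.end)
            if db <= params.endpoint_window and de <= params.endpoint_window:
                if best is None or db + de < best_offset:
                    best, best_offset = os_, db + de
        if best is None:
            out.append(CnvDifference(rs, None, "unmatched"))
        elif best.ploidy != rs.ploidy:
            out.append(CnvDifference(rs, best, "ploidy-differs"))
    return out


def filter_junctions_by_panel(
    junctions: Iterable[Junction], cutoff: float = 0.75
) -> list[Junction]:
    """Drop junctions seen in ``cutoff`` or more of the sequencing panel."""
    if not (0.0 <= cutoff <= 1.0):
        raise DataError("panel frequency cutoff must lie in [0, 1]")
    return [j for j in junctions if j.panel_frequency < cutoff]


def _compatible(ja: Junction, jb: Junction, max_distance: int) -> bool:
    return (
        ja.left_contig == jb.left_contig
        and ja.right_contig == jb.right_contig
        and ja.left_strand == jb.left_strand
        and ja.right_strand == jb.right_strand
        and abs(ja.left_pos - jb.left_pos) <= max_distance
        and abs(ja.right_pos - jb.right_pos) <= max_distance
    )


def junction_diff(
    a: Sequence[Junction],
    b: Sequence[Junction],
    params: JunctionDiffParams = JunctionDiffParams(),
) -> list[Junction]:
    """Junctions unique to sample A under the junctiondiff rule."""
    b_eligible = [j for j in b if j.support >= params.score_threshold_b]
    unique: list[Junction] = []
    for ja in a:
        if ja.support < params.score_threshold_a:
            continue
        if ja.is_deletion_like() and ja.span() < params.min_deletion_length:
            continue
        if any(_compatible(ja, jb, params.max_distance) for jb in b_eligible):
            continue
        unique.append(ja)
    return unique


def bin_junctions(
    junctions: Sequence[Junction],
    contig_lengths: dict[str, int],
    bin_size: int = 5_000_000,
) -> dict:
    """Per-bin counts of intra-contig junction left arms, plus the
    inter-contig junctions listed separately."""
    if bin_size <= 0:
        raise DataError("bin_size must be positive")
    bins = {
        contig: np.zeros(max(1, -(-length // bin_size)), dtype=int)
        for contig, length in contig_lengths.items()
    }
    inter: list[Junction] = []
    for j in junctions:
        if j.left_contig != j.right_contig:
            inter.append(j)
            continue
        if j.left_contig not in bins:
            raise DataError(f"junction on unknown contig {j.left_contig!r}")
        idx = j.left_pos // bin_size
        bins[j.left_contig][idx] += 1
    return {"bins": bins, "inter_contig": inter, "bin_size": bin_size}
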