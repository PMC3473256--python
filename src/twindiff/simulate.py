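"""Ground-truthed twin-genome simulator.

Generates a matched pair of call sets — a germline "genomic" sample and its
low-passage lymphoblastoid cell line ("cellline") derivative — together with
coverage windows, junction tables, a known-variant catalogue, a toy gene
model, unmapped read sets and complete truth labels, so the whole comparison
pipeline can be exercised without any external data.

What the twin pair emulates:

* shared germline variation (SNP/ins/del/sub at human-scale per-bp rates,
  het fraction ~0.61);
* cell-line-private novel SNPs (uniformly placed, absent from the known
  catalogue);
* technical noise: false-positive calls at ~1 per 150 kb per sample with
  stochastically lower call quality than true calls, plus rare dropped
  (false-negative) germline calls;
* contiguous no-call blocks per sample (~3% of the genome);
* B-cell-style copy-number losses private to the cell line and a 9-fold
  mitochondrial amplification;
* episomal EBV: viral-derived unmapped reads in the cell line only.

All randomness flows from one integer seed; per-stage substreams are derived
with fixed offsets, so identical configs and seeds give byte-identical
output files.
"""

from __future__ import annotations

import bisect
import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import io as tio
from .core import (
    CallSet,
    ConfigError,
    Junction,
    GeneModel,
    KnownVariantSet,
    PloidySegment,
    ReferenceGenome,
    VariantCall,
    revcomp,
)
from .structural import estimate_ploidy

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed per-stage substream offsets
_STAGES = {
    "reference": 11,
    "germline": 12,
    "genes": 13,
    "cnv": 14,
    "junctions": 15,
    "twin_genomic": 16,
    "twin_cellline": 17,
    "somatic": 18,
    "known": 19,
    "coverage_genomic": 20,
    "coverage_cellline": 21,
    "reads_genomic": 22,
    "reads_cellline": 23,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGES[stage], int(seed)])


def _default_contigs() -> dict[str, int]:
    return {
        "chr1": 1_200_000,
        "chr2": 800_000,
        "chrX": 300_000,
        "chrM": 16_000,
        "EBV": 40_000,
    }


def _default_classes() -> dict[str, str]:
    return {
        "chr1": "autosome",
        "chr2": "autosome",
        "chrX": "sexchrom",
        "chrM": "mito",
        "EBV": "viral",
    }


def _default_known_inclusion() -> dict[str, float]:
    # one minus the expected novel rate per variant type
    return {"snp": 0.951, "ins": 0.811, "del": 0.761, "sub": 0.690}


@dataclass
class SimulationConfig:
    """Study conditions for the twin-genome simulation (defaults are the
    conditions every acceptance property is evaluated under)."""

    contigs: dict[str, int] = field(default_factory=_default_contigs)
    contig_class: dict[str, str] = field(default_factory=_default_classes)
    snp_rate: float = 1.0e-3
    ins_rate: float = 5.6e-5
    del_rate: float = 6.1e-5
    sub_rate: float = 2.1e-5
    het_fraction: float = 0.61
    ts_probability: float = 0.68
    technical_error_rate: float = 1.0 / 150_000
    fn_rate: float = 5.0e-4
    half_call_rate: float = 0.005
    no_call_fraction: float = 0.03
    no_call_block_bp: int = 5_000
    somatic_snp_count: int = 300
    mito_amplification: float = 9.0
    viral_copies: float = 2.0
    autosomal_depth: float = 40.0
    read_length: int = 100
    junk_read_count: int = 300
    coverage_noise_sd: float = 0.03
    window_size: int = 2_000
    known_inclusion: dict[str, float] = field(default_factory=_default_known_inclusion)
    n_genes: int = 30
    cellline_haploid_losses: int = 3
    cellline_deletions: int = 1
    loss_length: int = 100_000
    shared_junction_count: int = 10
    artifact_junction_count: int = 5
    unique_junction_count: int = 2
    low_support_junction_count: int = 2
    true_quality_mean: float = 65.0
    true_quality_sd: float = 10.0
    noise_quality_mean: float = 25.0
    noise_quality_sd: float = 8.0
    min_quality: float = 3.0
    normal_ref_quality: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ConfigError("at least one contig is required")
        for name in self.contigs:
            if name not in self.contig_class:
                raise ConfigError(f"contig {name!r} lacks a contig class")
        for rate in (
            self.snp_rate,
            self.ins_rate,
            self.del_rate,
            self.sub_rate,
            self.het_fraction,
            self.technical_error_rate,
            self.fn_rate,
            self.half_call_rate,
            self.no_call_fraction,
            self.ts_probability,
        ):
            if not (0.0 <= rate <= 1.0):
                raise ConfigError(f"rate {rate!r} outside [0, 1]")
        if self.somatic_snp_count < 0 or self.viral_copies < 0:
            raise ConfigError("counts must be non-negative")

    @property
    def autosomes(self) -> list[str]:
        return [c for c, k in self.contig_class.items() if k == "autosome"]

    @property
    def viral_contig(self) -> Optional[str]:
        for c, k in self.contig_class.items():
            if k == "viral":
                return c
        return None

    def nonviral_length(self) -> int:
        return sum(
            l for c, l in self.contigs.items() if self.contig_class[c] != "viral"
        )

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class TruthLabels:
    """Ground truth for every difference between the emitted twin call sets."""

    origin: dict[tuple, str] = field(default_factory=dict)
    somatic_keys: list[tuple] = field(default_factory=list)
    dropped: dict[str, list[tuple]] = field(default_factory=dict)
    noise_keys: dict[str, list[tuple]] = field(default_factory=dict)
    cnv_truth: dict[str, list[dict]] = field(default_factory=dict)
    junction_truth: dict[str, list[dict]] = field(default_factory=dict)
    viral_copies: dict[str, float] = field(default_factory=dict)
    mito_relative_coverage: dict[str, float] = field(default_factory=dict)

    def difference_keys(self) -> set[tuple]:
        keys = set(self.somatic_keys)
        for ks in self.dropped.values():
            keys.update(ks)
        for ks in self.noise_keys.values():
            keys.update(ks)
        return keys

    def to_json(self, path: str) -> None:
        def enc_keys(keys):
            return [":".join(map(str, k)) for k in keys]

        payload = {
            "somatic_keys": enc_keys(self.somatic_keys),
            "dropped": {s: enc_keys(v) for s, v in self.dropped.items()},
            "noise_keys": {s: enc_keys(v) for s, v in self.noise_keys.items()},
            "cnv_truth": self.cnv_truth,
            "junction_truth": self.junction_truth,
            "viral_copies": self.viral_copies,
            "mito_relative_coverage": self.mito_relative_coverage,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class GermlineTemplate:
    calls: list[VariantCall]
    known_flags: list[bool]  # parallel to calls


# ---------------------------------------------------------------------------
# reference and germline


def simulate_reference(cfg: SimulationConfig) -> ReferenceGenome:
    """I.i.d. uniform A/C/G/T sequence for every configured contig."""
    if not any(
        cfg.contigs[c] >= 10_000 for c in cfg.autosomes
    ):
        raise ConfigError("need at least one autosome of >= 10 kb")
    rng = _rng(cfg.seed, "reference")
    contigs = {}
    for name in cfg.contigs:
        n = cfg.contigs[name]
        contigs[name] = _BASES[rng.integers(0, 4, size=n)].tobytes().decode()
    return ReferenceGenome(contigs=contigs, contig_class=dict(cfg.contig_class))


class _Occupancy:
    """Coarse collision grid: keeps placed variants >= one bucket apart."""

    BUCKET = 32

    def __init__(self) -> None:
        self._buckets: dict[str, set[int]] = {}

    def free(self, contig: str, pos: int) -> bool:
        b = pos // self.BUCKET
        taken = self._buckets.get(contig, set())
        return not any(b + d in taken for d in (-1, 0, 1))

    def take(self, contig: str, pos: int) -> None:
        self._buckets.setdefault(contig, set()).add(pos // self.BUCKET)


def _random_snp_alt(ref_base: str, rng: np.random.Generator, ts_prob: float) -> str:
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    if rng.random() < ts_prob:
        return transitions[ref_base]
    purine = ref_base in "AG"
    choices = ["C", "T"] if purine else ["A", "G"]
    return choices[int(rng.integers(0, 2))]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _quality(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    return float(max(floor, rng.normal(mean, sd)))


def simulate_individual(
    ref: ReferenceGenome, cfg: SimulationConfig
) -> GermlineTemplate:
    """Place germline variants (no per-haplotype overlap) with het/hom
    zygosity, transition-biased SNP alleles and per-type known-catalogue
    membership flags. Sex chromosomes receive no diploid variant calls."""
    rng = _rng(cfg.seed, "germline")
    occupied = _Occupancy()
    calls: list[VariantCall] = []
    flags: list[bool] = []
    margin = 50
    rates = {
        "snp": cfg.snp_rate,
        "ins": cfg.ins_rate,
        "del": cfg.del_rate,
        "sub": cfg.sub_rate,
    }
    for contig in cfg.contigs:
        cls = cfg.contig_class[contig]
        if cls in ("viral", "sexchrom"):
            continue
        length = cfg.contigs[contig]
        if length <= 2 * margin:
            continue
        requested = 0
        placed = 0
        proposals: list[tuple[int, str]] = []
        for vt, rate in rates.items():
            n = int(rng.poisson(rate * length))
            requested += n
            positions = rng.integers(margin, length - margin, size=n)
            proposals.extend((int(p), vt) for p in positions)
        proposals.sort()
        for pos, vt in proposals:
            if not occupied.free(contig, pos):
                continue
            call, _ = _make_germline_call(ref, contig, pos, vt, cfg, rng)
            if call is None:
                continue
            occupied.take(contig, pos)
            calls.append(call)
            flags.append(bool(rng.random() < cfg.known_inclusion[vt]))
            placed += 1
        if requested and placed < 0.5 * requested:
            raise ConfigError(
                f"variant rates too high to place without overlap on {contig} "
                f"({placed}/{requested} placed)"
            )
    order = sorted(range(len(calls)), key=lambda i: (calls[i].contig, calls[i].begin))
    return GermlineTemplate(
        calls=[calls[i] for i in order], known_flags=[flags[i] for i in order]
    )


def _make_germline_call(ref, contig, pos, vt, cfg, rng):
    het = rng.random() < cfg.het_fraction
    qual = _quality(rng, cfg.true_quality_mean, cfg.true_quality_sd, cfg.min_quality)
    if vt == "snp":
        b = ref.fetch(contig, pos, pos + 1)
        alt = _random_snp_alt(b, rng, cfg.ts_probability)
        a1, a2 = (b, alt) if het else (alt, alt)
        begin, end = pos, pos + 1
    elif vt == "ins":
        seq = _random_seq(rng, int(rng.integers(1, 7)))
        a1, a2 = (seq, "") if het else (seq, seq)
        begin = end = pos
    elif vt == "del":
        span = int(rng.integers(1, 7))
        begin, end = pos, pos + span
        ref_seq = ref.fetch(contig, begin, end)
        a1, a2 = ("", ref_seq) if het else ("", "")
    else:  # sub
        span = int(rng.integers(2, 7))
        begin, end = pos, pos + span
        ref_seq = ref.fetch(contig, begin, end)
        alt = _random_seq(rng, int(rng.integers(1, 7)))
        tries = 0
        while alt == ref_seq and tries < 10:
            alt = _random_seq(rng, int(rng.integers(1, 7)))
            tries += 1
        if alt == ref_seq:
            return None, None
        a1, a2 = (alt, ref_seq) if het else (alt, alt)
    if het and rng.random() < 0.5:
        a1, a2 = a2, a1
    return (
        VariantCall(contig, begin, end, vt, a1, a2, qual),
        het,
    )


def simulate_genes(ref: ReferenceGenome, cfg: SimulationConfig) -> list[GeneModel]:
    """Non-overlapping toy genes with 1-3 CDS exons, total length % 3 == 0."""
    rng = _rng(cfg.seed, "genes")
    genes: list[GeneModel] = []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.autosomes}
    attempts = 0
    while len(genes) < cfg.n_genes and attempts < cfg.n_genes * 50:
        attempts += 1
        contig = cfg.autosomes[int(rng.integers(0, len(cfg.autosomes)))]
        length = cfg.contigs[contig]
        n_exons = int(rng.integers(1, 4))
        exon_lens = [int(rng.integers(30, 201)) * 3 for _ in range(n_exons)]
        introns = [int(rng.integers(50, 501)) for _ in range(n_exons - 1)]
        total_span = sum(exon_lens) + sum(introns)
        if total_span + 200 >= length:
            continue
        start = int(rng.integers(100, length - total_span - 100))
        intervals = []
        cursor = start
        for i, el in enumerate(exon_lens):
            intervals.append((cursor, cursor + el))
            cursor += el
            if i < len(introns):
                cursor += introns[i]
        span = (start, cursor)
        if any(span[0] < e and span[1] > b for b, e in placed[contig]):
            continue
        placed[contig].append(span)
        strand = "+" if rng.random() < 0.5 else "-"
        ordered = intervals if strand == "+" else intervals[::-1]
        genes.append(
            GeneModel(
                gene_id=f"gene{len(genes) + 1}",
                contig=contig,
                strand=strand,
                cds_intervals=ordered,
                phase=0,
            )
        )
    genes.sort(key=lambda g: (g.contig, g.genomic_span()))
    return genes


# ---------------------------------------------------------------------------
# cell-line CNVs and junctions


def _simulate_cnv_truth(cfg: SimulationConfig) -> list[dict]:
    rng = _rng(cfg.seed, "cnv")
    w = cfg.window_size
    losses: list[dict] = []
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.autosomes}
    wanted = [1] * cfg.cellline_haploid_losses + [0] * cfg.cellline_deletions
    for ploidy in wanted:
        for _ in range(200):
            contig = cfg.autosomes[int(rng.integers(0, len(cfg.autosomes)))]
            length = cfg.contigs[contig]
            if length < cfg.loss_length + 4 * w:
                continue
            n_windows = (length - cfg.loss_length) // w
            begin = int(rng.integers(1, n_windows)) * w
            end = begin + cfg.loss_length
            if any(begin < e and end > b for b, e in taken[contig]):
                continue
            taken[contig].append((begin, end))
            losses.append(
                {"contig": contig, "begin": begin, "end": end, "ploidy": ploidy}
            )
            break
        else:
            raise ConfigError("could not place cell-line CNV losses")
    return losses


def _random_junction(
    rng: np.random.Generator, cfg: SimulationConfig, support: int, panel: float
) -> Junction:
    nonviral = [c for c in cfg.contigs if cfg.contig_class[c] != "viral"]
    inter = rng.random() < 0.4 and len(nonviral) > 1
    lc = nonviral[int(rng.integers(0, len(nonviral)))]
    if inter:
        others = [c for c in nonviral if c != lc]
        rc = others[int(rng.integers(0, len(others)))]
        lp = int(rng.integers(1_000, cfg.contigs[lc] - 1_000))
        rp = int(rng.integers(1_000, cfg.contigs[rc] - 1_000))
    else:
        rc = lc
        length = cfg.contigs[lc]
        span = int(rng.integers(10_000, max(10_001, length // 2)))
        lp = int(rng.integers(1_000, max(1_001, length - span - 1_000)))
        rp = lp + span
    strands = ["+", "-"]
    ls = strands[int(rng.integers(0, 2))]
    rs = strands[int(rng.integers(0, 2))]
    transition = _random_seq(rng, int(rng.integers(0, 25)))
    return Junction(
        left_contig=lc,
        left_pos=lp,
        left_strand=ls,
        right_contig=rc,
        right_pos=rp,
        right_strand=rs,
        transition_seq=transition,
        support=support,
        panel_frequency=panel,
    )


def _jitter(j: Junction, rng: np.random.Generator, amount: int = 30) -> Junction:
    return dataclasses.replace(
        j,
        left_pos=j.left_pos + int(rng.integers(-amount, amount + 1)),
        right_pos=j.right_pos + int(rng.integers(-amount, amount + 1)),
        support=max(1, j.support + int(rng.integers(-3, 4))),
    )


def simulate_junctions(cfg: SimulationConfig):
    """Per-sample junction tables plus the truth list of reportable
    sample-unique junctions (support above threshold, panel frequency below
    the artifact cutoff)."""
    rng = _rng(cfg.seed, "junctions")
    genomic: list[Junction] = []
    cellline: list[Junction] = []
    truth: dict[str, list[dict]] = {"genomic": [], "cellline": []}
    for _ in range(cfg.shared_junction_count):
        j = _random_junction(rng, cfg, int(rng.poisson(25) + 10), float(rng.uniform(0, 0.5)))
        genomic.append(_jitter(j, rng))
        cellline.append(_jitter(j, rng))
    for _ in range(cfg.artifact_junction_count):
        j = _random_junction(rng, cfg, int(rng.poisson(25) + 10), float(rng.uniform(0.75, 1.0)))
        genomic.append(_jitter(j, rng))
        cellline.append(_jitter(j, rng))
    for sample, bucket in (("genomic", genomic), ("cellline", cellline)):
        for _ in range(cfg.unique_junction_count):
            j = _random_junction(
                rng, cfg, int(rng.integers(12, 40)), float(rng.uniform(0, 0.3))
            )
            bucket.append(j)
            truth[sample].append(dataclasses.asdict(j))
        for _ in range(cfg.low_support_junction_count):
            bucket.append(
                _random_junction(rng, cfg, int(rng.integers(1, 10)), float(rng.uniform(0, 0.3)))
            )
    key = lambda j: (j.left_contig, j.left_pos, j.right_contig, j.right_pos)
    genomic.sort(key=key)
    cellline.sort(key=key)
    return genomic, cellline, truth


# ---------------------------------------------------------------------------
# twin call sets


class _Blocks:
    """Sorted disjoint interval list per contig with overlap queries."""

    def __init__(self) -> None:
        self._iv: dict[str, list[tuple[int, int]]] = {}

    def add(self, contig: str, begin: int, end: int) -> bool:
        ivs = self._iv.setdefault(contig, [])
        i = bisect.bisect_left(ivs, (begin, end))
        for j in (i - 1, i):
            if 0 <= j < len(ivs) and ivs[j][0] < end and ivs[j][1] > begin:
                return False
        ivs.insert(i, (begin, end))
        return True

    def overlaps(self, contig: str, begin: int, end: int) -> bool:
        ivs = self._iv.get(contig, [])
        i = bisect.bisect_left(ivs, (begin,)) - 1
        for j in (i, i + 1):
            if 0 <= j < len(ivs) and ivs[j][0] < end and ivs[j][1] > begin:
                return True
        return False

    def items(self):
        for contig, ivs in self._iv.items():
            for b, e in ivs:
                yield contig, b, e


def _place_no_call_blocks(cfg, rng) -> _Blocks:
    blocks = _Blocks()
    nonviral = [
        (c, l) for c, l in cfg.contigs.items() if cfg.contig_class[c] != "viral"
    ]
    total = sum(l for _, l in nonviral)
    target = cfg.no_call_fraction * total
    lengths = np.array([l for _, l in nonviral], dtype=float)
    weights = lengths / lengths.sum()
    placed_bp = 0
    attempts = 0
    while placed_bp + cfg.no_call_block_bp <= target and attempts < 10_000:
        attempts += 1
        idx = int(rng.choice(len(nonviral), p=weights))
        contig, length = nonviral[idx]
        if length <= cfg.no_call_block_bp + 2:
            continue
        begin = int(rng.integers(1, length - cfg.no_call_block_bp - 1))
        if blocks.add(contig, begin, begin + cfg.no_call_block_bp):
            placed_bp += cfg.no_call_block_bp
    return blocks


def _overlaps_call(blocks: _Blocks, c: VariantCall) -> bool:
    end = c.end if c.end > c.begin else c.begin + 1
    return blocks.overlaps(c.contig, c.begin, end)


def derive_twin_callsets(
    germline: GermlineTemplate,
    ref: ReferenceGenome,
    cfg: SimulationConfig,
):
    """Derive the genomic and cell-line call sets from one germline template.

    Both samples inherit the germline variants; each independently loses
    calls to no-call blocks and rare false negatives, gains low-quality
    false-positive noise calls, and the cell line additionally gains
    ``somatic_snp_count`` private novel het SNPs. Returns
    ``(genomic, cellline, truth)``.
    """
    truth = TruthLabels()
    truth.viral_copies = {"genomic": 0.0, "cellline": float(cfg.viral_copies)}
    truth.mito_relative_coverage = {
        "genomic": 1.0,
        "cellline": float(cfg.mito_amplification),
    }
    truth.cnv_truth = {"genomic": [], "cellline": _simulate_cnv_truth(cfg)}
    for call in germline.calls:
        for k in call.key(ref):
            truth.origin[k] = "germline"

    occupied = _Occupancy()
    for c in germline.calls:
        occupied.take(c.contig, c.begin)

    # somatic SNPs are drawn once, then subject to the cell line's no-call
    # masking like any other call
    rng_som = _rng(cfg.seed, "somatic")
    somatic_calls: list[VariantCall] = []
    nonviral = [
        (c, l)
        for c, l in cfg.contigs.items()
        if cfg.contig_class[c] not in ("viral", "sexchrom")
    ]
    lengths = np.array([l for _, l in nonviral], dtype=float)
    weights = lengths / lengths.sum()
    capacity = int(lengths.sum()) // (3 * _Occupancy.BUCKET)
    if cfg.somatic_snp_count > capacity:
        raise ConfigError(
            f"somatic count {cfg.somatic_snp_count} exceeds the ~{capacity} "
            "loci placeable without overlap"
        )
    guard = 0
    while len(somatic_calls) < cfg.somatic_snp_count:
        guard += 1
        if guard > cfg.somatic_snp_count * 50 + 1000:
            raise ConfigError("somatic count exceeds available loci")
        idx = int(rng_som.choice(len(nonviral), p=weights))
        contig, length = nonviral[idx]
        pos = int(rng_som.integers(50, length - 50))
        if not occupied.free(contig, pos):
            continue
        b = ref.fetch(contig, pos, pos + 1)
        alt = _random_snp_alt(b, rng_som, cfg.ts_probability)
        a1, a2 = (b, alt) if rng_som.random() < 0.5 else (alt, b)
        qual = _quality(
            rng_som, cfg.true_quality_mean, cfg.true_quality_sd, cfg.min_quality
        )
        call = VariantCall(contig, pos, pos + 1, "snp", a1, a2, qual)
        occupied.take(contig, pos)
        somatic_calls.append(call)

    samples = {}
    for sample in ("genomic", "cellline"):
        rng = _rng(cfg.seed, f"twin_{sample}")
        blocks = _place_no_call_blocks(cfg, rng)
        calls: list[VariantCall] = []
        dropped: list[tuple] = []
        partial_bp = 0
        base_calls = list(germline.calls)
        if sample == "cellline":
            base_calls = base_calls + somatic_calls
        for c in base_calls:
            if _overlaps_call(blocks, c):
                continue  # masked by a no-call region
            if rng.random() < cfg.fn_rate:
                dropped.extend(c.key(ref))
                continue
            if (
                cfg.half_call_rate > 0
                and c.is_fully_called()
                and rng.random() < cfg.half_call_rate
            ):
                if rng.random() < 0.5:
                    c = dataclasses.replace(c, allele1=None)
                else:
                    c = dataclasses.replace(c, allele2=None)
                partial_bp += max(1, c.end - c.begin)
            calls.append(c)

        # technical noise: uniformly placed low-quality FP snps / 1 bp indels
        noise_keys: list[tuple] = []
        n_noise = int(rng.poisson(cfg.technical_error_rate * cfg.nonviral_length()))
        placed = 0
        guard = 0
        while placed < n_noise and guard < n_noise * 200 + 1000:
            guard += 1
            idx = int(rng.choice(len(nonviral), p=weights))
            contig, length = nonviral[idx]
            pos = int(rng.integers(50, length - 50))
            if not occupied.free(contig, pos) or blocks.overlaps(
                contig, pos, pos + 2
            ):
                continue
            u = rng.random()
            qual = _quality(
                rng, cfg.noise_quality_mean, cfg.noise_quality_sd, cfg.min_quality
            )
            if u < 0.2:
                b = ref.fetch(contig, pos, pos + 1)
                alt = _random_snp_alt(b, rng, cfg.ts_probability)
                a1, a2 = (b, alt) if rng.random() < 0.5 else (alt, b)
                call = VariantCall(contig, pos, pos + 1, "snp", a1, a2, qual)
            elif u < 0.6:
                seq = _random_seq(rng, 1)
                a1, a2 = (seq, "") if rng.random() < 0.5 else ("", seq)
                call = VariantCall(contig, pos, pos, "ins", a1, a2, qual)
            else:
                ref_seq = ref.fetch(contig, pos, pos + 1)
                a1, a2 = ("", ref_seq) if rng.random() < 0.5 else (ref_seq, "")
                call = VariantCall(contig, pos, pos + 1, "del", a1, a2, qual)
            occupied.take(contig, pos)
            calls.append(call)
            noise_keys.extend(call.key(ref))
            placed += 1

        for contig, b, e in blocks.items():
            calls.append(VariantCall(contig, b, e, "no-call", None, None, 0.0))

        total = cfg.nonviral_length()
        nocalled = sum(e - b for _, b, e in blocks.items()) / total
        partial = partial_bp / total
        cs = CallSet(
            sample_id=sample,
            calls=calls,
            fully_called_fraction=1.0 - nocalled - partial,
            partially_called_fraction=partial,
            nocalled_fraction=nocalled,
        )
        samples[sample] = cs
        truth.dropped[sample] = dropped
        truth.noise_keys[sample] = noise_keys
        for k in noise_keys:
            truth.origin[k] = "noise-FP"

    emitted_cellline = {
        k for c in samples["cellline"].calls if c.vartype == "snp" for k in c.key(ref)
    }
    truth.somatic_keys = [
        k for c in somatic_calls for k in c.key(ref) if k in emitted_cellline
    ]
    for k in truth.somatic_keys:
        truth.origin[k] = "somatic"
    return samples["genomic"], samples["cellline"], truth


def simulate_known_set(
    germline: GermlineTemplate, ref: ReferenceGenome
) -> KnownVariantSet:
    """Known-variant catalogue: the flagged subset of germline variation.
    Cell-line somatic SNPs and noise calls are never included, so they are
    novel by construction."""
    keys = []
    for call, known in zip(germline.calls, germline.known_flags):
        if known:
            keys.extend(call.key(ref))
    return KnownVariantSet.from_keys(keys)


# ---------------------------------------------------------------------------
# coverage and reads


def simulate_coverage(
    ref: ReferenceGenome,
    cfg: SimulationConfig,
    sample: str,
    truth: TruthLabels,
) -> pd.DataFrame:
    """Per-2 kb relative-coverage windows for one sample (viral contig
    excluded: its reads are unmapped by definition)."""
    rng = _rng(cfg.seed, f"coverage_{sample}")
    w = cfg.window_size
    rows = []
    for contig in cfg.contigs:
        cls = cfg.contig_class[contig]
        if cls == "viral":
            continue
        length = cfg.contigs[contig]
        n = length // w
        base_ploidy = 1 if cls == "sexchrom" else 2
        true_cov = np.full(n, base_ploidy / 2.0)
        if cls == "mito":
            true_cov[:] = truth.mito_relative_coverage[sample]
        if sample == "cellline":
            for cnv in truth.cnv_truth["cellline"]:
                if cnv["contig"] != contig:
                    continue
                i0, i1 = cnv["begin"] // w, cnv["end"] // w
                true_cov[i0:i1] = cnv["ploidy"] / 2.0
        cov = np.maximum(true_cov + rng.normal(0.0, cfg.coverage_noise_sd, size=n), 0.0)
        for i in range(n):
            rows.append((contig, i * w, (i + 1) * w, float(cov[i])))
    return pd.DataFrame(rows, columns=tio.COVERAGE_COLUMNS)


def simulate_unmapped_reads(
    ref: ReferenceGenome, cfg: SimulationConfig, sample: str
) -> list[SeqRecord]:
    """Unmapped-read set: viral-derived reads at depth = viral copies x
    autosomal depth (cell line only) plus random junk reads (both samples).
    Read ids encode the simulation origin (``viral``/``junk``) as ground
    truth for screening tests."""
    viral_contig = cfg.viral_contig
    if viral_contig is None:
        raise ConfigError("no viral contig configured")
    viral_seq = ref.contigs[viral_contig]
    if cfg.read_length > len(viral_seq):
        raise ConfigError("read length exceeds the viral genome length")
    rng = _rng(cfg.seed, f"reads_{sample}")
    copies = cfg.viral_copies if sample == "cellline" else 0.0
    viral_depth = copies * cfg.autosomal_depth
    n_viral = int(round(viral_depth * len(viral_seq) / cfg.read_length))
    reads: list[SeqRecord] = []
    if n_viral:
        starts = rng.integers(0, len(viral_seq) - cfg.read_length + 1, size=n_viral)
        flips = rng.random(n_viral) < 0.5
        for i, (s, flip) in enumerate(zip(starts, flips)):
            seq = viral_seq[s : s + cfg.read_length]
            if flip:
                seq = revcomp(seq)
            reads.append(_read_record(f"{sample}:viral:{i}", seq))
    for i in range(cfg.junk_read_count):
        reads.append(_read_record(f"{sample}:junk:{i}", _random_seq(rng, cfg.read_length)))
    return reads


def _read_record(rid: str, seq: str) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=rid, description="")
    rec.letter_annotations["phred_quality"] = [30] * len(seq)
    return rec


# ---------------------------------------------------------------------------
# full bundle


@dataclass
class SimulationBundle:
    config: SimulationConfig
    ref: ReferenceGenome
    genes: list[GeneModel]
    genomic: CallSet
    cellline: CallSet
    known: KnownVariantSet
    truth: TruthLabels
    coverage: dict[str, pd.DataFrame]
    segments: dict[str, list[PloidySegment]]
    junctions: dict[str, list[Junction]]
    reads: dict[str, list[SeqRecord]]


def simulate_bundle(cfg: SimulationConfig, with_reads: bool = True) -> SimulationBundle:
    """Run every simulation stage and return the in-memory bundle."""
    ref = simulate_reference(cfg)
    germline = simulate_individual(ref, cfg)
    genes = simulate_genes(ref, cfg)
    genomic, cellline, truth = derive_twin_callsets(germline, ref, cfg)
    known = simulate_known_set(germline, ref)
    jg, jc, jtruth = simulate_junctions(cfg)
    truth.junction_truth = jtruth
    coverage = {
        s: simulate_coverage(ref, cfg, s, truth) for s in ("genomic", "cellline")
    }
    segments = {
        s: estimate_ploidy(coverage[s], sigma=cfg.coverage_noise_sd, window_size=cfg.window_size)
        for s in ("genomic", "cellline")
    }
    reads = (
        {s: simulate_unmapped_reads(ref, cfg, s) for s in ("genomic", "cellline")}
        if with_reads
        else {"genomic": [], "cellline": []}
    )
    return SimulationBundle(
        config=cfg,
        ref=ref,
        genes=genes,
        genomic=genomic,
        cellline=cellline,
        known=known,
        truth=truth,
        coverage=coverage,
        segments=segments,
        junctions={"genomic": jg, "cellline": jc},
        reads=reads,
    )


def write_bundle(bundle: SimulationBundle, outdir: str) -> dict[str, str]:
    """Write every bundle artifact as plain-text files; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    paths = {}
    tio.write_fasta(bundle.ref, p("reference.fasta"))
    paths["reference"] = p("reference.fasta")
    viral_contig = bundle.config.viral_contig
    if viral_contig:
        viral = ReferenceGenome(
            contigs={viral_contig: bundle.ref.contigs[viral_contig]},
            contig_class={viral_contig: "viral"},
        )
        tio.write_fasta(viral, p("viral.fasta"))
        paths["viral"] = p("viral.fasta")
    tio.write_genemodel(bundle.genes, p("genes.gff3"))
    paths["genes"] = p("genes.gff3")
    tio.write_known_set(bundle.known, p("known.tsv"))
    paths["known"] = p("known.tsv")
    for sample in ("genomic", "cellline"):
        cs = getattr(bundle, sample)
        tio.write_callset(cs, p(f"{sample}.var.tsv"), "cgi-var-tsv")
        tio.write_coverage_windows(bundle.coverage[sample], p(f"{sample}.coverage.tsv"))
        tio.write_segments(bundle.segments[sample], p(f"{sample}.segments.tsv"))
        tio.write_junctions(bundle.junctions[sample], p(f"{sample}.junctions.tsv"))
        tio.write_reads(bundle.reads[sample], p(f"{sample}.unmapped.fastq"))
        paths[f"{sample}_callset"] = p(f"{sample}.var.tsv")
        paths[f"{sample}_coverage"] = p(f"{sample}.coverage.tsv")
        paths[f"{sample}_segments"] = p(f"{sample}.segments.tsv")
        paths[f"{sample}_junctions"] = p(f"{sample}.junctions.tsv")
        paths[f"{sample}_reads"] = p(f"{sample}.unmapped.fastq")
    bundle.truth.to_json(p("truth.json"))
    paths["truth"] = p("truth.json")
    bundle.config.to_yaml(p("config.yaml"))
    paths["config"] = p("config.yaml")
    return paths
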