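# Methods

## The comparison problem

Two whole-genome call sets from the same individual — fresh-blood germline
DNA and its EBV-transformed lymphoblastoid cell line — are expected to be
nearly identical; the interesting questions are *where* they differ, whether
the differences exceed the platform's technical noise, and whether any are
plausibly transformation-driven (novel somatic SNPs, B-cell copy-number
losses, mitochondrial amplification, episomal viral DNA). Every stage of the
pipeline is organised around separating those signals from calling noise.

## Haplotype-aware variant diffing

**Superloci.** Comparing call sets record-by-record is unsound: equivalent
indel alignments, split representations and phase differences all create
false differences. Instead, variant records from both samples whose
reference spans lie within `merge_gap` (default 20 bp, configurable) of each
other are merged transitively into superloci; reference-called territory
between superloci is skipped; no-call records intersecting a superlocus are
attached to it.

**Classification.** For each sample the two haplotype sequences over the
superlocus are reconstructed (a no-called haplotype stretch becomes a
wildcard matching any DNA string). Verdicts, in decision order:

1. both samples fully called and haplotype multisets equal → `identical`
   (haplotype labels carry no cross-sample meaning);
2. one sample entirely reference-called, the other carrying a variant →
   `onlyA` / `onlyB`;
3. both fully called and equal after re-phasing some subset of individual
   het calls → `phase-mismatch` (same alleles at the same loci, arranged
   differently across haplotypes);
4. not fully called, and some completion of the no-called stretches makes
   the samples identical → `consistent` (decided exactly by a wildcard
   pattern-intersection dynamic program, not by sampling completions);
5. otherwise → `mismatch`.

Enumeration is bounded: superloci longer than 10 kb or with more than 12
variant records are classified conservatively as `mismatch` with a warning.
Indels are left-normalized (shifted left while the preceding reference base
equals the last base of the variable sequence) before keying, so equivalent
representations share identity keys; classification itself is
representation-invariant because it compares reconstructed sequences. The
`SuperlocusStats` summary counts superloci (not variant records), and its
identical fraction uses the denominator identical + onlyA + onlyB +
mismatch + phase-mismatch; `consistent` superloci are excluded as not fully
called.

**Somatic output and the SomaticScore.** With one sample designated "normal"
and the other "tumor", every tumor variant whose superlocus carries no
normal variant becomes a candidate; candidates over normal no-calls or with
half-called tumor genotypes are flagged and excluded from counting. The raw
confidence of a candidate is the joint correctness probability of the tumor
variant call and the normal reference call, computed from phred-scaled
qualities (the normal reference quality is a constant, default 60, since
reference territory carries no per-record quality). Because no closed-form
score with the published sensitivity contract exists, the score is defined
*by* that contract: the SomaticScore is the empirical quantile of the raw
confidence among labelled true somatic variants from a calibration
simulation. Scores of true somatic variants are then uniform on [0, 1], so
thresholding at x retains a fraction 1 − x of them. The calibration sample
is always drawn from an independent simulation seed, never from the data
being scored. The CT/GT sweep runs both tumor/normal assignments across a
cutoff grid; the GT direction (germline as "tumor") estimates technical
noise, and the CT/GT ratio rises with the cutoff because noise candidates
carry stochastically lower qualities.

## Structural comparison

**Ploidy.** Relative coverage (ratio to the autosomal median) is averaged in
2 kb windows; ploidy = round(2 × relative coverage), clamped at 0; adjacent
equal-ploidy windows merge. The segment confidence is

    ploidy_score = sqrt(n_windows) · |mean coverage − nearest alternative ploidy / 2| / σ

with σ = 0.03 by default, matching the simulator's per-window coverage noise
(2 kb windows at 40× are low-variance). Only the score's ordering matters:
the reporting gate is strictly `ploidy_score > 40`. Under the defaults a
50-window (100 kb) haploid loss scores ≈ 59 and the 8-window chrM segment at
ploidy 18 scores ≈ 47, while a single noisy window would need an 8σ
excursion to even leave ploidy 2.

**CNV matching.** Each non-diploid segment of the reference sample above the
score gate is looked up in the other sample; a match requires *both*
endpoints within the 2 kb window (the strictest reading of the endpoint
rule — the alternative "either endpoint" reading was rejected as weaker).
Unmatched segments and matched segments with differing ploidy are reported
with both loci.

**Junctions.** The junction "score" is the discordant-pair support count.
Junctions seen in ≥ 75% of the sequencing panel are removed first as
platform artifacts. An A-junction is unique iff support ≥ 10, it is not a
deletion-like event (same contig, both arms `+`, right > left) spanning
< 500 bp, and no B-junction with support ≥ 0 matches both arms (same
contigs and strands, both coordinate offsets ≤ 200 bp). Self-comparison is
therefore always empty. Junction density is summarised in 5 Mb bins of the
left-arm position, inter-contig junctions listed separately.

## Functional classes and QC metrics

One canonical coding transcript per gene; overlapping transcripts are out of
scope. CDS SNPs are translated on the coding strand with the standard codon
table (synonymous / missense / nonsense / nonstop; for het calls with two
non-reference alleles the most severe class is reported). Length-changing
CDS variants are frame-shifting iff the net length change mod 3 ≠ 0.
Equal-length block substitutions inside a CDS are resolved by translation
but counted under the frame-preserving SUB row of the report, matching how
such tables are conventionally tallied. The "Nonsyn/syn SNP ratio" is
missense / synonymous — despite the name it excludes nonsense and nonstop
loci, which is the quotient the published per-class counts reproduce
exactly. The report's "Coding SNP/all SNP" and coding-indel rows are
computed from this package's own class counts; the corresponding published
rows do not recompute from any combination of published counts (their
coding-locus definition is unstated), so no equality with them is claimed.
Every derived ratio in a report recomputes exactly from the counts in the
same report, and the called-fraction triple sums to 1.

## Viral screen

A canonical 31-mer index (lexicographic minimum of k-mer and reverse
complement) of the viral contig replaces read alignment: presence/absence
plus a depth estimate is all the analysis needs, and exact k-mer
classification is orientation-independent and collision-free in practice
(random 100-mers hit a 40 kb index with probability ≪ 1). A read is viral
when ≥ 50% of its k-mers hit — lenient enough for read-edge effects, far
above the noise floor. Viral depth is total viral-classified bases over the
viral genome length; episome copy number = viral depth / autosomal depth.
Sequences of 9–30 nt (above the > 8 nt screening floor but below k) are
screened by exact substring search on both strands so the floor remains
meaningful at k = 31.

## Validation bound and regional distribution

For an n-of-N Sanger-style validation outcome the upper confidence bound on
the true-difference fraction is computed three ways: exact Clopper-Pearson
(default; for 0 confirmed of N the two-sided 95% bound is
1 − 0.025^(1/N) ≈ 0.0596 at N = 60), a one-sided variant
(1 − 0.05^(1/N) ≈ 0.0487), and Wilson. The method behind the published
"< 5.8%" figure is not recoverable, so no method is tuned toward it; all
three are reported. Candidate positions are binned (default 200 kb) with a
chi-square uniformity test whose expectations are proportional to bin
length, and bins within 5% of a contig end are flagged as a
telomere/centromere surrogate — synthetic contigs have no annotated
centromeres, so this is explicitly a stand-in. Uniformity is judged over
diploid territory only (the simulated sex chromosome carries no diploid
calls and would bias the test).

## The simulator: what it emulates, and what it does not

Defaults (one 2.3 Mb miniature genome: chr1 1.2 Mb, chr2 800 kb, chrX
300 kb, chrM 16 kb, plus a 40 kb viral contig):

| parameter | default | rationale |
|---|---|---|
| snp / ins / del / sub rate (per bp) | 1e-3 / 5.6e-5 / 6.1e-5 / 2.1e-5 | whole-genome per-type counts scaled to rate |
| het fraction | 0.61 | het/hom ratio ≈ 1.58 |
| transition probability | 0.68 | ts/tv ≈ 2.1 |
| technical error rate | 1/150,000 per bp | platform error ~1 in 100–200 kb |
| no-call fraction / block | 0.03, 5 kb blocks | ~3% no-called genome; contiguous blocks exercise the `consistent` verdict |
| known-catalogue inclusion | 0.951 / 0.811 / 0.761 / 0.690 | 1 − per-type novel rates |
| somatic SNP count | 300 | desk-scale cell-line-private load |
| mito amplification | 9× | cell-line chrM copy-number gain |
| viral copies / depth / read length | 2 / 40× / 100 bp | episomal EBV load |
| cell-line CNVs | 3 haploid losses + 1 deletion, 100 kb | B-cell-style losses |
| call quality (true / noise) | N(65, 10) / N(25, 8), floor 3 | noise concentrates at low confidence |

All randomness flows from one integer seed through fixed per-stage
substreams; identical configs give byte-identical output files. Somatic SNPs
are uniformly placed and constructed absent from the known catalogue; noise
false positives are uniformly placed SNPs/1-bp indels (0.2/0.4/0.4), false
negatives drop a germline call from one sample at rate 5e-4 per call, and
0.5% of calls are half-called. The sex chromosome is simulated as an
ordinary contig with ploidy-1 coverage and no diploid variant calls (the
compared genomes come from one male; hemizygous calling is out of scope).

What the simulator does **not** emulate — and hence what green tests do not
demonstrate about real data: sequence-context-dependent error (errors are
uniform, real errors cluster in repeats and near indels), alignment
ambiguity beyond left-normalizable indels, GC/mappability coverage waves,
segmental duplications and centromeric/telomeric repeat pathology, somatic
indels/SVs in the cell line, subclonal allele fractions, and linked phasing
errors. Genome-scale headline figures from hundreds of Gb of real data
(total variant counts, the specific 99.2% concordance, absolute CT/GT
counts) are size-dependent and deliberately not reproduced; the test suite
asserts the scale-free properties instead (self-comparison identity, oracle
equivalence of the classifier, score calibration, CT/GT asymmetry with
novelty, structural and viral truth recovery, exact derived-ratio and
confidence-bound arithmetic).

## Numerical and design choices

* Coordinates are 0-based half-open everywhere inside the package;
  conversion to 1-based formats (VCF, GFF3) is confined to I/O.
* Insertions anchor at `begin == end`; the non-reference allele of a
  deletion is the empty string; a record is `ref` only if both alleles
  equal the reference span.
* Pattern-intersection (for `consistent`) trims common concrete
  prefix/suffix, then runs an iterative reachability DP over pointer pairs;
  a 25M-state cap degrades to "incompatible" with a warning.
* Phase re-assignment enumeration for `phase-mismatch` enumerates subsets of
  sample A's het records only — swapping a record in B is equivalent to a
  swap of the matching record in A combined with the global pairing choice,
  and loci private to one sample can never rescue equality.
* Ties in phase assignment are existential: any assignment proving equality
  suffices.
* Calibration quantiles use midpoint ranks ((i + 0.5)/n) with linear
  interpolation, clipped to [0, 1]; scoring needs only the ordering of raw
  confidences, so log-space accumulation avoids float saturation near
  quality 70+.
* TSV floats are written with `repr` and parsed with pandas'
  `float_precision="round_trip"` so every reader/writer pair is a bijection;
  VCF QUAL is float32 on disk, the one tolerated round-trip lossy field.
* Zero denominators (ts/tv with no transversions, het/hom with no homs,
  ratios with empty classes) return null rather than raising.

## Known limitations

* Diploid-only model: `ploidy-mismatch` is defined but never produced, and
  hemizygous (male X/Y) variant calling is not modelled.
* One transcript per gene; splice-site and UTR consequences collapse to
  `noncoding`.
* The vcf-subset dialect cannot carry no-call region records, called-fraction
  metadata, or the vartype label of all-reference partial records; the
  cgi-var-tsv dialect is the lossless native format.
* Junction arms are assumed stored in canonical (left ≤ right) order;
  arm-swapped representations of the same junction are not unified.
* The k-mer viral screen detects presence and depth, not integration sites;
  gapped/divergent viral matches below ~97% identity per 31-mer would be
  missed.
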