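# twindiff

Whole-genome concordance analysis between an individual's germline DNA and a
derived, EBV-transformed lymphoblastoid cell line (LCL).

LCLs are the workhorse renewable DNA source of clinical genetics, but the
transformation step raises an obvious question: is the cell line's genome
still the donor's genome? `twindiff` implements the comparison pipeline used
to answer that question from two whole-genome call sets of the same
individual:

* **Haplotype-aware variant diffing.** Nearby calls from both samples are
  grouped into *superloci*; the two haplotype sequences of each sample are
  reconstructed over each superlocus and the superlocus is classified as
  `identical`, `consistent` (not fully called but reconcilable), `onlyA`/
  `onlyB`, `mismatch`, or `phase-mismatch` (same alleles, different phase).
  Indels are left-normalized so equivalent alignments never masquerade as
  differences.
* **Reciprocal somatic analysis with a calibrated score.** Treating the cell
  line as a "tumor" against the germline "normal" (CT), and the reverse (GT)
  as a technical-noise control, every tumor-only variant gets a SomaticScore
  s ∈ [0, 1] — the calibrated quantile of its joint call-correctness
  probability — such that filtering at score ≥ x retains a fraction 1 − x of
  true somatic variants (sensitivity = 1 − x).
* **Structural comparison.** Integer ploidy is estimated per 2 kb coverage
  window as round(2·relative coverage) and merged into scored segments; CNV
  calls with ploidyScore > 40 in one genome are matched in the other within
  a 2 kb endpoint window. Rearrangement junctions are diffed with support
  thresholds 10/0, a 200 bp compatibility distance, a 500 bp minimum
  deletion length, and removal of junctions seen in ≥ 75% of a sequencing
  panel (platform artifacts).
* **Functional annotation and QC metrics.** SNPs in coding sequence are
  classified synonymous/missense/nonsense/nonstop via the standard codon
  table; length-changing variants as frame-shifting/preserving by the
  net-length mod 3 rule. A two-column QC report covers ts/tv, het/hom
  ratios, novel rates against a dbSNP-surrogate catalogue, called-fraction
  triple, per-class coding locus counts and the derived ratios.
* **Viral screening.** Unmapped reads are classified against a canonical
  31-mer index of the viral (EBV-surrogate) genome; episome copy number is
  estimated as viral depth / autosomal depth, and long insertions plus
  junction transition sequences (> 8 nt) are screened for viral content.
* **A ground-truthed twin-genome simulator** generates the matched pair —
  shared germline variation, cell-line-private novel SNPs, technical noise
  at ~1 error / 150 kb, no-call blocks, B-cell-style CNV losses, a 9-fold
  mitochondrial amplification, and episomal viral reads — with complete
  truth labels, so the whole pipeline runs and is tested without any
  external data.

## Worked example

```sh
twindiff run-all --seed 1 --out out/
```

simulates a ~2.3 Mb twin pair and runs the full comparison. Output (excerpt):

```
## Variant concordance (superloci)
- identical: 2038
- consistent: 152
- onlyA: 16
- onlyB: 299
- identical fraction: 0.8661

## Somatic analysis (CT = cell line as tumor, GT = genomic as tumor)
| cutoff | CT | GT | CT/GT |
| 0.0 | 299 | 16 | 18.69 |
| 0.5 | 135 | 0  | inf   |
At cutoff 0.5: CT=135 (SNPs: 135), GT=0 (SNPs: 0); novel fraction among CT survivors: 1.0

## CNV differences
- cellline_as_reference: 5 difference(s)
    - chr1:288000-388000 ploidy 1 (unmatched, other ploidy None)
    - chrM:0-16000 ploidy 18 (ploidy-differs, other ploidy 2)

## Viral screen
- genomic: 0/300 viral reads, depth 0.0, copies 0.00
- cellline: 32000/32300 viral reads, depth 80.0, copies 2.00
```

Reading the numbers: the samples agree at 2038 of 2353 fully-called
superloci; the 299 `onlyB` superloci are dominated by the 300 simulated
cell-line somatic SNPs, while the 16 `onlyA` ones are technical noise in the
germline sample. Filtering at SomaticScore 0.5 keeps 135 ≈ 300 × 0.5
cell-line candidates (sensitivity 0.5 by construction) and removes all noise
from the GT control; every surviving cell-line SNP is novel. The structural
section recovers the four injected B-cell losses and the chrM segment at
ploidy 18 (9× amplification of a diploid baseline), and the viral screen
reads out the configured 2 episomal EBV copies in the cell line, 0 in the
germline sample.

The same stages are available individually (`simulate`, `diff`, `somatic`,
`cnvdiff`, `junctiondiff`, `metrics`, `viral`, `report`) and as library
functions (`twindiff.compare_callsets`, `twindiff.ct_gt_sweep`, …).

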