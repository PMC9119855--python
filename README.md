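# molspikes

Analysis toolkit for **molecular spikes** — RNA spike-ins that carry a
built-in unique molecular identifier (a *spUMI*) inside the transcript
sequence itself. Because every spiked molecule is individually identifiable,
molecular spikes provide experimental ground truth for single-cell RNA-seq
molecule counting: they reveal when UMI-based counts are inflated by library
artefacts, allow direct benchmarking of computational UMI error correction,
and support absolute estimates of per-cell mRNA content. The package is
aimed at method developers and analysts who process spike-in-containing
scRNA-seq data or want a controlled simulation bench for UMI counting.

## What it does

* **Extraction** — read tagged alignments (SAM/BAM), filter reads whose
  library UMI has more than three bases below Phred 20, and validate spUMIs
  by anchor matching: the simple design requires an exactly 18-nt spUMI
  between flanking anchors; the complex design requires a 7-nt expression
  barcode (Hamming ≤ 1, unique best hit), a 14-nt spUMI and a 25-nt constant
  region (Hamming ≤ 3).
* **UMI collapse** — the four network error-correction algorithms
  (*adjacency*, *adjacency-directional*, *adjacency-singleton*, *cluster*)
  over Hamming-distance-*d* UMI graphs, plus UMI trimming and a brute-force
  oracle used only in tests. spUMIs are corrected per cell with adjacency at
  *d* = 2, justified by the coding capacity of an 18-nt UMI
  (4¹⁸ ≈ 68.7 × 10⁹ sequences makes chance 2-mismatch collisions negligible).
* **QC** — within-cell vs background minimum-distance profiles (PCR error
  clouds enrich distances 1–2 within cells), removal of over-represented
  spUMIs (> 4/8 cells or > 100 raw reads), and selection of the
  eligible-molecule pool (single-cell molecules with 10–20 reads).
* **Saturation** — nonlinear asymptotic fits `y = b0 + b1(1 − exp(−eᶜx))`
  for pool complexity and per-well captured molecules; empty-well
  classification (endogenous < 20% and spike > 80% of mapped reads).
* **Counting evaluation** — sample ground-truth molecules at designed
  expression levels (20 linear levels 1–100, or 60 log-spaced levels
  1–1,000), count them through any UMI length / collapse setting, and report
  percent counting error (observed/truth × 100) against the
  every-read-a-new-UMI inflation null.
* **Quasi-UMI rescue** — fit a Poisson-lognormal to per-cell spike barcode
  counts by maximum likelihood, derive expected per-cell totals from the
  spike read share, and quantile-normalize gene read counts onto the fitted
  distribution, fine-tuning the shape (±10%) so rescued totals match the
  expectation. Rescues cells with inflated counting and UMI-free protocols.
* **Design** — generate new spike sequences (GC within 1% of target, no
  homopolymer runs > 4, ranked by local GC smoothness) and 7-nt expression
  barcode sets (pairwise Hamming ≥ 3, runs ≤ 3, near-self-complementary
  excluded), assembled into a 264-species complex set (11 sequences × 24
  barcodes over 12 twofold titration levels).
* **Simulator** — seeded ground-truth generator with per-molecule read
  amplification, PCR-lineage and sequencing substitution errors, count
  inflation modes, and SAM/TSV fixture emission for end-to-end runs.

## Worked example

`examples/01_simulate_extract_collapse.py` simulates 3 cells × 40 spike
molecules with PCR and sequencing errors, writes a tagged SAM file, extracts
the spUMIs back and corrects them:

```
simulated reads        : 731
validated spUMI reads  : 731
raw distinct spUMIs    : {'CELL0000': 56, 'CELL0001': 66, 'CELL0002': 61}
corrected molecules    : {'CELL0000': 40, 'CELL0001': 40, 'CELL0002': 40}
simulated truth        : {'CELL0000': 40, 'CELL0001': 40, 'CELL0002': 40}
```

Errors minted 16–26 spurious spUMI sequences per cell; Hamming-2 adjacency
collapse recovers the exact simulated molecule counts. The other examples
show the UMI-length/collapse sweep (raw counts inflate to 184% at 10 nt and
collapse restores 100%), per-well saturation fitting (asymptote 7,913 vs
8,000 true molecules, 1.1% error), quasi-UMI rescue of a fivefold-inflated
cell (rescued total 26,010 vs 25,774 true molecules, per-gene Spearman
r = 0.963) and complex-set design (264 species over a 2,048-fold range).

A thin CLI mirrors the pipeline stages:

```bash
molspikes simulate --cells 2 --molecules 100 --seed 1 --out sim/
molspikes extract --alignments sim/reads.sam --fasta sim/spikes.fasta \
    --structure sim/structure.tsv --out records.tsv
molspikes collapse --records records.tsv --distance 2 --mode adjacency \
    --out molecules.tsv
```

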