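# atacvar

From tissue-sorted ATAC-seq fragments to prioritized noncoding risk
variants: a tested, reusable pipeline covering

- **accessibility** — nucleosome-free-region (NFR) selection (fragments
  < 100 bp), Tn5 cut-site shifting (+4 / −5), a simplified
  local-background peak caller, and differential accessibility between
  two cell populations (|log2FC| > 0.5, FDR < 0.01, exact binomial test
  with BH adjustment);
- **enhancers** — active-enhancer annotation by H3K27Ac overlap or
  flanking (inter-peak gaps ≤ 1500 bp), TSS removal, resizing to 400 bp
  windows maximizing ATAC signal, > 70 %-repeat filtering, and
  two-nearest-gene assignment within 100 kb;
- **gkm** — an exact gapped k-mer SVM (l = 10, k = 6 defaults): the
  mismatch-coefficient kernel `f(m) = C(l−m, k)`, GC/repeat-matched 10×
  negative sampling, 5-fold cross-validated ROC/PR, and extraction of the
  per-10-mer weight table that makes scoring linear;
- **tiling** — 400 bp / 100 bp-step genome tiling, model scoring,
  percentile binning (top 0.1 % …) and annotation enrichment;
- **variants** — deltaSVM over 19 bp allele windows, a 1000-SNP
  resampling null within 100 kb, empirical lower-tail p-values and
  Bonferroni correction over the tested SNPs;
- **motifs** — PWM scanning at an 80 % relative-score threshold,
  known-motif enrichment, two/three-motif combination counts, Tn5
  footprint aggregation (±100 bp), allele-specific site loss/gain calls
  (ref ≥ 5.0 → alt < 2.0 or undetected), and the TF→target network;
- **homology** — affine-gap global alignment with reverse-complement /
  reversal / Fisher–Yates shuffle controls, identity-block and
  null-character statistics, three-way profile alignment, and
  shuffle-null z-scores;
- **simulate** — a deterministic synthetic study universe (genome,
  motif-planted enhancers for two populations, bimodal fragment lengths,
  H3K27Ac peaks, TSS, SNP catalog with one planted motif-disrupting
  variant) that exercises every stage against a recorded truth table.

## CLI

```bash
atacvar simulate --seed 1 --out data/           # synthetic dataset
atacvar nfr --data data/ --out results/         # NFRs + differential table
atacvar run-all --out results/ --seed 1         # full pipeline (simulates
                                                # a dataset if --data absent)
atacvar homology --fasta seqs.fa --out rep.json # homology report
atacvar make-fixtures                           # regenerate test fixtures
```

Parameters live in a YAML config (`--config`); the defaults reproduce the
published settings (100 bp fragment cutoff, 0.5/0.01 differential
thresholds, 1500 bp flank, 400 bp / 70 % enhancer rules, 10× negatives,
l = 10 / k = 6, 400/100 tiling, 19 bp deltaSVM window, 1000-SNP null in
100 kb, 0.8/5.0/2.0 motif thresholds).  Every output directory carries a
`provenance.json` (config hash, seed, versions); reruns with the same
seed are byte-identical.

## Layout

```
src/atacvar/
  genome.py         # intervals, FASTA/BED/TSV IO, sequence utilities
  simulate.py       # synthetic dataset generator (+ truth tables)
  accessibility.py  # NFRs, cut sites, peaks, counts, differential calls
  enhancers.py      # K27 integration, TSS filter, resizing, genes
  gkm.py            # gapped k-mer kernel, SVM, weight table
  tiling.py         # genome tiles, percentile bins, enrichment
  variants.py       # deltaSVM, resampling null, prioritization
  motifs.py         # PWMs, scanning, footprints, allele effects, network
  homology.py       # affine aligner, shuffle controls, reports
  cli.py            # click subcommands + run-all orchestration
```
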