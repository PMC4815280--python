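# hiscan

Integrated SNP-array analysis of hybridization intensities and genotypes:
per-sample tracks of individual-level allele frequency (AF), allelic
imbalance (AI), loss of heterozygosity / long contiguous stretches of
homozygosity (LOH/LCSH), and copy-number variation/alteration (CNV/CNA),
with copy-number segmentation by circular binary segmentation (CBS) and a
quick weighted CBS variant restricted to AI/LOH regions.

## What it does

1. **data_io** — reads Axiom-style `calls`/`summary` matrices, per-sample
   "Log Ratio"/"Strength" exports (inverted to allele intensities via
   `h_A = 2^(S+0.5L)`, `h_B = 2^(S-0.5L)`), and a marker annotation table;
   writes per-marker track TSVs, BED/TSV region files and run logs.
2. **preprocess** — log2 transform, per-chip centering (mean or median, both
   divided by the chip SD), quantile normalization, and removal of the
   aberrant-probe perturbation (subtracting the mean intensity over
   allelically balanced autosomal SNPs) to produce the final intensity `t`.
3. **af_estimation** — individual-level AF with a preferential-hybridization
   correction (per-marker kappa estimated from heterozygous references) and
   piecewise-linear recalibration anchored at the genotype cluster means.
4. **reference_panel** — per-marker genotype-specific and pooled statistics
   from normal samples, plus leave-one-out WAP mean/SD/quantile tracks for
   the multipoint procedures; persisted as a single HDF5 container.
5. **detect_single** — confidence-interval detectors for AI, LOH/LCSH and
   CNV/CNA (genotype-specific or pooled; unpaired or paired) with
   per-chromosome Bonferroni-adjusted quantiles and p-values.
6. **detect_multi** — sliding-window scan: run indicator of `n_c` consecutive
   significant markers, window-based aberrant proportion (WAP), LOESS
   smoothing, quantile and hypothesis-test significance procedures, and
   region joining.
7. **segmentation** — full circular binary segmentation with permutation
   split tests, and the quick weighted variant restricted to AI/LOH regions
   (weights from the WAP excess over the reference; `b/a < 5%` applicability
   rule).
8. **simulate** — synthetic reference populations (HWE genotypes, kappa
   bias, copy-number intensity structure), aberration injection with
   effect-size truncation, the FPR/TPR simulation study, region-overlap
   metrics (successful-detection rate S, consistency rate C) and the
   delta-delta-Ct qPCR copy-number estimator.
9. **pipeline / cli** — orchestration of build-ref → detect → segment →
   report with deterministic, seed-fixed outputs.

## CLI

```sh
# build a reference panel from normal samples
hiscan build-ref --calls calls.txt --summary summary.txt \
    --annotation annot.tsv --window 11 --consecutive 2 --quantile 95 \
    --out panel.h5

# detect AI / LOH / CNV-CNA for test samples
hiscan detect --panel panel.h5 --calls calls.txt --summary summary.txt \
    --window 11 --consecutive 2 --mode both --out results/

# copy-number segmentation (original or quick CBS)
hiscan segment --panel panel.h5 --calls calls.txt --summary summary.txt \
    --method quick --alpha 0.01 --min-markers 5 --permutations 1000 \
    --seed 7 --out results/

# synthetic FPR/TPR simulation for one configuration cell
hiscan simulate --scenario loss --nt 51 --r 2 --q 0 --window 11 \
    --consecutive 2 --reps 1000 --seed 42 --out sim.tsv

# summarize region calls in a results directory
hiscan report --results results/
```

Recommended window settings: `(w, n_c) = (11, 2)` for clean data and
`(51, 3)` under noise interference.

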