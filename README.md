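# lcmproteo

Spectral-count differential proteomics for laser-capture-microdissected
(LCM) tissue.

Shotgun proteomics of microdissected tumor and control tissue yields, per
protein and sample, a *spectral count* — the number of MS/MS spectra
matched to that protein's peptides, a semi-quantitative abundance proxy
riddled with informative zeros.  `lcmproteo` is a library (plus a thin CLI)
for turning such a proteins × samples count grid, with group annotations
(early-/late-stage cancer, healthy epithelium, stroma, cell lines), into
candidate marker lists and downstream results.  It is aimed at proteomics
analysts who want the complete chain — from count table to significance
calls — reproducible, seeded and unit-tested, including a synthetic-study
generator with planted ground truth for validating every stage.

## What it computes

* **Fold-changes and volcano tables** — zeros floored at a pseudocount of
  0.125, then log2 FC = log2 mean_a(counts\*) − log2 mean_b(counts\*); a
  protein absent from the reference group maps to a 32-fold ratio
  (log2 FC = 5) when its test-group mean is 4.  Per-protein p-values from a
  two-sided Welch t-test on log2 counts or an exact presence/absence test.
* **Three selection regimes** — "all-or-nothing" exclusivity (zero counts
  in all healthy-epithelium and stroma samples, detection in ≥ 7/11
  early cancers, p < 0.05), Bonferroni (p < α/m, strict), and
  Benjamini-Hochberg step-up FDR (p(i) ≤ i·q/m).
* **Gene-set enrichment with a permutation threshold** — sets scored by
  −log10 of the right-tail hypergeometric p of their overlap with the input
  list; the significance cutoff is the upper 95% confidence limit of the
  mean of per-repeat maximum scores of random same-sized lists
  (mean + t₀.₉₇₅,ᵣ₋₁·sd/√r over r = 10 repeats), exceeded strictly.
* **Ward clustering** — Lance-Williams recurrence, Euclidean distance,
  deterministic tie-breaking, for heat-map row/column ordering.
* **PRM quantification** — stable-isotope-labeled spike-in arithmetic
  (fmol = endo/SIL × spike × scale; ng = fmol × MW × 10⁻⁶) and
  dilution-series calibration (slope, R², LOD = 3.3σ/slope,
  LOQ = 10σ/slope, per-level CV%).
* **Transcriptome comparison** — Wilcoxon rank-sum test of mean log2 FPKM
  of differential genes against the proteome-identified background
  (called at p < 0.01).
* **Synthetic studies** — negative-binomial counts with dropout and planted
  null / fold-change / tumor-exclusive / healthy-exclusive classes over the
  11/11/13/13 group design, plus gene-set, PRM-series and expression
  generators, all driven by one seed.

See `docs/methods.md` for the full model description and defaults.

## Worked example

Score gene sets against a permutation background
(`examples/network_threshold.py`): one 35-member set is planted with 14 of
the 30 input proteins over a 3,000-gene background, nine sets are random.

```
permutation null: mean 0.93, 95% CL of the mean (0.62, 1.23)
threshold (upper CL): 1.23

NET01: overlap 14, score  20.24, PASSES
NET04: overlap  2, score   1.33, PASSES
NET02: overlap  1, score   0.53, below threshold
...
```

The planted set's score of 20.24 (p ≈ 10⁻²⁰) towers over the threshold of
1.23 derived from ten random lists; random sets hover around it.  Scores
are −log10 p, so 20.24 means the overlap is essentially impossible by
chance.

Classify the bundled published cell-line fold-change table
(`examples/cell_line_filter.py`), which holds log2 fold-changes versus
healthy epithelium for both cancer stages and the HeLa/U87/HEK293 lines:

```
tumor_and_HeLa (19 proteins): AKAP13, TAP2, ZNF326, UBR4, GPKOW, ICAM1, ...
tumor_only (14 proteins): CLCA4, CEACAM5, CAMP, COL12A1, FMO3, DTX3L, ...
```

At a 2.5 log2-unit cutoff, 19 proteins are up-regulated in tumor tissue
*and* the cervical HeLa line but not in the non-cervical lines, and 14 in
the microdissected tumor cells only — candidate cervical-cancer markers.

The other scripts in `examples/` each demonstrate one capability
(simulation + volcano, selection regimes, clustering, PRM, transcriptome)
and print a line explaining their numbers.

## Command line

```sh
lcmproteo simulate --seed 1 --out study/
lcmproteo diff --matrix study/matrix.tsv --annotations study/annotations.tsv \
    --contrast early_cancer:healthy_epithelium --out volcano.tsv
lcmproteo run --config pipeline.yaml --out results/
```

`run` executes diff → select → network → cluster from a YAML config and
writes a `manifest.json` with the version, seed, parameters and row counts
of every output; identical config + seed gives byte-identical outputs.

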