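# Methods

`lcmproteo` implements a label-free differential-proteomics workflow for
spectral-count data from laser-capture-microdissected (LCM) tissue: four
sample groups (early-stage cervical cancer, late-stage cervical cancer,
healthy cervical epithelium, cervical stroma), a proteins × samples grid of
nonnegative integer spectral counts, and a chain of analyses that turns the
grid into candidate marker lists, enriched gene sets, heat-map orderings and
absolute protein amounts.  This note records the statistical model behind
each stage, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Differential abundance from spectral counts

Spectral counts are a semi-quantitative abundance proxy; zeros are common
and carry information (a protein below the detection limit).  To allow
logarithms, zero counts are replaced by a pseudocount of 0.125 before any
ratio is formed.  The per-protein fold-change is

    log2 FC = log2( mean_a(counts*) ) − log2( mean_b(counts*) )

where `counts*` are the zero-replaced counts and the means run over the
samples of the test (a) and reference (b) groups.  Defining the fold-change
on group means (rather than as a mean of per-sample log ratios) preserves
the floor arithmetic that makes a protein completely absent from the
reference group map to a large but finite value: a group mean of 4 against
an all-zero reference (mean 0.125) gives a linear ratio of 32, log2 FC = 5.
Computing the difference of logs rather than the log of the ratio makes the
antisymmetry under group swap exact in floating point.

Two per-protein tests are available, selected by `ContrastSpec.test_method`:

* **`welch_log`** (default): two-sided unequal-variance t-test on the log2
  zero-replaced counts.  Chosen as the default because the published
  Bonferroni/BH lists pair p-values with graded fold-changes, which implies
  a test on abundance rather than on detection; the underlying source does
  not name its test, so the choice is a documented config switch.  Rows that
  are constant and equal in both groups carry no evidence and are assigned
  p = 1 rather than NaN.
* **`fisher_presence`**: two-sided exact test on the 2×2 table of detection
  (count ≥ 1) versus non-detection by group.  Conditional on the margins,
  the number of detections in group a is hypergeometric; the two-sided
  p-value is twice the smaller tail, capped at 1.  This "tail-doubling"
  convention is used (rather than the minimum-likelihood convention of some
  implementations) because it has a direct enumeration semantics — the
  fully separated 11/11 vs 0/13 table gives p = 2/C(24,11) ≈ 8.0 × 10⁻⁷ —
  and is validated in the tests against exhaustive enumeration of all
  tables with fixed margins.

No between-sample count normalization is applied by default, mirroring the
workflow being reproduced; the readers accept any integer grid, so a
normalized matrix can be supplied upstream if desired.

## Selection regimes

Three regimes of increasing permissiveness:

1. **All-or-nothing exclusivity**: a protein qualifies when it has zero
   counts in *every* sample of the excluded groups (healthy epithelium and
   stroma), is detected in at least 7 of the 11 early-cancer samples, and
   has raw p < 0.05.  Detection in late-stage cancer is explicitly allowed.
   The mirror operation `exclusive_in_group` finds proteins detected only
   in one group (≥ 6 of 13 samples by default), e.g. healthy-epithelium- or
   stroma-exclusive proteins.
2. **Bonferroni** at family-wise level α = 0.05 with strict inequality
   p < α/m.  The family size m defaults to the number of proteins actually
   tested; an `explicit_m` override exists because published thresholds do
   not always disclose the family they divide by (a printed cutoff of
   9.88 × 10⁻⁶ corresponds to m = 5,061, which matches none of the study's
   printed protein totals — the package exposes m instead of guessing).
3. **Benjamini-Hochberg** step-up at FDR q = 0.05: the largest i with
   p(i) ≤ i·q/m is found and all smaller p-values rejected, ties rejected
   together; adjusted p-values are the standard monotone step-up values.
   The implementation delegates to `statsmodels.stats.multitest` and is
   checked against an independent literal step-up oracle in the tests; its
   empirical false-discovery proportion on simulated null+signal studies is
   verified to stay at or below q within Monte-Carlo error.

The monotonicity Bonferroni ⇒ BH ⇒ raw p ≤ threshold (at equal α = q) holds
by construction and is property-tested.

## Gene-set enrichment with a permutation threshold

Gene sets replace proprietary network content with user-supplied GMT
collections; each set is scored by the right-tail hypergeometric
probability of its overlap with the input protein list (one-sided Fisher
exact: population N = |background|, successes K = |set ∩ background|,
draws n = |input|), reported as score = −log10 p.  The default set size in
the generator is 35, the typical size of curated interaction networks.

Significance uses a permutation background rather than a fixed α: for the
observed list size, random lists are drawn uniformly without replacement
from the background (10 repeats by default), the best set score of each
repeat is recorded, and the threshold is the upper 95% confidence limit of
the mean of those maxima, mean + t₀.₉₇₅,ᵣ₋₁ · sd/√r.  The Student t
quantile is used because the repeats are few (r = 10); a normal-quantile
option is available.  A set is called only when its unrounded score
*strictly* exceeds the threshold.  With max scores (1, …, 10) the threshold
is 5.5 + 2.2622 · 3.0277/√10 ≈ 7.666, which the tests pin down.

## Hierarchical clustering

Heat-map orderings use agglomerative clustering under Ward's
minimum-variance criterion with Euclidean distance, applied independently
to proteins (rows) and samples (columns) of the log2 zero-replaced counts.
The implementation maintains squared inter-cluster distances with the
Lance-Williams recurrence

    d²(k, i∪j) = [(nᵢ+nₖ)d²(k,i) + (nⱼ+nₖ)d²(k,j) − nₖd²(i,j)] / (nᵢ+nⱼ+nₖ)

and merge heights h = √(2·ΔESS), so singleton merges sit at their Euclidean
distance (the same convention as SciPy's `linkage(..., "ward")`, against
which heights are cross-checked).  Ties are broken deterministically by the
lowest cluster-index pair, making the tree invariant to row permutation up
to relabeling.  An O(n³) oracle that recomputes every candidate merge cost
from cluster members is used in the tests.  Seriation beyond the standard
recursive leaf order is out of scope: it affects display order only, not
tree structure.

## PRM quantification

Targeted quantification assumes the standard isotope-dilution model: the
endogenous amount equals (endogenous area / SIL area) × spiked fmol ×
scale factor, where the scale factor maps the digested aliquot back to the
whole lysate (e.g. 4 when 50 of 200 µL were digested).  A zero SIL area is
flagged not-quantifiable rather than propagating infinity.  Protein
amounts are the median over the protein's peptides (robust to one
interfered transition; mean optional) converted by ng = fmol × MW(Da) × 10⁻⁶.

Calibration fits ordinary least squares of mean area on level over the
dilution series (default levels 0, 0.625, 1.25, 2.5, 5, 10, 20 fmol/µL,
triplicates).  LOD = 3.3·σ_blank/slope and LOQ = 10·σ_blank/slope with
σ_blank the standard deviation of the level-0 replicates — the common
blank-based convention, chosen because the reproduced workflow states no
formula; when no blank replicates exist the residual standard deviation of
the fit is used instead.  Per-level CV% = 100·sd/mean.  A non-positive
slope marks the curve invalid.  These quantities are scale-equivariant in
the expected way: multiplying all areas by c scales slope and σ_blank by c
and leaves R², CVs, LOD and LOQ unchanged.

## Transcriptome comparison

Per-gene mean log2 FPKM across tumor samples is compared between the
differential gene list and the full proteome-identified background with a
two-sided Wilcoxon rank-sum test; the verdict threshold is p < 0.01 and
the direction is reported as the difference of medians.  The comparison is
against the full background (not background minus the list) so that a list
identical to the background degenerates cleanly to p = 1.  Exact
enumeration is used when min(n₁, n₂) ≤ 8 and there are no ties, otherwise
the normal approximation with tie and continuity correction; the branches
agree to about 0.01 at the crossover size.  Genes absent from the
expression table are reported as dropped, never silently ignored.

## Synthetic-data generator

The generator produces studies with the structure the analyses assume,
with planted ground truth, so every stage is testable without any data
download.  Defaults are the emulated study's conditions:

| parameter | default | rationale |
|---|---|---|
| group sizes | 11 / 11 / 13 / 13 | early, late, healthy epithelium, stroma |
| n_proteins | 2,000 | within the 1,500–3,000 identified-protein range |
| count model | negative binomial, µ = 5, k = 1 | overdispersion is the norm in spectral counting; k → ∞ recovers Poisson |
| dropout | 0.15 per cell | with µ and k this yields ≈ 1,400 detected proteins per sample, matching the reported 1,296–2,189 per-sample range at this matrix size |
| planted fc_up / fc_down | 5% each, effect 2 log2 units | a 4-fold change, mid-range of the published fold-changes |
| tumor-exclusive | ≈ 31 proteins, detected in exactly 8/11 early cancers | the all-or-nothing list size; presence above the 7/11 rule |
| healthy-exclusive | ≈ 10 proteins, detected in 6/13 healthy samples | the mirror rule's boundary |

Counts are NB draws thinned by independent per-cell dropout; fold-change
classes scale the NB mean in both cancer groups; exclusivity patterns are
imposed after dropout so they hold exactly (zero counts in all excluded
samples, a fixed number of detected target samples with counts ≥ 1).  The
expression generator places strata at log2 FPKM ≈ 5 (high), ≈ 2
(intermediate) and ≈ −5 (undetectable, sd 1.5) over 50 tumor samples; the
PRM generator applies mean-1 multiplicative lognormal noise of a given CV
to an exactly linear series.  All randomness flows from one mandatory seed
through `numpy.random.default_rng`; no global state is touched.

What the generator does **not** emulate: peptide-level identification and
protein inference, correlated missingness (dropout is independent of
abundance, whereas real detection limits censor low counts
preferentially), between-sample loading differences, batch effects, and
correlation between proteins.  Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
model, not robustness of the workflow to those real-data pathologies.

## Numerical conventions and degenerate inputs

* p-values are clipped into (0, 1]; NaN from zero-variance tests becomes 1.
* Bonferroni uses strict `<`; BH uses `≤` in the step-up comparison; the
  permutation threshold uses strict `>`.
* FIGO stage parsing matches Roman numerals longest-first (IV, III, II, I)
  so "IIb" cannot be misread as a III prefix; I/II map to early, III/IV to
  late.
* Cell-count estimation from a microdissected area assumes cubic cells:
  cells = area(mm²) × 10⁶ × thickness(µm) / edge(µm)³, rounded to the
  nearest integer (0.8 mm² at 10 µm with 10 µm cells ≈ 8,000 cells).
* Writers emit TSV with 6-significant-digit floats; readers treat duplicate
  identifiers, non-integer counts and missing annotations as hard errors.
* A constant matrix clusters into a valid tree with all heights zero; a
  both-groups-all-zero protein has log2 FC exactly 0.

## Problem sizes

Test-suite and acceptance-script simulations use 250–2,000 proteins,
200-replicate Monte-Carlo loops for FDR calibration, 100 seeded runs for
permutation-threshold recovery and slope recovery, and n ≤ 8 matrices for
the exhaustive clustering oracle — sizes at which the exact oracles
(enumeration, brute-force step-up, O(n³) Ward) remain practical while the
statistical assertions have adequate power.

## Known limitations

* The per-protein test behind the published p-values is not identifiable
  from the source material; neither candidate reproduces the published
  Table-style p-values exactly, so both are provided and the default is a
  documented choice.
* IPA's proprietary network knowledge base and PermutMatrix's
  bipolarization seriation are not reproduced; gene sets come from GMT
  files and leaf order is the standard recursive order.
* Absolute ng amounts for real lysates require per-sample scale factors
  and molecular weights that the published material does not print; the
  package computes them from user-supplied values.
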