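# Methods

## Scope and model

`scqpcr` implements the analysis chain for single-cell qPCR profiling of
mouse preimplantation development on BioMark-style chips, together with
a generative simulator of such experiments. All expression values live
on the inverted-Ct log2 scale: `baseline − Ct` before normalization
(one unit ≈ one PCR cycle ≈ one doubling of transcript abundance), and
the same quantity minus the per-cell mean over the endogenous reference
genes after normalization.

### Preprocessing

1. **Inversion.** `expr = baseline − Ct`, baseline 30 cycles by default
   (exposed as a parameter; other chip runs use 24 or 40).
2. **Gene QC.** Assays flagged non-specific by the melting-curve QC are
   dropped. A non-specific *reference* gene is a hard error, since the
   normalization contract cannot be met.
3. **Cell QC.** Cells whose mean raw inverted Ct over passing reference
   reactions is below `min_ref_level` (default 3), or whose reference
   reactions all failed, are removed. The default cleanly separates
   total failures from modest cells in simulated data; it is a free
   parameter because "low or absent" control signal has no universal
   cutoff.
4. **Normalization.** Per cell, the mean inverted Ct of the reference
   genes is subtracted from every gene. If one or two of the three
   reference reactions failed in a retained cell, the mean of the
   passing ones is used.
5. **Censoring.** Failed (non-detect) reactions never enter the
   arithmetic above; they carry an explicit mask and are assigned a
   floor value (default −14 normalized, safely below the −10 detection
   threshold) *after* normalization, keeping the matrix complete while
   letting threshold rules treat non-detects as unexpressed.

### Stage dynamics

* **Detection threshold.** Default fixed at −10 (the conventional value
  for this normalization); alternatively estimated as the antimode of
  the pooled value density between the censoring-floor peak and the next
  expressed mode. The floor peak sits at the lower edge of the value
  range, so boundary maxima are considered explicitly.
* **Threshold classes** are defined on per-stage means over embryonic
  stages (ESC controls excluded): exclusively zygotic (MII mean below
  threshold, some later stage at or above), exclusively maternal (MII at
  or above, both 16- and 32-cell below — the two late stages are tested
  separately by default, with a pooled variant behind a flag), not
  expressed (all below), else expressed throughout.
* **Branches.** Gene rows are mean-centred and clustered (Euclidean +
  Ward, both configurable) and the tree is cut into three branches.
  Naming uses the branch's mean per-stage profile: a profile spanning
  less than `flat_range` (2 log2 units) — or with |Spearman trend| below
  `trend_cutoff` (0.3) against stage order — is *ubiquitous*; otherwise
  the trend sign gives *maternal* (decreasing) or *zygotic*
  (increasing). The dynamic-range test exists because rank correlation
  is scale-free: a flat branch measured with noise draws an arbitrary
  trend statistic, while its expression range honestly reports flatness.
* **PCA** runs on the gene-centred matrix without unit-variance scaling
  (loadings should reflect expression magnitude); ESC samples are
  included. Per-component signs are fixed by forcing the
  largest-magnitude loading positive. Loading ranks use the Euclidean
  norm of the first two components, ties broken by gene id.

### Lineage analysis

* **Correlation matrix.** Pairwise Spearman rho with two-tailed
  p-values over 16/32-cell blastomeres; the t approximation for the
  usual cell counts, full permutation enumeration for n ≤ 7 (the two
  can differ in the third decimal; downstream use is insensitive at
  that scale). Genes constant across blastomeres get rho 0 / p 1 and a
  flag. So do genes detected in fewer than half the blastomeres: with
  the ranks dominated by limit-of-detection ties, their apparent
  correlations reflect shared per-cell measurement structure rather
  than co-expression, and they otherwise contaminate marker clusters.
* **Marker discovery.** Genes are clustered on `1 − rho` with Ward
  linkage. Average/complete linkage fail here by construction:
  anti-correlated programmes are *maximally distant* under `1 − rho`,
  so distance-based linkages absorb each programme into the
  uncorrelated background before the pair ever becomes visible, while
  variance-minimizing merges keep each coherent block intact. The
  cluster count is chosen automatically: tree cuts for k ∈ 2..10 are
  ranked by mean silhouette, and among them the cut whose best cluster
  pair (within-cluster mean rho ≥ 0.2 on both sides, between-cluster
  mean rho ≤ 0) is most strongly anti-correlated wins. Members whose
  median p-value against their own set exceeds 0.05 are trimmed. The
  set containing the anchor genes (*Pou5f1, Sox2, Klf2, Klf4* by
  default) is labelled ICM; without anchors the labels are arbitrary
  and flagged.
* **Lineage score and fates.** `L = mean(ICM set) − mean(TE set)` per
  blastomere; ICM if `L ≥ high`, TE if `L ≤ low`, else n.d. A
  `set_means` mode reproduces the per-set low/mid/high rule (ICM when
  the ICM-set mean is high *and* the TE-set mean is low, and
  conversely). Default thresholds are equal-width thirds of the
  observed score range, trimmed to the 5th–95th percentiles so a few
  censoring-floored outliers cannot stretch the bands. Quantile
  terciles are available (`thresholds="quantile"`) but are a poor
  default for this problem: with a balanced bimodal score distribution
  the 1/3 and 2/3 quantiles necessarily fall *inside* the two score
  clumps, pushing a third of well-separated cells into "n.d." and
  capping the agreement between any two callers near 70%; the
  range-based bands put the undefined zone in the gap between the
  lineage levels, where it belongs.
* **Panel evaluation.** A reduced panel's per-cell mean is banded the
  same way; a high panel mean calls the lineage the panel belongs to
  (inferred from marker-set membership, else from the sign of its
  correlation with the reference score). Concordance is the fraction of
  reference-called (non-n.d.) blastomeres whose panel call agrees.

## The simulator

The generator emulates the study design the analysis assumes, with every
constant exposed in `SimConfig`:

* **Scale.** 192 assays — 3 reference genes, 36 non-specific assays
  (dropped at QC), 153 informative genes — and 194 samples: 191 single
  cells over MII, zygote, 2-, 4-, 8-, 16-, 32-cell stages plus 3 ESC
  controls, of which 5 planted low-RNA cells fail the reference QC,
  leaving the 156 × 189 post-QC matrix. Per-stage counts are an
  assumption (the source design reports totals, not per-stage counts
  after QC); group-of-blastomere samples are not modelled separately.
* **Classes.** 31 maternal, 62 ubiquitous, 36 zygotic, 12 ICM-marker,
  10 TE-marker and 2 silent genes (fractions configurable). Together
  with references this yields 31/67/58 maternal/ubiquitous/zygotic
  branches. Seven maternal genes decay fully (exclusively maternal);
  sixteen zygotic-like genes are silent in MII (exclusively zygotic),
  apportioned over plain zygotic and marker classes by size.
* **Profiles.** Expressed level +2, silent level −14, partially
  expressed level −6 (normalized log2). Maternal genes decay linearly
  from the zygote to the 16-cell stage; zygotic genes ramp up from the
  2-cell to the 8-cell stage; markers ramp to an intermediate level and
  bifurcate by ±`lineage_effect`/2 (default separation 6) in 16/32-cell
  blastomeres, whose fates are a balanced ICM/TE split per stage. ESC
  samples follow the zygotic pattern with the ICM programme high — they
  sit near ICM cells without modelling ESC biology. The balanced fate
  split is also the condition under which low/mid/high score bands are
  meaningful; a strongly skewed split would put a band boundary inside
  the majority clump.
* **Emission.** Raw signal = normalized level + per-cell reference
  level (mean 10, cell-to-cell sd 1, a total-RNA proxy) + Gaussian
  reaction noise (sd 0.8 log2 units). `Ct = 30 − raw`. Reactions drop
  out with probability `dropout_rate · logistic(−(raw − midpoint)/scale)`
  (midpoint 0 = the Ct baseline, scale 1.5), the simplest
  level-dependent censoring mechanism consistent with a floor-shaped
  value distribution. Embryo-of-origin random effects exist as a
  parameter but default to 0.

**What passing recovery tests do and do not show.** The simulator emits
Gaussian noise, logistic dropout and piecewise-linear stage profiles; it
does not model preamplification bias, chamber position effects,
melting-curve shapes, bursty transcription, or embryo-to-embryo
variability (by default). Perfect recovery on this generator therefore
validates the pipeline's logic and its robustness to censoring and
reaction noise at realistic magnitudes — not the biological accuracy of
any particular threshold on real chips.

## Numerical choices

* Determinism: one integer seed drives all simulator randomness;
  analysis is deterministic given the data (PCA signs fixed, clustering
  deterministic, lexicographic tie-breaks in rankings).
* The normalization invariant (per-cell mean of detected reference
  values = 0) holds to 1e-9 by construction and is asserted in tests.
* Degenerate inputs: empty matrices, missing stages, all-removed cells,
  unnamable branches, non-anti-correlated correlation structures and
  missing marker genes all raise `PipelineError` with a diagnostic
  rather than returning silently wrong output.
* Problem sizes in the test-suite recovery runs match the study design
  (192 × 194 per seed; ten seeds for the stochastic recovery suite),
  which keeps the whole suite in the tens of seconds.

## Known limitations

* The accession-based checks (re-deriving the published counts from the
  deposited matrix) require the public dataset; this repository
  exercises the identical code path on the synthetic emulation instead,
  and the loaders accept the deposited wide-TSV layout for offline use
  with a manual download.
* Spearman p-values use the t approximation for n > 7; exact values
  are enumerated only for tiny n (n! growth).
* The antimode threshold estimator assumes a clearly bimodal pooled
  distribution; unimodal data produce an error advising the fixed −10.
* Branch naming assumes monotone-in-expectation maternal/zygotic
  dynamics; non-monotone dynamic branches (rise-then-fall) would be
  named by their overall trend.
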