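# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of `imtx`.  It states no empirical claim
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate-based meta-analysis

Per-study effect maps are reconstructed from reported peaks.  A peak
statistic is first converted to a two-sample t (z by normal/t quantile
matching at df = n₁ + n₂ − 2; a two-tailed p through the t inverse survival
function, signed by the reported direction), then to a small-sample-corrected
standardized difference (Hedges g).  Voxels take kernel-weighted peak
contributions from an **isotropic** Gaussian kernel at FWHM 20 mm, truncated
at twice the FWHM.  Anisotropic kernels would require a tissue-correlation
template that is not part of this package; the kernel is an injectable
function, so that refinement plugs in without touching the pooling code.
Overlapping kernels combine by signed maximum magnitude — summation (available
via `combine="sum"`) inflates effects wherever two reported peaks sit within
one kernel radius, which is common with 20-mm kernels.  The per-voxel variance
uses the standard Hedges-g variance, (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)).

Pooling is voxel-wise DerSimonian–Laird with τ² truncated at zero.  The voxel
null relocates every study's peaks uniformly over in-mask voxel centers,
re-pools, and pools all in-mask |z| values of all iterations into a single
null distribution (default 60–200 iterations; with ~25k mask voxels even 60
iterations give >10⁶ null values, so the p-resolution is set by the voxel
count, not the iteration count).  Voxel p-values use the add-one permutation
convention.  Thresholding applies the voxel-p rule first and the peak-height
rule per cluster afterwards; the interaction order between the two published
thresholds is not stated anywhere we could find, and this order is the
conservative reading (a cluster must both be suprathreshold and reach peak
|z| ≥ 1).  Cluster extent minima are 50 voxels (main) and 10 (heterogeneity).

Jackknife runs re-pool each leave-one-out subset and re-apply the main
thresholds, reusing the full-sample relocation null rather than rebuilding a
null per subset: the null describes the no-effect distribution of pooled |z|,
which changes only marginally when one of ≥ 14 studies is removed, and
rebuilding it would multiply the dominant cost of the analysis by the study
count.  Egger regression (g/SE on 1/SE at the cluster peak, two-sided
intercept test) uses only studies with a nonzero reconstructed effect at the
peak and is reported as missing below three contributors.

Peaks without a usable statistic are excluded with a warning (the original
software imputes bounds for such peaks; that imputation is out of scope).
Study covariates (mean age, illness duration) are carried through parsing but
no meta-regression is fitted.

## Synthetic data

The generators are pure functions of (parameters, seed) and write the same
file formats the analysis stages read, with a ground-truth JSON sidecar.

* **Study sets.**  Defaults encode the study conditions of the emulated
  design: 15 studies, group sizes uniform on 13–67, two planted loci of
  opposite sign at d = 0.8, isotropic 8-mm coordinate jitter.  Reported t
  values are drawn from the noncentral-t sampling distribution with
  ncp = d·√(n₁n₂/(n₁+n₂)), so reported effects carry realistic sampling
  error.  Spurious peaks (uniform in-mask, Poisson rate per study, default 0)
  support null simulations.
* **GM mask.**  An ellipsoid of ≈1.6 L centered in the MNI bounding box
  stands in for a gray-matter analysis mask; the grid is a configurable
  isotropic MNI-box lattice (2 mm default; experiments use 4–6 mm to keep
  desk-scale runtimes).
* **Expression atlas.**  Six donors; only the first two contribute
  right-hemisphere samples, mirroring the hemispheric coverage of real donor
  atlases; 30% of samples fall outside the mask.  Signal genes get
  ρ·z(map) + √(1−ρ²)·ε with the noise ε spatially structured (a shared
  smooth-field basis) and orthogonalized against the map, so the realized
  in-mask correlation equals ρ exactly before normalization.  Signal genes
  carry a larger smooth (donor-consistent) noise share (0.8) than null genes
  (0.5): genes with anatomically organized expression are empirically the
  more donor-stable ones, and this is what makes a differential-stability
  filter meaningful.  Each gene has one faithful probe and degraded ones; a
  configurable probe fraction fails the background-intensity rule and a small
  gene fraction has only degraded probes, exercising both probe filters.
* **Categories and specificity panels.**  Enriched categories draw most
  members from signal genes of a **single** correlation sign (category means
  of mixed-sign members cancel); null categories draw uniformly.
* **PPI graphs.**  An Erdős–Rényi background layer (expected degree 6) plus
  planted hubs topped up to degree 30 with high-confidence edges; 30% of
  background edges score below the 0.9 cutoff.
* **Receptor maps.**  ρ·z(map) + √(1−ρ²)·ε with ε a smooth Gaussian field
  (squared-exponential, 10-mm scale) orthogonalized against the map, making
  the planted in-mask correlation exact per realization (`exact=False` gives
  plain mixing, where the realized r only converges to ρ with the number of
  independent spatial degrees of freedom).

What the generators do **not** emulate: scanner artifacts and site effects,
donor demographics, batch structure beyond donor identity, hemispheric
asymmetry beyond the coverage flags, anisotropic spatial covariance, and the
GO DAG (annotations are flat sets).  Passing tests therefore demonstrate
correctness of the statistical machinery under a known, idealized data model,
not robustness to the full messiness of real atlases.

## Expression preprocessing

Stage order is fixed and logged: intensity filter → probe selection → SRS
normalization → DS filter → mask restriction.  The scaled robust sigmoid uses
IQR/1.35, which estimates the SD under normality; zero-IQR vectors map to a
constant 0.5.  Normalization runs within-sample (across genes) and then
within-gene (across samples).  DS uses Spearman correlation over per-donor
regional means (Pearson by configuration); regions for synthetic data come
from spatial k-means parcels (default 30).  The top-fraction filter keeps
exactly ⌈fraction·G⌉ genes with deterministic tie-breaking.  A left-hemisphere
restriction is on by default, reflecting that right-hemisphere coverage comes
from a minority of donors.

## Surrogate maps and GCEA

Surrogates are variogram-matched: permute the in-mask values, smooth the
permutation at each of 9 log-spaced candidate scales (0.75·voxel size to
50 mm) with mask-normalized Gaussian filtering, fit the nonnegative mixture
α·γ_smooth(h) + β (smooth plus white noise) to the source map's empirical
variogram by least squares over 25 distance bins, pick the best-fitting
scale, and rank-remap the mixed field to the original value distribution.
The variogram design subsamples 80,000 voxel pairs and bins lags up to the
lower quartile of sampled distances: short lags carry the autocorrelation
information, while the long-lag tail of a single finite-domain realization is
dominated by apparent trend that no stationary surrogate can or should match.
Candidate selection deliberately uses the **fitted** variogram, not each
candidate's realized variogram — selecting on the realized variogram
conditions the ensemble on its own sampling noise and measurably narrows the
null (we observed gene-level type-I inflation near 0.10 with realized-variogram
selection versus ≈0.05 with fit-based selection).

GCEA re-scores every surrogate (sphere sampling is a precomputed sparse
averaging operator, so the ensemble cost is one matrix product per stage),
aggregates per category, and computes two-sided add-one p-values centered on
each category's null mean — gene-score nulls are not mean-zero under spatial
autocorrelation.  Surrogate gene scores reuse the same retained-sample set as
the observed analysis.  p-values are bounded below by 1/(N+1).

Known limitation: on strongly nonstationary maps (isolated high-amplitude
clusters on a flat background), the stationary surrogate ensemble
underestimates the spread of map–gene correlations and the ensemble null is
anticonservative; the calibration experiments therefore use stationary smooth
alteration maps whose length scale (8.5 mm) matches the smoothness a
20-mm-FWHM reconstruction kernel imprints on pooled maps.  This is a known
property of variogram-matched nulls, not specific to this implementation.

## Specificity enrichment, hubs, receptor panel

Fisher tests are two-sided with BH-FDR across each panel; the background
universe is the DS-filtered gene set of the expression matrix (the population
all candidate sets are drawn from), configurable.  Hub detection deduplicates
edges (maximum score per pair), drops self-loops, filters at confidence 0.9,
and takes the top ⌈0.10·n⌉ of the n nodes with at least one retained edge,
ties broken by (degree, node id).  The receptor-panel null surrogates the GM
map (one ensemble serves the whole panel); the correction denominator m is
the supplied panel's size, never hard-coded.  An optional cubic-block
parcellation supports parcel-level analysis.

## Problem sizes and experiment design

The recovery and calibration experiments (`imtx.experiments`, reused by
`tests/test_acceptance.py` and `scripts/acceptance.py`) run at desk scale,
chosen so the full battery completes in minutes on one CPU: CBMA on a 4-mm
grid with 60 relocation iterations and 20 replicate study sets; expression
experiments on a 6-mm grid with 500–800 genes, ~350–550 retained samples, and
1,000-surrogate ensembles (the production default is 10,000); receptor
inference with 1,000 permutations (production 5,000).  The GCEA type-I rate
pools three independent replicate draws of map, atlas, and annotation
(≥1,500 categories total) because the per-map rate fluctuates with the
realized large-scale structure of the alteration map.  All randomness flows
from one master seed through named substreams; the demo writes every output
with fixed float formatting and is bit-reproducible.

## Deliberate deviations and open choices

* Talairach→MNI uses the single fixed inverse Lancaster affine, not the
  piecewise transform — adequate for synthetic round-trips; documented as
  approximate.
* The "top 10%" hub denominator counts only nodes with ≥1 retained edge.
* The heterogeneity peak-height rule is applied to the normal-quantile
  transform of the Q p-value.
* Within a published description that calls one count "genes" in one place
  and "samples" in another (926), this implementation follows the
  sample-by-gene matrix reading: rows are tissue samples.
* No GO DAG propagation; no probe re-annotation; no meta-regression; no
  acquisition of real atlas, PET/SPECT, or interaction-database releases.
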