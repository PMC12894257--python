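# imtx — imaging transcriptomics of meta-analytic gray-matter maps

`imtx` implements, end to end, the analysis chain that links coordinate-based
meta-analysis (CBMA) of voxel-based-morphometry findings to molecular brain
maps: reconstruction and random-effects pooling of reported gray-matter (GM)
peaks, preprocessing of a donor-based expression atlas to a sample-by-gene
matrix, spatial "gene scores" with ensemble-based gene-category enrichment
against autocorrelation-preserving surrogate maps, specificity (tissue /
cell-type / developmental) enrichment and PPI hub extraction, and spatially
corrected correlation with receptor/transporter density maps.  It is aimed at
methodologists who want a tested, fully synthetic-data-driven re-implementation
of this pipeline — every stage ships with generators that plant known ground
truth, so recovery and calibration are measurable without any external data
download.

## The model in brief

**CBMA.** Each study's reported peaks (t, z or p statistics at MNI/Talairach
coordinates) are converted to small-sample-corrected standardized effects
g = J·t·√(1/n₁+1/n₂), J = 1 − 3/(4·df − 1), and spread over the lattice with an
isotropic Gaussian kernel (FWHM 20 mm, truncated at 2·FWHM; overlapping kernels
combine by signed maximum magnitude).  Voxel-wise pooling is DerSimonian–Laird:
weights wᵢ* = 1/(vᵢ + τ²) with τ² = max{0, (Q − k + 1)/(Σw − Σw²/Σw)}, and
z = ĝ/SE(ĝ).  Voxel p-values come from a peak-relocation permutation null;
clusters survive at voxel p < 0.005, peak |z| ≥ 1, extent ≥ 50 voxels
(heterogeneity: Cochran Q vs χ²ₖ₋₁, extent ≥ 10).  Robustness: leave-one-study-
out jackknife and Egger regression of g/SE on 1/SE.

**Expression preprocessing.** Probes must exceed background intensity in ≥ 50%
of samples; among a gene's probes, the one correlating best with an RNA-seq
reference represents it (probes with r < 0.2 are dropped).  Scaled robust
sigmoid normalization, y = 1/(1 + exp(−(x − median)/(IQR/1.35))) then min–max
to [0, 1], is applied within-sample and within-gene.  Differential stability
(mean inter-donor Spearman correlation of regional expression profiles) ranks
genes; the top 50% are retained (40%/60% as sensitivity alternates), and
samples are restricted to the GM mask.

**Gene scores and GCEA.** The pooled z-map is averaged in 3-mm spheres at each
tissue sample; a gene's score is the Pearson correlation of its expression
profile with that sphere vector.  Category scores (mean member gene score,
categories with 10–200 annotated genes) are tested two-sided against nulls
built by re-scoring variogram-matched surrogate maps of the z-map — surrogates
permute the map, smooth at a fitted length scale, mix with white noise to match
the empirical variogram, and rank-remap to the original value distribution.

**Specificity, hubs, receptors.** Fisher's exact test with Benjamini–Hochberg
FDR evaluates candidate-gene enrichment in pSI-style specificity sets; hubs
are the top 10% of nodes by degree on the ≥ 0.9-confidence PPI graph; receptor
maps correlate with the z-map over in-mask voxels with permutation p-values
from the same surrogate machinery, FDR- and Bonferroni-corrected.

## Worked example

The numbered drivers under `analysis/` run the chain on synthetic inputs with
planted ground truth (two GM loci at d = 0.8 — a basal-ganglia decrease and an
orbitofrontal increase — 60 signal genes, 5 enriched categories, 10 hubs, and
five receptor maps planted at r = −0.30 … −0.38):

```bash
python analysis/01_simulate_inputs.py --seed 3
python analysis/02_cbma.py --seed 3
python analysis/03_expression_preprocessing.py --seed 3
python analysis/04_gene_scores_gcea.py --seed 3
python analysis/05_specificity_and_hubs.py
python analysis/06_receptor_correlations.py --seed 3
```

Stage 02 prints the recovered cluster table (peak coordinates in mm, extent in
voxels, pooled z, relocation-null p, Egger p, jackknife survival):

```
    x    y     z  extent    peak_z        p     sign  heterogeneity  egger_p jackknife
 18.0 18.0 -24.0     172  4.305182 0.000001 increase          False 0.769668     15/15
-30.0 -6.0  -6.0     181 -4.849625 0.000001 decrease          False 0.606724     15/15
```

Both planted loci are recovered with the correct sign, survive all 15
leave-one-out runs, and show no Egger-detectable small-study bias (none was
planted).  Stage 06 prints the receptor correlations:

```
   map         r   p_perm    q_fdr   p_bonf  sig_fdr
    D2 -0.336218 0.000999 0.001798 0.008991     True
    D1 -0.310635 0.000999 0.001798 0.008991     True
   DAT -0.310522 0.000999 0.001798 0.008991     True
 VAChT -0.271737 0.000999 0.001798 0.008991     True
  5HT4 -0.267782 0.000999 0.001798 0.008991     True
 5HT1a  0.004031 0.938062 0.938062 1.000000    False
```

The five planted negative associations are significant after FDR (and
Bonferroni); the four null maps are not.  `imtx demo --seed 0 --out demo/`
runs the same chain as one deterministic command.

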