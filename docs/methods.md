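# Methods

This note documents the models, conventions and numerical choices behind
`biofilmquant`, and what its synthetic-data tests do and do not
demonstrate about real assay data.

## Settling (flocculation) ratio

A flocculent culture clears from the top down as clumps settle; the
photograph of the tube at the final time point therefore shows a
low-intensity cleared band above a high-intensity dense region. The
measurement follows the plot-profile procedure: a line annotated from
the meniscus to the tube bottom is sampled at ~1-px spacing with
bilinear interpolation (`scipy.ndimage.map_coordinates`, order 1), and
the cleared fraction is

```
ratio = (distance to first sample >= max_gray / 2) / line length
```

with `max_gray` taken over the sampled profile of that line (not the
whole image). Three lines per image are averaged.

Conventions and caveats:

* **Polarity.** The dense region is assumed brighter than the cleared
  supernatant. Photographs with the opposite contrast are handled by the
  `invert` flag (value → 255 − value), exposed on `settling_score`,
  `load_image` and the CLI (`--invert-contrast`).
* **Degenerate profiles.** A constant positive profile crosses half-max
  at the origin and returns 0. This is correct for a fully dense tube
  (nothing settled ⇒ nothing cleared) but means a *fully cleared* tube —
  a constant low-intensity profile — is indistinguishable from it and
  also returns 0. The first-crossing definition simply carries no
  information once no dense region remains in the frame; recovery tests
  therefore cover cleared fractions up to 0.9. An all-zero profile
  (empty frame) returns 0 with a warning.
* **Discretization.** With 1-px sampling on an H-px tube the crossing is
  resolved to one sample, so recovered fractions carry an O(1/H) bias
  (≈0.004 for the default 240-px render). The synthetic recovery
  tolerance of ±0.02 is dominated by this, not by the σ = 2 gray-level
  noise.

## Background-corrected invasion intensity

Each washed invasion spot is measured inside an annotated ROI (circle by
center/radius with center-of-pixel membership, or an explicit mask). With
the total image area and mean gray `A_t, I_t` and the spot's `A_s, I_s`,

```
background   = (A_t * I_t - A_s * I_s) / (A_t - A_s)
corrected    = max(0, I_s - background)
```

The background expression is algebraically the mean of the pixels outside
the ROI — an identity the test suite checks to 1e−9 against a brute-force
complement mean on random images. Clamping to zero is applied per spot
measurement, before replicate averaging; `invasion_score` then averages
the three replicate spots. The corrected value is invariant to a constant
intensity offset (until clipping at 0/255 interferes), which is what
makes the statistic robust to overall exposure differences between
plates.

Color photographs are converted to gray with fixed ITU-R BT.709 luminance
weights (0.2126, 0.7152, 0.0722). Consumer photo software performs an
unspecified conversion; the fixed weights are a documented, reproducible
stand-in, and any monotone channel mix leaves the half-max crossing and
background-difference statistics nearly unchanged on these
low-chroma images.

## Crystal-violet adhesion

`adhesion_score` averages OD570 across the 2–3 technical replicate
wells. Blank subtraction is available but off by default — the assay
protocol modelled here has no blank wells — and negative post-blank
readings are clamped to zero with a warning.

## Panel model and simulated data

The long-format panel holds one row per (strain, ploidy, phenotype,
replicate). The simulator draws, per strain, a latent propensity vector

```
h = softplus(loc + L z),   z ~ N(0, Sigma),  Sigma a correlation matrix
```

where `softplus(x) = log(1 + e^x)` maps to the nonnegative scale while
approximately preserving the correlation target, and `L` is the
(eigendecomposition) square root of Sigma, so semidefinite targets are
accepted. Diploid propensities are `factor × h` with a per-phenotype
factor and optional per-strain exception overrides, applied **before**
replicate noise, so the ground-truth effect is explicit. Technical
replicates add Gaussian noise (clipped below 0); ordinal 0–5 scores
threshold the noise-free latent at per-phenotype ascending cut points,
and are therefore monotone in the latent by construction.

Default study conditions (chosen once, as the realistic panel this
package targets): 31 strains, six phenotypes, three technical
replicates, latent location 1.0 (median propensity ≈ 1.3 on a 0–4 working
scale), replicate SD 0.05, ordinal cuts at 0.5–2.5 in steps of 0.5, and
diploid factors {colony 0.8, mat 0.9, flocculation 0.1, invasion 0.8,
adhesion 0.3, filamentous 1.0} reflecting the observed pattern that
diploidy collapses flocculation, strongly weakens polystyrene adhesion,
and leaves invasion largely intact. Photograph noise magnitudes are not
documented for the real assays, so the synthetic noise levels are free
parameters rather than calibrated values.

What the simulator does **not** emulate: spatial invasion patterns
(edges, punctae), tube meniscus curvature and reflections, uneven
illumination, clump texture in the settled band, plate-position effects
in OD570, or biological-replicate variance components. Passing recovery
tests show the estimators are correct for their geometric/statistical
model, not that annotation placement or lighting artifacts are harmless
on real photographs.

## Statistics

* **Kendall tau-b** (`scipy.stats.kendalltau`, asymptotic p) with tie
  correction — rubric scores are heavily tied, and the tie-corrected
  normal approximation is the standard treatment (and R's default for
  tied data). A brute-force O(n²) pair-count oracle backs the
  implementation in tests. Vectors that are entirely tied in either
  argument raise an error rather than return NaN.
* **Welch's t-test** (`scipy.stats.ttest_ind(equal_var=False)`),
  two-sided, across technical replicates. A "paired test assuming
  unequal variance" is internally contradictory — paired tests operate
  on per-pair differences, where a variance inequality between samples
  has no meaning — and replicate cultures of a haploid and its diploid
  have no natural pairing, so the unpaired Welch form is the defensible
  reading and the one implemented. The degenerate both-samples-constant,
  equal-means case returns t = 0, p = 1.
* **FDR**: Benjamini–Hochberg step-up adjusted p-values, used as
  q-values with significance at q ≤ α (default 0.05). Storey's π₀
  estimation is not implemented; BH is deterministic and is the named
  procedure. Pooling is per phenotype across strains — one family per
  phenotype column of the summary table.
* **Calls**: per strain and phenotype, `decrease`/`increase` by the sign
  of (diploid mean − haploid mean) when significant, else `no_change`.
  Strains lacking ≥2 replicate values in either ploidy are excluded with
  a logged warning, not imputed.
* **OLS** (`scipy.stats.linregress`): slope, intercept, R². A constant
  response returns slope 0 and R² = 0 by convention; a constant
  predictor is an error. Because biological replicates can be kept
  separate or averaged first (`aggregate_replicates`), correlation R²
  values depend on that input choice; the pipeline exposes both rather
  than designating one as canonical.

## Clustering and TreeView output

Strains are clustered on their phenotype vectors after per-phenotype
linear normalization to [0, 5] within one ploidy stratum (haploid by
default), by Euclidean distance and agglomerative linkage
(`scipy.cluster.hierarchy`). Average linkage is the default — the common
choice in the Cluster 3.0 lineage of tools — with single and complete
available. Rows are put in lexicographic strain order before linkage so
results are invariant to input row order (deterministic tie-breaking).
Strains missing any phenotype are dropped with a warning, not imputed.

Outputs: a CDT (tab-delimited matrix with the GID/ORF/NAME/GWEIGHT
header, rows in dendrogram leaf order), a GTR whose node values are on
the similarity scale `1 − height/max_height` (TreeView stores
correlations, not distances), a Newick tree with branch lengths
(parent height − child height) and a leaf-order text file. All files use
Unix line endings.

## Problem sizes in tests and the acceptance script

Recovery and Monte-Carlo checks run at sizes where the target property
is statistically decidable in seconds: 9 cleared fractions × 3 lines on
240-px tubes; 200 random images for the background identity; 1,000
random length-8 ordinal vectors for the tau oracle; 10,000 null draws
(n = 10 per sample) for the Welch type-I rate; 50-strain panels for
classification recovery; 20 seeds of 10 + 10 strain two-group panels for
the top-split check. These sizes give Monte-Carlo standard errors well
inside the asserted tolerances (e.g. ±0.01 on a 0.05 rejection rate at
10,000 draws ≈ 4.6 SE).

## Known limitations

* No automatic detection of tubes, menisci or spots; annotation quality
  bounds measurement quality.
* The settling statistic reduces the whole profile to one crossing; the
  slope and integral of the profile carry additional information about
  settling behaviour that is deliberately not captured.
* The invasion statistic discards spatial structure within the spot.
* Clustering of ~30 strains is underpowered for niche-level conclusions;
  no bootstrap support is computed.
* No phylogenetic correction: correlated phenotypes across related
  strains may reflect shared ancestry rather than mechanistic links.
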