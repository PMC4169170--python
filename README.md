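# biofilmquant

Quantification and statistical analysis of yeast biofilm-related
phenotypes in strain panels — the kind of multi-assay survey run on
natural isolates of *Saccharomyces cerevisiae*, where each strain is
characterized for complex colony morphology, complex mat formation,
flocculation (settling), agar invasion, polystyrene adhesion and
filamentous growth, in both haploid and diploid form.

The package is aimed at yeast geneticists who photograph their assays and
export plate-reader tables, and want reproducible numbers and statistics
out the other end. It provides:

* **Settling (flocculation) ratio** from tube photographs: along a line
  drawn from the meniscus to the tube bottom, the intensity plot-profile
  is sampled (bilinear interpolation, 1-px steps) and the cleared
  fraction is the first position where the gray value reaches half of the
  profile maximum, divided by the line length; three lines per image are
  averaged.
* **Background-corrected invasion intensity** from washed agar-spot
  photographs: with the whole-image area/mean *A*ₜ, *I*ₜ and the spot ROI
  area/mean *Aₛ*, *Iₛ*, the background is
  (*A*ₜ·*I*ₜ − *Aₛ*·*Iₛ*)/(*A*ₜ − *Aₛ*) — algebraically the mean gray of
  the pixels outside the spot — and the corrected intensity is
  max(0, *Iₛ* − background), averaged over three replicate spots.
* **Crystal-violet adhesion**: mean OD570 across technical replicate
  wells, with optional blank subtraction.
* **Statistics**: Kendall's tau-b (tie-corrected) on ordinal 0–5 scores;
  Welch's unequal-variance t-test comparing haploid vs diploid technical
  replicates per strain; Benjamini–Hochberg FDR control within each
  phenotype, yielding per-strain *decrease / no_change / increase* calls
  and the per-phenotype count summary; OLS slope and R² for
  replicate-vs-replicate and haploid-vs-diploid correlation plots.
* **Clustering**: per-phenotype linear normalization to [0, 5],
  Euclidean distances between strain phenotype vectors, agglomerative
  clustering (average linkage by default) and TreeView-compatible
  CDT/GTR output plus Newick.
* **Synthetic data** with known ground truth — rendered tube and spot
  images, simulated panels with a chosen inter-phenotype correlation and
  per-phenotype diploid attenuation — so every stage is testable by
  parameter recovery.

## Worked example

```python
import biofilmquant as bq

# a synthetic tube photo, 65% cleared, with camera noise
spec = bq.TubeSpec(cleared_fraction=0.65, noise_sd=2, seed=12)
img = bq.render_settling_image(spec)
lines = [bq.ProfileLine((x, 0.0), (x, img.height - 1.0)) for x in (15.0, 30.0, 45.0)]
print(bq.settling_score(img, lines).ratio)        # 0.6527

# a synthetic invasion spot: level 120 on background 20
sspec = bq.SpotSpec(background_level=20, spot_level=120, noise_sd=1, seed=12)
image, truth = bq.render_invasion_image(sspec)    # truth = 100
m = bq.measure_spot(image, bq.SpotROI(center=sspec.spot_center,
                                      radius=sspec.spot_radius_px))
print(m.background, m.corrected)                  # 20.014  99.998

# a 24-strain haploid/diploid panel with the default attenuation pattern
panel = bq.simulate_panel(bq.PanelSpec(n_strains=24, seed=12))
calls = bq.classify_ploidy_changes(panel, ["flocculation", "invasion", "adhesion"])
print(bq.summarize_ploidy_changes(calls))
```

The summary prints the per-phenotype triple of diploid-change calls:

```
   phenotype  n_strains  n_decrease  n_no_change  n_increase
    adhesion         24          24            0           0
flocculation         24          24            0           0
    invasion         24          23            1           0
```

i.e. with the default simulated attenuation, diploid flocculation and
adhesion are called significantly decreased for every strain, and
invasion for all but one (q-value above 0.05 after BH correction).

The measured settling ratio 0.6527 differs from the true cleared
fraction 0.65 only by the 1-pixel discretization of the half-max
crossing on a 240-px tube; the corrected invasion intensity recovers the
constructed 100 gray-unit truth to well within one gray unit.

A command-line interface wraps the same stages:

```bash
biofilmquant simulate --out demo --seed 1 --n-strains 30
biofilmquant quantify-settling --images demo --annotations lines.csv --out settling.csv
biofilmquant analyze --panel demo/panel.csv --out results/
```

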