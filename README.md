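# acfsa

Analyte classification and sensor-set selection for fluorescence
sensor arrays.

Optical "nose" platforms identify analytes from the joint response
pattern of many cross-reactive sensors — here, near-infrared
fluorescent carbon-nanotube suspensions whose peptide corona phases
respond to transition-metal ions with chirality-specific intensity
changes. Running every sensor for every assay is wasteful: a small,
well-chosen subset often carries the whole fingerprint. `acfsa`
implements the full pipeline from raw emission spectra to a minimal
sensor set and a ready-to-use analyte classifier, for chemometricians
and sensor developers screening candidate sensor libraries.

## Method

Given a response table of relative intensity changes
ΔI/I₀ = (I − I₀)/I₀ for *n* sensors × *k* analytes × *r* replicates,
each iteration of the selection loop:

1. reduces the surviving responses to two principal components (PCA,
   mean-centering only);
2. partitions the samples with *k*-means (k-means++ init, 10 seeded
   restarts) into *k* clusters;
3. matches cluster indices to analyte names with the Kuhn–Munkres
   (Hungarian) assignment on the contingency table;
4. scores the clustering against ground truth with the adjusted Rand
   index (ARI);
5. builds a nearest-centroid Voronoi classifier from the cluster
   centers and quantifies it by the mean intercluster distance ⟨D⟩ and
   by the classification error — the probability mass of each
   cluster's fitted 2D Gaussian falling outside its own Voronoi cell
   (Monte-Carlo estimate, equal priors);
6. uniformly discretizes each sensor's responses into ten bins, forms
   the bins × cluster-labels contingency table, and eliminates the
   sensor with the smallest Pearson chi-squared statistic.

The loop repeats, refitting everything on the survivors, until a
stopping condition is met (a sensor count, or ARI / error thresholds).
A spectral front end fits Lorentzian peaks I(λ) = b + A·γ²/((λ−λ₀)²+γ²)
per chirality emission window to turn raw spectra into ΔI/I₀, and a
synthetic generator reproduces the statistical structure of a
30-sensor × 5-analyte × 5-replicate screen for end-to-end testing.

## Worked example

```python
import acfsa

spec = acfsa.paper_like_spec(seed=1)          # 30 sensors × 5 metal ions
table = acfsa.generate_response_table(spec)   # 25 samples × 30 sensors
trace = acfsa.run_acfsa(
    table,
    acfsa.StoppingCondition(min_sensors=2),
    acfsa.ACFSAConfig(kmeans_seed=1, mc_seed=2, n_mc=100_000),
)
first, last = trace.records[0], trace.records[-1]
print(f"iterations: {len(trace.records)}  eliminations: {trace.n_eliminations}")
print(f"min ARI over run: {min(r.ari for r in trace.records):.3f}")
print(f"full set:  <D> = {first.mean_intercluster_distance:.3f}  "
      f"error = {first.error:.5f}")
print(f"final set: {last.sensors}  <D> = "
      f"{last.mean_intercluster_distance:.3f}  error = {last.error:.5f}")
```

prints

```
iterations: 29  eliminations: 28
min ARI over run: 1.000
full set:  <D> = 2.546  error = 0.00000
final set: ('Gly-(7,5)', 'GlyOx-(6,5)')  <D> = 0.762  error = 0.00000
```

All 28 eliminations keep the clustering identical to ground truth
(ARI = 1): two sensors carry the full five-metal fingerprint. Shrinking
the set reduces ⟨D⟩ — the centers move closer in PC space — while the
estimated misclassification probability stays ≈ 0 because the cluster
Gaussians (σ ≈ 0.03 per axis) remain far narrower than the cell sizes.
The same entry points are available from a shell:

```sh
acfsa simulate --spec paper_like --seed 1 -o out/
acfsa run --table out/responses.csv --stopping min_sensors=2 -o out/run/
acfsa classify --classifier out/run/classifier.json --sample sample.csv
acfsa fitpeaks --manifest spectra/manifest.csv -o responses.csv
```

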