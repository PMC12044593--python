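# Methods

This note documents the models and numerical choices behind `acfsa`:
what each stage assumes, which knobs matter, what the synthetic screen
does and does not emulate, and where genuinely open design questions
were settled.

## Response model and spectral front end

A sensor is one (suspension, nanotube chirality) channel. Its signal is
the height of the chirality's emission peak, obtained by least-squares
fitting of a Lorentzian line shape with a constant baseline,

I(λ) = b + A·γ² / ((λ − λ₀)² + γ²),

restricted to a per-chirality wavelength window. The height
parameterization (A = peak height above baseline) is used — rather
than the area form common in spectroscopy toolkits — because the
response statistic is the fractional height change
ΔI/I₀ = (A − A₀)/A₀ against the analyte-free baseline fit; positive
responses are turn-on, negative turn-off. Peak area would be an
equally defensible intensity proxy; height was chosen because it is
what the fractional-change definition acts on directly and is
insensitive to window truncation of the Lorentzian's heavy tails.

Fitting uses `scipy.optimize.curve_fit` with deterministic initial
guesses (λ₀ at the window argmax, A = max − min, γ = quarter window
width, b = window minimum) and box constraints (λ₀ inside the window,
γ > 0, A ≥ 0). On noiseless in-model spectra the fit recovers all four
parameters to ≤ 1e-6 relative; at 1% additive noise the center is
recovered to well under 1 nm on average. Overlapping chirality peaks
are handled by *disjoint single-peak windows*, not joint multi-peak
deconvolution: the three default windows (950–1040, 1010–1090,
1090–1170 nm for the (6,5), (7,5), (9,4) chiralities at 570/660/730 nm
excitation) bracket well-separated emission maxima, which is the reason
those chiralities are used as channels in the first place. The default
windows are overridable wherever a `ChiralityWindow` is accepted.

## The selection loop

Inputs: a complete samples × sensors table of ΔI/I₀ (k analytes ×
r replicates) with ground-truth labels. Each iteration refits, from
scratch, on the surviving sensors:

1. **PCA to 2 components.** Mean-centering only by default; responses
   are already dimensionless on a shared scale, so unit-variance
   scaling is off (a `standardize` flag enables it). Component signs
   are fixed deterministically (largest-magnitude loading positive) so
   repeated runs are byte-identical. With a single surviving sensor
   the second component is a zero-variance axis and all downstream 2D
   geometry degenerates gracefully to 1D.
2. **k-means, k = number of analytes**, on the 2D coordinates
   (k-means++, 10 restarts, fixed seed). Clustering in the 2D score
   space rather than the full sensor space matches the fact that the
   classifier operates in that plane.
3. **Kuhn–Munkres matching** of cluster indices to analyte names,
   maximizing the trace of the permuted contingency table.
4. **ARI** against ground truth. ARI is permutation-invariant, so the
   matching affects naming only, never the score.
5. **Voronoi classifier** from the centers (next section).
6. **Chi-squared ranking.** Each surviving sensor's *raw* responses
   (not PC scores) are uniformly discretized into 10 bins over the
   sensor's own [min, max]; the Pearson statistic of the bins ×
   matched-cluster-labels contingency table (empty bins dropped) ranks
   the sensors, and the minimum is eliminated. Ties break
   lexicographically by sensor id, constant sensors score 0 with a
   warning. Cluster labels, not ground truth, are the response
   variable; the two coincide whenever ARI = 1, which is the regime the
   method is designed to operate in.

**Stopping semantics.** `min_sensors` is an elimination floor: the loop
stops once that many sensors survive. `min_ari` / `max_error` are
*performance floors*: the practically useful question is "what is the
smallest sensor set still meeting the thresholds", and a
stop-at-first-satisfaction rule would terminate immediately at the full
set (which typically already satisfies them). The loop therefore runs
down to the floor and then selects the smallest surviving set whose
iteration met all set thresholds; if none did, the trace is returned
with status `"exhausted"` rather than raising. ARI need not be
monotone along the elimination — removing a noisy sensor can *improve*
clustering — and this selection rule is robust to that.

A `random` strategy replaces step 6 with a seeded uniform draw; it is
the baseline against which the chi-squared ranking is compared (the
ranking reaches a perfect low-error classifier with at most as many
sensors, verified over seeded repeats).

## Voronoi classifier and classification error

The classifier is the set of labeled cluster centers plus the trained
PCA transform; a query's raw responses are projected with the
*training* mean and loadings and assigned to the nearest center
(perpendicular-bisector cells). Centers are stored in analyte-name
order and exact ties resolve to the lower index, so tie-breaking is
reproducible; ties are flagged in the result.

Classifier quality:

* **⟨D⟩** — the mean of the k(k−1)/2 pairwise Euclidean center
  distances. More sensors generally yield larger ⟨D⟩, and ⟨D⟩
  anticorrelates with the error along the elimination, making it a
  useful design proxy.
* **Classification error** — per cluster, fit a 2D Gaussian (sample
  mean and covariance of the cluster's points) and estimate the
  probability mass falling outside that cluster's cell; report the
  unweighted mean over clusters. Equal priors are assumed because the
  screen is balanced by design. The estimate is Monte-Carlo
  (default 10⁶ draws per cluster, seeded; the estimate's standard
  error is reported alongside) rather than analytic polygon
  integration: it is exact in expectation for arbitrary cell geometry,
  trivially correct for any k, and its error is controlled by the
  reported SE. Singular covariances (collinear clusters) are
  regularized with a 1e-10 diagonal jitter. MC assignment ties go to
  the lower-index center — a measure-zero convention.

## Synthetic screens

The generator exists so every stage is testable end-to-end without
measured data. The default screen mirrors a realistic metal-ion
fingerprinting study: 10 corona phases (5 peptide sequences, each
plain and photo-oxidized) × 3 chiralities = 30 sensors, 5 analytes,
5 replicates, i.i.d. Gaussian noise with absolute σ = 0.03 in ΔI/I₀
units (the "~3%" per-sensor scatter of such screens; absolute rather
than proportional because the responses are themselves already
relative quantities).

The mean response matrix is drawn once per seed from a low-rank
scheme M = u·vᵀ + w·zᵀ + ε: analytes sit on a dominant response axis
(scores equally spaced over ±1.1, permuted and jittered), every sensor
loads on that axis with magnitude in [0.25, 0.55] and a random sign,
plus a weak secondary axis (loading σ 0.07) and per-entry residuals
(σ 0.035), clipped to the physical range (ΔI/I₀ > −1). This structure
was chosen over i.i.d. uniform profiles deliberately: real
sensor-array screens of this kind are strongly PC1-dominated
(≈ 90% / 5% explained variance), and a shared dominant axis is what
makes *any* sensor subset preserve the analyte ordering — with
i.i.d. profiles the five analyte means span four dimensions and the
top-2 PC plane of an intermediate subset can project two analytes onto
each other, which is not how the measured screens behave. The
generated screens reproduce the documented regime: PC1/PC2 ≈ 96%/3%,
responses spanning roughly ±0.8 with both signs, ARI = 1 at every
elimination iteration, and the signed per-sensor profiles that make
the ±1 binarized variant collapse same-sign analytes. A drawn matrix
is audited (any analyte pair within L∞ distance 0.3 = 10σ triggers a
full redraw) so separability is guaranteed, not assumed.

What the generator does **not** emulate: analyte-concentration
dependence, inter-replicate drift or batch effects, sensor-sensor
noise correlation, heteroscedastic noise, or matrix effects (serum,
mineral water). Passing tests therefore demonstrate the algorithmic
pipeline under the stated noise model, not robustness to those
real-data pathologies. The stress preset (50 replicates, 4× σ) probes
one failure axis — inflated i.i.d. noise — and shows the expected
graceful degradation: clusters overlap, some ground-truth points leave
their 95% ellipses, and ARI drops during (not at the start of) the
elimination.

Spectra fixtures are generated by the same module: sums of Lorentzians
with chosen centers/widths/amplitudes plus seeded Gaussian noise, and
`spectra_from_responses` plants a whole screen's ΔI/I₀ into baseline/
analyte spectrum pairs so the spectra → table round trip can be checked
against known values.

## Confidence ellipses

Per-cluster 95% ellipses follow the Gaussian quadratic form: axes along
the eigenvectors of the sample covariance, semi-axis lengths
√(χ²₂(0.95)·λᵢ) ≈ 2.4477·σ per axis for isotropic data. Collinear
clusters yield a degenerate (zero-minor-axis) ellipse, flagged rather
than raised.

## Problem sizes and tolerances

Default problem sizes were picked so a full run is interactive on one
CPU: the 30 → 2 elimination on the default screen takes seconds with
10⁵ MC draws per cluster per iteration, and the brute-force test
oracles (exhaustive partitions at n ≤ 8, permutations at k ≤ 6,
pair-counting ARI at n ≤ 12) each complete in well under a minute.
Noiseless round-trip assertions use 1e-6 tolerances (limited by
optimizer convergence, not arithmetic); Monte-Carlo assertions use
3 estimated standard errors.

## Known limitations

* Two retained components are hard-wired, as is the nearest-centroid
  decision rule; neither is adequate if more than ~2 effective response
  dimensions separate the analytes.
* The error estimate trusts the per-cluster Gaussian fit, which rests
  on r − 1 degrees of freedom per cluster (4, at 5 replicates); with
  few replicates the reported error is itself noisy.
* Chi-squared ranking is univariate: a sensor informative only jointly
  with another can be eliminated early. The random baseline bounds how
  much this costs in practice on well-structured screens.
* The classifier has no rejection option: an out-of-library analyte is
  always assigned to some known analyte's cell.
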