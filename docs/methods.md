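# Methods

## Model

A transcriptome profile is treated as a point in gene space. For each
labeled subset *g* of samples the center is the arithmetic mean of its
members' profiles, computed on whatever scale the matrix is in — no
internal re-normalization is applied, because the default metric (the
uncentered cosine dissimilarity, called "Pearson distance" throughout)
is invariant to per-sample positive rescaling. Each sample is then
described by its distance profile (r₁, …, r_k) to all centers; the
distance to the normal-tissue center is interpreted as drift away from
homeostasis and is the quantity carried into the downstream statistics.

Three layers sit on the geometry:

* **Classification.** A sample is assigned to the nearest center; the
  margin (runner-up minus best) quantifies confidence. Exact ties break
  lexicographically by label and are flagged. Because a sample pulls its
  own group's mean toward itself, naive centroids overstate accuracy;
  `leave_one_out_profiles` recomputes each sample's own-group centroid
  without it (mean-update identity, O(1) per sample) and should back any
  accuracy claim. Naive centroids remain the default because they define
  the center geometry itself.
* **Ternary view.** With exactly three centers the normalized
  coordinates dᵢ = rᵢ / (r₁+r₂+r₃) place each sample in an equilateral
  triangle. Plotting packages use the mixture convention
  Dᵢ = ½(1 − dᵢ/Σⱼdⱼ), which for normalized d reduces to (1 − dᵢ)/2 —
  the unique affine image with ΣD = 1, so the two conventions are
  mutually invertible. `D` is the plotting default; `d` is the faithful
  distance-proportional form. Note the semantics flip: a sample at
  center j has dⱼ = 0 but maximal Dⱼ.
* **Association.** Distances-to-normal of two groups are compared with
  Welch's unequal-variance t-test (default) or Mann-Whitney; when more
  than one pair is tested, Benjamini-Hochberg adjusted p-values are
  reported next to the raw ones (raw values are primary). Survival is
  fit by OLS, `days = a + b·r_normal`, with the two-sided t-test of
  b = 0 and R² equal to the squared Pearson correlation. Censoring is
  deliberately not modeled: survival enters as an observed time, and
  any censoring annotation is ignored with a warning. Cox or
  Kaplan-Meier analyses are out of scope by design.

## Distances and their numerics

* Euclidean, scaled (per-gene RMS normalization Mᵢ² = ⟨xᵢ²⟩ over the
  dataset), cosine, Mahalanobis — definitions in the README table.
* The cosine form is **uncentered** (1 − cos∠); a mean-centered variant
  exists behind `centered=True` but is never a default. The cosine is
  clamped to [−1, 1] so identical vectors give exactly 0.
* The covariance matrix defaults to the centered sample covariance with
  divisor n; the literal uncentered second-moment matrix ⟨xᵢxⱼ⟩ is
  selectable and the choice is recorded on the result
  (`CovarianceMatrix.centered`).
* With more genes than samples S is singular. Default inversion is the
  Moore-Penrose pseudo-inverse with singular values below 1e-10 of the
  largest truncated; a ridge inverse (S + λI)⁻¹ with user-supplied λ is
  the alternative. The mode actually applied is recorded
  (`inverse_used`). The pseudo-inverse metric is a seminorm: directions
  in the null space contribute zero distance, which is the honest
  statement of what n samples can calibrate.
* Genes with zero RMS scale (zero in every sample) are dropped, with a
  warning, before scaled distances — they carry no information and
  would divide by zero. They are kept for Euclidean and cosine.
* All distance computations are deterministic; profile tables are
  computed vectorized (scipy `cdist`) and unit tests pin them to the
  scalar definitions.

## Value scale

Expression matrices arrive either linear (FPKM-like) or log2 (RMA-like);
the loader's `transform` option (`none` | `log2p1`) makes the choice
explicit rather than guessing. The scale matters for the cosine metric:
on linear values with a realistically heavy-tailed expression
distribution, the few most-expressed genes dominate the inner products
and the effective dimensionality collapses; on log2 values all genes
contribute comparably. Classification benchmarks in this package
therefore run on `log2p1`-transformed values, mirroring how log-scale
microarray matrices are consumed in practice; distances on linear values
remain fully supported.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes,
with every draw governed by one integer seed:

* per-gene baseline `bᵢ`, log-normal with log-mean 3 and log-sd 1 —
  right-skewed positive values spanning a few orders of magnitude, like
  normalized expression;
* group centroid `c = b ⊙ exp(drift · u)` with `u` a seed-fixed random
  unit vector: **drift** is the Euclidean norm of a log-space
  displacement, so no gene subset is privileged and values stay
  positive without clipping;
* samples `x = c ⊙ exp(ε)`, `εᵢ ~ N(0, dispersion²)`: **dispersion** is
  the per-gene log-sd, making drift/dispersion a signal-to-noise ratio
  independent of the gene count (between-centroid log-distance = drift;
  per-gene log-noise = dispersion);
* survival `days = intercept + slope · r_normal + N(0, σ)`, truncated
  at 0. Defaults: slope −1.35 × 10⁴ days per unit cosine distance,
  intercept 1.94 × 10³ days. When σ is left unset it is calibrated from
  the realized distance spread so the population R² is 0.09 — a weak
  but real prognostic signal; σ = |slope|·sd(r)·√((1−R²)/R²).

Draw order does not depend on the drift values, so cohorts generated
from the same seed at different drifts share their random numbers —
drift-response studies are exact common-random-number comparisons.

What the generator does **not** emulate: probe/batch effects, gene-gene
correlation structure beyond the shared baseline, censoring, multimodal
subtypes within a group. Passing tests therefore demonstrate the
machinery and its statistical calibration, not performance on any real
cohort.

## Validation study sizes

The test suite and `scripts/acceptance.py` use deliberately compact
cohorts chosen to make their effects unambiguous:

* separation regime: 3 groups × 50 samples, 300 genes, drift 10× the
  dispersion (log-space SNR 10) — leave-one-out accuracy ≥ 99%;
* null regime: the same design with zero drift over 20 seeds — accuracy
  statistically indistinguishable from 1/3 (pooled binomial test);
* drift grid 0.25–4.0 at fixed seed — median distance-to-normal of the
  diseased group strictly increasing, and within each cohort
  normal < low-grade < high-grade;
* survival recovery: 400 tumor + 50 normal samples per replicate,
  planted slope −1.35 × 10⁴, noise calibrated to population R² = 0.09;
  across replicates the fitted slope is negative in ≥ 99%, the planted
  slope falls in the 95% CI in ≥ 90%, and the mean fitted R² sits
  within ±0.05 of 0.09 (200 replicates in the test suite, 100 in the
  acceptance script). The tumor drift (1.0) and dispersion (0.05) keep
  the planted survival essentially always positive, so the 0-day
  truncation never distorts the OLS coverage;
* calibration: 1000 null Welch simulations, rejection rate 5% ± 2% at
  α = 0.05.

## Design choices and degenerate inputs

* Duplicate gene rows (multiple probes per gene) are mean-collapsed by
  default (`max` and `first` selectable); genes with any missing value
  are dropped, not imputed — every metric assumes complete vectors.
* Multi-dataset merging intersects gene identifiers (sorted, so the
  result is order-independent) and applies **no** cross-normalization;
  the cosine metric's scale invariance is what makes the merge usable.
* Zero-norm vectors make the cosine distance undefined and raise;
  constant distance columns make the survival design degenerate and
  raise; a constant survival response yields slope 0, R² 0, p 1.
* The "normal" group is always designated explicitly (CLI
  `--normal-label`); nothing is inferred from label names. The CLI's
  survival fit excludes the normal group — reference samples anchor the
  axis but carry no disease prognosis.
* Result tables are written with 6 significant digits; expression
  matrices with 12, so a read → write → read round trip is lossless to
  1e-9.

## Known limitations

* Naive centroids include the scored sample; use `--centroid-mode loo`
  for any accuracy statement.
* The survival model is a straight line on observed times; it neither
  handles censoring nor claims more than the linear trend.
* The Mahalanobis metric in the p ≫ n regime measures distance only
  within the sample-spanned subspace (pseudo-inverse) or shrinks all
  directions (ridge); neither recovers the true population covariance.
* Barycentric views exist only for exactly three centers.
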