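# exprdrift

Distance-based classification and prognosis from whole-transcriptome
expression profiles.

## The idea

Gene-signature biomarkers are notoriously unstable: with tens of
thousands of genes and a few dozen patients (the *p ≫ n* regime),
different training sets yield almost disjoint "predictive" gene panels.
`exprdrift` takes the opposite approach and uses **all** genes at once.
Each sample's expression profile `X = [x₁, x₂, …]` is a point in the
space whose axes are genes. For every labeled subset of samples (normal
tissue, tumor, metastasis, …) the package computes a **center** — the
arithmetic mean of the member profiles — and summarizes each sample by
its distances `(r₁, …, r_k)` to all centers.

The distance from the **normal center** is read as the sample's drift
away from tissue homeostasis: a composite, continuous biomarker. On top
of this geometry the package provides nearest-center classification,
ternary (barycentric) views of three-group cohorts, two-group separation
tests, and a linear survival-vs-distance prognosis model.

Four distances are implemented:

| metric        | definition                                        |
|---------------|---------------------------------------------------|
| Euclidean     | `d² = Σᵢ (xᵢ − yᵢ)²`                              |
| scaled        | `d² = Σᵢ (xᵢ − yᵢ)² / Mᵢ²`, `Mᵢ² = ⟨xᵢ²⟩`         |
| Pearson       | `d = 1 − X·Y / (|X||Y|) = 1 − cos ∠(X, Y)`        |
| Mahalanobis   | `d² = (X−Y)ᵀ S⁻¹ (X−Y)`, `S` dataset covariance   |

"Pearson" here is the **uncentered cosine** dissimilarity: for
non-negative expression values it lies in `[0, 1]` and is invariant
under positive rescaling of either profile, so arbitrarily normalized
samples remain comparable. It is the default metric. With genes
outnumbering samples the covariance `S` is singular; the Mahalanobis
metric then uses a Moore–Penrose pseudo-inverse (or a ridge inverse
`(S + λI)⁻¹` on request).

Survival is modeled as `days = a + b·r_normal` by ordinary least
squares — a deliberately simple continuous prognosis model (no
censoring handling; see `docs/methods.md`).

## Worked example

Simulate a cohort — 20 normal, 120 tumor and 60 metastasis samples, 500
genes, tumor groups drifted away from the baseline, survival coupled to
distance-from-normal — and run the full pipeline:

```sh
exprdrift simulate --n-genes 500 \
    --groups "normal:20:0:0.05,tumor:120:0.8:0.1,metastasis:60:0.6:0.1" \
    --seed 42 --out demo/sim
exprdrift all demo/sim/matrix.tsv demo/sim/metadata.tsv \
    --normal-label normal --out demo/run
```

`demo/run/comparisons.tsv` — Welch tests on distance-to-normal:

```
group_a     group_b  n_a  n_b  test   statistic  p_value      p_adj_bh
metastasis  normal   60   20   welch  28.4833    1.43731e-41  2.15597e-41
metastasis  tumor    60   120  welch  -1.37532   0.171119     0.171119
normal      tumor    20   120  welch  -32.6732   1.45774e-66  4.37322e-66
```

Both diseased groups sit far from the normal center (p ≈ 10⁻⁴¹ and
10⁻⁶⁶) while tumor and metastasis overlap each other — primary tumors
need not be closer to homeostasis than the metastases seeded from them.

`demo/run/survival_fit.txt` — the prognosis fit on the 180 diseased
samples:

```
survival ~ distance (OLS)
  n          180
  slope      -16278.6 days per unit distance (95% CI -22620.3 .. -9936.89)
  intercept  1957.98 days
  p (slope)  1.01e-06
  R^2        0.126
```

The farther a sample drifts from the normal center, the shorter the
survival; the generator's planted slope (−1.35 × 10⁴ days per unit
cosine distance) lies inside the confidence interval, and distance
explains ~13% of survival variance here (the planted population value
is 9%). The run also writes `profiles.tsv` (per-sample distances,
nearest-center call and margin), `barycentric.tsv` (ternary coordinates
in both the distance-proportional `d` and plot-convention `D` forms),
four PNG plots, and `provenance.txt` with the config and input
checksums.

Classification in the same cohort, scored honestly with leave-one-out
centroids on log2-scale values:

```
$ exprdrift classify demo/sim/matrix.tsv demo/sim/metadata.tsv \
      --centroid-mode loo --transform log2p1 --out demo/cls
accuracy (loo centroids, pearson): 1.0000
```

The same steps are available as a library — `generate_cohort`,
`compute_centers`, `distance_profiles`, `to_barycentric`,
`compare_groups`, `fit_survival` — see the docstrings and
`docs/methods.md`.

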