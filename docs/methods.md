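# Methods

## Model and assumptions

The package models a grayscale MR slice as piecewise-constant tissue
intensities corrupted by a smooth, strictly positive multiplicative gain
(the bias field `h`) plus noise. Clustering and bias estimation are solved
jointly by minimizing

```
A(V, T, U, h) = Σ_i Σ_{k∈Ω} v_ik^n N_ik + γ Σ_{k∈Ω} (1 − h_k)²
N_ik = α T_i(k) (I_k − h_k u_i)² + (1−α) Σ_{r∈O_k} K(r−k) (I_k − h_r u_i)²
```

over the foreground domain Ω, where `V = [v_ik]` are fuzzy memberships
(rows on the probability simplex), `U = {u_i}` the class intensity centers,
`T` a one-hot label function that gates the global term, and `K` a
truncated Gaussian kernel. The kernel term is what identifies `h` as
*smooth* structure: a pixel's dissimilarity depends on the bias at all
pixels in its window, so the stationary `h` is a kernel-weighted average
and cannot fit pixel-to-pixel noise. The `γ` penalty anchors the otherwise
scale-free gain at 1, which both fixes the `h·u` degeneracy and keeps the
corrected image `I/h` at the gray level of the input.

Assumptions worth stating: the gain is multiplicative and varies slowly
relative to the kernel width; tissue classes are unimodal in intensity;
the background is separable by a threshold on intensity.

### Block updates

All three blocks have closed-form exact minimizers, derived by setting the
corresponding partial derivative of `A` to zero:

* memberships: `v_ik = [Σ_a (N_ik/N_ak)^{1/(n−1)}]^{-1}`; exact zeros of
  `N` receive the full (equally split) membership;
* centers: `u_i = Σ_k v_ik^n I_k [α h_k T_i + (1−α)(h ∗~ K)_k] /
  Σ_k v_ik^n [α h_k² T_i + (1−α)(h² ∗~ K)_k]`;
* bias: `h_k = [α I_k A1⁽¹⁾ + (1−α)((I·A2⁽¹⁾/Z) ∗ K)_k + γ] /
  [α A1⁽²⁾ + (1−α)((A2⁽²⁾/Z) ∗ K)_k + γ]` with
  `A1⁽¹⁾ = Σ_i v_i^n u_i T_i`, `A1⁽²⁾ = Σ_i v_i^n u_i² T_i`,
  `A2⁽¹⁾ = Σ_i v_i^n u_i`, `A2⁽²⁾ = Σ_i v_i^n u_i²`.

`∗~` denotes the foreground-renormalized convolution
`(f ∗~ K)_k = Σ_r K(r−k) m_r f_r / Z_k`, `Z_k = Σ_r K(r−k) m_r`; the bias
update uses its adjoint (hence the division by `Z` *inside* the
convolution). Correctness of each update is pinned in the test-suite by
independent numerical minimizers (simplex grid search, golden-section
search, per-pixel parabola fit of the energy), not by the algebra alone.

### Label step and monotonicity

The label function is conceptually the argmax of the current membership.
Taken literally, that step can *increase* the energy at ambiguous pixels
(the argmax class can have both larger membership weight and larger squared
distance), which we observed as energy upticks of up to ~0.4% on seeded
phantoms. The solver therefore uses a guarded update: a pixel's label moves
to the membership argmax only when the move does not increase the
label-gated global term `α v_i^n (I_k − h_k u_i)²` at that pixel. The guard
is exact and per-pixel, preserves the guidance role of `T` (a pure
energy-minimizing `T` would perversely select near-zero-membership
classes), and makes every step of the loop — and hence the per-iteration
energy trace — non-increasing. The hard segmentation returned to the user
is always the plain argmax of the final membership.

## Pre-processing

Foreground is `I > f · max(I)` with `f = 0.05` by default; the threshold is
a fraction of the maximum so masking is scale-invariant. Each foreground
pixel is then replaced by a convex combination of its `(2r+1)²` window
(`r = 1` default) with weights
`ω_kp ∝ exp(−δ_kp) · exp(−max(|Δrow|, |Δcol|))`, background neighbours
excluded, renormalized per pixel. The deviation statistic is
`δ_kp = a_kp / mean_{p'∈M_k} a_kp'` with
`a_kp = sqrt(var_{M_p}(I) + (I_p − I_k)²)`: neighbours that are intensity
outliers, or sit in high-variance (edge) territory, are down-weighted.
Degenerate windows (constant patch, fewer than two foreground pixels)
yield the neutral `δ = 1`. Because `δ` is a ratio of deviations it is
exactly invariant under `I → cI`, and so are the filter weights.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_classes` (`d`) | required (3 for the phantom) | number of tissue classes; the data give no way to infer it, so it is a user parameter |
| `alpha` | 0.5 | global/local balance in `[0,1]`; 1 = pure label-gated clustering, 0 = pure kernel-local model |
| `gamma` | 0.01 | grayscale-preservation weight, on unit-normalized intensities |
| `fuzzifier` (`n`) | 2.0 | membership softness; must exceed 1 |
| `kernel_sigma` | 4 px | bias smoothness scale; radius defaults to `ceil(2σ)` (17×17 support) |
| `spatial_weight_radius` | 1 px | pre-filter window half-width |
| `epsilon` | 1e-4 | convergence tolerance on `‖U_new − U_old‖` (normalized scale) |
| `max_iter` | 100 | iteration cap; reaching it sets `converged_ = False`, not an error |
| `background_threshold_fraction` | 0.05 | foreground cut as fraction of max intensity |

Two defaults deserve their rationale:

* **Internal normalization is scale-only.** Intensities are divided by the
  foreground maximum before fitting (and the output rescaled back). A
  min–max *shift* would break the multiplicative model `I = h·u` that the
  closed-form updates assume; pure scaling commutes with it exactly, and
  makes `gamma` and `epsilon` meaningful across inputs of any dynamic
  range.
* **`gamma = 0.01`.** The per-pixel data weight multiplying `h` in the
  energy is of order `E[v^n u²] ≈ 0.1–0.6` on normalized intensities, so
  `γ` at a few percent of that regularizes without biasing: measured on the
  evaluation phantom, `γ = 1` pins `h` at 1 (bias recovery r ≈ 0.34) while
  `γ ≤ 0.05` recovers the simulated field with r ≥ 0.95 at per-class
  Dice 1.0. Larger `γ` trades bias-tracking for stricter grayscale
  preservation; `γ = numpy.inf` is the plain-FCM baseline with `h ≡ 1`.

## Synthetic phantoms

`generate_phantom` emulates exactly what the model assumes: a
piecewise-constant tissue map (stripes, nested equal-area disks, or Voronoi
blobs), multiplied by a smooth gain built from heavily Gaussian-smoothed
seeded noise, affinely rescaled to `[1−a, 1+a]` and normalized to
foreground mean 1, plus additive Gaussian noise (Rician available as an
option), inside a zero background margin. The default evaluation phantom is
128×128, three classes with means 0.25/0.55/0.85, amplitude 0.3,
smoothness 32 px, noise σ 0.02, margin 8, seed 17. With amplitude 0.3 the
class intensity ranges overlap (0.55·1.3 > 0.85·0.7), so a method that
ignores the bias *must* misclassify somewhere — which is why the frozen-bias
baseline loses by construction, not by accident.

What the phantom does **not** emulate: real anatomy (tissue regions are
geometric), partial-volume mixing, spatially correlated or Rician-by-default
noise, k-space artifacts, and 3D continuity. Passing the phantom tests
therefore demonstrates the estimator's internal correctness and its ability
to separate smooth gain from piecewise-constant structure — not clinical
performance on patient scans.

## Numerical choices

* Convolutions use the exact separability of the truncated Gaussian (two
  1D passes); borders and the mask are handled by renormalizing the kernel
  mass `Z` rather than padding, so all weight-sum invariants hold exactly.
* Membership ratios are computed against the per-pixel minimum
  dissimilarity to avoid overflow; exact zero dissimilarities split the
  membership equally among the zero classes.
* The bias field is floored at 1e-6 and fixed to 1 on background; argmax
  ties break toward the lowest class index; an emptied class is re-seeded
  at the foreground intensity farthest from the surviving centers (with a
  warning) rather than aborting.
* Initialization is deterministic: centers at the `(2j−1)/2d` quantiles of
  the foreground intensities, bias at 1, labels by nearest center. Two runs
  on the same input are bit-identical.
* Cluster indices are sorted by ascending center intensity on output; the
  evaluation matches predicted to true classes by maximum overlap
  (Hungarian assignment) before computing Dice, since cluster indices are
  arbitrary.

## Known limitations

* The convex pre-filter mixes classes slightly at tissue boundaries
  (cross-class neighbours keep ~7% of the weight at a step edge). On a
  noise-free, bias-free image the energy then genuinely prefers a bias
  field that bends by a few percent to fit those boundary rows; with the
  default `γ` the estimated `h` of an uncorrupted two-class image deviates
  from 1 by up to ~0.03 near (and, through the center coupling, away from)
  class boundaries. Suppressing this entirely requires `γ` large enough to
  also suppress genuine bias recovery, so it is accepted as a property of
  the energy.
* 3D volumes are processed slice-wise by the CLI; there is no through-plane
  smoothness coupling.
* `d` must be supplied by the user; there is no model-order selection.
* The diagnostic-rate helpers (sensitivity, specificity, PPV, NPV,
  accuracy) operate on confusion counts supplied by the caller; the package
  contains no clinical data.
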