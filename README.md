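# fcmbias

Grayscale-preserving bias field correction and fuzzy tissue clustering for
MR images.

MR images are corrupted by a smooth multiplicative intensity gain — the
*bias field* `h` — caused by radiofrequency coil inhomogeneity. The same
tissue then appears brighter in one part of the image than another, which
breaks intensity-based segmentation. `fcmbias` jointly estimates a tissue
segmentation and the bias field by minimizing a modified fuzzy-c-means
energy, and returns the corrected image `I / h` whose overall gray level is
explicitly constrained to match the input.

## The model

For a pre-filtered image `I` with `d` tissue classes (centers `u_i`), fuzzy
memberships `v_ik` (summing to 1 over classes at each foreground pixel `k`),
one-hot labels `T_i`, and bias field `h`, the objective is

```
A = Σ_i Σ_k v_ik^n · N_ik  +  γ Σ_k (1 − h_k)²

N_ik = α · T_i(k) · (I_k − h_k u_i)²
     + (1 − α) · Σ_{r ∈ O_k} K(r − k) · (I_k − h_r u_i)²
```

* the `α` term ties each pixel to its class center through its own bias
  (global intensity, gated by the label function `T`);
* the `1 − α` term couples the bias across the truncated Gaussian window
  `O_k` (kernel `K`), enforcing smoothness of `h`;
* the `γ` penalty pulls `h` toward 1 so the corrected image keeps the gray
  level of the input ("grayscale preservation").

Each block — memberships, centers, bias — has a closed-form exact minimizer
with the others fixed; the solver alternates them until the center shift
`‖U_new − U_old‖` falls below `ε`. Before clustering, background is removed
by an intensity threshold and the image is smoothed by a data-adaptive
convex filter with weights `ω_kp ∝ exp(−δ_kp) · exp(−Chebyshev(p, k))`,
where `δ_kp` is a dimensionless neighbour-deviation statistic — all
quantities are invariant when the image is scaled by a positive constant.

## Worked example

```python
import numpy as np
from fcmbias import FCMBiasCorrector, generate_phantom, evaluate_run

# 128x128 phantom: 3 tissue classes (means 0.25/0.55/0.85), +-30% smooth
# multiplicative bias, Gaussian noise sigma 0.02, ground truth retained
phantom = generate_phantom()

est = FCMBiasCorrector(n_classes=3).fit(phantom.image)
report = evaluate_run(est.to_result(), phantom)

print("iterations:", est.n_iter_, "converged:", est.converged_)
print("per-class Dice:", report.dice_per_class)
print("bias recovery r:", round(report.bias_recovery, 4))
print("grayscale shift:", round(report.grayscale_shift, 4))
```

prints

```
iterations: 51 converged: True
per-class Dice: {1: 1.0, 2: 1.0, 3: 1.0}
bias recovery r: 0.9871
grayscale shift: 0.0124
```

Every pixel is assigned to its true tissue class (Dice 1.0 per class), the
estimated bias field correlates 0.987 with the simulated truth, and the
foreground mean intensity of the corrected image moves by only 1.2%
relative to the filtered input — the grayscale-preservation contract. The
same model with the bias frozen at 1 (`gamma=np.inf`, i.e. plain fuzzy
c-means on the filtered image) reaches only mean Dice 0.719 on this
phantom: the bias estimation is what rescues the segmentation.

The corrected image is `est.corrected_`, the estimated gain `est.bias_field_`,
the hard segmentation `est.labels_`.

The same pipeline runs from the shell:

```
fcmbias simulate --out truth/
fcmbias correct --in truth/image.nii --classes 3 --out run/
fcmbias evaluate --run run/ --truth truth/ --out report.csv
```

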