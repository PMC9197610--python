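import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from fcmbias import FCMBiasCorrector, build_kernel
from fcmbias import solver


KERNEL1 = build_kernel(radius=1, sigma=1.0)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_dissimilarity(image, mask, centers, bias, labels, kernel, alpha):
    """Triple-loop evaluation of N_ik with border/mask kernel renormalization."""
    h, w = image.shape
    r = kernel.radius
    kw = kernel.weights
    out = np.zeros((len(centers), h, w))
    for i, u in enumerate(centers):
        for ky in range(h):
            for kx in range(w):
                if not mask[ky, kx]:
                    continue
                t = 1.0 if labels[ky, kx] == i + 1 else 0.0
                glob = t * (image[ky, kx] - bias[ky, kx] * u) ** 2
                num = 0.0
                z = 0.0
                for dy in range(-r, r + 1):
                    for dx in range(-r, r + 1):
                        ry, rx = ky + dy, kx + dx
                        if 0 <= ry < h and 0 <= rx < w and mask[ry, rx]:
                            kv = kw[dy + r, dx + r]
                            z += kv
                            num += kv * (image[ky, kx] - bias[ry, rx] * u) ** 2
                loc = num / z if z > 0 else 0.0
                out[i, ky, kx] = alpha * glob + (1 - alpha) * loc
    return out


def total_energy(image, mask, membership, centers, bias, labels, kernel,
                 alpha, gamma, fuzzifier):
    nik = brute_force_dissimilarity(image, mask, centers, bias, labels,
                                    kernel, alpha)
    return solver.compute_energy(membership, nik, bias, mask, gamma, fuzzifier)


def random_instance(rng, shape=(3, 3), d=2):
    image = rng.random(shape) + 0.2
    mask = np.ones(shape, dtype=bool)
    centers = np.sort(rng.random(d) + 0.1)
    bias = 1.0 + 0.2 * (rng.random(shape) - 0.5)
    labels = rng.integers(1, d + 1, size=shape)
    nik = brute_force_dissimilarity(image, mask, centers, bias, labels, KERNEL1, 0.5)
    membership = solver.update_membership(nik, mask, 2.0)
    return image, mask, centers, bias, labels, membership


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def test_initialize_two_level_image_hits_levels():
    img = np.array([[2.0, 2.0], [8.0, 8.0]])
    mask = np.ones((2, 2), dtype=bool)
    centers, bias, labels = solver.initialize(img, mask, 2)
    assert np.allclose(centers, [2.0, 8.0])
    assert np.all(bias == 1.0)
    assert labels.tolist() == [[1, 1], [2, 2]]


def test_initialize_single_class_is_median():
    img = np.array([[1.0, 2.0], [3.0, 10.0]])
    mask = np.ones((2, 2), dtype=bool)
    centers, _, labels = solver.initialize(img, mask, 1)
    assert centers[0] == pytest.approx(np.median(img))
    assert np.all(labels == 1)


def test_initialize_deterministic_and_rejects_excess_classes(rng):
    img = rng.random((5, 5))
    mask = np.ones((5, 5), dtype=bool)
    a = solver.initialize(img, mask, 3)
    b = solver.initialize(img, mask, 3)
    for x, y in zip(a, b):
        assert np.array_equal(x, y)
    with pytest.raises(ValueError, match="distinct"):
        solver.initialize(np.full((4, 4), 2.0), np.ones((4, 4), dtype=bool), 2)


# ---------------------------------------------------------------------------
# dissimilarity and energy
# ---------------------------------------------------------------------------

def test_dissimilarity_global_reduces_to_squared_difference():
    img = np.full((1, 1), 3.0)
    mask = np.ones((1, 1), dtype=bool)
    labels = np.ones((1, 1), dtype=int)
    nik = solver.compute_dissimilarity(img, mask, np.array([1.0]),
                                       np.ones((1, 1)), labels, KERNEL1, 1.0)
    assert nik[0, 0, 0] == pytest.approx(4.0)


def test_dissimilarity_local_constant_image():
    img = np.full((4, 4), 0.7)
    mask = np.ones((4, 4), dtype=bool)
    labels = np.ones((4, 4), dtype=int)
    nik = solver.compute_dissimilarity(img, mask, np.array([0.3]),
                                       np.ones((4, 4)), labels, KERNEL1, 0.0)
    assert np.allclose(nik[0], (0.7 - 0.3) ** 2)


def test_dissimilarity_matches_brute_force(rng):
    for _ in range(5):
        image, mask, centers, bias, labels, _ = random_instance(rng, (2, 2))
        got = solver.compute_dissimilarity(image, mask, centers, bias, labels,
                                           KERNEL1, 0.5)
        want = brute_force_dissimilarity(image, mask, centers, bias, labels,
                                         KERNEL1, 0.5)
        assert np.allclose(got, want, atol=1e-12)


def test_energy_direct_evaluation():
    # single pixel, d=1, v=1, n=2, N=4, gamma=2, h=0.5 -> 4 + 2*0.25 = 4.5
    membership = np.ones((1, 1, 1))
    nik = np.full((1, 1, 1), 4.0)
    bias = np.full((1, 1), 0.5)
    mask = np.ones((1, 1), dtype=bool)
    e = solver.compute_energy(membership, nik, bias, mask, gamma=2.0, fuzzifier=2.0)
    assert e == pytest.approx(4.5)
    # penalty vanishes at h == 1
    e1 = solver.compute_energy(membership, nik, np.ones((1, 1)), mask, 2.0, 2.0)
    assert e1 == pytest.approx(4.0)


def test_energy_nonnegative(rng):
    image, mask, centers, bias, labels, membership = random_instance(rng)
    e = total_energy(image, mask, membership, centers, bias, labels,
                     KERNEL1, 0.5, 0.01, 2.0)
    assert np.isfinite(e) and e >= 0


# ---------------------------------------------------------------------------
# membership update
# ---------------------------------------------------------------------------

def test_membership_closed_form_and_simplex_oracle():
    mask = np.ones((1, 1), dtype=bool)
    nik = np.array([1.0, 3.0]).reshape(2, 1, 1)
    v = solver.update_membership(nik, mask, 2.0)
    assert np.allclose(v[:, 0, 0], [0.75, 0.25])
    # brute-force: grid over the 1-simplex minimizing v1^2*N1 + v2^2*N2
    grid = np.linspace(0, 1, 1001)
    cost = grid**2 * 1.0 + (1 - grid) ** 2 * 3.0
    assert grid[np.argmin(cost)] == pytest.approx(0.75, abs=1e-3)


def test_membership_single_class_and_zero_rules():
    mask = np.ones((1, 2), dtype=bool)
    v = solver.update_membership(np.ones((1, 1, 2)), mask, 2.0)
    assert np.all(v == 1.0)
    nik = np.array([[[0.0, 0.0]], [[5.0, 0.0]]])  # shape (2, 1, 2)
    v = solver.update_membership(nik, np.ones((1, 2), dtype=bool), 2.0)
    assert np.allclose(v[:, 0, 0], [1.0, 0.0])   # one zero class takes all
    assert np.allclose(v[:, 0, 1], [0.5, 0.5])   # two zero classes split


def test_membership_rows_sum_to_one_and_masked(rng):
    nik = rng.random((3, 6, 6)) + 1e-3
    mask = rng.random((6, 6)) > 0.3
    nik *= mask
    v = solver.update_membership(nik, mask, 2.5)
    assert np.allclose(v.sum(axis=0)[mask], 1.0, atol=1e-10)
    assert np.all(v[:, ~mask] == 0.0)


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def test_label_argmax_and_tie_break():
    mask = np.ones((1, 3), dtype=bool)
    v = np.array([[[0.75, 0.5, 0.0]], [[0.25, 0.5, 1.0]]])
    labels = solver.update_labels(v, mask)
    assert labels.tolist() == [[1, 1, 2]]  # tie goes to the lowest index


def test_guarded_labels_never_increase_energy(rng):
    for _ in range(5):
        image, mask, centers, bias, labels, membership = random_instance(rng)
        e_before = total_energy(image, mask, membership, centers, bias, labels,
                                KERNEL1, 0.5, 0.01, 2.0)
        new_labels = solver.update_labels_guarded(membership, labels, image,
                                                  bias, centers, mask, 0.5, 2.0)
        e_after = total_energy(image, mask, membership, centers, bias,
                               new_labels, KERNEL1, 0.5, 0.01, 2.0)
        assert e_after <= e_before + 1e-12


def test_guarded_labels_equal_argmax_when_alpha_zero(rng):
    image, mask, centers, bias, labels, membership = random_instance(rng)
    guarded = solver.update_labels_guarded(membership, labels, image, bias,
                                           centers, mask, 0.0, 2.0)
    assert np.array_equal(guarded, solver.update_labels(membership, mask))


# ---------------------------------------------------------------------------
# center update
# ---------------------------------------------------------------------------

def test_centers_reduce_to_class_means_in_global_crisp_case():
    img = np.array([[2.0, 4.0], [10.0, 12.0]])
    mask = np.ones((2, 2), dtype=bool)
    labels = np.array([[1, 1], [2, 2]])
    membership = np.stack([(labels == 1).astype(float),
                           (labels == 2).astype(float)])
    centers = solver.update_centers(img, membership, np.ones((2, 2)), labels,
                                    KERNEL1, mask, alpha=1.0, fuzzifier=2.0)
    assert np.allclose(centers, [3.0, 11.0])


def test_centers_constant_image_all_equal():
    img = np.full((3, 3), 5.0)
    mask = np.ones((3, 3), dtype=bool)
    labels = np.ones((3, 3), dtype=int)
    labels[0, 0] = 2
    membership = np.stack([(labels == 1).astype(float),
                           (labels == 2).astype(float)]) * 0.5 + 0.25
    centers = solver.update_centers(img, membership, np.ones((3, 3)), labels,
                                    KERNEL1, mask, alpha=0.5, fuzzifier=2.0)
    assert np.allclose(centers, 5.0)


def test_centers_match_numerical_minimization(rng):
    for _ in range(3):
        image, mask, centers, bias, labels, membership = random_instance(rng)
        updated = solver.update_centers(image, membership, bias, labels,
                                        KERNEL1, mask, 0.5, 2.0)
        for i in range(len(centers)):
            def energy_of_u(u, i=i):
                c = updated.copy()
                c[i] = u
                return total_energy(image, mask, membership, c, bias, labels,
                                    KERNEL1, 0.5, 0.01, 2.0)
            res = minimize_scalar(energy_of_u, bracket=(0.0, 2.0),
                                  method="golden", options={"xtol": 1e-10})
            assert updated[i] == pytest.approx(res.x, abs=1e-6)


def test_empty_class_reseeded_with_warning():
    img = np.array([[1.0, 2.0], [3.0, 9.0]])
    mask = np.ones((2, 2), dtype=bool)
    labels = np.ones((2, 2), dtype=int)
    membership = np.stack([np.ones((2, 2)), np.zeros((2, 2))])
    with pytest.warns(RuntimeWarning, match="re-seeding"):
        centers = solver.update_centers(img, membership, np.ones((2, 2)),
                                        labels, KERNEL1, mask, 1.0, 2.0)
    assert np.isfinite(centers).all()
    assert centers[1] == 9.0  # intensity farthest from the surviving center


# ---------------------------------------------------------------------------
# bias update
# ---------------------------------------------------------------------------

def test_bias_single_pixel_closed_form():
    # minimize (I - h u)^2 + gamma (1 - h)^2 with I=2, u=1, gamma=1 -> h = 1.5
    img = np.full((1, 1), 2.0)
    mask = np.ones((1, 1), dtype=bool)
    labels = np.ones((1, 1), dtype=int)
    membership = np.ones((1, 1, 1))
    h = solver.update_bias_field(img, membership, np.array([1.0]), labels,
                                 KERNEL1, mask, alpha=1.0, fuzzifier=2.0,
                                 gamma=1.0)
    assert h[0, 0] == pytest.approx(1.5)


def test_bias_huge_gamma_pins_to_one(rng):
    image, mask, centers, bias, labels, membership = random_instance(rng)
    h = solver.update_bias_field(image, membership, centers, labels, KERNEL1,
                                 mask, 0.5, 2.0, gamma=1e9)
    assert np.abs(h - 1.0).max() < 1e-6


def test_bias_stationary_when_image_matches_center():
    img = np.full((3, 3), 0.6)
    mask = np.ones((3, 3), dtype=bool)
    labels = np.ones((3, 3), dtype=int)
    membership = np.ones((1, 3, 3))
    h = solver.update_bias_field(img, membership, np.array([0.6]), labels,
                                 KERNEL1, mask, 0.5, 2.0, gamma=0.01)
    assert np.allclose(h, 1.0, atol=1e-12)


def test_bias_matches_per_pixel_quadratic_oracle(rng):
    # the energy is quadratic in each h_k: fit a parabola through three
    # evaluations and compare its vertex with the closed-form update
    for _ in range(3):
        image, mask, centers, bias, labels, membership = random_instance(rng)
        updated = solver.update_bias_field(image, membership, centers, labels,
                                           KERNEL1, mask, 0.5, 2.0, 0.01)
        for (ky, kx) in [(0, 0), (1, 1), (2, 1)]:
            def energy_of_h(val):
                h = updated.copy()
                h[ky, kx] = val
                return total_energy(image, mask, membership, centers, h,
                                    labels, KERNEL1, 0.5, 0.01, 2.0)
            e0, e1, e2 = energy_of_h(0.0), energy_of_h(1.0), energy_of_h(2.0)
            a = (e0 + e2 - 2 * e1) / 2.0
            slope_mid = (e2 - e0) / 2.0  # f'(1)
            vertex = 1.0 - slope_mid / (2 * a)
            assert updated[ky, kx] == pytest.approx(vertex, abs=1e-8)


def test_bias_infinite_gamma_returns_ones(rng):
    image, mask, centers, bias, labels, membership = random_instance(rng)
    h = solver.update_bias_field(image, membership, centers, labels, KERNEL1,
                                 mask, 0.5, 2.0, np.inf)
    assert np.all(h == 1.0)


# ---------------------------------------------------------------------------
# correction and full fit
# ---------------------------------------------------------------------------

def test_correct_image_division_rules(rng):
    img = rng.random((3, 3)) + 0.5
    mask = np.ones((3, 3), dtype=bool)
    assert np.allclose(solver.correct_image(img, np.ones((3, 3)), mask), img)
    assert np.allclose(solver.correct_image(img, np.full((3, 3), 0.5), mask),
                       2.0 * img)
    h = np.ones((3, 3))
    h[0, 0] = 0.0  # below floor
    out = solver.correct_image(img, h, mask)
    assert np.isfinite(out).all()
    assert out[0, 0] == pytest.approx(img[0, 0] / 1e-6)


def test_fit_recovers_clean_two_level_image(clean_two_class_phantom):
    from fcmbias import evaluate_run

    ph = clean_two_class_phantom
    est = FCMBiasCorrector(n_classes=2).fit(ph.image)
    report = evaluate_run(est.to_result(), ph)
    assert report.dice_per_class == {1: 1.0, 2: 1.0}


def test_fit_energy_trace_non_increasing(default_fit):
    tr = default_fit.energy_trace_
    slack = 1e-8 * abs(tr[0])
    assert np.all(np.diff(tr) <= slack)


def test_fit_huge_gamma_reduces_to_filtered(default_phantom):
    est = FCMBiasCorrector(n_classes=3, gamma=1e9).fit(default_phantom.image)
    m = est.mask_
    rel = np.abs(est.corrected_[m] - est.filtered_[m]) / np.abs(est.filtered_[m])
    assert rel.max() < 1e-4


def test_fit_deterministic_bit_identical(default_phantom):
    a = FCMBiasCorrector(n_classes=3).fit(default_phantom.image)
    b = FCMBiasCorrector(n_classes=3).fit(default_phantom.image)
    for attr in ("corrected_", "bias_field_", "membership_", "centers_",
                 "labels_", "energy_trace_"):
        assert np.array_equal(getattr(a, attr), getattr(b, attr))


def test_fit_infinite_gamma_matches_plain_fcm_labels(default_phantom):
    # as gamma -> inf the labels converge to plain FCM on the filtered image
    big = FCMBiasCorrector(n_classes=3, gamma=1e9).fit(default_phantom.image)
    frozen = FCMBiasCorrector(n_classes=3, gamma=np.inf).fit(default_phantom.image)
    assert np.array_equal(big.labels_, frozen.labels_)
    assert np.all(frozen.bias_field_ == 1.0)


def test_fit_validates_parameters(default_phantom):
    with pytest.raises(ValueError):
        FCMBiasCorrector(n_classes=0).fit(default_phantom.image)
    with pytest.raises(ValueError):
        FCMBiasCorrector(alpha=1.5).fit(default_phantom.image)
    with pytest.raises(ValueError):
        FCMBiasCorrector(fuzzifier=1.0).fit(default_phantom.image)


def test_estimator_follows_sklearn_param_protocol():
    est = FCMBiasCorrector(n_classes=4, gamma=0.5)
    params = est.get_params()
    assert params["n_classes"] == 4 and params["gamma"] == 0.5
    est.set_params(alpha=0.25)
    assert est.alpha == 0.25
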