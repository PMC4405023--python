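"""Unit oracles for the membership, spatial-function and center operations."""

import numpy as np
import pytest

from fsafcm import (
    NeighborhoodModel,
    build_joint_histogram,
    compute_lambda,
    compute_omega,
    defuzzify,
    fcm_membership,
    fcm_objective,
    fuse_memberships,
    spatial_function,
    update_centers,
)
from fsafcm.core import omega_stack
from fsafcm.errors import (
    ConsistencyError,
    DegenerateCentersError,
    DegenerateClusterError,
    ParameterError,
)


class TestFcmMembership:
    def test_pixel_on_center_is_crisp(self):
        U = fcm_membership([5.0, 1.0], [1.0, 3.0], m=2.0)
        np.testing.assert_array_equal(U[:, 1], [1.0, 0.0])

    def test_equidistant_pixel_splits_evenly(self):
        U = fcm_membership([2.0], [1.0, 3.0], m=2.0)
        np.testing.assert_allclose(U[:, 0], [0.5, 0.5], atol=1e-12)

    def test_closed_form_two_center_value(self):
        # 1 / (1 + (1/3)^2) = 9/10 for x=0 against centers 1 and 3 at m=2
        U = fcm_membership([0.0], [1.0, 3.0], m=2.0)
        np.testing.assert_allclose(U[:, 0], [0.9, 0.1], atol=1e-12)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        U = fcm_membership(rng.uniform(0, 255, 100), [10.0, 90.0, 200.0], m=2.5)
        np.testing.assert_allclose(U.sum(axis=0), 1.0, atol=1e-12)
        assert U.min() >= 0.0 and U.max() <= 1.0

    def test_duplicated_centers_rejected(self):
        with pytest.raises(DegenerateCentersError):
            fcm_membership([1.0, 2.0], [5.0, 5.0], m=2.0)


class TestLambdaAndOmega:
    def test_flat_window_gives_zero_lambda(self):
        img = np.full((8, 8), 55.0)
        nb = NeighborhoodModel(1)
        lam = compute_lambda(img, build_joint_histogram(img, nb), nb)
        assert np.all(lam == 0.0)

    def test_vessel_noise_patch_value(self, vessel_noise_patch):
        # Oracle: p_j * sum (f - 613/9)^2 / 9 with p_j = 1/9 for the unique
        # center bin of the 3x3 patch.
        nb = NeighborhoodModel(1)
        hist = build_joint_histogram(vessel_noise_patch, nb)
        lam = compute_lambda(vessel_noise_patch, hist, nb)
        mean = 613.0 / 9.0
        ssd = float(((vessel_noise_patch - mean) ** 2).sum())
        assert ssd == pytest.approx(6634.888, abs=1e-2)
        assert hist.p_image[1, 1] == pytest.approx(1.0 / 9.0)
        assert lam[1, 1] == pytest.approx((1.0 / 9.0) * ssd / 9.0, rel=1e-12)
        assert lam[1, 1] == pytest.approx(81.91, abs=0.01)

    def test_lambda_linear_in_frequency(self, vessel_noise_patch):
        nb = NeighborhoodModel(1)
        hist = build_joint_histogram(vessel_noise_patch, nb)
        lam = compute_lambda(vessel_noise_patch, hist, nb)
        doubled = hist.__class__(
            counts=hist.counts,
            freqs=hist.freqs,
            M_star=hist.M_star,
            g_image=hist.g_image,
            p_image=2.0 * hist.p_image,
            N=hist.N,
            r=hist.r,
            image_shape=hist.image_shape,
        )
        np.testing.assert_allclose(
            compute_lambda(vessel_noise_patch, doubled, nb), 2.0 * lam, rtol=1e-12
        )

    def test_lambda_shape_mismatch_rejected(self, vessel_noise_patch):
        nb = NeighborhoodModel(1)
        hist = build_joint_histogram(vessel_noise_patch, nb)
        with pytest.raises(ConsistencyError):
            compute_lambda(np.zeros((5, 5)), hist, nb)

    @pytest.mark.parametrize(
        "center,neighbor,lam,expected",
        [
            (77.0, 77.0, 3.5, 1.0),  # zero gray difference
            (12.0, 200.0, 0.0, 1.0),  # zero adaptive factor
            (10.0, 11.0, np.log(2.0), 0.5),  # exp(-ln 2)
        ],
    )
    def test_omega_values(self, center, neighbor, lam, expected):
        assert compute_omega(center, neighbor, lam) == pytest.approx(expected, abs=1e-12)

    def test_omega_monotone_in_difference_and_lambda(self):
        diffs = compute_omega(np.array([10.0, 10.0, 10.0]), np.array([11.0, 15.0, 40.0]), 0.1)
        assert np.all(np.diff(diffs) < 0)
        lams = [compute_omega(10.0, 20.0, lam) for lam in (0.0, 0.01, 0.1)]
        assert lams[0] > lams[1] > lams[2]
        with pytest.raises(ParameterError):
            compute_omega(1.0, 2.0, -0.5)


def spatial_oracle(U, img, lam, r, mode):
    """Explicit double loop over pixels and window offsets."""
    C = U.shape[0]
    h, w = img.shape
    Um = U.reshape(C, h, w)
    out = np.zeros((C, h, w))
    for y in range(h):
        for x in range(w):
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    omega = np.exp(-((img[y, x] - img[yy, xx]) ** 2) * lam[y, x])
                    for i in range(C):
                        if mode == "weighted":
                            out[i, y, x] += omega * Um[i, yy, xx]
                        else:
                            out[i, y, x] += Um[i, yy, xx] + omega
    return out.reshape(C, -1)


class TestSpatialFunction:
    @pytest.mark.parametrize("mode", ["weighted", "additive"])
    def test_matches_explicit_loop(self, mode, random_image):
        img = random_image(21, shape=(6, 6)).pixels
        nb = NeighborhoodModel(1)
        hist = build_joint_histogram(img, nb)
        lam = compute_lambda(img, hist, nb)
        rng = np.random.default_rng(2)
        U = rng.random((2, 36))
        U /= U.sum(axis=0)
        omg = omega_stack(img, lam, nb)
        H = spatial_function(U, omg, nb, img.shape, mode=mode)
        np.testing.assert_allclose(H, spatial_oracle(U, img, lam, 1, mode), atol=1e-10)

    def test_unanimous_window_reaches_window_size(self):
        # Flat image -> lambda would be 0 -> all omega 1; with every neighbor
        # fully in cluster 0 the weighted spatial function hits (2r+1)^2 = 9.
        img = np.full((5, 5), 60.0)
        nb = NeighborhoodModel(1)
        U = np.zeros((2, 25))
        U[0] = 1.0
        omg = omega_stack(img, np.zeros((5, 5)), nb)
        H = spatial_function(U, omg, nb, (5, 5), mode="weighted")
        np.testing.assert_allclose(H[0], 9.0, atol=1e-12)
        # ... and zero when no neighbor carries mass in the cluster.
        np.testing.assert_allclose(H[1], 0.0, atol=1e-12)


class TestFuseMemberships:
    def test_equal_spatial_evidence_passes_through(self):
        U = np.array([[0.3, 0.7], [0.7, 0.3]])
        H = np.full((2, 2), 4.0)
        np.testing.assert_allclose(fuse_memberships(U, H, 1.0, 2.0), U, atol=1e-12)

    def test_zero_spatial_exponent_is_identity(self):
        rng = np.random.default_rng(1)
        U = rng.random((3, 10))
        U /= U.sum(axis=0)
        H = rng.random((3, 10))
        np.testing.assert_array_equal(fuse_memberships(U, H, 1.0, 0.0), U)

    def test_worked_two_cluster_example(self):
        # (0.5 * 2^2) / (0.5 * 2^2 + 0.5 * 1^2) = 0.8
        U = np.array([[0.5], [0.5]])
        H = np.array([[2.0], [1.0]])
        np.testing.assert_allclose(
            fuse_memberships(U, H, 1.0, 2.0)[:, 0], [0.8, 0.2], atol=1e-12
        )

    def test_all_zero_column_falls_back_to_unfused(self):
        U = np.array([[0.6], [0.4]])
        H = np.zeros((2, 1))
        np.testing.assert_array_equal(fuse_memberships(U, H, 1.0, 2.0), U)

    def test_columns_stay_normalized(self):
        rng = np.random.default_rng(4)
        U = rng.random((3, 50))
        U /= U.sum(axis=0)
        H = rng.random((3, 50)) * 9
        out = fuse_memberships(U, H, 1.0, 2.0)
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-12)


class TestUpdateCenters:
    def test_crisp_two_region_recovery_when_windows_flat(self):
        # With g == x (every window flat), the normalized update returns the
        # region gray values exactly and the as-printed form doubles them.
        x = np.array([40.0] * 6 + [200.0] * 6)
        g = x.copy()
        U = np.zeros((2, 12))
        U[0, :6] = 1.0
        U[1, 6:] = 1.0
        np.testing.assert_allclose(
            update_centers(x, g, U, 2.0, "normalized"), [40.0, 200.0], atol=1e-12
        )
        np.testing.assert_allclose(
            update_centers(x, g, U, 2.0, "as_printed"), [80.0, 400.0], atol=1e-12
        )

    def test_uniform_memberships_give_global_mean(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 255, 30)
        g = rng.uniform(0, 255, 30)
        U = np.full((2, 30), 0.5)
        expected = np.mean((x + g) / 2.0)
        np.testing.assert_allclose(
            update_centers(x, g, U, 2.0, "normalized"), [expected, expected], atol=1e-9
        )

    def test_plain_mode_ignores_neighborhood(self):
        x = np.array([10.0, 30.0])
        U = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(
            update_centers(x, None, U, 2.0, "plain"), [10.0, 30.0], atol=1e-12
        )

    def test_zero_mass_cluster_rejected(self):
        U = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(DegenerateClusterError):
            update_centers(np.array([1.0, 2.0]), np.array([1.0, 2.0]), U, 2.0)


class TestObjectiveAndDefuzzify:
    def test_crisp_on_center_data_has_zero_objective(self):
        x = np.array([40.0, 40.0, 200.0])
        U = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        assert fcm_objective(x, U, [40.0, 200.0], 2.0) == 0.0

    def test_single_pixel_value(self):
        # 1^2 * (5-3)^2 = 4
        U = np.array([[1.0], [0.0]])
        assert fcm_objective([5.0], U, [3.0, 8.0], 2.0) == pytest.approx(4.0)

    def test_matches_triple_loop_oracle(self, random_image):
        img = random_image(9, shape=(6, 6))
        x = img.pixels.ravel()
        rng = np.random.default_rng(5)
        U = rng.random((3, 36))
        U /= U.sum(axis=0)
        V = np.array([20.0, 120.0, 240.0])
        m = 2.0
        expected = 0.0
        for i in range(3):
            for j in range(36):
                expected += U[i, j] ** m * (x[j] - V[i]) ** 2
        assert fcm_objective(x, U, V, m) == pytest.approx(expected, rel=1e-10)

    def test_defuzzify_argmax_and_tie_break(self):
        U = np.array([[0.9, 0.5, 0.2], [0.1, 0.5, 0.8]])
        np.testing.assert_array_equal(defuzzify(U), [0, 0, 1])

    def test_defuzzify_matches_per_column_loop(self):
        rng = np.random.default_rng(12)
        U = rng.random((4, 25))
        U /= U.sum(axis=0)
        expected = [int(np.argmax(U[:, j])) for j in range(25)]
        np.testing.assert_array_equal(defuzzify(U), expected)
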