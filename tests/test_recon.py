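import itertools

import numpy as np
import pytest

from betapet.acquisition import AcquisitionModel, ProjectionData, forward_project, sample_counts, system_matrix
from betapet.geometry import ActivityVolume, GridGeometry
from betapet.recon import (
    PenaltyParams,
    ReconParams,
    poisson_loglik,
    rdp_gradient,
    rdp_value,
    reconstruct,
)


def brute_force_rdp(values, voxel_size, gamma, neighborhood):
    """Independent double-loop reference for the relative difference penalty."""
    shape = values.shape
    single = shape[0] == 1
    offsets = []
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        nz = sum(o != 0 for o in off)
        if single:
            if off[0] != 0:
                continue
        elif neighborhood == 6 and nz > 1:
            continue
        elif neighborhood == 18 and nz > 2:
            continue
        offsets.append(off)
    dists = [np.linalg.norm(np.multiply(o, voxel_size)) for o in offsets]
    dmin = min(dists)
    total = 0.0
    for j in itertools.product(*[range(n) for n in shape]):
        for off, dist in zip(offsets, dists):
            k = tuple(a + o for a, o in zip(j, off))
            if any(c < 0 or c >= n for c, n in zip(k, shape)):
                continue
            a, b = values[j], values[k]
            denom = a + b + gamma * abs(a - b)
            if denom > 0:
                total += (dmin / dist) * (a - b) ** 2 / denom
    return total


class TestRdpValue:
    def test_uniform_volume_is_zero(self, small_grid):
        for c in (0.0, 1.0, 7.3):
            vol = ActivityVolume(small_grid, np.full(small_grid.shape, c))
            assert rdp_value(vol, PenaltyParams()) == 0.0

    def test_two_voxel_closed_form(self):
        grid = GridGeometry((1, 1, 2), (1, 1, 1))
        vol = ActivityVolume(grid, np.array([[[2.0, 1.0]]]))
        # ordered pairs (j,k) and (k,j): 2 * 1^2 / (3 + 2*1)
        assert rdp_value(vol, PenaltyParams(gamma=2.0)) == pytest.approx(0.4)

    @pytest.mark.parametrize("neighborhood", [6, 18, 26])
    def test_matches_brute_force_double_loop(self, neighborhood, rng):
        for shape in [(2, 3, 3), (4, 4, 4), (1, 4, 4)]:
            grid = GridGeometry(shape, (2.8, 2.73, 2.73))
            values = rng.uniform(0, 5, shape)
            values[values < 0.5] = 0.0  # exercise the removable singularity
            got = rdp_value(ActivityVolume(grid, values), PenaltyParams(neighborhood=neighborhood))
            want = brute_force_rdp(values, grid.voxel_size, 2.0, neighborhood)
            assert got == pytest.approx(want, rel=1e-10)

    def test_homogeneity_degree_one(self, small_grid, rng):
        x = rng.uniform(0, 4, small_grid.shape)
        pen = PenaltyParams()
        v1 = rdp_value(ActivityVolume(small_grid, x), pen)
        v3 = rdp_value(ActivityVolume(small_grid, 3.0 * x), pen)
        assert v3 == pytest.approx(3.0 * v1, rel=1e-12)

    def test_negative_voxel_rejected(self, small_grid):
        vol = ActivityVolume(small_grid, np.zeros(small_grid.shape))
        vol.values[0, 0, 0] = -1.0  # bypass constructor check on purpose
        with pytest.raises(ValueError):
            rdp_value(vol, PenaltyParams())


class TestRdpGradient:
    def test_uniform_volume_zero_gradient(self, small_grid):
        vol = ActivityVolume(small_grid, np.full(small_grid.shape, 2.5))
        assert not rdp_gradient(vol, PenaltyParams()).any()

    @pytest.mark.parametrize("neighborhood", [6, 26])
    def test_matches_central_finite_differences(self, neighborhood, rng):
        grid = GridGeometry((1, 5, 5), (2.8, 2.73, 2.73))
        x = rng.uniform(0.5, 5.0, grid.shape)  # strictly positive, generic
        pen = PenaltyParams(gamma=2.0, neighborhood=neighborhood)
        g = rdp_gradient(ActivityVolume(grid, x), pen)
        h = 1e-6
        for _ in range(12):
            k = tuple(rng.integers(0, s) for s in grid.shape)
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            fd = (
                rdp_value(ActivityVolume(grid, xp), pen)
                - rdp_value(ActivityVolume(grid, xm), pen)
            ) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=1e-4)

    def test_gradient_scale_invariance(self, rng):
        # psi' is 0-homogeneous: grad(a*x) == grad(x) for a > 0
        grid = GridGeometry((1, 4, 4), (2.8, 2.73, 2.73))
        x = rng.uniform(0.5, 5.0, grid.shape)
        pen = PenaltyParams()
        g1 = rdp_gradient(ActivityVolume(grid, x), pen)
        g2 = rdp_gradient(ActivityVolume(grid, 2.5 * x), pen)
        assert np.allclose(g1, g2, rtol=1e-12)


class TestPoissonLoglik:
    def test_empty_data_convention(self, small_grid):
        acq = AcquisitionModel(n_angles=8, n_radial_bins=24, psf_fwhm=0.0)
        counts = ProjectionData(acq, np.zeros(acq.projection_shape(small_grid)), kind="sampled")
        vol = ActivityVolume.zeros(small_grid)
        assert poisson_loglik(vol, counts, acq) == 0.0

    def test_single_bin_closed_form(self, small_grid):
        acq = AcquisitionModel(n_angles=8, n_radial_bins=24, psf_fwhm=0.0)
        counts = np.zeros(acq.projection_shape(small_grid))
        counts[0, 0, 0] = 3.0
        proj = ProjectionData(acq, counts, kind="sampled")
        yhat = np.zeros_like(counts)
        yhat[0, 0, 0] = 3.0
        vol = ActivityVolume.zeros(small_grid)
        got = poisson_loglik(vol, proj, acq, expected=yhat)
        assert got == pytest.approx(3.0 * np.log(3.0) - 3.0)

    def test_zero_expected_positive_observed_is_error(self, small_grid):
        acq = AcquisitionModel(n_angles=8, n_radial_bins=24, psf_fwhm=0.0)
        counts = np.zeros(acq.projection_shape(small_grid))
        counts[0, 0, 0] = 1.0
        proj = ProjectionData(acq, counts, kind="sampled")
        with pytest.raises(ValueError, match="-inf"):
            poisson_loglik(ActivityVolume.zeros(small_grid), proj, acq)

    def test_truth_maximizes_likelihood_at_expectation_data(self, small_grid, rng):
        # at noiseless data y = E[y|x_true], no perturbed volume beats the truth
        acq = AcquisitionModel(n_angles=24, n_radial_bins=24, psf_fwhm=0.0, count_scale=1.0)
        truth = rng.uniform(0.5, 4.0, small_grid.shape)
        vol = ActivityVolume(small_grid, truth)
        y = forward_project(vol, acq)
        counts = ProjectionData(acq, np.round(y.values * 0) + y.values)  # expected data
        ll_true = poisson_loglik(vol, counts, acq)
        for _ in range(100):
            pert = np.clip(truth * rng.uniform(0.8, 1.2, truth.shape), 1e-9, None)
            ll = poisson_loglik(ActivityVolume(small_grid, pert), counts, acq)
            assert ll <= ll_true + 1e-9 * abs(ll_true)


def _mlem_params(n_iter):
    return ReconParams(
        penalty=PenaltyParams(beta=0.0),
        n_iterations=n_iter,
        n_subsets=1,
        relaxation_decay=0.0,
    )


class TestReconstruct:
    def test_point_source_recovered_at_true_location(self):
        grid = GridGeometry((1, 16, 16), (2.8, 2.73, 2.73))
        acq = AcquisitionModel(n_angles=16, n_radial_bins=16, psf_fwhm=0.0, count_scale=1.0)
        truth = np.zeros(grid.shape)
        truth[0, 5, 9] = 10.0
        expected = forward_project(ActivityVolume(grid, truth), acq)
        res = reconstruct(expected, grid, _mlem_params(200))
        assert res.converged
        peak = np.unravel_index(np.argmax(res.volume.values), grid.shape)
        assert peak == (0, 5, 9)

    def test_mlem_preserves_total_counts_every_iteration(self, toy_volume):
        grid = toy_volume.grid
        acq = AcquisitionModel(n_angles=24, n_radial_bins=24, psf_fwhm=0.0, count_scale=1.0)
        counts = sample_counts(forward_project(toy_volume, acq), 5)
        P = system_matrix(grid, acq)
        sens = np.asarray(P.sum(axis=0)).ravel().reshape(grid.shape[1:])
        x_total = []
        for n_iter in range(1, 6):
            res = reconstruct(counts, grid, _mlem_params(n_iter))
            x_total.append(float((res.volume.values[0] * sens).sum()))
        for t in x_total:
            assert t == pytest.approx(counts.total_counts, rel=1e-3)

    def test_em_fixed_point_is_stationary(self, toy_volume):
        # a (near-)converged ML-EM image is unchanged by one more update
        grid = toy_volume.grid
        acq = AcquisitionModel(n_angles=24, n_radial_bins=24, psf_fwhm=0.0, count_scale=1.0)
        expected = forward_project(toy_volume, acq)
        long_run = reconstruct(expected, grid, _mlem_params(300)).volume.values
        one_more = reconstruct(expected, grid, _mlem_params(301)).volume.values
        body = long_run > 0.1
        assert np.allclose(one_more[body], long_run[body], rtol=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_penalized_objective_monotone_full_iterations(self, toy_volume, seed):
        grid = toy_volume.grid
        acq = AcquisitionModel(n_angles=24, n_radial_bins=24, psf_fwhm=0.0, count_scale=1.0)
        counts = sample_counts(forward_project(toy_volume, acq), seed)
        params = ReconParams(penalty=PenaltyParams(beta=500.0), n_iterations=15, n_subsets=1)
        res = reconstruct(counts, grid, params)
        obj = res.trace["objective"].to_numpy()
        assert res.converged
        assert np.all(np.diff(obj) >= -1e-7 * (np.abs(obj[:-1]) + 1))

    def test_stronger_beta_smoother_image(self, toy_volume):
        grid = toy_volume.grid
        acq = AcquisitionModel(n_angles=24, n_radial_bins=24, psf_fwhm=0.0, count_scale=1.0)
        counts = sample_counts(forward_project(toy_volume, acq), 9)
        imgs = {}
        for beta in (100.0, 1000.0):
            params = ReconParams(penalty=PenaltyParams(beta=beta), n_iterations=20, n_subsets=4)
            imgs[beta] = reconstruct(counts, grid, params).volume
        pen = PenaltyParams(beta=1.0)
        assert rdp_value(imgs[1000.0], pen) < rdp_value(imgs[100.0], pen)
        bg = np.zeros(grid.shape, dtype=bool)
        bg[0, 5:9, 5:19] = True  # background strip away from the hot square
        assert imgs[1000.0].values[bg].std() < imgs[100.0].values[bg].std()

    def test_rdp_of_converged_image_nonincreasing_in_beta(self, toy_volume):
        grid = toy_volume.grid
        acq = AcquisitionModel(n_angles=24, n_radial_bins=24, psf_fwhm=0.0, count_scale=1.0)
        counts = sample_counts(forward_project(toy_volume, acq), 11)
        pen_ref = PenaltyParams(beta=1.0)
        values = []
        for beta in (100.0, 350.0, 650.0, 1000.0):
            params = ReconParams(penalty=PenaltyParams(beta=beta), n_iterations=20, n_subsets=4)
            values.append(rdp_value(reconstruct(counts, grid, params).volume, pen_ref))
        assert np.all(np.diff(values) < 0)

    def test_deterministic_given_inputs(self, toy_volume):
        grid = toy_volume.grid
        acq = AcquisitionModel(n_angles=24, n_radial_bins=24, psf_fwhm=0.0, count_scale=1.0)
        counts = sample_counts(forward_project(toy_volume, acq), 2)
        params = ReconParams(penalty=PenaltyParams(beta=350.0), n_iterations=5, n_subsets=4)
        r1 = reconstruct(counts, grid, params)
        r2 = reconstruct(counts, grid, params)
        assert np.array_equal(r1.volume.values, r2.volume.values)

    def test_subsets_must_divide_angles(self, toy_volume):
        grid = toy_volume.grid
        acq = AcquisitionModel(n_angles=24, n_radial_bins=24, psf_fwhm=0.0, count_scale=1.0)
        counts = forward_project(toy_volume, acq)
        with pytest.raises(ValueError, match="divide"):
            reconstruct(counts, grid, ReconParams(n_subsets=7, penalty=PenaltyParams(beta=0)))
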