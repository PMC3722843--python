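"""TSVD solver, threshold search, contrast and localization metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eitroi as e
from eitroi.reconstruction import ReconstructionError, _TSVD


class TestTSVD:
    def test_identity_passthrough(self):
        b = np.arange(5.0)
        assert np.allclose(e.tsvd_solve(np.eye(5), b, 0.0), b)

    def test_matches_constructed_factorization(self):
        """Truncated solution agrees with the expected value computed from
        a matrix with *known* singular factors."""
        rng = np.random.default_rng(0)
        U, _ = np.linalg.qr(rng.normal(size=(20, 15)))
        V, _ = np.linalg.qr(rng.normal(size=(15, 15)))
        s = np.geomspace(1.0, 1e-4, 15)
        A = U @ np.diag(s) @ V.T
        b = rng.normal(size=20)
        for tau in (0.0, 1e-3, 1e-1, 1.0):
            keep = s >= max(tau, 1e-14) * s[0]
            expected = V[:, keep] @ ((U[:, keep].T @ b) / s[keep])
            assert np.allclose(e.tsvd_solve(A, b, tau), expected, atol=1e-10)

    def test_threshold_domain_enforced(self):
        A = np.eye(3)
        for tau in (-0.1, 1.5):
            with pytest.raises(ReconstructionError):
                e.tsvd_solve(A, np.ones(3), tau)
        with pytest.raises(ReconstructionError):
            e.tsvd_solve(np.zeros((3, 3)), np.ones(3), 0.5)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_solution_norm_nonincreasing_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(12, 9))
        b = rng.normal(size=12)
        norms = [
            np.linalg.norm(e.tsvd_solve(A, b, tau))
            for tau in (0.0, 0.01, 0.1, 0.3, 0.7, 1.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestReconstruct:
    def test_zero_data_gives_zero_image(self, model1):
        dv0 = e.VoltageVector(np.zeros(model1.protocol.n_data), model1.protocol)
        res = e.reconstruct_conventional(model1.S, dv0, 0.01)
        assert np.all(res.image == 0.0)

    def test_single_anomaly_peak_within_one_pixel(self, model1):
        res = e.reconstruct_conventional(model1.S, model1.dv, 1e-3)
        peak = e.local_maxima(res, 1)[0]
        assert np.hypot(peak[0] - 0.8, peak[1]) <= model1.grid.size

    def test_amplitude_linearity(self, model1):
        """Within the linear regime, doubling the perturbation doubles the
        reconstructed amplitude."""
        tri = model1.mesh.centroids()
        mask = np.hypot(tri[:, 0] - 0.8, tri[:, 1]) < 0.0714
        images = []
        for eps in (0.01, 0.02):
            per = model1.sigma_ref.values.copy()
            per[mask] *= 1 + eps
            dv = e.difference_data(
                model1.mesh, model1.sigma_ref, e.ConductivityField(per), model1.protocol
            )
            images.append(e.reconstruct_conventional(model1.S, dv, 1e-3).image)
        ratio = np.linalg.norm(images[1]) / np.linalg.norm(images[0])
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_local_image_supported_in_roi(self, model1):
        F = e.build_filter(model1.S)
        res = e.reconstruct_local(F, model1.S, model1.dv, 1e-3)
        assert np.all(res.image[model1.grid.n_roi :] == 0.0)
        assert np.any(res.image[: model1.grid.n_roi] != 0.0)

    def test_orthogonal_filter_matches_direct_local_solve(self):
        """With orthogonal ROI/outside columns (zero leakage) and purely
        in-ROI data, the filtered reconstruction equals solving the
        restricted system S_D x = dV_D directly."""
        rng = np.random.default_rng(42)
        roi = e.ROIRegion(center=(0.35, 0.0), radius=0.45)
        grid = e.build_pixel_grid(e.DiskDomain(1.0), 10, roi)
        from eitroi.forward import DrivePattern, Protocol
        from eitroi.sensitivity import SensitivityMatrix

        R, N = grid.n_roi, grid.n_pixels
        Q, _ = np.linalg.qr(rng.normal(size=(2 * N, N)))
        M = Q * np.geomspace(1, 0.1, N)  # distinct singular values
        protocol = Protocol(
            tuple(DrivePattern(1, 2) for _ in range(2 * N)), ((3, 4),), "s"
        )
        S = SensitivityMatrix(matrix=M, grid=grid, protocol=protocol)
        x_true = np.zeros(N)
        x_true[:R] = rng.normal(size=R)
        dv = e.VoltageVector(M[:, :R] @ x_true[:R], protocol)
        F = e.build_filter(S, grid, alpha=1.0)
        res = e.reconstruct_local(F, S, dv, 0.0)
        direct = np.linalg.lstsq(M[:, :R], dv.values, rcond=None)[0]
        assert np.allclose(res.image[:R], direct, atol=1e-8)


class TestContrast:
    def test_flat_and_indicator_images(self, grid_unit):
        flat = e.ReconstructionResult(
            np.zeros(grid_unit.n_pixels), 0.1, 1, "t", grid_unit
        )
        anom = np.array([0, 1, 2])
        bg = np.array([10, 11, 12, 13])
        assert e.contrast(flat, anom, bg) == 0.0
        img = np.zeros(grid_unit.n_pixels)
        img[anom] = 2.5
        ind = e.ReconstructionResult(img, 0.1, 1, "t", grid_unit)
        assert e.contrast(ind, anom, bg) == pytest.approx(2.5)

    def test_degenerate_sets_rejected(self, grid_unit):
        res = e.ReconstructionResult(np.zeros(grid_unit.n_pixels), 0.1, 1, "t", grid_unit)
        with pytest.raises(ReconstructionError):
            e.contrast(res, np.array([], dtype=int), np.array([1]))
        with pytest.raises(ReconstructionError):
            e.contrast(res, np.array([1, 2]), np.array([2, 3]))


class TestThresholdSearch:
    def test_recovers_endpoint_target(self, model1):
        anom, bg = e.contrast_sets(model1.grid, [(0.8, 0.0)], 0.1428)
        svd = _TSVD(model1.S.matrix)
        x0, _ = svd.solve(model1.dv.values, 0.0)
        target = float(x0[anom].mean() - x0[bg].mean())
        res = e.threshold_search(
            model1.S.matrix, model1.dv.values, target, anom, bg, tolerance=0.02
        )
        assert res.converged
        assert abs(res.contrast - target) <= 0.02 * abs(target)
        assert res.threshold < 0.05

    def test_zero_data_flagged(self, model1):
        anom = np.array([0, 1])
        bg = np.array([5, 6])
        res = e.threshold_search(
            model1.S.matrix, np.zeros(model1.protocol.n_data), 0.0, anom, bg
        )
        assert not res.converged

    def test_unattainable_target_flagged(self, model1):
        anom, bg = e.contrast_sets(model1.grid, [(0.8, 0.0)], 0.1428)
        res = e.threshold_search(
            model1.S.matrix, model1.dv.values, 1e6, anom, bg
        )
        assert not res.converged
        assert "not bracketed" in res.note


class TestLocalization:
    def _indicator(self, grid, centers, radius, amplitude=1.0):
        img = np.zeros(grid.n_pixels)
        for c in centers:
            img[grid.pixels_in_disk(c, radius)] = amplitude
        return e.ReconstructionResult(img, 0.1, 1, "t", grid)

    def test_exact_indicators_have_zero_error(self, grid_unit):
        centers = [(0.5, 0.3), (-0.4, -0.2)]
        res = self._indicator(grid_unit, centers, 0.12)
        errs = e.localization_error(res, centers)
        assert np.all(errs <= grid_unit.size)

    def test_shifted_indicator_reports_shift(self, grid_unit):
        res = self._indicator(grid_unit, [(0.5, 0.0)], 0.12)
        errs = e.localization_error(res, [(0.3, 0.0)])
        assert errs[0] == pytest.approx(0.2, abs=grid_unit.size)

    def test_negative_anomalies_detected(self, grid_unit):
        res = self._indicator(grid_unit, [(0.4, 0.2)], 0.12, amplitude=-1.0)
        errs = e.localization_error(res, [(0.4, 0.2)])
        assert errs[0] <= grid_unit.size

    def test_missing_peaks_reported_as_nan(self, grid_unit):
        res = self._indicator(grid_unit, [(0.5, 0.0)], 0.12)
        errs = e.localization_error(res, [(0.5, 0.0), (-0.5, 0.0)])
        assert np.isnan(errs).sum() == 1


class TestOutsideInfluence:
    def test_reference_case_has_zero_norms(self, model1):
        F = e.build_filter(model1.S)
        table = e.outside_influence(model1.dv, {"ref": model1.dv}, F)
        assert table.loc["ref", "raw_norm"] == 0.0
        assert table.loc["ref", "filtered_norm"] == 0.0
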