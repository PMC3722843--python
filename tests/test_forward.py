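"""Forward model: protocols, conservation, symmetry, analytic oracle."""

import math

import numpy as np
import pytest

import eitroi as e
from eitroi.forward import ForwardError, Protocol, DrivePattern


class TestProtocol:
    def test_adjacent_counts(self, model0):
        assert model0.protocol.n_drives == 16
        assert model0.protocol.n_measurements == 16
        assert model0.protocol.n_data == 256  # E^2 boundary voltage data

    def test_augmented_counts(self, model1):
        # probe drives added, surface measurement ring kept: 2E x E
        assert model1.protocol.n_drives == 32
        assert model1.protocol.n_measurements == 16

    def test_full_augmented_counts(self):
        lay = e.make_layout(16, "equidistant", internal_position=(0.5, 0.0))
        prot = e.make_protocol(lay, "internal_augmented_full")
        assert prot.n_drives == 32 and prot.n_measurements == 32

    def test_augmented_requires_internal(self):
        lay = e.make_layout(16, "equidistant")
        with pytest.raises(ForwardError):
            e.make_protocol(lay, "internal_augmented")

    def test_degenerate_drive_rejected(self):
        with pytest.raises(ForwardError):
            DrivePattern(3, 3)


class TestForwardSolve:
    def test_current_conservation(self, model0):
        """Gap-model Neumann loads sum to zero for every drive."""
        for drive in model0.protocol.drives:
            b = model0.solver.load_vector(drive.source, drive.sink)
            assert abs(b.sum()) < 1e-14

    def test_conductivity_scaling(self, model0):
        """Doubling a homogeneous conductivity halves every potential."""
        sigma2 = e.ConductivityField(2.0 * model0.sigma_ref.values)
        u1 = model0.solver.solve(model0.protocol.drives[0])
        u2 = e.solve_forward(model0.mesh, sigma2, model0.protocol.drives[0])
        assert np.allclose(u2, 0.5 * u1, atol=1e-12 * np.abs(u1).max())

    def test_mirror_antisymmetry(self, model0):
        """Drive between electrodes at angles 0 and pi: measurements are
        antisymmetric under reflection through the y-axis."""
        u = model0.solver.solve(DrivePattern(1, 9))
        mirr = lambda i: ((9 - i) % 16) + 1
        vals, devs = [], []
        for k in range(1, 17):
            a = model0.solver.measure(u, (k, k % 16 + 1))
            b = model0.solver.measure(u, (mirr(k), mirr(k % 16 + 1)))
            vals.append(abs(a))
            devs.append(abs(a + b))
        assert max(devs) < 1e-3 * max(vals)

    def test_constant_potential_average(self, model0):
        u = np.full(model0.mesh.n_nodes, 3.7)
        assert e.electrode_voltage(u, model0.mesh, 5) == pytest.approx(3.7)

    def test_missing_marker_rejected(self, model0):
        with pytest.raises(ForwardError):
            e.electrode_voltage(np.zeros(model0.mesh.n_nodes), model0.mesh, 99)


class TestCollectData:
    def test_ring_sum_telescopes(self, model0):
        """Adjacent measurements around the closed ring sum to zero."""
        V = model0.v_ref.as_matrix()
        assert np.abs(V.sum(axis=1)).max() < 1e-10 * np.abs(V).max()

    def test_reciprocity(self, model0):
        V = model0.v_ref.as_matrix()
        assert np.abs(V - V.T).max() < 1e-6 * np.abs(V).max()

    def test_rotational_shift_invariance(self, model0):
        """On the homogeneous equidistant disk the data are invariant (to
        discretization error) under rotating drive and measurement by one."""
        V = model0.v_ref.as_matrix()
        shifted = np.roll(np.roll(V, 1, axis=0), 1, axis=1)
        assert np.abs(V - shifted).max() < 1e-2 * np.abs(V).max()

    def test_difference_of_identical_fields_is_zero(self, model0):
        dv = e.difference_data(
            model0.mesh, model0.sigma_ref, model0.sigma_ref, model0.protocol
        )
        assert np.all(dv.values == 0.0)

    def test_difference_scales_linearly(self, model1):
        """|dV| is first-order in the perturbation amplitude."""
        base = model1.sigma_ref.values
        tri = model1.mesh.centroids()
        mask = np.hypot(tri[:, 0] - 0.6, tri[:, 1]) < 0.1
        norms = []
        for eps in (1e-3, 5e-4):
            per = base.copy()
            per[mask] *= 1 + eps
            dv = e.difference_data(
                model1.mesh, model1.sigma_ref, e.ConductivityField(per), model1.protocol
            )
            norms.append(np.linalg.norm(dv.values))
        assert norms[0] / norms[1] == pytest.approx(2.0, rel=2e-3)


class TestAnalyticOracle:
    @staticmethod
    def _analytic_voltages(E, width, exclude_touching=True):
        """Point-drive solution u = (1/pi/sigma) ln(|x-sink|/|x-source|),
        arc-averaged over the measurement electrodes by Gauss quadrature."""
        from numpy.polynomial.legendre import leggauss

        gx, gw = leggauss(32)
        centers = 2 * math.pi * np.arange(E) / E

        def arc_avg(th_c, th_s, th_k):
            th = th_c + 0.5 * width * gx
            x, y = np.cos(th), np.sin(th)
            vals = (1 / math.pi) * (
                np.log(np.hypot(x - math.cos(th_k), y - math.sin(th_k)))
                - np.log(np.hypot(x - math.cos(th_s), y - math.sin(th_s)))
            )
            return float((vals * gw).sum() / gw.sum())

        out = {}
        for j in range(E):
            th_s, th_k = centers[j], centers[(j + 1) % E]
            for k in range(E):
                if exclude_touching and k in (j, (j + 1) % E, (j - 1) % E):
                    continue
                out[(j, k)] = arc_avg(centers[k], th_s, th_k) - arc_avg(
                    centers[(k + 1) % E], th_s, th_k
                )
        return out

    @staticmethod
    def _fem_error(h, width):
        lay = e.make_layout(16, "equidistant", arc_width=width)
        mesh = e.build_mesh(lay, h)
        sigma = e.ConductivityField.homogeneous(mesh, 1.0)
        V = e.collect_data(mesh, sigma, e.make_protocol(lay)).as_matrix()
        ana = TestAnalyticOracle._analytic_voltages(16, width)
        errs = [abs(V[j, k] - v) for (j, k), v in ana.items()]
        scale = max(abs(v) for v in ana.values())
        return max(errs) / scale

    def test_converges_to_point_drive_solution(self):
        """Narrow-electrode FEM voltages approach the closed-form disk
        solution, and the error decreases under mesh refinement."""
        coarse = self._fem_error(0.05, 0.04)
        fine = self._fem_error(0.03, 0.04)
        assert fine < coarse
        assert fine < 0.01


class TestNoise:
    def _long_vector(self, n=10000, seed=7):
        protocol = Protocol(
            tuple(DrivePattern(1, 2) for _ in range(n // 100)),
            tuple((3, 4) for _ in range(100)),
            "synthetic",
        )
        rng = np.random.default_rng(seed)
        return e.VoltageVector(rng.normal(size=n), protocol)

    def test_infinite_snr_is_identity(self, model0):
        out = e.add_noise(model0.v_ref, math.inf, seed=1)
        assert np.array_equal(out.values, model0.v_ref.values)

    def test_seed_reproducibility(self, model0):
        a = e.add_noise(model0.v_ref, 40.0, seed=123)
        b = e.add_noise(model0.v_ref, 40.0, seed=123)
        assert np.array_equal(a.values, b.values)

    def test_empirical_snr(self):
        data = self._long_vector()
        noisy = e.add_noise(data, 20.0, seed=11)
        noise = noisy.values - data.values
        snr = 10 * math.log10(np.mean(data.values**2) / np.mean(noise**2))
        assert abs(snr - 20.0) < 0.5
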