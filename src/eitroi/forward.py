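"""FEM forward model: conductivity equation, gap electrodes, voltage data.

The potential :math:`u` satisfies :math:`\\nabla\\cdot(\\sigma\\nabla u)=0`
in the disk with Neumann boundary data given by the injected current.
Electrodes follow the gap (shunt-free) model: the current density is uniform
over the electrode arc (:math:`\\pm I/|\\mathcal{E}|`), and the electrode
voltage is the arc-average of the potential.  The additive constant is fixed
by a zero-mean gauge over all mesh nodes.

Measurement protocols enumerate drive pairs and measurement pairs; the data
vector stacks entries drive-major, ``m = (j-1)*K + (k-1)`` for drive ``j``
of ``J`` and measurement ``k`` of ``K``.  The adjacent boundary protocol
yields the classical ``E^2`` data; with an internal electrode the protocol
is augmented with internal-to-surface drive pairs and surface-to-internal
measurement pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .geometry import ElectrodeLayout, TriangleMesh


class ForwardError(ValueError):
    """Invalid conductivity field, protocol, or singular forward system."""


@dataclass(frozen=True)
class ConductivityField:
    """Per-triangle (piecewise-constant) conductivity in S/m."""

    values: np.ndarray
    is_reference: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ForwardError("conductivity values must be finite and positive")

    @classmethod
    def homogeneous(cls, mesh: TriangleMesh, sigma: float, is_reference: bool = True):
        return cls(np.full(mesh.n_triangles, float(sigma)), is_reference=is_reference)


@dataclass(frozen=True)
class DrivePattern:
    """Current injection between a source and a sink electrode."""

    source: int
    sink: int
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.source == self.sink:
            raise ForwardError("drive source and sink must differ")
        if not self.amplitude > 0:
            raise ForwardError("drive amplitude must be positive")


@dataclass(frozen=True)
class Protocol:
    """Ordered drives and measurement pairs with a scheme label."""

    drives: Tuple[DrivePattern, ...]
    measurements: Tuple[Tuple[int, int], ...]
    scheme: str

    @property
    def n_drives(self) -> int:
        return len(self.drives)

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    @property
    def n_data(self) -> int:
        return self.n_drives * self.n_measurements


@dataclass(frozen=True)
class VoltageVector:
    """Measurement vector, drive-major then measurement ordering."""

    values: np.ndarray
    protocol: Protocol

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.protocol.n_data,):
            raise ForwardError(
                f"expected {self.protocol.n_data} values, got {v.shape}"
            )

    def as_matrix(self) -> np.ndarray:
        """Reshape to (J, K): row j holds drive j's measurements."""
        return self.values.reshape(self.protocol.n_drives, self.protocol.n_measurements)

    def __sub__(self, other: "VoltageVector") -> "VoltageVector":
        if other.protocol is not self.protocol and other.protocol != self.protocol:
            raise ForwardError("voltage vectors use different protocols")
        return VoltageVector(self.values - other.values, self.protocol)


def make_protocol(layout: ElectrodeLayout, scheme: str = "boundary_adjacent") -> Protocol:
    """Build a measurement protocol for a layout.

    ``boundary_adjacent``
        Drives (j, j+1) and measurements (k, k+1) over the surface ring —
        the classical ``E^2`` data.

    ``internal_augmented``
        Additionally drives (E+1, j) from the internal electrode to every
        surface electrode, keeping the surface measurement ring — ``2E x E``
        data.  By reciprocity, surface-to-probe voltage measurements under
        surface drives duplicate the probe-drive data, and measurements on
        the tiny current-carrying probe itself are dominated by the
        immediate probe vicinity; this subset therefore carries the full
        non-redundant information of the augmented configuration.

    ``internal_augmented_full``
        The complete cross product: probe drives *and* surface-to-probe
        measurement pairs — ``(2E)^2`` data.
    """
    E = layout.n_boundary
    adjacent_drives = [DrivePattern(j, j % E + 1) for j in range(1, E + 1)]
    adjacent_meas = [(k, k % E + 1) for k in range(1, E + 1)]
    if scheme == "boundary_adjacent":
        return Protocol(tuple(adjacent_drives), tuple(adjacent_meas), scheme)
    if scheme in ("internal_augmented", "internal_augmented_full"):
        if layout.internal is None:
            raise ForwardError(f"{scheme} requires an internal electrode")
        ii = layout.internal_index
        drives = adjacent_drives + [DrivePattern(ii, j) for j in range(1, E + 1)]
        meas = list(adjacent_meas)
        if scheme == "internal_augmented_full":
            meas += [(k, ii) for k in range(1, E + 1)]
        return Protocol(tuple(drives), tuple(meas), scheme)
    raise ForwardError(f"unknown protocol scheme {scheme!r}")


# ---------------------------------------------------------------------------
# P1 Galerkin assembly and solver
# ---------------------------------------------------------------------------


def p1_gradients(mesh: TriangleMesh) -> Tuple[np.ndarray, np.ndarray]:
    """Gradients of the nodal hat functions on each triangle.

    Returns ``(grads, areas)`` where ``grads`` has shape (m, 3, 2): the
    (constant) gradient of the barycentric basis function of each local
    vertex.
    """
    p = mesh.nodes[mesh.triangles]
    areas = mesh.triangle_areas()
    if np.any(areas <= 0):
        raise ForwardError("mesh contains non-positively-oriented triangles")
    b = np.stack(
        [p[:, 1, 1] - p[:, 2, 1], p[:, 2, 1] - p[:, 0, 1], p[:, 0, 1] - p[:, 1, 1]],
        axis=1,
    )
    c = np.stack(
        [p[:, 2, 0] - p[:, 1, 0], p[:, 0, 0] - p[:, 2, 0], p[:, 1, 0] - p[:, 0, 0]],
        axis=1,
    )
    grads = np.stack([b, c], axis=2) / (2.0 * areas)[:, None, None]
    return grads, areas


def assemble_stiffness(mesh: TriangleMesh, sigma: ConductivityField) -> sparse.csr_matrix:
    """Sparse stiffness matrix of the P1 Galerkin discretization."""
    if sigma.values.shape != (mesh.n_triangles,):
        raise ForwardError("conductivity field does not match the mesh")
    grads, areas = p1_gradients(mesh)
    # local 3x3 blocks: sigma * area * grad_i . grad_j
    local = np.einsum("tic,tjc->tij", grads, grads) * (sigma.values * areas)[:, None, None]
    t = mesh.triangles
    rows = np.repeat(t, 3, axis=1).ravel()
    cols = np.tile(t, (1, 3)).ravel()
    K = sparse.coo_matrix(
        (local.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    return K.tocsr()


def electrode_weight_vector(mesh: TriangleMesh, electrode_index: int) -> Tuple[np.ndarray, float]:
    """Trapezoidal arc-length weights of an electrode's boundary chain.

    Returns ``(w, total_length)`` with ``w`` a nodal vector summing to the
    electrode arc length; ``w @ u / total_length`` is the arc-average of a
    nodal field ``u`` (and ``w/total_length`` is also the gap-model current
    load shape for unit injected current).
    """
    if electrode_index not in mesh.electrode_edges:
        raise ForwardError(f"mesh has no electrode marker {electrode_index}")
    edges = mesh.electrode_edges[electrode_index]
    lengths = mesh.electrode_edge_lengths(electrode_index)
    w = np.zeros(mesh.n_nodes)
    np.add.at(w, edges[:, 0], 0.5 * lengths)
    np.add.at(w, edges[:, 1], 0.5 * lengths)
    return w, float(lengths.sum())


def electrode_voltage(potential: np.ndarray, mesh: TriangleMesh, electrode_index: int) -> float:
    """Arc-length-weighted mean of the potential over an electrode."""
    w, total = electrode_weight_vector(mesh, electrode_index)
    return float(w @ np.asarray(potential, dtype=float)) / total


class ForwardSolver:
    """Factorized forward operator for one mesh/conductivity pair.

    The singular pure-Neumann system is augmented with a Lagrange
    multiplier enforcing the zero-mean gauge; the augmented matrix is
    factorized once (sparse LU) and reused for every drive pattern.
    """

    def __init__(self, mesh: TriangleMesh, sigma: ConductivityField):
        self.mesh = mesh
        self.sigma = sigma
        K = assemble_stiffness(mesh, sigma)
        n = mesh.n_nodes
        ones = np.ones((n, 1)) / n
        A = sparse.bmat([[K, ones], [ones.T, None]], format="csc")
        try:
            self._lu = splu(A)
        except RuntimeError as exc:  # pragma: no cover - singular only if mesh broken
            raise ForwardError(f"forward system could not be factorized: {exc}")
        self._weights: Dict[int, Tuple[np.ndarray, float]] = {}

    def weights(self, electrode_index: int) -> Tuple[np.ndarray, float]:
        if electrode_index not in self._weights:
            self._weights[electrode_index] = electrode_weight_vector(
                self.mesh, electrode_index
            )
        return self._weights[electrode_index]

    def load_vector(self, source: int, sink: int, amplitude: float = 1.0) -> np.ndarray:
        """Gap-model Neumann load: +I/|E| on the source arc, -I/|E| on the sink."""
        ws, ls = self.weights(source)
        wk, lk = self.weights(sink)
        return amplitude * (ws / ls - wk / lk)

    def solve(self, drive: DrivePattern) -> np.ndarray:
        """Nodal potential for one drive, zero-mean gauge."""
        b = self.load_vector(drive.source, drive.sink, drive.amplitude)
        rhs = np.append(b, 0.0)
        u = self._lu.solve(rhs)[:-1]
        return u - u.mean()

    def measure(self, u: np.ndarray, pair: Tuple[int, int]) -> float:
        """Voltage between a pair of electrodes (first minus second)."""
        wp, lp = self.weights(pair[0])
        wn, ln = self.weights(pair[1])
        return float(wp @ u) / lp - float(wn @ u) / ln


def solve_forward(mesh: TriangleMesh, sigma: ConductivityField, drive: DrivePattern) -> np.ndarray:
    """One-off forward solve (see :class:`ForwardSolver` for batched use)."""
    return ForwardSolver(mesh, sigma).solve(drive)


def collect_data(
    mesh: TriangleMesh,
    sigma: ConductivityField,
    protocol: Protocol,
    solver: Optional[ForwardSolver] = None,
) -> VoltageVector:
    """Simulate the full measurement vector for a protocol.

    One forward solve per distinct drive pattern; entry ``(j, k)`` is the
    voltage of measurement pair ``k`` under drive ``j``.
    """
    solver = solver or ForwardSolver(mesh, sigma)
    values = np.empty(protocol.n_data)
    K = protocol.n_measurements
    for j, drive in enumerate(protocol.drives):
        try:
            u = solver.solve(drive)
        except ForwardError as exc:
            raise ForwardError(f"drive {j + 1} ({drive.source},{drive.sink}): {exc}")
        for k, pair in enumerate(protocol.measurements):
            values[j * K + k] = solver.measure(u, pair)
    return VoltageVector(values, protocol)


def difference_data(
    mesh: TriangleMesh,
    sigma_ref: ConductivityField,
    sigma_perturbed: ConductivityField,
    protocol: Protocol,
) -> VoltageVector:
    """Time-difference data: perturbed minus reference measurements."""
    if sigma_ref.values.shape != sigma_perturbed.values.shape:
        raise ForwardError("reference and perturbed fields use different meshes")
    v_ref = collect_data(mesh, sigma_ref, protocol)
    v_per = collect_data(mesh, sigma_perturbed, protocol)
    return v_per - v_ref


def add_noise(data: VoltageVector, snr_db: float, seed: int) -> VoltageVector:
    """Additive white Gaussian noise at a prescribed signal-to-noise ratio.

    ``snr_db = inf`` returns the data unchanged.  The noise standard
    deviation is set from the mean signal power so that the expected
    power ratio matches ``snr_db``; fully reproducible from ``seed``.
    """
    if math.isinf(snr_db):
        return VoltageVector(data.values.copy(), data.protocol)
    if not math.isfinite(snr_db):
        raise ForwardError("snr_db must be finite or +inf")
    rng = np.random.default_rng(seed)
    p_signal = float(np.mean(data.values**2))
    sigma = math.sqrt(p_signal / (10.0 ** (snr_db / 10.0)))
    return VoltageVector(data.values + rng.normal(0.0, sigma, data.values.shape), data.protocol)
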