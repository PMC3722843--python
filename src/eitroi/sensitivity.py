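"""Sensitivity (Jacobian) matrix and its ROI diagnostics.

The sensitivity matrix :math:`S` maps a per-pixel conductivity change
:math:`\\delta\\gamma` to the first-order change of the measurement vector,

.. math:: S[m, n] = -\\int_{q_n} \\nabla u^j \\cdot \\nabla w^k \\, dr,

where ``m = (j, k)`` indexes drive/measurement pairs, :math:`u^j` is the
reference-field potential of drive ``j`` and :math:`w^k` is the adjoint
field obtained by driving the measurement pair ``k`` with unit current
(reciprocity).  Pixel integrals are evaluated by triangle-centroid binning:
a triangle contributes its full area-weighted integrand to the pixel
containing its centroid.

With an ROI attached to the pixel grid the columns come out ROI-first, so
``S[:, :R]`` are the in-ROI sensitivity columns and ``S[:, R:]`` the
outside columns.  Diagnostics:

* :func:`cross_correlation` — mean normalized inner product between each
  ROI column and the outside columns (low values mean the ROI is easier to
  separate from the rest of the domain);
* :func:`norm_ratio` — spectral norms of the in-ROI and outside column
  blocks relative to the whole matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import sparse

from .forward import ConductivityField, ForwardSolver, Protocol, p1_gradients
from .geometry import PixelGrid, TriangleMesh

logger = logging.getLogger(__name__)


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class SensitivityMatrix:
    """Jacobian of the measurement vector w.r.t. per-pixel conductivity.

    ``matrix`` has shape (J*K, N) with columns in the grid's canonical
    (ROI-first) pixel order.
    """

    matrix: np.ndarray
    grid: PixelGrid
    protocol: Protocol

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.protocol.n_data, self.grid.n_pixels):
            raise SensitivityError(
                f"matrix shape {self.matrix.shape} does not match protocol/grid"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise SensitivityError("sensitivity matrix has non-finite entries")

    @property
    def n_roi(self) -> int:
        return self.grid.n_roi


def _field_gradients(solver: ForwardSolver, pairs, grads) -> np.ndarray:
    """Per-triangle gradient of the unit-current field of each electrode pair.

    Fields are cached per unordered pair; reversing a pair flips the sign.
    """
    from .forward import DrivePattern

    mesh = solver.mesh
    cache: dict[tuple[int, int], np.ndarray] = {}
    out = np.empty((len(pairs), mesh.n_triangles, 2))
    tri = mesh.triangles
    for i, (a, b) in enumerate(pairs):
        key = (min(a, b), max(a, b))
        if key not in cache:
            u = solver.solve(DrivePattern(key[0], key[1], 1.0))
            cache[key] = np.einsum("ti,tic->tc", u[tri], grads)
        out[i] = cache[key] if (a, b) == key else -cache[key]
    return out


def compute_sensitivity(
    mesh: TriangleMesh,
    sigma_ref: ConductivityField,
    protocol: Protocol,
    grid: PixelGrid,
    solver: Optional[ForwardSolver] = None,
) -> SensitivityMatrix:
    """Assemble the sensitivity matrix on the reference conductivity.

    One forward solve per distinct drive pair and per distinct measurement
    pair (adjoint fields by reciprocity); triangles whose centroid falls in
    no pixel (rim cells whose centre lies outside the disk) contribute to no
    column, and pixels containing no triangle centroid give zero columns
    with a logged warning.
    """
    solver = solver or ForwardSolver(mesh, sigma_ref)
    grads, areas = p1_gradients(mesh)

    drive_pairs = [(d.source, d.sink) for d in protocol.drives]
    amp = np.array([d.amplitude for d in protocol.drives])
    Gd = _field_gradients(solver, drive_pairs, grads) * amp[:, None, None]
    Gm = _field_gradients(solver, list(protocol.measurements), grads)

    # M[(j,k), t] = -area_t * grad u^j . grad w^k
    M = -np.einsum("jtc,ktc,t->jkt", Gd, Gm, areas)
    M = M.reshape(protocol.n_data, mesh.n_triangles)

    pix = grid.lattice_of_points(mesh.centroids())
    keep = pix >= 0
    assign = sparse.coo_matrix(
        (np.ones(keep.sum()), (np.nonzero(keep)[0], pix[keep])),
        shape=(mesh.n_triangles, grid.n_pixels),
    ).tocsr()
    S = M @ assign

    empty = np.asarray(assign.sum(axis=0)).ravel() == 0
    if empty.any():
        logger.warning("%d pixels contain no triangle centroid (zero columns)", empty.sum())
    return SensitivityMatrix(matrix=np.asarray(S), grid=grid, protocol=protocol)


def partition_columns(S: SensitivityMatrix, grid: Optional[PixelGrid] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Split the Jacobian into in-ROI and outside column blocks.

    Returns ``(S_D, S_out)``; together they are a column permutation of the
    full matrix (the canonical order is already ROI-first).
    """
    grid = grid or S.grid
    if grid.roi is None:
        raise SensitivityError("pixel grid has no ROI attached")
    R = grid.n_roi
    N = grid.n_pixels
    if R == 0 or R == N:
        raise SensitivityError(f"degenerate ROI partition (R={R}, N={N})")
    return S.matrix[:, :R], S.matrix[:, R:]


def cross_correlation(S: SensitivityMatrix, grid: Optional[PixelGrid] = None) -> np.ndarray:
    """Mean absolute normalized correlation of ROI columns with outside columns.

    For each ROI pixel ``j``, the average over outside pixels ``i`` of
    ``|s_i . s_j| / (||s_i|| ||s_j||)`` — a value in [0, 1].  Zero outside
    columns are excluded from the average (logged); a zero ROI column gives
    NaN for that pixel.
    """
    Sd, So = partition_columns(S, grid)
    nd = np.linalg.norm(Sd, axis=0)
    no = np.linalg.norm(So, axis=0)
    ok_out = no > 0
    if not ok_out.all():
        logger.warning("%d zero outside columns excluded from mu", (~ok_out).sum())
    if not ok_out.any():
        raise SensitivityError("no nonzero outside columns")
    C = np.abs(Sd.T @ So[:, ok_out])  # (R, n_out_ok)
    mu = (C / no[ok_out][None, :]).mean(axis=1) / np.where(nd > 0, nd, np.nan)
    return mu


def norm_ratio(A: np.ndarray, n_roi: int) -> Tuple[float, float]:
    """Spectral-norm ratios of the ROI / outside column blocks.

    ``A`` must have its first ``n_roi`` columns corresponding to the ROI.
    Returns ``(||A_in|| / ||A||, ||A_out|| / ||A||)``; each ratio is at
    most 1 since a submatrix norm never exceeds the full norm.
    """
    A = np.asarray(A, dtype=float)
    if not (0 < n_roi < A.shape[1]):
        raise SensitivityError("n_roi must split the columns non-trivially")
    full = np.linalg.norm(A, 2)
    if full == 0:
        raise SensitivityError("zero matrix has no norm ratio")
    return (
        float(np.linalg.norm(A[:, :n_roi], 2) / full),
        float(np.linalg.norm(A[:, n_roi:], 2) / full),
    )
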