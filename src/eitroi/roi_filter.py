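"""Construction and application of the ROI filter matrix.

Each filter column :math:`\\phi_k` (one per ROI pixel) minimizes the
strictly convex quadratic

.. math::
   \\sum_{p_j \\notin D} |s_j \\cdot \\phi|^2
   + \\alpha \\| \\phi - s_k \\|_2^2,

i.e. it stays close to the ROI sensitivity column :math:`s_k` while being
as orthogonal as possible to every outside-ROI column.  The unique
minimizer solves the normal equations

.. math:: (S_{out} S_{out}^T + \\alpha I)\\,\\phi_k = \\alpha\\, s_k,

so the whole filter needs a single symmetric positive-definite
factorization reused across all ROI columns.  Multiplying the linearized
system by :math:`\\Phi^T` yields a small localized system whose data are
dominated by in-ROI conductivity changes; :func:`leakage` quantifies the
residual out-of-ROI contribution.

The trade-off parameter :math:`\\alpha` balances suppression (small
:math:`\\alpha`) against fidelity to the ROI columns (large
:math:`\\alpha`); :func:`default_alpha` scales it to the squared spectral
norm of the outside block so the two terms are dimensionally comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .forward import VoltageVector
from .geometry import PixelGrid
from .sensitivity import SensitivityMatrix, partition_columns


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class ROIFilter:
    """Filter matrix with one column per ROI pixel.

    ``matrix`` has shape (J*K, R); column ``k`` corresponds to the grid's
    k-th ROI pixel (canonical ROI-first order).
    """

    matrix: np.ndarray
    alpha: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise FilterError("filter matrix has non-finite entries")
        if not self.alpha > 0:
            raise FilterError("alpha must be positive")

    @property
    def n_roi(self) -> int:
        return self.matrix.shape[1]


def _gram(S_out: np.ndarray, alpha: float) -> np.ndarray:
    G = S_out @ S_out.T
    G[np.diag_indices_from(G)] += alpha
    return G


def filter_vector(
    S: SensitivityMatrix, grid: PixelGrid, k: int, alpha: float
) -> np.ndarray:
    """Exact minimizer of the filter objective for one ROI pixel ``k``."""
    if not alpha > 0:
        raise FilterError("alpha must be positive")
    Sd, So = partition_columns(S, grid)
    if not (0 <= k < Sd.shape[1]):
        raise FilterError(f"k={k} is not an ROI pixel index (R={Sd.shape[1]})")
    cho = cho_factor(_gram(So, alpha), lower=True)
    return cho_solve(cho, alpha * Sd[:, k])


def build_filter(
    S: SensitivityMatrix,
    grid: Optional[PixelGrid] = None,
    alpha: Optional[float] = None,
    provenance: str = "",
) -> ROIFilter:
    """Build the full filter: all ROI columns through one factorization."""
    grid = grid or S.grid
    if alpha is None:
        alpha = default_alpha(S, grid)
    if not alpha > 0:
        raise FilterError("alpha must be positive")
    Sd, So = partition_columns(S, grid)
    cho = cho_factor(_gram(So, alpha), lower=True)
    Phi = cho_solve(cho, alpha * Sd)
    return ROIFilter(matrix=Phi, alpha=float(alpha), provenance=provenance)


def default_alpha(S: SensitivityMatrix, grid: Optional[PixelGrid] = None) -> float:
    """Spectral-norm-scaled default: ``alpha = 1e-2 * ||S_out S_out^T||``.

    Falls back to 1 when the outside block vanishes.  Scaling the matrix by
    ``c`` scales the default by ``c**2``, keeping the filter scale-free.
    """
    _, So = partition_columns(S, grid or S.grid)
    s = np.linalg.norm(So, 2) ** 2
    return float(s * 1e-2) if s > 0 else 1.0


def apply_filter(
    F: ROIFilter,
    S: Optional[SensitivityMatrix] = None,
    data: Optional[VoltageVector] = None,
) -> Tuple[Optional[np.ndarray], Optional[np.ndarray]]:
    """Project the linearized system onto the filter: (Phi^T S, Phi^T dV).

    Either argument may be omitted; dimensions are checked against the
    filter.  The filtered matrix keeps all N pixel columns (use the first R
    for the localized reconstruction system).
    """
    Phi = F.matrix
    fS = fV = None
    if S is not None:
        if S.matrix.shape[0] != Phi.shape[0]:
            raise FilterError("sensitivity matrix and filter row counts differ")
        fS = Phi.T @ S.matrix
    if data is not None:
        if data.values.shape[0] != Phi.shape[0]:
            raise FilterError("data vector and filter row counts differ")
        fV = Phi.T @ data.values
    return fS, fV


def leakage(
    F: ROIFilter, data_out: VoltageVector, data_roi: VoltageVector
) -> Tuple[float, Optional[float]]:
    """Out-of-ROI leakage through the filter.

    ``data_out`` / ``data_roi`` are the simulated components of the
    difference data due to conductivity changes outside / inside the ROI
    (available in simulation only).  Returns ``||Phi^T data_out||_2`` and
    the ratio ``||Phi^T data_out|| / ||Phi^T data_roi||`` (None when the
    ROI component vanishes).
    """
    lam = float(np.linalg.norm(F.matrix.T @ data_out.values))
    denom = float(np.linalg.norm(F.matrix.T @ data_roi.values))
    return lam, (lam / denom if denom > 0 else None)
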