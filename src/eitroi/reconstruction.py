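"""TSVD reconstruction, threshold search and image-quality metrics.

Both the conventional (full-domain) and the localized (ROI-filtered)
linear systems are solved by truncated SVD: singular components with
:math:`\\sigma_i \\ge \\tau \\sigma_{max}` are inverted, the rest
discarded.  The truncation level :math:`\\tau` is expressed relative to
the largest singular value, so it is dimensionless and comparable across
electrode configurations.

The contrast metric is the difference of image means over a known anomaly
pixel set and a background pixel set; :func:`threshold_search` bisects the
truncation level until a target contrast is met, mirroring the procedure
of tuning the singular-value threshold until reconstructions reach the
same conductivity contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .forward import VoltageVector
from .geometry import PixelGrid
from .roi_filter import ROIFilter, apply_filter
from .sensitivity import SensitivityMatrix, partition_columns


class ReconstructionError(ValueError):
    pass


@dataclass(frozen=True)
class ReconstructionResult:
    """Per-pixel conductivity-change estimate on the full grid.

    The localized method fills zeros outside the ROI.  ``threshold`` is
    relative to the largest singular value; ``rank`` is the number of
    singular components retained.
    """

    image: np.ndarray
    threshold: float
    rank: int
    method: str
    grid: PixelGrid

    def as_image(self) -> np.ndarray:
        return self.grid.to_image(self.image)


class _TSVD:
    """SVD computed once, reusable across truncation levels."""

    def __init__(self, A: np.ndarray):
        A = np.asarray(A, dtype=float)
        if A.size == 0 or not np.any(A):
            raise ReconstructionError("matrix is zero or empty")
        self.U, self.s, self.Vt = np.linalg.svd(A, full_matrices=False)
        self.shape = A.shape

    def solve(self, b: np.ndarray, rel_threshold: float) -> Tuple[np.ndarray, int]:
        if not (0.0 <= rel_threshold <= 1.0):
            raise ReconstructionError("rel_threshold must lie in [0, 1]")
        b = np.asarray(b, dtype=float)
        if b.shape != (self.shape[0],):
            raise ReconstructionError("right-hand side length mismatch")
        cutoff = max(rel_threshold, 1e-14) * self.s[0]
        keep = self.s >= cutoff
        rank = int(keep.sum())
        coef = (self.U[:, keep].T @ b) / self.s[keep]
        return self.Vt[keep].T @ coef, rank


def tsvd_solve(A: np.ndarray, b: np.ndarray, rel_threshold: float) -> np.ndarray:
    """Truncated-SVD least-squares solution of ``A x = b``.

    Retains singular triplets with ``sigma_i >= rel_threshold * sigma_max``
    (exactly-zero singular values are always discarded).
    """
    x, _ = _TSVD(A).solve(b, rel_threshold)
    return x


def reconstruct_conventional(
    S: SensitivityMatrix, data: VoltageVector, rel_threshold: float
) -> ReconstructionResult:
    """Full-domain TSVD reconstruction of the linearized system."""
    x, rank = _TSVD(S.matrix).solve(data.values, rel_threshold)
    return ReconstructionResult(
        image=x, threshold=rel_threshold, rank=rank, method="conventional", grid=S.grid
    )


def reconstruct_local(
    F: ROIFilter, S: SensitivityMatrix, data: VoltageVector, rel_threshold: float
) -> ReconstructionResult:
    """ROI-filtered reconstruction: solve ``(Phi^T S_D) x_D = Phi^T dV``.

    The in-ROI estimate is embedded into the full grid with zeros outside.
    """
    Sd, _ = partition_columns(S)
    if F.n_roi != Sd.shape[1]:
        raise ReconstructionError("filter and sensitivity matrix disagree on R")
    _, fV = apply_filter(F, data=data)
    xd, rank = _TSVD(F.matrix.T @ Sd).solve(fV, rel_threshold)
    image = np.zeros(S.grid.n_pixels)
    image[: S.grid.n_roi] = xd
    return ReconstructionResult(
        image=image, threshold=rel_threshold, rank=rank, method="local", grid=S.grid
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def contrast(
    result: ReconstructionResult,
    anomaly_pixels: np.ndarray,
    background_pixels: np.ndarray,
) -> float:
    """Mean image value over the anomaly pixels minus the background mean."""
    a = np.asarray(anomaly_pixels, dtype=int)
    b = np.asarray(background_pixels, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ReconstructionError("anomaly and background pixel sets must be nonempty")
    if np.intersect1d(a, b).size:
        raise ReconstructionError("anomaly and background pixel sets overlap")
    return float(result.image[a].mean() - result.image[b].mean())


def contrast_sets(
    grid: PixelGrid, centers: Sequence[Sequence[float]], diameter: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Anomaly footprint and background pixel sets for contrast evaluation.

    The anomaly set is the union of the true disk footprints; the
    background is the complement of their two-times-dilated footprints.
    """
    anomaly: List[np.ndarray] = []
    dilated: List[np.ndarray] = []
    for c in centers:
        anomaly.append(grid.pixels_in_disk(c, diameter / 2))
        dilated.append(grid.pixels_in_disk(c, diameter))
    a = np.unique(np.concatenate(anomaly))
    d = np.unique(np.concatenate(dilated))
    b = np.setdiff1d(np.arange(grid.n_pixels), d)
    if a.size == 0:
        raise ReconstructionError("no pixel centre falls inside the anomaly footprint")
    return a, b


@dataclass(frozen=True)
class ThresholdSearchResult:
    threshold: float
    contrast: float
    rank: int
    converged: bool
    note: str = ""


def threshold_search(
    A: np.ndarray,
    b: np.ndarray,
    target_contrast: float,
    anomaly_pixels: np.ndarray,
    background_pixels: np.ndarray,
    tolerance: float = 0.02,
    max_iter: int = 60,
) -> ThresholdSearchResult:
    """Bisect the relative truncation level to a target image contrast.

    The solution of ``A x = b`` is treated as a pixel image indexed like
    the supplied pixel sets.  The search brackets on [0, 1] and bisects
    until ``|contrast - target| <= tolerance * |target|``; if the target is
    not bracketed (or the data are degenerate) the closest evaluated
    threshold is returned with ``converged=False``.
    """
    svd = _TSVD(A)
    anomaly_pixels = np.asarray(anomaly_pixels, dtype=int)
    background_pixels = np.asarray(background_pixels, dtype=int)

    def eval_at(tau: float) -> Tuple[float, int]:
        x, rank = svd.solve(b, tau)
        return float(x[anomaly_pixels].mean() - x[background_pixels].mean()), rank

    tol = abs(tolerance * target_contrast)
    evals: Dict[float, Tuple[float, int]] = {}

    def f(tau: float) -> float:
        if tau not in evals:
            evals[tau] = eval_at(tau)
        return evals[tau][0]

    if target_contrast == 0.0 and not np.any(b):
        return ThresholdSearchResult(0.0, 0.0, svd.shape[0], False, "degenerate zero-data problem")

    lo, hi = 0.0, 1.0
    c_lo, c_hi = f(lo), f(hi)
    if not (min(c_lo, c_hi) - tol <= target_contrast <= max(c_lo, c_hi) + tol):
        best = min(evals, key=lambda t: abs(evals[t][0] - target_contrast))
        return ThresholdSearchResult(
            best, evals[best][0], evals[best][1], False, "target contrast not bracketed"
        )
    increasing = c_hi > c_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c_mid = f(mid)
        if abs(c_mid - target_contrast) <= tol:
            return ThresholdSearchResult(mid, c_mid, evals[mid][1], True)
        if (c_mid < target_contrast) == increasing:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    best = min(evals, key=lambda t: abs(evals[t][0] - target_contrast))
    return ThresholdSearchResult(
        best, evals[best][0], evals[best][1], False, "bisection did not meet tolerance"
    )


def local_maxima(result: ReconstructionResult, n_peaks: int, sign: str = "auto") -> np.ndarray:
    """Positions of the strongest local extrema of the image.

    With ``sign="auto"`` the dominant polarity of the image decides whether
    peaks (conductivity increase) or troughs (decrease) are sought;
    ``"positive"``/``"negative"`` force it.  The image is smoothed with a
    3x3 mean filter (outside-disk pixels held at zero), then strict
    8-neighbour maxima are ranked by value; ties break deterministically by
    pixel index.  Returns an (n, 2) array of pixel-centre coordinates,
    n <= n_peaks.
    """
    img = result.grid.to_image(result.image, fill=0.0)
    if sign == "auto":
        flip = result.image[np.argmax(np.abs(result.image))] < 0
    elif sign in ("positive", "negative"):
        flip = sign == "negative"
    else:
        raise ReconstructionError("sign must be 'auto', 'positive' or 'negative'")
    if flip:
        img = -img
    sm = uniform_filter(img, size=3, mode="constant", cval=0.0)
    P = result.grid.shape[0]
    peaks = []
    for iy in range(P):
        for ix in range(P):
            v = sm[iy, ix]
            if v <= 0:
                continue
            y0, x0 = max(iy - 1, 0), max(ix - 1, 0)
            neigh = sm[y0 : iy + 2, x0 : ix + 2]
            if v < neigh.max():
                continue
            # flat plateaus yield one peak: the smallest pixel index wins
            ties = [
                (y0 + dy) * P + (x0 + dx)
                for dy, dx in zip(*np.nonzero(neigh == v))
            ]
            if min(ties) == iy * P + ix:
                peaks.append((v, iy * P + ix, iy, ix))
    peaks.sort(key=lambda p: (-p[0], p[1]))
    out = []
    R = result.grid.domain.radius
    size = result.grid.size
    for v, _, iy, ix in peaks[:n_peaks]:
        out.append((-R + (ix + 0.5) * size, R - (iy + 0.5) * size))
    return np.asarray(out).reshape(-1, 2)


def localization_error(
    result: ReconstructionResult,
    true_centers: Sequence[Sequence[float]],
    sign: str = "auto",
) -> np.ndarray:
    """Distance of each true anomaly centre to its matched local extremum.

    The strongest ``len(true_centers)`` extrema are matched greedily
    (smallest pairwise distance first); centres left without a match get
    NaN.
    """
    centers = np.asarray(true_centers, dtype=float)
    peaks = local_maxima(result, len(centers), sign=sign)
    errors = np.full(len(centers), np.nan)
    if peaks.size == 0:
        return errors
    dists = np.hypot(
        centers[:, None, 0] - peaks[None, :, 0], centers[:, None, 1] - peaks[None, :, 1]
    )
    used_c: set = set()
    used_p: set = set()
    order = np.dstack(np.unravel_index(np.argsort(dists, axis=None), dists.shape))[0]
    for ci, pi in order:
        if ci in used_c or pi in used_p:
            continue
        errors[ci] = dists[ci, pi]
        used_c.add(int(ci))
        used_p.add(int(pi))
    return errors


def outside_influence(
    delta_v_ref: VoltageVector,
    delta_v_cases: Dict[str, VoltageVector],
    F: ROIFilter,
) -> pd.DataFrame:
    """Influence of out-of-ROI anomalies on raw vs filtered data.

    For each case the table reports ``||dV_i - dV_ref||`` and
    ``||Phi^T (dV_i - dV_ref)||`` together with the same quantities
    normalized by the reference norms — the filtered ratio being smaller
    means the filter shields the localized system from the outside anomaly.
    """
    ref = delta_v_ref.values
    fref = F.matrix.T @ ref
    n_ref, n_fref = np.linalg.norm(ref), np.linalg.norm(fref)
    rows = []
    for name, dv in delta_v_cases.items():
        if dv.values.shape != ref.shape:
            raise ReconstructionError(f"case {name!r} has mismatched data length")
        diff = dv.values - ref
        fdiff = F.matrix.T @ diff
        rows.append(
            {
                "case": name,
                "raw_norm": float(np.linalg.norm(diff)),
                "filtered_norm": float(np.linalg.norm(fdiff)),
                "raw_ratio": float(np.linalg.norm(diff) / n_ref),
                "filtered_ratio": float(np.linalg.norm(fdiff) / n_fref),
            }
        )
    return pd.DataFrame(rows).set_index("case")
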