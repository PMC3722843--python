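"""Circular-domain geometry for 2-D EIT with an optional internal electrode.

The imaging domain is a disk (a 2-D cross-section of a cylindrical tank)
carrying ``E`` surface electrodes on its boundary and, optionally, a single
internal electrode — a thin conducting probe modelled as a small circular
hole in the mesh.  This module provides

* electrode layouts: equidistant rings and two-density "clustered" rings
  with a denser sector of surface electrodes facing the region of interest;
* the region of interest (ROI): a disk centred on the internal electrode
  whose radius is 5/6 of the distance to the nearest surface electrode;
* a conforming triangular finite-element mesh of the disk, with marked
  boundary-edge chains for every electrode and a hole for the internal
  electrode;
* a square pixel lattice clipped to the disk on which conductivity changes
  are reconstructed, with an ROI-first pixel ordering.

All coordinates are Cartesian with the origin at the disk centre; lengths
are in whatever unit the scenario uses (normalized or metres).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import Delaunay

TWO_PI = 2.0 * math.pi

#: Internal-electrode radius as a fraction of the domain radius.  A 0.25 cm
#: diameter probe in a 14 cm diameter tank gives 0.125/7.
INTERNAL_RADIUS_FRACTION = 0.125 / 7.0

#: Factor of the internal-to-surface electrode distance defining the ROI.
ROI_RADIUS_FACTOR = 5.0 / 6.0


class GeometryError(ValueError):
    """Invalid electrode layout, infeasible mesh, or degenerate ROI/grid."""


@dataclass(frozen=True)
class DiskDomain:
    """Circular imaging domain centred at the origin.

    Parameters
    ----------
    radius : float
        Domain radius, strictly positive.  The centre is fixed at (0, 0).
    """

    radius: float = 1.0

    def __post_init__(self) -> None:
        if not (self.radius > 0.0 and math.isfinite(self.radius)):
            raise GeometryError(f"domain radius must be positive, got {self.radius}")

    def contains(self, point: Sequence[float], margin: float = 0.0) -> bool:
        x, y = float(point[0]), float(point[1])
        return math.hypot(x, y) < self.radius - margin


@dataclass(frozen=True)
class BoundaryElectrode:
    """Surface electrode occupying an arc of the domain boundary.

    ``center_angle`` is in radians; ``arc_width`` is the angular extent of
    the electrode (so the metal arc length is ``arc_width * radius``).
    Indices run 1..E around the ring.
    """

    center_angle: float
    arc_width: float
    index: int

    def __post_init__(self) -> None:
        if not self.arc_width > 0.0:
            raise GeometryError("electrode arc_width must be positive")
        if self.index < 1:
            raise GeometryError("electrode indices are 1-based")

    def center_point(self, domain: DiskDomain) -> np.ndarray:
        return domain.radius * np.array(
            [math.cos(self.center_angle), math.sin(self.center_angle)]
        )


@dataclass(frozen=True)
class InternalElectrode:
    """Internal (probe) electrode: a small disk strictly inside the domain."""

    position: Tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0.0:
            raise GeometryError("internal electrode radius must be positive")

    @property
    def azimuth(self) -> float:
        return math.atan2(self.position[1], self.position[0])


@dataclass(frozen=True)
class ROIRegion:
    """Disk-shaped region of interest, strictly inside the domain."""

    center: Tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0.0:
            raise GeometryError("ROI radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean point-in-ROI test for an (n, 2) array of points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.hypot(p[:, 0] - self.center[0], p[:, 1] - self.center[1])
        return d < self.radius


@dataclass(frozen=True)
class ElectrodeLayout:
    """Complete electrode configuration on a disk domain.

    ``boundary`` electrodes are sorted by angle and indexed 1..E; the
    optional ``internal`` electrode carries index E+1 wherever electrode
    indices are used (protocols, mesh markers).
    """

    domain: DiskDomain
    boundary: Tuple[BoundaryElectrode, ...]
    internal: Optional[InternalElectrode] = None
    mode: str = "equidistant"

    def __post_init__(self) -> None:
        E = len(self.boundary)
        if E < 4:
            raise GeometryError(f"need at least 4 boundary electrodes, got {E}")
        angles = [e.center_angle for e in self.boundary]
        if any(a2 <= a1 for a1, a2 in zip(angles, angles[1:])):
            raise GeometryError("boundary electrodes must be sorted by angle")
        # no-overlap check, including the wrap-around gap
        for i in range(E):
            a = self.boundary[i]
            b = self.boundary[(i + 1) % E]
            gap = (b.center_angle - a.center_angle) % TWO_PI
            if gap - 0.5 * (a.arc_width + b.arc_width) < -1e-12:
                raise GeometryError(
                    f"electrodes {a.index} and {b.index} overlap "
                    f"(gap {gap:.4f} rad, widths {a.arc_width:.4f}/{b.arc_width:.4f})"
                )
        if self.internal is not None:
            r = math.hypot(*self.internal.position) + self.internal.radius
            if r >= self.domain.radius:
                raise GeometryError("internal electrode must lie strictly inside the domain")

    @property
    def n_boundary(self) -> int:
        return len(self.boundary)

    @property
    def internal_index(self) -> int:
        """Electrode index used for the internal electrode (E + 1)."""
        if self.internal is None:
            raise GeometryError("layout has no internal electrode")
        return self.n_boundary + 1


def make_layout(
    E: int,
    mode: str = "equidistant",
    domain: Optional[DiskDomain] = None,
    internal_position: Optional[Sequence[float]] = None,
    cluster_fraction: float = 0.5,
    cluster_sector: float = TWO_PI / 3.0,
    internal_radius: Optional[float] = None,
    arc_width: Optional[float] = None,
) -> ElectrodeLayout:
    """Build an electrode layout on the disk.

    Parameters
    ----------
    E : int
        Number of surface electrodes (>= 4).
    mode : {"equidistant", "clustered"}
        ``equidistant`` places centres at angles ``2*pi*j/E``.  ``clustered``
        places ``ceil(cluster_fraction * E)`` electrodes uniformly over a
        sector of width ``cluster_sector`` centred on the internal
        electrode's azimuth, and the remainder uniformly over the
        complementary sector (denser electrodes facing the ROI).
    internal_position : pair of float, optional
        Position of the internal electrode.  Required for ``clustered``.
    internal_radius : float, optional
        Radius of the internal electrode hole.  Defaults to
        ``INTERNAL_RADIUS_FRACTION * domain.radius``.
    arc_width : float, optional
        Angular width of every electrode.  Defaults to half the minimal
        centre-to-centre angular gap, which guarantees no overlap.
    """
    if E < 4:
        raise GeometryError(f"need at least 4 boundary electrodes, got {E}")
    if mode not in ("equidistant", "clustered"):
        raise GeometryError(f"unknown layout mode {mode!r}")
    domain = domain or DiskDomain(1.0)

    internal = None
    if internal_position is not None:
        r_int = internal_radius if internal_radius is not None else (
            INTERNAL_RADIUS_FRACTION * domain.radius
        )
        internal = InternalElectrode(
            (float(internal_position[0]), float(internal_position[1])), r_int
        )

    if mode == "equidistant":
        centers = [TWO_PI * j / E for j in range(E)]
    else:
        if internal is None:
            raise GeometryError("clustered layouts require an internal electrode")
        if not (0.0 < cluster_fraction < 1.0):
            raise GeometryError("cluster_fraction must lie in (0, 1)")
        if not (0.0 < cluster_sector < TWO_PI):
            raise GeometryError("cluster_sector must lie in (0, 2*pi)")
        theta0 = internal.azimuth
        n_in = math.ceil(cluster_fraction * E)
        n_out = E - n_in
        if n_out < 1:
            raise GeometryError("cluster_fraction leaves no electrode outside the sector")
        centers = [
            theta0 - cluster_sector / 2 + cluster_sector * (i + 0.5) / n_in
            for i in range(n_in)
        ]
        comp = TWO_PI - cluster_sector
        centers += [
            theta0 + cluster_sector / 2 + comp * (i + 0.5) / n_out for i in range(n_out)
        ]
        centers = sorted(a % TWO_PI for a in centers)

    gaps = [(centers[(j + 1) % E] - centers[j]) % TWO_PI for j in range(E)]
    min_gap = min(gaps)
    width = arc_width if arc_width is not None else 0.5 * min_gap
    if width >= min_gap - 1e-12:
        raise GeometryError(
            f"arc width {width:.4f} rad does not fit the minimal electrode gap "
            f"{min_gap:.4f} rad"
        )
    electrodes = tuple(
        BoundaryElectrode(center_angle=a, arc_width=width, index=j + 1)
        for j, a in enumerate(centers)
    )
    return ElectrodeLayout(domain=domain, boundary=electrodes, internal=internal, mode=mode)


def compute_roi(layout: ElectrodeLayout) -> ROIRegion:
    """ROI disk centred on the internal electrode.

    The radius is 5/6 of the Euclidean distance from the internal electrode
    position to the nearest surface electrode centre point on the boundary
    circle.  With that factor the ROI never reaches the domain boundary.
    """
    if layout.internal is None:
        raise GeometryError("ROI is undefined without an internal electrode")
    p = np.asarray(layout.internal.position, dtype=float)
    dists = [
        float(np.hypot(*(e.center_point(layout.domain) - p))) for e in layout.boundary
    ]
    return ROIRegion(center=tuple(p), radius=ROI_RADIUS_FACTOR * min(dists))


# ---------------------------------------------------------------------------
# Pixel grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PixelGrid:
    """Square pixel lattice clipped to the disk, in ROI-first order.

    Attributes
    ----------
    centers : (N, 2) ndarray
        Pixel centres in the canonical ordering: pixels inside the ROI come
        first (``n_roi`` of them), each group in row-major lattice order.
    size : float
        Pixel side length.
    shape : (P, P)
        Underlying lattice shape (``pixels_per_diameter`` per side).
    rowmajor : (N,) ndarray of int
        Row-major lattice index ``iy * P + ix`` of each canonical pixel;
        rows run from the top of the disk (largest y) downwards.
    in_roi : (N,) ndarray of bool
        True for the first ``n_roi`` entries when an ROI is attached.
    """

    centers: np.ndarray
    size: float
    shape: Tuple[int, int]
    rowmajor: np.ndarray
    in_roi: np.ndarray
    domain: DiskDomain
    roi: Optional[ROIRegion] = None

    @property
    def n_pixels(self) -> int:
        return self.centers.shape[0]

    @property
    def n_roi(self) -> int:
        return int(self.in_roi.sum())

    def lattice_of_points(self, points: np.ndarray) -> np.ndarray:
        """Canonical pixel index of each point (-1 if outside every pixel)."""
        P = self.shape[0]
        R = self.domain.radius
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ix = np.floor((pts[:, 0] + R) / self.size).astype(int)
        iy = np.floor((R - pts[:, 1]) / self.size).astype(int)
        ok = (ix >= 0) & (ix < P) & (iy >= 0) & (iy < P)
        lut = np.full(P * P, -1, dtype=int)
        lut[self.rowmajor] = np.arange(self.n_pixels)
        out = np.full(len(pts), -1, dtype=int)
        out[ok] = lut[iy[ok] * P + ix[ok]]
        return out

    def to_image(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter canonical-order pixel values onto the (P, P) lattice."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_pixels,):
            raise ValueError(f"expected {self.n_pixels} pixel values")
        P = self.shape[0]
        img = np.full(P * P, fill, dtype=float)
        img[self.rowmajor] = values
        return img.reshape(P, P)

    def pixels_in_disk(self, center: Sequence[float], radius: float) -> np.ndarray:
        """Canonical indices of pixels whose centre lies inside a disk."""
        d = np.hypot(self.centers[:, 0] - center[0], self.centers[:, 1] - center[1])
        return np.nonzero(d < radius)[0]


def build_pixel_grid(
    domain: DiskDomain,
    pixels_per_diameter: int,
    roi: Optional[ROIRegion] = None,
) -> PixelGrid:
    """Regular square lattice clipped to the disk.

    Pixels whose centre falls strictly inside the domain are kept, ordered
    row-major (top row first); if ``roi`` is given, pixels whose centre lies
    inside the ROI disk are re-indexed first, preserving row-major order
    within each group.
    """
    if pixels_per_diameter < 8:
        raise GeometryError("pixels_per_diameter must be at least 8")
    P = int(pixels_per_diameter)
    R = domain.radius
    size = 2.0 * R / P
    ix, iy = np.meshgrid(np.arange(P), np.arange(P))
    x = -R + (ix + 0.5) * size
    y = R - (iy + 0.5) * size
    centers = np.column_stack([x.ravel(), y.ravel()])
    keep = np.hypot(centers[:, 0], centers[:, 1]) < R
    centers = centers[keep]
    rowmajor = np.nonzero(keep)[0]

    if roi is None:
        in_roi = np.zeros(len(centers), dtype=bool)
        order = np.arange(len(centers))
    else:
        mask = roi.contains(centers)
        if not mask.any():
            raise GeometryError("ROI contains no pixel centre; refine the grid")
        order = np.argsort(~mask, kind="stable")
        in_roi = mask[order]
    return PixelGrid(
        centers=centers[order],
        size=size,
        shape=(P, P),
        rowmajor=rowmajor[order],
        in_roi=in_roi,
        domain=domain,
        roi=roi,
    )


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriangleMesh:
    """Conforming triangulation of the disk with marked electrode edges.

    ``electrode_edges`` maps electrode index (1..E for surface electrodes,
    E+1 for the internal electrode) to an (n_edges, 2) array of node-index
    pairs tracing the electrode's boundary chain.  Triangles are positively
    oriented (counter-clockwise).
    """

    nodes: np.ndarray
    triangles: np.ndarray
    electrode_edges: Dict[int, np.ndarray]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def triangle_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def electrode_edge_lengths(self, index: int) -> np.ndarray:
        edges = self.electrode_edges[index]
        d = self.nodes[edges[:, 1]] - self.nodes[edges[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])


def _boundary_ring(layout: ElectrodeLayout, h: float, refine: float):
    """Boundary node angles conforming to electrode arc endpoints.

    Returns the angle list (walking the circle once, no duplicate at the
    seam) and, per electrode, the list of its node indices along the arc.
    """
    R = layout.domain.radius
    elecs = sorted(layout.boundary, key=lambda e: e.center_angle)
    E = len(elecs)
    segments = []  # (a0, a1, n_sub, marker)
    for i, e in enumerate(elecs):
        a0 = e.center_angle - e.arc_width / 2
        a1 = e.center_angle + e.arc_width / 2
        n_e = max(2, math.ceil(e.arc_width * R / (h * refine)))
        segments.append((a0, a1, n_e, e.index))
        nxt = elecs[(i + 1) % E]
        g1 = nxt.center_angle - nxt.arc_width / 2 + (TWO_PI if i == E - 1 else 0.0)
        if g1 - a1 > 1e-9:
            n_g = max(1, math.ceil((g1 - a1) * R / h))
            segments.append((a1, g1, n_g, 0))

    angles: list[float] = []
    marker_nodes: Dict[int, list[int]] = {}
    for a0, a1, n, marker in segments:
        start = len(angles)
        angles.extend(a0 + (a1 - a0) * t / n for t in range(n))
        if marker:
            marker_nodes[marker] = list(range(start, start + n + 1))
    nb = len(angles)
    for m in marker_nodes:
        marker_nodes[m] = [i % nb for i in marker_nodes[m]]
    return np.asarray(angles), marker_nodes


def build_mesh(
    layout: ElectrodeLayout,
    target_edge_length: float,
    electrode_refine: float = 0.5,
    hole_segments: int = 16,
) -> TriangleMesh:
    """Triangulate the disk, conforming to electrodes and the probe hole.

    Node placement is structured (boundary ring conforming to electrode arc
    endpoints, graded rings around the internal-electrode hole, concentric
    interior rings at the target spacing with a small deterministic angular
    jitter to avoid degenerate co-circular Delaunay configurations); the
    triangulation itself is a scipy Delaunay of that point set with the
    hole carved out afterwards.

    Raises
    ------
    GeometryError
        If the requested edge length cannot resolve the geometry (e.g. the
        hole boundary does not come out as a closed chain of mesh edges).
    """
    h = float(target_edge_length)
    R = layout.domain.radius
    if not (0 < h < R):
        raise GeometryError("target_edge_length must be in (0, domain radius)")

    angles, marker_nodes = _boundary_ring(layout, h, electrode_refine)
    bpoints = R * np.column_stack([np.cos(angles), np.sin(angles)])
    points = [bpoints]
    n_total = len(bpoints)

    hole_chain = None
    hole_center = None
    hole_radius = 0.0
    r_exclude = 0.0
    if layout.internal is not None:
        c = np.asarray(layout.internal.position, dtype=float)
        rh = layout.internal.radius
        hole_center, hole_radius = c, rh
        n_h = max(int(hole_segments), 8)
        th = TWO_PI * np.arange(n_h) / n_h
        ring = c + rh * np.column_stack([np.cos(th), np.sin(th)])
        start = n_total
        hole_chain = np.column_stack(
            [start + np.arange(n_h), start + (np.arange(n_h) + 1) % n_h]
        )
        points.append(ring)
        n_total += n_h
        # graded rings: circumferential spacing grows until it reaches ~h
        r = rh
        k = 0
        while True:
            s = TWO_PI * r / n_h
            if s >= 0.9 * h:
                break
            r = r + s
            if math.hypot(*c) + r >= R - 0.8 * h:
                break
            k += 1
            phase = 0.5 * (k % 2) * TWO_PI / n_h
            th = phase + TWO_PI * np.arange(n_h) / n_h
            points.append(c + r * np.column_stack([np.cos(th), np.sin(th)]))
            n_total += n_h
        r_exclude = r + 0.45 * h

    # interior: concentric rings about the origin at spacing h
    rng = np.random.default_rng(20130708)  # fixed: meshes are deterministic
    interior = [np.zeros((1, 2))]
    m = 1
    while m * h < R - 0.8 * h:
        r_m = m * h
        n_m = max(6, int(round(TWO_PI * m)))
        phase = 0.5 * (m % 2) * TWO_PI / n_m
        jitter = 0.03 * (TWO_PI / n_m) * (rng.random(n_m) - 0.5)
        th = phase + TWO_PI * np.arange(n_m) / n_m + jitter
        interior.append(r_m * np.column_stack([np.cos(th), np.sin(th)]))
        m += 1
    ipts = np.vstack(interior)
    if hole_center is not None:
        d = np.hypot(ipts[:, 0] - hole_center[0], ipts[:, 1] - hole_center[1])
        ipts = ipts[d > r_exclude]
    points.append(ipts)
    pts = np.vstack(points)

    tri = Delaunay(pts)
    simplices = tri.simplices.copy()
    if hole_center is not None:
        cen = pts[simplices].mean(axis=1)
        d = np.hypot(cen[:, 0] - hole_center[0], cen[:, 1] - hole_center[1])
        simplices = simplices[d > hole_radius]

    # enforce CCW orientation, drop exactly degenerate slivers
    p = pts[simplices]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = area2 < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]
    simplices = simplices[np.abs(area2) > 1e-14 * R * R]

    electrode_edges: Dict[int, np.ndarray] = {}
    for idx, nodes_list in marker_nodes.items():
        pairs = np.column_stack([nodes_list[:-1], nodes_list[1:]])
        electrode_edges[idx] = pairs
    if hole_chain is not None:
        electrode_edges[layout.internal_index] = hole_chain

    # conformity check: every marked edge must be an edge of the kept mesh
    edge_set = set()
    for t in simplices:
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            edge_set.add((min(a, b), max(a, b)))
    for idx, pairs in electrode_edges.items():
        for a, b in pairs:
            if (min(a, b), max(a, b)) not in edge_set:
                raise GeometryError(
                    f"mesh does not conform to electrode {idx}; "
                    "decrease target_edge_length"
                )
        if len(pairs) < 2:
            raise GeometryError(f"electrode {idx} has fewer than 2 edges")

    return TriangleMesh(nodes=pts, triangles=simplices, electrode_edges=electrode_edges)
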