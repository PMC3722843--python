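"""Plain-text file formats for meshes, data vectors, matrices and images.

All formats are deterministic, human-readable and round-trip exactly at
``repr`` precision:

* mesh: ``nodes N elements M`` header, N ``x y`` lines, M 0-based ``i j k``
  lines, then per-electrode blocks ``electrode <idx> <edge-count>``
  followed by node-pair lines;
* voltage vector: CSV with header ``drive_pos,drive_neg,meas_pos,meas_neg,
  value`` in protocol order (the internal electrode is index E+1);
* matrix container: comment header lines carrying the shape, the pixel
  permutation (row-major lattice indices of the canonical columns) and,
  for filters, alpha — followed by CSV rows;
* image: comment header with the lattice shape, pixel size and domain
  radius, then the full P x P lattice (NaN outside the disk).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from .forward import DrivePattern, Protocol, VoltageVector
from .geometry import TriangleMesh
from .reconstruction import ReconstructionResult


def write_mesh(mesh: TriangleMesh, path) -> None:
    lines = [f"nodes {mesh.n_nodes} elements {mesh.n_triangles}"]
    lines += [f"{float(x)!r} {float(y)!r}" for x, y in mesh.nodes]
    lines += [f"{i} {j} {k}" for i, j, k in mesh.triangles]
    for idx in sorted(mesh.electrode_edges):
        edges = mesh.electrode_edges[idx]
        lines.append(f"electrode {idx} {len(edges)}")
        lines += [f"{a} {b}" for a, b in edges]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh(path) -> TriangleMesh:
    tokens = Path(path).read_text().split("\n")
    head = tokens[0].split()
    if head[0] != "nodes" or head[2] != "elements":
        raise ValueError("not a mesh file")
    n, m = int(head[1]), int(head[3])
    nodes = np.array([[float(v) for v in line.split()] for line in tokens[1 : 1 + n]])
    tris = np.array(
        [[int(v) for v in line.split()] for line in tokens[1 + n : 1 + n + m]], dtype=int
    )
    pos = 1 + n + m
    edges: Dict[int, np.ndarray] = {}
    while pos < len(tokens) and tokens[pos].strip():
        _, idx, count = tokens[pos].split()
        idx, count = int(idx), int(count)
        block = tokens[pos + 1 : pos + 1 + count]
        edges[idx] = np.array([[int(v) for v in line.split()] for line in block], dtype=int)
        pos += 1 + count
    return TriangleMesh(nodes=nodes, triangles=tris, electrode_edges=edges)


def write_voltage(data: VoltageVector, path) -> None:
    lines = ["drive_pos,drive_neg,meas_pos,meas_neg,value"]
    K = data.protocol.n_measurements
    for j, drive in enumerate(data.protocol.drives):
        for k, (mp, mn) in enumerate(data.protocol.measurements):
            lines.append(
                f"{drive.source},{drive.sink},{mp},{mn},{float(data.values[j * K + k])!r}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_voltage(path, scheme: str = "file") -> VoltageVector:
    rows = Path(path).read_text().strip().split("\n")[1:]
    parsed = [r.split(",") for r in rows]
    drives: list = []
    meas: list = []
    for dp, dn, mp, mn, _ in parsed:
        pair = DrivePattern(int(dp), int(dn))
        if not drives or drives[-1] != pair:
            drives.append(pair)
    K = len(parsed) // len(drives)
    meas = [(int(r[2]), int(r[3])) for r in parsed[:K]]
    protocol = Protocol(tuple(drives), tuple(meas), scheme)
    values = np.array([float(r[4]) for r in parsed])
    return VoltageVector(values, protocol)


def write_matrix(
    matrix: np.ndarray,
    path,
    pixel_permutation: Optional[np.ndarray] = None,
    alpha: Optional[float] = None,
) -> None:
    matrix = np.asarray(matrix, dtype=float)
    lines = [f"# matrix rows {matrix.shape[0]} cols {matrix.shape[1]}"]
    if pixel_permutation is not None:
        lines.append("# pixels " + " ".join(str(int(i)) for i in pixel_permutation))
    if alpha is not None:
        lines.append(f"# alpha {float(alpha)!r}")
    lines += [",".join(repr(float(v)) for v in row) for row in matrix]
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix(path) -> Tuple[np.ndarray, Optional[np.ndarray], Optional[float]]:
    lines = Path(path).read_text().strip().split("\n")
    perm = None
    alpha = None
    pos = 0
    while lines[pos].startswith("#"):
        parts = lines[pos].split()
        if parts[1] == "pixels":
            perm = np.array([int(v) for v in parts[2:]], dtype=int)
        elif parts[1] == "alpha":
            alpha = float(parts[2])
        pos += 1
    matrix = np.array([[float(v) for v in line.split(",")] for line in lines[pos:]])
    return matrix, perm, alpha


def write_image(result: ReconstructionResult, path) -> None:
    grid = result.grid
    img = result.as_image()
    lines = [
        f"# grid {grid.shape[0]} {grid.shape[1]} {float(grid.size)!r} {float(grid.domain.radius)!r}",
        f"# method {result.method} threshold {result.threshold!r} rank {result.rank}",
    ]
    lines += [",".join(repr(float(v)) for v in row) for row in img]
    Path(path).write_text("\n".join(lines) + "\n")
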