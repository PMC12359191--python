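"""Labeled tetrahedral meshes: volumes, barycentric point sampling, node/ele I/O.

Sampling follows the two-stage procedure used for dump-file sources: a
tetrahedron is selected by acceptance/rejection against volumes normalized by
the set maximum, then a point is placed inside it with barycentric weights
``delta_i = u_i / sum(u)`` from four uniform draws.  Tetrahedralization
itself is out of scope — this module only consumes and emits the format —
but a structured box decomposition is provided for building test fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def tet_volume(A, B, C, D) -> float:
    """|det([B-A, C-A, D-A])| / 6 — orientation-free tetrahedron volume."""
    A, B, C, D = (np.asarray(x, float) for x in (A, B, C, D))
    return abs(float(np.linalg.det(np.stack([B - A, C - A, D - A])))) / 6.0


@dataclass
class TetMesh:
    nodes: np.ndarray  # (n, 3)
    elements: np.ndarray  # (m, 4) node indices (0-based internally)
    labels: np.ndarray  # (m,) int region labels
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, float).reshape(-1, 3)
        self.elements = np.asarray(self.elements, int).reshape(-1, 4)
        self.labels = np.asarray(self.labels, int).reshape(-1)
        if len(self.labels) != len(self.elements):
            raise ValueError("one label per element required")
        if self.elements.size and (self.elements.min() < 0 or self.elements.max() >= len(self.nodes)):
            raise ValueError("element references a missing node")

    def volumes(self) -> np.ndarray:
        t = self.nodes[self.elements]
        return np.abs(np.linalg.det(t[:, 1:] - t[:, :1])) / 6.0

    def region_volumes(self) -> dict[int, float]:
        v = self.volumes()
        return {int(lbl): float(v[self.labels == lbl].sum()) for lbl in np.unique(self.labels)}

    def total_volume(self) -> float:
        return float(self.volumes().sum())

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.nodes.min(axis=0), self.nodes.max(axis=0)

    def label_of(self, name_or_label) -> int:
        if isinstance(name_or_label, str):
            for lbl, name in self.region_names.items():
                if name == name_or_label:
                    return lbl
            raise KeyError(f"unknown region name {name_or_label!r}")
        return int(name_or_label)


def sample_points(
    mesh: TetMesh,
    region,
    n: int,
    seed: int,
    use_alias: bool = False,
) -> np.ndarray:
    """``n`` uniform random points within a region of the mesh.

    Default tetrahedron selection is acceptance/rejection with thresholds
    V_i / V_max (fidelity to the reference procedure); ``use_alias=True``
    switches to direct volume-weighted categorical sampling (faster, same
    distribution).
    """
    lbl = mesh.label_of(region)
    idx = np.flatnonzero(mesh.labels == lbl)
    if len(idx) == 0:
        raise ValueError(f"region {region!r} has no elements")
    vols = mesh.volumes()[idx]
    if vols.sum() <= 0:
        raise ValueError(f"region {region!r} has zero volume")
    rng = np.random.default_rng(seed)
    if use_alias:
        chosen = rng.choice(idx, size=n, p=vols / vols.sum())
    else:
        thresholds = vols / vols.max()
        chosen = np.empty(n, int)
        got = 0
        while got < n:
            m = max(2 * (n - got), 64)
            cand = rng.integers(0, len(idx), size=m)
            accept = rng.random(m) < thresholds[cand]
            sel = idx[cand[accept]][: n - got]
            chosen[got : got + len(sel)] = sel
            got += len(sel)
    u = rng.random((n, 4))
    u = np.where(u == 0.0, np.nextafter(0.0, 1.0), u)  # open-interval draws
    delta = u / u.sum(axis=1, keepdims=True)
    corners = mesh.nodes[mesh.elements[chosen]]
    return np.einsum("ni,nij->nj", delta, corners)


# ---------------------------------------------------------------------------
# TetGen-dialect .node/.ele files
# ---------------------------------------------------------------------------

def _clean_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if line:
                yield lineno, line.split()


def read_node_ele(node_path, ele_path) -> TetMesh:
    """Read a node/element file pair; 1-based or 0-based indices auto-detected."""
    lines = list(_clean_lines(node_path))
    lineno, header = lines[0]
    n_nodes = int(header[0])
    if len(lines) - 1 != n_nodes:
        raise ValueError(f"{node_path}:{lineno}: header declares {n_nodes} nodes, found {len(lines) - 1}")
    ids = np.empty(n_nodes, int)
    coords = np.empty((n_nodes, 3))
    for k, (lineno, parts) in enumerate(lines[1:]):
        if len(parts) < 4:
            raise ValueError(f"{node_path}:{lineno}: expected 'id x y z'")
        ids[k] = int(parts[0])
        coords[k] = [float(x) for x in parts[1:4]]
    base = ids.min()
    if base not in (0, 1):
        raise ValueError(f"{node_path}: node ids must start at 0 or 1, got {base}")
    id_to_row = {int(i): k for k, i in enumerate(ids)}

    lines = list(_clean_lines(ele_path))
    lineno, header = lines[0]
    n_ele = int(header[0])
    has_attr = len(header) >= 3 and int(header[2]) > 0
    if len(lines) - 1 != n_ele:
        raise ValueError(f"{ele_path}:{lineno}: header declares {n_ele} elements, found {len(lines) - 1}")
    elements = np.empty((n_ele, 4), int)
    labels = np.zeros(n_ele, int)
    for k, (lineno, parts) in enumerate(lines[1:]):
        need = 5 + (1 if has_attr else 0)
        if len(parts) < need:
            raise ValueError(f"{ele_path}:{lineno}: expected {need} columns")
        for j, tok in enumerate(parts[1:5]):
            nid = int(tok)
            if nid not in id_to_row:
                raise ValueError(f"{ele_path}:{lineno}: reference to missing node {nid}")
            elements[k, j] = id_to_row[nid]
        if has_attr:
            labels[k] = int(float(parts[5]))
    return TetMesh(coords, elements, labels)


def write_node_ele(mesh: TetMesh, node_path, ele_path, one_based: bool = True) -> None:
    off = 1 if one_based else 0
    with open(node_path, "w") as fh:
        fh.write(f"{len(mesh.nodes)} 3 0 0\n")
        for i, p in enumerate(mesh.nodes):
            fh.write(f"{i + off} {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
    with open(ele_path, "w") as fh:
        fh.write(f"{len(mesh.elements)} 4 1\n")
        for i, (e, lbl) in enumerate(zip(mesh.elements, mesh.labels)):
            fh.write(f"{i + off} {e[0] + off} {e[1] + off} {e[2] + off} {e[3] + off} {lbl}\n")


def write_points(points: np.ndarray, path) -> None:
    """Whitespace-separated xyz dump of sampled source points."""
    np.savetxt(path, np.atleast_2d(points), fmt="%.9g")


# ---------------------------------------------------------------------------
# structured fixtures
# ---------------------------------------------------------------------------

_CUBE_TETS = np.array(
    [[0, 1, 3, 5], [0, 3, 2, 6], [0, 5, 4, 6], [3, 5, 6, 7], [0, 3, 5, 6]]
)


def box_tet_mesh(lo, hi, divisions=(1, 1, 1), label_fn=None) -> TetMesh:
    """Axis-aligned box split into 5 tets per cell (test/fixture helper).

    ``label_fn(centroids) -> labels`` assigns a region per tetrahedron from
    its centroid; default labels everything 1.
    """
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    nx, ny, nz = divisions
    xs = np.linspace(lo[0], hi[0], nx + 1)
    ys = np.linspace(lo[1], hi[1], ny + 1)
    zs = np.linspace(lo[2], hi[2], nz + 1)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    elements = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corner = [
                    nid(i, j, k), nid(i, j, k + 1), nid(i, j + 1, k), nid(i, j + 1, k + 1),
                    nid(i + 1, j, k), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k), nid(i + 1, j + 1, k + 1),
                ]
                corner = np.asarray(corner)
                # flip parity on odd cells so faces match across neighbors
                tets = _CUBE_TETS if (i + j + k) % 2 == 0 else _CUBE_TETS[:, [0, 2, 1, 3]]
                for t in tets:
                    elements.append(corner[t])
    elements = np.array(elements)
    cent = nodes[elements].mean(axis=1)
    labels = np.ones(len(elements), int) if label_fn is None else np.asarray(label_fn(cent), int)
    return TetMesh(nodes, elements, labels)
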