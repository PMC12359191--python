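"""Synthetic vascular centerline trees.

Trees grow inside an organ boundary by sequential constructive attachment:
random interior terminals are connected to the existing tree at whichever
edge split minimizes the added segment volume (sum of pi r^2 l over the new
segments), with the junction position itself optimized by derivative-free
minimization of the same local volume cost.  Bifurcation radii follow a
radius-power conservation rule (default exponent 3) with equal flow per
terminal, which keeps the power-law residual identically zero at every
junction.  Endpoint triplet matching across trees solves two assignment
problems (arterial->venous, portal->venous).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, minimize

from .boundary import Boundary

log = logging.getLogger(__name__)


@dataclass
class GraphNode:
    id: int
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float).reshape(3)


@dataclass
class GraphEdge:
    id: int
    tail: int  # parent-side node
    head: int  # child-side node
    radius: float
    tree: str = "tree"


@dataclass
class CenterlineGraph:
    nodes: dict[int, GraphNode] = field(default_factory=dict)
    edges: dict[int, GraphEdge] = field(default_factory=dict)
    roots: dict[str, int] = field(default_factory=dict)

    # -- structure ---------------------------------------------------------
    def add_node(self, position) -> int:
        nid = max(self.nodes, default=-1) + 1
        self.nodes[nid] = GraphNode(nid, position)
        return nid

    def add_edge(self, tail: int, head: int, radius: float, tree: str = "tree") -> int:
        if radius <= 0:
            raise ValueError("edge radius must be positive")
        eid = max(self.edges, default=-1) + 1
        self.edges[eid] = GraphEdge(eid, tail, head, radius, tree)
        return eid

    def children(self) -> dict[int, list[GraphEdge]]:
        out: dict[int, list[GraphEdge]] = {}
        for e in self.edges.values():
            out.setdefault(e.tail, []).append(e)
        return out

    def tree_edges(self, tree: str) -> list[GraphEdge]:
        return [e for e in self.edges.values() if e.tree == tree]

    def terminals(self, tree: str) -> list[int]:
        tails = {e.tail for e in self.tree_edges(tree)}
        heads = {e.head for e in self.tree_edges(tree)}
        return sorted(heads - tails)

    def terminal_positions(self, tree: str) -> np.ndarray:
        return np.array([self.nodes[n].position for n in self.terminals(tree)])

    def edge_length(self, e: GraphEdge) -> float:
        return float(np.linalg.norm(self.nodes[e.head].position - self.nodes[e.tail].position))

    def segment_endpoints(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
        ids = sorted(self.edges)
        a = np.array([self.nodes[self.edges[i].tail].position for i in ids])
        b = np.array([self.nodes[self.edges[i].head].position for i in ids])
        r = np.array([self.edges[i].radius for i in ids])
        return a, b, r, ids

    def murray_residuals(self, exponent: float = 3.0) -> dict[int, float]:
        """Per-bifurcation |r_p^e - sum r_c^e| for nodes with >= 2 children."""
        by_head = {e.head: e for e in self.edges.values()}
        res = {}
        for node, kids in self.children().items():
            if len(kids) < 2 or node not in by_head:
                continue
            rp = by_head[node].radius
            res[node] = abs(rp**exponent - sum(k.radius**exponent for k in kids))
        return res

    def validate(self, boundary: Boundary | None = None, exponent: float = 3.0) -> None:
        by_head: dict[int, list[GraphEdge]] = {}
        for e in self.edges.values():
            by_head.setdefault(e.head, []).append(e)
            if e.radius <= 0:
                raise ValueError(f"edge {e.id} has nonpositive radius")
        for head, incoming in by_head.items():
            if len(incoming) > 1:
                raise ValueError(f"node {head} has multiple parents (cycle or merge)")
        for e in self.edges.values():
            parents = by_head.get(e.tail, [])
            for p in parents:
                if e.radius > p.radius + 1e-12:
                    raise ValueError(f"edge {e.id} radius exceeds parent edge {p.id}")
        for tree, root in self.roots.items():
            seen = set()
            stack = [root]
            kids = self.children()
            while stack:
                n = stack.pop()
                if n in seen:
                    raise ValueError(f"cycle detected in tree {tree!r}")
                seen.add(n)
                stack.extend(k.head for k in kids.get(n, []) if k.tree == tree)
            nodes_in_tree = {e.tail for e in self.tree_edges(tree)} | {e.head for e in self.tree_edges(tree)}
            if nodes_in_tree - seen:
                raise ValueError(f"tree {tree!r} is disconnected from its root")
        if boundary is not None:
            root_ids = set(self.roots.values())
            for n in self.nodes.values():
                if n.id in root_ids:
                    continue
                if not boundary.contains(n.position[None, :])[0]:
                    raise ValueError(f"node {n.id} lies outside the boundary")

    # -- I/O ---------------------------------------------------------------
    def to_json(self) -> dict:
        return {
            "nodes": [{"id": n.id, "x": n.position[0], "y": n.position[1], "z": n.position[2]} for n in self.nodes.values()],
            "edges": [{"id": e.id, "a": e.tail, "b": e.head, "radius": e.radius, "tree": e.tree} for e in self.edges.values()],
            "roots": dict(self.roots),
        }

    @classmethod
    def from_json(cls, data: dict) -> "CenterlineGraph":
        g = cls()
        for n in data["nodes"]:
            g.nodes[int(n["id"])] = GraphNode(int(n["id"]), [n["x"], n["y"], n["z"]])
        for e in data["edges"]:
            g.edges[int(e["id"])] = GraphEdge(int(e["id"]), int(e["a"]), int(e["b"]), float(e["radius"]), e.get("tree", "tree"))
        g.roots = {k: int(v) for k, v in data.get("roots", {}).items()}
        return g

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh)

    @classmethod
    def load(cls, path) -> "CenterlineGraph":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


@dataclass
class GrowthConfig:
    boundary: Boundary
    n_terminals: int
    root_position: tuple[float, float, float]
    root_radius: float
    tree_label: str = "tree"
    murray_exponent: float = 3.0
    min_radius: float = 0.1
    curvature_degree: int = 2
    seed: int = 0
    n_candidates: int = 8
    clearance: float = 0.0
    retry_limit: int = 50

    def __post_init__(self) -> None:
        if self.n_terminals < 1:
            raise ValueError("terminal count must be >= 1")
        if self.murray_exponent <= 0:
            raise ValueError("murray exponent must be > 0")
        if self.root_radius * self.n_terminals ** (-1.0 / self.murray_exponent) < self.min_radius - 1e-12:
            raise ValueError(
                "terminal radius would fall below min_radius: reduce terminal count, "
                "raise the root radius, or lower min_radius"
            )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def sample_candidate_points(boundary: Boundary, n: int, seed: int) -> np.ndarray:
    """``n`` random points strictly inside the boundary; deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return boundary.sample_interior(n, rng)


def murray_split_radii(parent_radius: float, flow_fractions, exponent: float = 3.0) -> np.ndarray:
    """Child radii from parent radius and flow split: r_i = r_p * f_i^(1/e)."""
    if parent_radius <= 0:
        raise ValueError("parent radius must be positive")
    f = np.asarray(flow_fractions, float)
    if (f <= 0).any():
        raise ValueError("flow fractions must be positive")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("flow fractions must sum to 1")
    return parent_radius * f ** (1.0 / exponent)


def optimize_bifurcation(parent_point, child_points, radii, tol: float = 1e-6):
    """Junction position minimizing sum(pi r_i^2 l_i) over the incident segments.

    ``radii`` pairs with [parent, child1, child2].  Collinear/degenerate
    anchors fall back to the radius^2-weighted midpoint.
    """
    anchors = np.vstack([np.asarray(parent_point, float)] + [np.asarray(c, float) for c in child_points])
    w = np.pi * np.asarray(radii, float) ** 2
    if len(anchors) != len(w):
        raise ValueError("need one radius per anchor")
    if len(np.unique(anchors.round(12), axis=0)) < 3:
        log.warning("degenerate bifurcation anchors; using weighted midpoint")
        return (w[:, None] * anchors).sum(axis=0) / w.sum()

    def cost(x):
        return float((w * np.linalg.norm(anchors - x, axis=1)).sum())

    x0 = (w[:, None] * anchors).sum(axis=0) / w.sum()
    res = minimize(cost, x0, method="Nelder-Mead", options={"xatol": tol, "fatol": tol * 1e-3, "maxiter": 2000})
    return res.x


def interpolate_curvature(polyline, degree: int, samples: int, boundary: Boundary | None = None) -> np.ndarray:
    """Polynomial smoothing of a polyline on its chord-length parameter.

    Passes exactly through the endpoints; with ``degree >= n_points - 1`` the
    curve interpolates every control point.  Samples that leave a supplied
    boundary are pulled back to the nearest point of the original polyline.
    """
    pts = np.atleast_2d(np.asarray(polyline, float))
    if len(pts) < 2:
        raise ValueError("need at least two control points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.r_[0.0, np.cumsum(seg)]
    if t[-1] == 0:
        raise ValueError("degenerate polyline")
    t /= t[-1]
    deg = min(max(degree, 1), len(pts) - 1)
    ts = np.linspace(0.0, 1.0, samples)
    out = np.empty((samples, 3))
    for k in range(3):
        coef = np.polynomial.polynomial.polyfit(t, pts[:, k], deg)
        out[:, k] = np.polynomial.polynomial.polyval(ts, coef)
        # force exact endpooints by linear correction of the residual
        r0 = pts[0, k] - np.polynomial.polynomial.polyval(0.0, coef)
        r1 = pts[-1, k] - np.polynomial.polynomial.polyval(1.0, coef)
        out[:, k] += r0 * (1 - ts) + r1 * ts
    if boundary is not None:
        bad = ~boundary.contains(out)
        bad[0] = bad[-1] = False
        if bad.any():
            log.warning("curvature interpolation: %d samples outside boundary projected inward", bad.sum())
            out[bad] = _nearest_on_polyline(out[bad], pts)
    return out


def _nearest_on_polyline(queries: np.ndarray, pts: np.ndarray) -> np.ndarray:
    a, b = pts[:-1], pts[1:]
    ab = b - a
    denom = (ab * ab).sum(axis=1)
    out = np.empty_like(queries)
    for i, q in enumerate(queries):
        tt = np.clip(((q - a) * ab).sum(axis=1) / np.where(denom > 0, denom, 1), 0, 1)
        proj = a + tt[:, None] * ab
        out[i] = proj[np.linalg.norm(proj - q, axis=1).argmin()]
    return out


def segment_pair_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between segments [a0,a1] and [b0,b1]."""
    a0, a1, b0, b1 = (np.asarray(x, float) for x in (a0, a1, b0, b1))
    d1, d2 = a1 - a0, b1 - b0
    r = a0 - b0
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    if a <= 1e-18 and e <= 1e-18:
        return float(np.linalg.norm(r))
    if a <= 1e-18:
        s, t = 0.0, np.clip(f / e, 0, 1)
    else:
        c = d1 @ r
        if e <= 1e-18:
            t, s = 0.0, np.clip(-c / a, 0, 1)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0, 1) if denom > 1e-18 else 0.0
            t = (b * s + f) / e
            if t < 0:
                t, s = 0.0, np.clip(-c / a, 0, 1)
            elif t > 1:
                t, s = 1.0, np.clip((b - c) / a, 0, 1)
    return float(np.linalg.norm(a0 + s * d1 - (b0 + t * d2)))


def check_intersections(graph: CenterlineGraph, clearance: float = 0.0, brute: bool = False) -> list[tuple[int, int]]:
    """Nonadjacent edge pairs whose capsules approach closer than radii sum + clearance.

    ``brute=True`` forces the plain O(n^2) scan (used as the oracle for the
    midpoint-prefiltered default path).
    """
    a, b, r, ids = graph.segment_endpoints()
    n = len(ids)
    if n < 2:
        return []
    lengths = np.linalg.norm(b - a, axis=1)
    mids = (a + b) / 2
    edge_nodes = [ {graph.edges[i].tail, graph.edges[i].head} for i in ids ]
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if edge_nodes[i] & edge_nodes[j]:
                continue
            thresh = r[i] + r[j] + clearance
            if not brute:
                if np.linalg.norm(mids[i] - mids[j]) > (lengths[i] + lengths[j]) / 2 + thresh:
                    continue
            d = segment_pair_distance(a[i], b[i], a[j], b[j])
            if d < thresh:
                pairs.append((ids[i], ids[j]))
    return pairs


def grow_tree(config: GrowthConfig, existing: CenterlineGraph | None = None) -> CenterlineGraph:
    """Grow one tree to the configured terminal count (sequential attachment)."""
    g = existing if existing is not None else CenterlineGraph()
    rng = np.random.default_rng(config.seed)
    b = config.boundary
    label = config.tree_label

    root_pos = np.asarray(config.root_position, float)
    root_id = g.add_node(root_pos)
    g.roots[label] = root_id

    first = b.sample_interior(1, rng)[0]
    tid = g.add_node(first)
    g.add_edge(root_id, tid, config.root_radius, label)

    n_terminals = 1
    while n_terminals < config.n_terminals:
        placed = False
        for _attempt in range(config.retry_limit):
            p = b.sample_interior(1, rng)[0]
            if _try_attach(g, config, p):
                placed = True
                break
            log.info("terminal rejected, resampling")
        if not placed:
            raise RuntimeError(f"could not place terminal {n_terminals + 1} within retry limit")
        n_terminals += 1
        _recompute_radii(g, config)
    return g


def _subtree_counts(g: CenterlineGraph, label: str) -> dict[int, int]:
    kids: dict[int, list[GraphEdge]] = {}
    for e in g.tree_edges(label):
        kids.setdefault(e.tail, []).append(e)
    counts: dict[int, int] = {}

    def count(e: GraphEdge) -> int:
        below = kids.get(e.head, [])
        c = 1 if not below else sum(count(k) for k in below)
        counts[e.id] = c
        return c

    for e in kids.get(g.roots[label], []):
        count(e)
    return counts


def _try_attach(g: CenterlineGraph, config: GrowthConfig, p: np.ndarray) -> bool:
    b = config.boundary
    edges = g.tree_edges(config.tree_label)
    a_pos = np.array([g.nodes[e.tail].position for e in edges])
    b_pos = np.array([g.nodes[e.head].position for e in edges])
    # distance from p to each segment to shortlist candidates
    ab = b_pos - a_pos
    denom = (ab * ab).sum(axis=1)
    tt = np.clip(((p - a_pos) * ab).sum(axis=1) / np.where(denom > 0, denom, 1), 0, 1)
    proj = a_pos + tt[:, None] * ab
    dists = np.linalg.norm(proj - p, axis=1)
    order = np.argsort(dists)[: config.n_candidates]

    counts = _subtree_counts(g, config.tree_label)
    n_now = sum(counts[e.id] for e in edges if e.tail == g.roots[config.tree_label])
    best = None
    for k in order:
        e = edges[k]
        a, bb = a_pos[k], b_pos[k]
        old_vol = np.pi * e.radius**2 * np.linalg.norm(bb - a)
        r_term = e.radius  # provisional; radii rebalanced globally afterwards
        x = optimize_bifurcation(a, [bb, p], [e.radius, e.radius, r_term])
        # keep the junction off the original endpoints (degenerate segments)
        seg = bb - a
        seglen = np.linalg.norm(seg)
        if np.linalg.norm(x - a) < 0.02 * seglen:
            x = a + 0.02 * seg
        elif np.linalg.norm(x - bb) < 0.02 * seglen:
            x = bb - 0.02 * seg
        new_vol = (
            np.pi * e.radius**2 * (np.linalg.norm(x - a) + np.linalg.norm(bb - x))
            + np.pi * r_term**2 * np.linalg.norm(p - x)
        )
        cost = new_vol - old_vol
        if not _segments_admissible(g, config, e, a, bb, p, x, counts, n_now):
            continue
        if best is None or cost < best[0]:
            best = (cost, e, x)
    if best is None:
        return False
    _, e, x = best
    xid = g.add_node(x)
    tid = g.add_node(p)
    tree = e.tree
    del g.edges[e.id]
    g.add_edge(e.tail, xid, e.radius, tree)
    g.add_edge(xid, e.head, e.radius, tree)
    g.add_edge(xid, tid, e.radius, tree)
    return True


def _segments_admissible(g, config, split_edge, a, b, p, x, counts, n_now) -> bool:
    """Boundary containment and clearance for the three candidate segments.

    Clearance is checked against an upper bound on each edge's *final* radius
    (its subtree could still absorb every remaining terminal), so radii
    rebalancing after later insertions cannot create overlaps retroactively.
    """
    bd = config.boundary
    for s0, s1 in ((a, x), (x, b), (x, p)):
        ts = np.linspace(0, 1, 7)[1:-1]
        pts = s0 + ts[:, None] * (s1 - s0)
        if not bd.contains(pts).all():
            return False
    if not bd.contains(x[None, :])[0]:
        return False
    remaining = max(config.n_terminals - (n_now + 1), 0)
    exp = config.murray_exponent

    def final_radius_bound(n_below: int) -> float:
        return config.root_radius * min((n_below + remaining) / config.n_terminals, 1.0) ** (1.0 / exp)

    new_bound = final_radius_bound(1)
    new_segs = (
        ((a, x), {split_edge.tail}),
        ((x, b), {split_edge.head}),
        ((x, p), set()),
    )
    split_bound = final_radius_bound(counts[split_edge.id] + 1)
    for e in g.edges.values():
        if e.id == split_edge.id:
            continue
        e0 = g.nodes[e.tail].position
        e1 = g.nodes[e.head].position
        e_bound = final_radius_bound(counts.get(e.id, 1))
        e_nodes = {e.tail, e.head}
        for (s0, s1), adj in new_segs:
            if e_nodes & adj:
                continue
            seg_bound = new_bound if (s1 is p) else split_bound
            d = segment_pair_distance(s0, s1, e0, e1)
            if d < e_bound + seg_bound + config.clearance:
                return False
    return True


def _recompute_radii(g: CenterlineGraph, config: GrowthConfig) -> None:
    """Equal flow per terminal: r_e = r_root * (terminals below e / total)^(1/exp)."""
    label = config.tree_label
    kids = {}
    for e in g.tree_edges(label):
        kids.setdefault(e.tail, []).append(e)

    counts: dict[int, int] = {}

    def count(e: GraphEdge) -> int:
        below = kids.get(e.head, [])
        c = 1 if not below else sum(count(k) for k in below)
        counts[e.id] = c
        return c

    root = g.roots[label]
    total = sum(count(e) for e in kids.get(root, []))
    for e in g.tree_edges(label):
        e.radius = config.root_radius * (counts[e.id] / total) ** (1.0 / config.murray_exponent)


def match_endpoint_triplets(arterial: np.ndarray, venous: np.ndarray, portal: np.ndarray) -> list[tuple[int, int, int]]:
    """Closed-circulation triplets (arterial idx, venous idx, portal idx).

    Solves the assignment problem twice — arterial->venous then
    portal->venous — each minimizing the total Euclidean matching cost with
    every endpoint used exactly once.
    """
    A = np.atleast_2d(np.asarray(arterial, float))
    V = np.atleast_2d(np.asarray(venous, float))
    P = np.atleast_2d(np.asarray(portal, float))
    if not (len(A) == len(V) == len(P)):
        raise ValueError("the three endpoint sets must have equal sizes")
    cost_av = np.linalg.norm(A[:, None, :] - V[None, :, :], axis=2)
    ra, cv = linear_sum_assignment(cost_av)
    cost_pv = np.linalg.norm(P[:, None, :] - V[None, :, :], axis=2)
    rp, cv2 = linear_sum_assignment(cost_pv)
    v_to_a = dict(zip(cv.tolist(), ra.tolist()))
    v_to_p = dict(zip(cv2.tolist(), rp.tolist()))
    return [(v_to_a[v], v, v_to_p[v]) for v in range(len(V))]
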