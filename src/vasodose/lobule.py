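"""Stylized hexagonal-prism liver lobule and its tileable rectangular variant.

Geometry strategy: every component is a union of convex polytopes —
area-preserving polygonal cylinders for vessels and channels, annular wedge
prisms for the Space of Disse, regular icosahedra for Kupffer cells — laid
out on a mirror-symmetric motif (azimuths in closed reflection sets, layers
symmetric about mid-height).  That makes component volumes exact, pairwise
overlap zero by construction, and cropping to the rectangular tiling cell an
exact sequence of half-space clips, so relative mass fractions survive
cropping to floating-point precision.

The hepatocyte compartment is the fill: prism volume minus all explicit
components.  Sinusoid cylinders are split around each Kupffer site so that
cells occupy carve-outs of the lumen rather than overlapping it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import masses
from .geometry import ConvexPoly, annular_shell_wedges, cylinder, icosahedron, regular_hex_prism
from .surface import TriangleMesh

log = logging.getLogger(__name__)

#: classification priority (explicit components before the hepatocyte fill)
COMPONENT_ORDER = (
    "central_vein",
    "portal_veins",
    "portal_arteries",
    "bile_ducts",
    "kupffer_cells",
    "sinusoids",
    "space_of_disse",
    "bile_canaliculi",
    "hepatocytes",
)


@dataclass
class LobuleSpec:
    """Geometric parameters of the lobule (lengths in micrometres).

    Dimensions other than the sinusoid diameter are stylized defaults; they
    are free parameters tuned at build time so that achieved component mass
    fractions hit the configured targets.
    """

    side_um: float = 300.0
    height_um: float = 300.0
    sinusoid_diameter_um: float = 16.0
    kupffer_circumradius_um: float = 6.0
    canaliculus_radius_um: float = 4.0
    layer_spacing_um: float = 30.0
    end_margin: float = 0.96
    n_sides_sinusoid: int = 12
    n_sides_vessel: int = 16
    n_sides_canaliculus: int = 8
    seed: int = 0
    targets: masses.LobuleMassFractions | None = None
    densities: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.sinusoid_diameter_um <= 0:
            raise ValueError("sinusoid diameter must be positive")
        if self.targets is None:
            self.targets = masses.reference_lobule_fractions()
        if self.densities is None:
            self.densities = masses.reference_lobule_densities()

    @property
    def apothem_um(self) -> float:
        return np.sqrt(3) / 2 * self.side_um

    def prism_volume(self) -> float:
        return 1.5 * np.sqrt(3) * self.side_um**2 * self.height_um

    def target_volume_fractions(self) -> dict[str, float]:
        """Mass-fraction targets converted to volume fractions via densities."""
        v = {c: self.targets.fractions[c] / self.densities[c] for c in masses.LOBULE_COMPONENTS}
        total = sum(v.values())
        return {c: x / total for c, x in v.items()}


@dataclass
class LabeledMeshSet:
    """Component name -> list of convex parts, inside a prism domain.

    ``fill`` names the remainder component (volume = domain minus explicit
    parts); its mesh is the domain boundary.
    """

    components: dict[str, list[ConvexPoly]]
    domain: ConvexPoly
    fill: str | None = "hepatocytes"
    spec: LobuleSpec | None = None
    _bounds_cache: dict = field(default_factory=dict, repr=False)

    def component_names(self) -> list[str]:
        names = [c for c in COMPONENT_ORDER if c in self.components or c == self.fill]
        for c in self.components:
            if c not in names:
                names.append(c)
        return names

    def component_volumes(self) -> dict[str, float]:
        vols = {name: sum(p.volume for p in parts) for name, parts in self.components.items()}
        if self.fill is not None:
            vols[self.fill] = self.domain.volume - sum(vols.values())
        return vols

    def meshes(self) -> dict[str, TriangleMesh]:
        out = {}
        for name, parts in self.components.items():
            sub = [TriangleMesh(p.hull.points, p.faces) for p in parts]
            out[name] = TriangleMesh.concatenate(sub)
        if self.fill is not None:
            out[self.fill] = TriangleMesh(self.domain.hull.points, self.domain.faces)
        return out

    def classify(self, points: np.ndarray) -> np.ndarray:
        """Component name per point ('' for points outside the domain)."""
        pts = np.atleast_2d(np.asarray(points, float))
        labels = np.full(len(pts), "", dtype=object)
        in_dom = self.domain.contains(pts)
        if self.fill is not None:
            labels[in_dom] = self.fill
        todo = in_dom.copy()
        for name in self.component_names():
            if name == self.fill or name not in self.components:
                continue
            for part in self.components[name]:
                lo, hi = part.bounds()
                cand = todo & ((pts >= lo - 1e-9) & (pts <= hi + 1e-9)).all(axis=1)
                if not cand.any():
                    continue
                idx = np.flatnonzero(cand)
                hit = part.contains(pts[idx])
                labels[idx[hit]] = name
                todo[idx[hit]] = False
        return labels

    def crop_to_box(self, lo, hi, translations) -> "LabeledMeshSet":
        """Clip translated copies of this set to an axis-aligned box."""
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        comps: dict[str, list[ConvexPoly]] = {name: [] for name in self.components}
        for t in translations:
            for name, parts in self.components.items():
                for p in parts:
                    plo, phi = p.bounds()
                    if ((plo + t) >= hi).any() or ((phi + t) <= lo).any():
                        continue
                    clipped = p.translated(t).clip_box(lo, hi)
                    if clipped is not None:
                        comps[name].append(clipped)
        from .geometry import box as _box

        return LabeledMeshSet(comps, _box(lo, hi), fill=self.fill, spec=self.spec)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _hex_boundary_distance(theta: float, side: float) -> float:
    """Distance from the axis to the hexagon boundary along azimuth theta
    (flat-top hexagon, vertices at multiples of 60 degrees)."""
    a = np.sqrt(3) / 2 * side
    t = np.mod(theta, np.pi / 3)
    return a / np.cos(t - np.pi / 6)


def build_hexagonal_lobule(spec: LobuleSpec) -> LabeledMeshSet:
    """Assemble the lobule; raises if the volume targets are infeasible."""
    s, h = spec.side_um, spec.height_um
    V = spec.prism_volume()
    fv = spec.target_volume_fractions()
    rng = np.random.default_rng(spec.seed)
    r_s = spec.sinusoid_diameter_um / 2.0

    comps: dict[str, list[ConvexPoly]] = {}

    # central vein: on-axis cylinder sized exactly to its volume target
    r_cv = np.sqrt(fv["central_vein"] * V / (np.pi * h))
    comps["central_vein"] = [cylinder((0, 0, 0), (0, 0, h), r_cv, spec.n_sides_vessel)]

    # portal triads: vertical cylinders on the six vertex radial lines
    def triad_radius(name: str) -> float:
        return np.sqrt(fv[name] * V / (6 * np.pi * h))

    r_pv, r_pa, r_bd = (triad_radius(n) for n in ("portal_veins", "portal_arteries", "bile_ducts"))
    d_pv = 0.88 * s
    d_pa = d_pv - (r_pv + r_pa + 3.0)
    d_bd = d_pa - (r_pa + r_bd + 3.0)
    apo = spec.apothem_um
    for d, r, name in ((d_pv, r_pv, "portal_veins"), (d_pa, r_pa, "portal_arteries"), (d_bd, r_bd, "bile_ducts")):
        if apo - (d * np.cos(np.pi / 6)) < r + 0.5:
            raise ValueError(f"triad component {name} does not fit inside the hexagon")
        comps[name] = [
            cylinder(
                (d * np.cos(th), d * np.sin(th), 0),
                (d * np.cos(th), d * np.sin(th), h),
                r,
                spec.n_sides_vessel,
            )
            for th in np.deg2rad(np.arange(6) * 60.0)
        ]

    # sinusoid line layout: dyadic azimuth tiers, each tier starting at the
    # radius where its angular pitch clears the tube (sinusoid + Disse shell);
    # every tier set is closed under the hexagon mirror symmetries
    dz = spec.layer_spacing_um
    n_layers = int(round(h / dz))
    if abs(n_layers * dz - h) > 1e-9:
        raise ValueError("height must be an integer multiple of layer spacing")
    z_layers = (np.arange(n_layers) + 0.5) * dz

    def poly_scale(n: int) -> float:
        return np.sqrt(2 * np.pi / (n * np.sin(2 * np.pi / n)))

    # Disse outer radius is fixed by the Disse/sinusoid volume-fraction ratio
    r_o = r_s * np.sqrt(1.0 + fv["space_of_disse"] / fv["sinusoids"])
    ro_eff = r_o * poly_scale(spec.n_sides_sinusoid) + 0.3

    def pitch_start(delta_deg: float) -> float:
        return (2 * ro_eff + 1.0) / (2 * np.sin(np.deg2rad(delta_deg) / 2))

    inner_start = r_cv * poly_scale(spec.n_sides_vessel) + ro_eff + 1.0
    tiers = [
        (np.arange(12) * 30.0, max(inner_start, pitch_start(30.0))),
        (np.arange(12) * 30.0 + 15.0, max(inner_start, pitch_start(15.0))),
        (np.arange(24) * 15.0 + 7.5, max(inner_start, pitch_start(7.5))),
        (np.arange(48) * 7.5 + 3.75, max(inner_start, pitch_start(3.75))),
    ]
    d_triad_inner = d_bd - r_bd
    area_s = np.pi * r_s**2
    target_s = fv["sinusoids"] * V
    lines = []  # (start_radius, azimuth_rad, max_end, z)
    for az_deg, start in tiers:
        tier_lines = []
        for z in z_layers:
            for deg in az_deg:
                th = np.deg2rad(deg)
                d_end = spec.end_margin * _hex_boundary_distance(th, s)
                if np.isclose(np.mod(deg, 60.0), 0.0):
                    d_end = min(d_end, d_triad_inner - 8.0 - ro_eff)
                if d_end - start > 4 * r_s:
                    tier_lines.append((start, th, d_end, z))
        lines.extend(tier_lines)
        capacity = area_s * sum(d_end - s0 for s0, _, d_end, _ in lines)
        if capacity > target_s / 0.9:  # enough headroom; skip finer tiers
            break
    if not lines:
        raise ValueError("no feasible sinusoid lines; lobule too small for the sinusoid diameter")

    # Kupffer sites: carve-outs on a seeded random subset of lines
    R_k = spec.kupffer_circumradius_um
    v_ico = icosahedron((0, 0, 0), R_k).volume
    target_k = fv["kupffer_cells"] * V
    n_k = int(round(target_k / v_ico)) if target_k > 0 else 0
    if R_k >= r_s:
        raise ValueError("Kupffer circumradius must be smaller than the sinusoid radius")
    site_lines = rng.choice(len(lines), size=min(n_k, len(lines)), replace=False) if n_k else np.array([], int)
    site_frac = rng.uniform(0.25, 0.75, size=len(site_lines))

    # solve the common length-scale factor so net sinusoid volume hits target
    cap_lengths = np.array([d_end - start for start, _, d_end, _ in lines])
    gap_per_cell = 2 * R_k
    kappa = (target_s / area_s + len(site_lines) * gap_per_cell) / cap_lengths.sum()
    if kappa > 1.0:
        raise ValueError(
            f"sinusoid volume target infeasible: would need length scale {kappa:.3f} > 1; "
            "increase lobule size or layer density"
        )
    if kappa < 0.3:
        log.warning("sinusoid lines much longer than needed (kappa=%.2f)", kappa)

    # exact Disse outer radius given the final line lengths (shells span the
    # Kupffer gaps, so this lands at or just below the upfront estimate)
    total_len = (kappa * cap_lengths).sum()
    target_d = fv["space_of_disse"] * V
    r_o = min(r_o, np.sqrt(r_s**2 + target_d / (np.pi * total_len)))

    sin_parts: list[ConvexPoly] = []
    disse_parts: list[ConvexPoly] = []
    kupffer_parts: list[ConvexPoly] = []
    gaps_by_line = {int(li): f for li, f in zip(site_lines, site_frac)}
    for li, (start, th, d_end, z) in enumerate(lines):
        L = kappa * (d_end - start)
        u = np.array([np.cos(th), np.sin(th), 0.0])
        p0 = start * u + [0, 0, z]
        p1 = (start + L) * u + [0, 0, z]
        if li in gaps_by_line:
            c = start + gaps_by_line[li] * L
            g0, g1 = c - R_k, c + R_k
            sin_parts.append(cylinder(p0, g0 * u + [0, 0, z], r_s, spec.n_sides_sinusoid, phase=th))
            sin_parts.append(cylinder(g1 * u + [0, 0, z], p1, r_s, spec.n_sides_sinusoid, phase=th))
            kupffer_parts.append(icosahedron(c * u + [0, 0, z], R_k, rng=rng))
        else:
            sin_parts.append(cylinder(p0, p1, r_s, spec.n_sides_sinusoid, phase=th))
        disse_parts.extend(annular_shell_wedges(p0, p1, r_s, r_o, spec.n_sides_sinusoid, phase=th))
    comps["sinusoids"] = sin_parts
    comps["space_of_disse"] = disse_parts
    if kupffer_parts:
        comps["kupffer_cells"] = kupffer_parts

    # bile canaliculi: thin channels between sinusoid layers; the half-layer
    # gap must clear the Disse shell and the canaliculus (polygon vertex radii)
    r_bc = spec.canaliculus_radius_um
    clearance = dz / 2 - r_o * poly_scale(spec.n_sides_sinusoid) - r_bc * poly_scale(spec.n_sides_canaliculus)
    if clearance < 0.25:
        raise ValueError(
            f"layer spacing {dz} um too tight for Disse shell ({r_o:.2f} um) plus "
            f"canaliculus ({r_bc} um); increase layer_spacing_um"
        )
    z_canal = np.arange(1, n_layers) * dz
    rc_eff = r_bc * poly_scale(spec.n_sides_canaliculus)

    def c_pitch_start(delta_deg: float) -> float:
        return (2 * rc_eff + 1.0) / (2 * np.sin(np.deg2rad(delta_deg) / 2))

    inner_c = r_cv * poly_scale(spec.n_sides_vessel) + rc_eff + 1.0
    target_c = fv["bile_canaliculi"] * V
    c_tiers = [
        (np.arange(24) * 15.0 + 7.5, max(inner_c, c_pitch_start(15.0))),
        (np.arange(48) * 7.5 + 3.75, max(inner_c, c_pitch_start(3.75))),
        (np.arange(96) * 3.75 + 1.875, max(inner_c, c_pitch_start(1.875))),
    ]
    clines = []
    for az_deg, start in c_tiers:
        for z in z_canal:
            for deg in az_deg:
                th = np.deg2rad(deg)
                d_end = spec.end_margin * _hex_boundary_distance(th, s)
                if d_end - start > 4 * r_bc:
                    clines.append((start, th, d_end, z))
        capacity = np.pi * r_bc**2 * sum(d_end - s0 for s0, _, d_end, _ in clines)
        if capacity > target_c / 0.9:
            break
    cap_c = np.array([d_end - start for start, _, d_end, _ in clines]) if clines else np.zeros(0)
    if cap_c.sum() * np.pi * r_bc**2 < target_c:
        raise ValueError("bile canaliculi volume target infeasible; increase radius or layer count")
    kappa_c = target_c / (np.pi * r_bc**2) / cap_c.sum()
    comps["bile_canaliculi"] = []
    for (start, th, d_end, z), cap in zip(clines, cap_c):
        L = kappa_c * cap
        u = np.array([np.cos(th), np.sin(th), 0.0])
        comps["bile_canaliculi"].append(
            cylinder(start * u + [0, 0, z], (start + L) * u + [0, 0, z], r_bc, spec.n_sides_canaliculus, phase=th)
        )

    domain = regular_hex_prism(s, h, center=(0, 0, h / 2))
    out = LabeledMeshSet(comps, domain, fill="hepatocytes", spec=spec)

    achieved = out.component_volumes()
    for name, target in fv.items():
        if name == "hepatocytes" or (name == "kupffer_cells" and n_k == 0):
            continue
        got = achieved.get(name, 0.0) / V
        if target > 0 and abs(got - target) > 0.05 * target:
            raise RuntimeError(f"component {name}: achieved volume fraction {got:.5f} misses target {target:.5f}")
    return out


def place_kupffer_cells(
    sinusoids: list[ConvexPoly],
    target_volume: float,
    cell_size: float,
    seed: int,
    retry_limit: int = 20_000,
) -> list[ConvexPoly]:
    """Random icosahedra inside the sinusoid lumen until the volume target.

    Candidate cells are drawn uniformly in the sinusoid bounding box with
    random orientation; each is clipped to the lumen (intersection with the
    convex sinusoid parts) and kept if the clipped volume is nonzero.  Stops
    within 2% of the target; raises with the achieved volume if the target
    cannot be reached.
    """
    if target_volume <= 0:
        return []
    rng = np.random.default_rng(seed)
    los = np.array([p.bounds()[0] for p in sinusoids])
    his = np.array([p.bounds()[1] for p in sinusoids])
    lo, hi = los.min(axis=0), his.max(axis=0)
    total_lumen = sum(p.volume for p in sinusoids)
    if target_volume >= total_lumen:
        raise ValueError("Kupffer target volume exceeds the sinusoid lumen volume")
    cells: list[ConvexPoly] = []
    achieved = 0.0
    for _ in range(retry_limit):
        if achieved >= target_volume * 0.98:
            return cells
        center = lo + (hi - lo) * rng.random(3)
        ico = icosahedron(center, cell_size, rng=rng)
        for part in sinusoids:
            plo, phi = part.bounds()
            if ((center - cell_size) > phi).any() or ((center + cell_size) < plo).any():
                continue
            clipped: ConvexPoly | None = ico
            for eq in part.hull.equations:
                clipped = clipped.clip_halfspace(eq[:3], -eq[3])
                if clipped is None:
                    break
            if clipped is not None and clipped.volume > 0:
                if achieved + clipped.volume <= target_volume * 1.02:
                    cells.append(clipped)
                    achieved += clipped.volume
                break
    if achieved < target_volume * 0.98:
        raise RuntimeError(f"Kupffer placement exhausted retries; achieved {achieved:.4g} of {target_volume:.4g}")
    return cells


def tile_and_crop_prism(lob: LabeledMeshSet) -> LabeledMeshSet:
    """Duplicate the lobule over the hexagonal lattice and crop to the
    rectangular unit cell.

    The cell is [0, 1.5 side] x [0, 2 apothem] x [0, height] — one lattice
    unit, with every face on a mirror plane of the tiling — so relative mass
    fractions are preserved exactly and reflected boundary content maps onto
    itself.
    """
    if lob.spec is None:
        raise ValueError("lobule lacks its spec; cannot infer the lattice")
    s = lob.spec.side_um
    a = lob.spec.apothem_um
    h = lob.spec.height_um
    lo = np.array([0.0, 0.0, 0.0])
    hi = np.array([1.5 * s, 2 * a, h])
    offsets = [np.array([0.0, 0.0, 0.0])]
    for k1 in (-1, 0, 1, 2):
        for k2 in (-1, 0, 1, 2):
            t = np.array([1.5 * s * (k1 + k2), a * (k1 - k2), 0.0])
            if np.linalg.norm(t) > 0:
                offsets.append(t)
    return lob.crop_to_box(lo, hi, offsets)


def lattice_reduce(points: np.ndarray, spec: LobuleSpec) -> np.ndarray:
    """Map points to their representative inside the central lobule's cell
    (hexagonal lattice in x/y, period ``height`` in z)."""
    pts = np.atleast_2d(np.asarray(points, float)).copy()
    s, a, h = spec.side_um, spec.apothem_um, spec.height_um
    pts[:, 2] = np.mod(pts[:, 2], h)
    # lattice basis t1=(1.5s, a), t2=(1.5s, -a)
    B = np.array([[1.5 * s, 1.5 * s], [a, -a]])
    Binv = np.linalg.inv(B)
    frac = pts[:, :2] @ Binv.T
    pts[:, :2] -= np.round(frac) @ B.T
    # snap to the nearest center among remaining neighbors
    cands = [np.zeros(2), [1.5 * s, a], [1.5 * s, -a], [-1.5 * s, a], [-1.5 * s, -a], [0, 2 * a], [0, -2 * a]]
    d = np.stack([np.linalg.norm(pts[:, :2] - np.asarray(c), axis=1) for c in cands], axis=1)
    best = d.argmin(axis=1)
    for i, c in enumerate(cands):
        sel = best == i
        pts[sel, :2] -= np.asarray(c)
    return pts


def classify_tiled(points: np.ndarray, lob: LabeledMeshSet) -> np.ndarray:
    """Classify points against the infinite hexagonal tiling of the lobule."""
    if lob.spec is None:
        raise ValueError("lobule lacks its spec")
    reduced = lattice_reduce(points, lob.spec)
    reduced[:, 2] = np.clip(reduced[:, 2], 1e-9, lob.spec.height_um - 1e-9)
    return lob.classify(reduced)


def region_mass_report(mesh_set: LabeledMeshSet, densities: dict[str, float]) -> dict[str, dict[str, float]]:
    """Mass and mass fraction per component (mesh volume x density).

    Explicit component volumes are measured from their (watertight) meshes;
    the fill component volume is the domain minus the others.  Raises on open
    meshes.
    """
    meshes = mesh_set.meshes()
    vols = {}
    for name, parts in mesh_set.components.items():
        if not meshes[name].is_watertight():
            raise ValueError(f"component {name} mesh is not watertight")
        vols[name] = meshes[name].volume()
    if mesh_set.fill is not None:
        if not meshes[mesh_set.fill].is_watertight():
            raise ValueError(f"fill component {mesh_set.fill} mesh is not watertight")
        vols[mesh_set.fill] = meshes[mesh_set.fill].volume() - sum(vols.values())
    mass = {name: v * densities[name] for name, v in vols.items()}
    total = sum(mass.values())
    return {
        name: {"volume": vols[name], "mass": mass[name], "mass_fraction": mass[name] / total}
        for name in vols
    }
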