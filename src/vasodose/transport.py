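"""Desk-scale particle transport surrogate on labeled voxel geometry.

Physics is deliberately crude — the point is to exercise the two-scale
absorbed-fraction coupling, not to replicate a production Monte Carlo code:

* charged particles (alphas, electrons) travel a straight track of length
  equal to their CSDA range and deposit energy uniformly along it,
  apportioned to regions by path length (constant LET, no scattering,
  no secondaries);
* photons fly exponential free paths against a single total attenuation
  coefficient per region (Woodcock tracking across regions) and deposit all
  of their energy at the interaction point;
* the geometry bounding box is either reflective (positions and directions
  mirrored, representing an infinite tiling) or escaping (energy leaving the
  box, or deposited in the void label 0, is lost).

Absorbed-fraction tables produced by real transport codes can be imported
through the same CSV schema this module writes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .lobule import LabeledMeshSet
from .tetmesh import TetMesh

VOID = 0  # reserved label: outside the modeled geometry but inside the box


# ---------------------------------------------------------------------------
# particles
# ---------------------------------------------------------------------------

def _load_table(name: str, ycol: str) -> np.ndarray:
    txt = resources.files("vasodose.data").joinpath(name).read_text()
    df = pd.read_csv(io.StringIO(txt))
    return df[["energy_MeV", ycol]].to_numpy(float).T


@dataclass
class ParticleSpec:
    """Particle kind + energy with its range or attenuation data.

    ``range_table`` is (2, n): energy MeV vs CSDA range in mm (charged kinds).
    ``mu_table`` is (2, n): energy MeV vs mass attenuation cm^2/g (photons).
    Both must be strictly positive and monotone in energy.
    """

    kind: str
    energy_MeV: float
    range_table: np.ndarray | None = None
    mu_table: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("alpha", "electron", "photon"):
            raise ValueError(f"unknown particle kind {self.kind!r}")
        if self.energy_MeV <= 0:
            raise ValueError("energy must be positive")
        for tbl in (self.range_table, self.mu_table):
            if tbl is None:
                continue
            e, y = np.asarray(tbl)
            if (e <= 0).any() or (y <= 0).any() or (np.diff(e) <= 0).any():
                raise ValueError("tables must be strictly positive with increasing energies")
        if self.kind in ("alpha", "electron") and self.range_table is None:
            raise ValueError(f"{self.kind} needs a range-energy table")
        if self.kind == "photon" and self.mu_table is None:
            raise ValueError("photon needs an attenuation table")

    def csda_range_mm(self, energy: float | None = None) -> float:
        e = self.energy_MeV if energy is None else energy
        et, rt = np.asarray(self.range_table)
        return float(np.exp(np.interp(np.log(e), np.log(et), np.log(rt))))

    def mu_per_mm(self, density_g_cm3: float = 1.0, energy: float | None = None) -> float:
        e = self.energy_MeV if energy is None else energy
        et, mt = np.asarray(self.mu_table)
        mu_rho = np.exp(np.interp(np.log(e), np.log(et), np.log(mt)))
        return float(mu_rho * density_g_cm3 * 0.1)  # cm^2/g * g/cm^3 -> 1/cm -> 1/mm


def monoenergetic(kind: str, energy_MeV: float) -> ParticleSpec:
    """ParticleSpec backed by the bundled tissue range / water attenuation fixtures."""
    if kind == "alpha":
        return ParticleSpec(kind, energy_MeV, range_table=_load_table("alpha_csda_range_tissue.csv", "range_mm"))
    if kind == "electron":
        return ParticleSpec(kind, energy_MeV, range_table=_load_table("electron_csda_range_tissue.csv", "range_mm"))
    if kind == "photon":
        return ParticleSpec(kind, energy_MeV, mu_table=_load_table("photon_attenuation_water.csv", "mu_over_rho_cm2_g"))
    raise ValueError(f"unknown particle kind {kind!r}")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class VoxelGeometry:
    """Regular label grid: region id per voxel, 0 = void (outside the model)."""

    labels: np.ndarray  # (nx, ny, nz) int
    origin: np.ndarray  # (3,) geometry units
    spacing: float  # isotropic, geometry units
    region_names: dict[int, str] = field(default_factory=dict)
    mm_per_unit: float = 1.0
    densities: dict[int, float] = field(default_factory=dict)  # g/cm^3 per label

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.origin = np.asarray(self.origin, float)

    def bounds(self):
        return self.origin, self.origin + self.spacing * np.array(self.labels.shape)

    def label_at(self, points: np.ndarray) -> np.ndarray:
        idx = np.floor((points - self.origin) / self.spacing).astype(int)
        idx = np.clip(idx, 0, np.array(self.labels.shape) - 1)
        return self.labels[idx[:, 0], idx[:, 1], idx[:, 2]]

    def region_volume_fractions(self, include_void: bool = False) -> dict[int, float]:
        labels, counts = np.unique(self.labels, return_counts=True)
        sel = {int(l): int(c) for l, c in zip(labels, counts) if include_void or l != VOID}
        total = sum(sel.values())
        return {l: c / total for l, c in sel.items()}

    @classmethod
    def from_classifier(cls, classify, lo, hi, shape, name_to_label, mm_per_unit=1.0, densities=None):
        """Build by classifying voxel centers; classify returns names ('' = void)."""
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        shape = tuple(int(s) for s in shape)
        spacing = float((hi - lo).max() / max(shape))
        axes = [lo[i] + spacing * (np.arange(shape[i]) + 0.5) for i in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        names = classify(pts)
        labels = np.zeros(len(pts), np.int16)
        for name, lbl in name_to_label.items():
            labels[names == name] = lbl
        region_names = {v: k for k, v in name_to_label.items()}
        return cls(labels.reshape(shape), lo, spacing, region_names, mm_per_unit, densities or {})

    @classmethod
    def from_tetmesh(cls, mesh: TetMesh, shape=(64, 64, 64), mm_per_unit=1.0, densities=None):
        """Rasterize per-tetrahedron region labels onto a voxel grid."""
        lo, hi = mesh.bounds()
        shape = tuple(int(s) for s in shape)
        spacing = float((hi - lo).max() / max(shape))
        labels = np.zeros(shape, int)
        corners = mesh.nodes[mesh.elements]
        for tet, lbl in zip(corners, mesh.labels):
            tlo = np.maximum(np.floor((tet.min(axis=0) - lo) / spacing).astype(int), 0)
            thi = np.minimum(np.floor((tet.max(axis=0) - lo) / spacing).astype(int) + 1, shape)
            if (thi <= tlo).any():
                continue
            axes = [lo[i] + spacing * (np.arange(tlo[i], thi[i]) + 0.5) for i in range(3)]
            gx, gy, gz = np.meshgrid(*axes, indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
            T = np.column_stack([tet[1] - tet[0], tet[2] - tet[0], tet[3] - tet[0]])
            try:
                bary = np.linalg.solve(T, (pts - tet[0]).T).T
            except np.linalg.LinAlgError:
                continue
            inside = (bary >= -1e-12).all(axis=1) & (bary.sum(axis=1) <= 1 + 1e-12)
            sub = labels[tlo[0]:thi[0], tlo[1]:thi[1], tlo[2]:thi[2]]
            m = inside.reshape(sub.shape)
            sub[m] = lbl
        region_names = dict(mesh.region_names)
        return cls(labels, lo, spacing, region_names, mm_per_unit, densities or {})

    @classmethod
    def from_labeled_meshes(cls, ms: LabeledMeshSet, shape=(64, 64, 64), name_to_label=None, mm_per_unit=1e-3, densities=None):
        """Voxelize a labeled component set (default units: um).

        Each convex part only rasterizes its own bounding-box subgrid, so the
        cost scales with total component volume, not grid size x part count.
        """
        names = ms.component_names()
        if name_to_label is None:
            name_to_label = {n: i + 1 for i, n in enumerate(names)}
        lo, hi = ms.domain.bounds()
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        shape = tuple(int(s) for s in shape)
        spacing = float((hi - lo).max() / max(shape))
        axes = [lo[i] + spacing * (np.arange(shape[i]) + 0.5) for i in range(3)]
        labels = np.zeros(shape, np.int16)
        if ms.fill is not None:
            gx, gy, gz = np.meshgrid(*axes, indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
            labels.ravel()[ms.domain.contains(pts)] = name_to_label[ms.fill]
            del gx, gy, gz, pts
        for name, parts in ms.components.items():
            lbl = name_to_label[name]
            for part in parts:
                plo, phi = part.bounds()
                i0 = np.maximum(np.floor((plo - lo) / spacing - 0.5).astype(int), 0)
                i1 = np.minimum(np.ceil((phi - lo) / spacing + 0.5).astype(int), shape)
                if (i1 <= i0).any():
                    continue
                sub_axes = [axes[k][i0[k]:i1[k]] for k in range(3)]
                gx, gy, gz = np.meshgrid(*sub_axes, indexing="ij")
                pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
                hit = part.contains(pts).reshape(gx.shape)
                sub = labels[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
                sub[hit] = lbl
        region_names = {v: k for k, v in name_to_label.items()}
        return cls(labels, lo, spacing, region_names, mm_per_unit, densities or {})


@dataclass
class TransportConfig:
    n: int
    seed: int = 0
    boundary_mode: str = "escape"  # or "reflective"
    source_region: int | str = 1
    steps_per_range: float = 4.0
    max_steps: int = 4000
    chunk: int = 20_000

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one history")
        if self.boundary_mode not in ("escape", "reflective"):
            raise ValueError("boundary_mode must be 'escape' or 'reflective'")


@dataclass
class EnergyDepositTally:
    region_energy: dict[int, float]  # MeV total
    rel_err: dict[int, float]
    emitted: float  # MeV total
    n_histories: int
    region_names: dict[int, str] = field(default_factory=dict)

    def absorbed_fraction(self, region) -> float:
        return self.region_energy.get(self._lbl(region), 0.0) / self.emitted

    def _lbl(self, region) -> int:
        if isinstance(region, str):
            for lbl, name in self.region_names.items():
                if name == region:
                    return lbl
            raise KeyError(region)
        return int(region)

    def check_conservation(self, reflective: bool) -> None:
        tot = sum(self.region_energy.values())
        if reflective:
            if abs(tot - self.emitted) > 1e-9 * self.emitted:
                raise AssertionError("reflective run lost energy")
        elif tot > self.emitted * (1 + 1e-9):
            raise AssertionError("deposited more energy than emitted")


# ---------------------------------------------------------------------------
# the transport loop
# ---------------------------------------------------------------------------

def _isotropic_directions(rng, n):
    z = rng.uniform(-1, 1, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(1 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _fold(points, lo, hi):
    """Mirror coordinates into [lo, hi] (reflective boundary)."""
    span = hi - lo
    y = np.mod(points - lo, 2 * span)
    return lo + span - np.abs(span - y)


def _sample_source_points(geometry, source, n, rng, tet_source: TetMesh | None):
    if tet_source is not None:
        from .tetmesh import sample_points

        return sample_points(tet_source, source, n, seed=int(rng.integers(2**31)))
    inv = {v: k for k, v in geometry.region_names.items()}

    def to_label(x):
        if isinstance(x, str):
            if x not in inv:
                raise ValueError(f"unknown source region {x!r}")
            return inv[x]
        return int(x)

    if isinstance(source, (list, tuple, set)):
        lbls = [to_label(x) for x in source]
        vox = np.argwhere(np.isin(geometry.labels, lbls))
    else:
        vox = np.argwhere(geometry.labels == to_label(source))
    if len(vox) == 0:
        raise ValueError(f"source region {source!r} is empty")
    pick = vox[rng.integers(0, len(vox), n)]
    return geometry.origin + geometry.spacing * (pick + rng.random((n, 3)))


def run_transport(
    geometry,
    particle: ParticleSpec,
    cfg: TransportConfig,
    tet_source: TetMesh | None = None,
    grid_shape=(64, 64, 64),
) -> EnergyDepositTally:
    """Score energy deposited per region for ``cfg.n`` primary histories.

    ``geometry`` may be a VoxelGeometry, a labeled TetMesh, or a
    LabeledMeshSet (the latter two are voxelized at ``grid_shape``).  Source
    points are drawn uniformly from the source region (exactly, via
    barycentric sampling, when ``tet_source`` is given).
    """
    if isinstance(geometry, TetMesh):
        tet_source = geometry if tet_source is None else tet_source
        geometry = VoxelGeometry.from_tetmesh(geometry, grid_shape)
    elif isinstance(geometry, LabeledMeshSet):
        geometry = VoxelGeometry.from_labeled_meshes(geometry, grid_shape)
    if not isinstance(geometry, VoxelGeometry):
        raise TypeError("geometry must be VoxelGeometry, TetMesh, or LabeledMeshSet")

    rng = np.random.default_rng(cfg.seed)
    labels_present = np.unique(geometry.labels)
    n_lbl = int(labels_present.max()) + 1
    sum_e = np.zeros(n_lbl)
    sum_e2 = np.zeros(n_lbl)
    E = particle.energy_MeV
    lo, hi = geometry.bounds()

    done = 0
    while done < cfg.n:
        m = min(cfg.chunk, cfg.n - done)
        p0 = _sample_source_points(geometry, cfg.source_region, m, rng, tet_source)
        dirs = _isotropic_directions(rng, m)
        if particle.kind in ("alpha", "electron"):
            dep = _charged_chunk(geometry, particle, cfg, p0, dirs, n_lbl, lo, hi)
        else:
            dep = _photon_chunk(geometry, particle, cfg, p0, dirs, n_lbl, lo, hi, rng)
        sum_e += dep.sum(axis=0)
        sum_e2 += (dep**2).sum(axis=0)
        done += m

    n = cfg.n
    mean = sum_e / n
    var = np.maximum(sum_e2 / n - mean**2, 0.0)
    sem = np.sqrt(var / n)
    rel = np.divide(sem, mean, out=np.zeros_like(sem), where=mean > 0)
    region_energy = {int(l): float(sum_e[l]) for l in labels_present if sum_e[l] > 0 or l != VOID}
    rel_err = {int(l): float(rel[l]) for l in region_energy}
    return EnergyDepositTally(region_energy, rel_err, emitted=n * E, n_histories=n, region_names=dict(geometry.region_names))


def _charged_chunk(geom, particle, cfg, p0, dirs, n_lbl, lo, hi):
    m = len(p0)
    track = particle.csda_range_mm() / geom.mm_per_unit
    n_steps = int(np.clip(np.ceil(cfg.steps_per_range * track / geom.spacing), 10, cfg.max_steps))
    de = particle.energy_MeV / n_steps
    dep = np.zeros((m, n_lbl))
    ts = (np.arange(n_steps) + 0.5) / n_steps * track
    alive = np.ones(m, bool)
    for t in ts:
        pts = p0 + t * dirs
        if cfg.boundary_mode == "reflective":
            pts = _fold(pts, lo, hi)
            lab = geom.label_at(pts)
            np.add.at(dep, (np.arange(m), lab), de)
        else:
            inside = alive & ((pts > lo) & (pts < hi)).all(axis=1)
            alive &= inside  # a straight ray cannot re-enter the convex box
            if not alive.any():
                break
            idx = np.flatnonzero(inside)
            lab = geom.label_at(pts[idx])
            np.add.at(dep, (idx, lab), de)
    if cfg.boundary_mode == "escape":
        dep[:, VOID] = 0.0  # void deposits are escapes
    return dep


def _photon_chunk(geom, particle, cfg, p0, dirs, n_lbl, lo, hi, rng):
    m = len(p0)
    dep = np.zeros((m, n_lbl))
    labels_present = np.unique(geom.labels)
    mu = np.zeros(n_lbl)
    for l in labels_present:
        if l == VOID:
            continue
        rho = geom.densities.get(int(l), 1.0)
        mu[l] = particle.mu_per_mm(rho) * geom.mm_per_unit
    mu_max = mu.max()
    if mu_max <= 0:
        raise ValueError("photon transport needs at least one attenuating region")
    pos = p0.copy()
    d = dirs.copy()
    active = np.ones(m, bool)
    for _ in range(100_000):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        step = rng.exponential(1.0 / mu_max, size=len(idx))
        pos[idx] += step[:, None] * d[idx]
        if cfg.boundary_mode == "reflective":
            # rays fly straight in unfolded space; collision points are folded
            # back into the box (exact for mirror-tiled geometry)
            lookup = _fold(pos[idx], lo, hi)
        else:
            out = ~((pos[idx] > lo) & (pos[idx] < hi)).all(axis=1)
            active[idx[out]] = False
            idx = idx[~out]
            if len(idx) == 0:
                continue
            lookup = pos[idx]
        lab = geom.label_at(lookup)
        accept = rng.random(len(idx)) < mu[lab] / mu_max
        hit = idx[accept]
        dep[hit, lab[accept]] = particle.energy_MeV
        active[hit] = False
    if cfg.boundary_mode == "escape":
        dep[:, VOID] = 0.0
    return dep


# ---------------------------------------------------------------------------
# absorbed fractions
# ---------------------------------------------------------------------------

def estimate_absorbed_fractions(
    tally: EnergyDepositTally,
    grouping: dict,
    scale: str,
    source_group: str,
    particle: ParticleSpec,
) -> pd.DataFrame:
    """Group tallied regions and emit AF rows in the interchange schema.

    ``grouping`` maps region (label or name) -> target group name; every
    tallied non-void region must be covered.  Relative errors combine in
    quadrature across the grouped regions.
    """
    if tally.emitted <= 0:
        raise ValueError("no emitted energy")
    lbl_group = {}
    for region, grp in grouping.items():
        lbl_group[tally._lbl(region)] = grp
    for lbl in tally.region_energy:
        if lbl != VOID and lbl not in lbl_group:
            raise ValueError(f"region {lbl} ({tally.region_names.get(lbl)}) not covered by grouping")
    rows = []
    for grp in sorted(set(lbl_group.values())):
        e = sum(tally.region_energy.get(l, 0.0) for l, g in lbl_group.items() if g == grp)
        err2 = sum(
            (tally.region_energy.get(l, 0.0) * tally.rel_err.get(l, 0.0)) ** 2
            for l, g in lbl_group.items()
            if g == grp
        )
        af = e / tally.emitted
        rows.append(
            {
                "scale": scale,
                "source": source_group,
                "target": grp,
                "particle": particle.kind,
                "energy_MeV": particle.energy_MeV,
                "af": af,
                "rel_err": np.sqrt(err2) / e if e > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


AF_COLUMNS = ["scale", "source", "target", "particle", "energy_MeV", "af", "rel_err"]


def write_af_table(df: pd.DataFrame, path) -> None:
    df[AF_COLUMNS].to_csv(path, index=False)


def read_af_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(AF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"AF table missing columns: {sorted(missing)}")
    return df
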