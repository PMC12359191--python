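"""Fully resolvable two-scale toy organ for validating the coupling math.

Macro model: a sphere (radius 0.4 mm) carrying three orthogonal "vessel"
cylinders (macro blood, LBM) in composite tissue (LCTM), inside an escaping
bounding box.  Micro model: a cubic unit cell (period 0.06 mm) with one
axial capillary cylinder (micro blood, LBmu) in parenchyma (LP), reflective.
Direct model: the same sphere with the capillary pattern tiled throughout the
composite tissue, so absorbed fractions between total blood and parenchyma
can be measured outright and compared against macro+micro coupling.

All densities are 1, so mass ratios equal voxel-count ratios on the direct
grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from vasodose.coupling import assemble_coupled_curves
from vasodose.masses import MassTable
from vasodose.transport import (
    TransportConfig,
    VoxelGeometry,
    estimate_absorbed_fractions,
    monoenergetic,
    run_transport,
)

R_SPHERE = 0.4  # mm
CENTER = 0.5
# thin macro vessels keep phi_M(LBM<-LCTM) small, where the printed
# source-mass-scaled micro-blood pickup term is a good approximation
R_VESSEL = 0.02  # mm, macro cylinders
PERIOD = 0.06  # mm, micro cell
R_CAP = 0.015  # mm, micro capillary radius

# direct voxel = 1/200 mm so the micro period is exactly 12 voxels and the
# capillary pattern discretizes identically on the direct and micro grids
DIRECT_SHAPE = (200, 200, 200)
MICRO_SHAPE = (12, 12, 12)


def _in_macro_vessels(pts: np.ndarray) -> np.ndarray:
    p = pts - CENTER
    hit = np.zeros(len(pts), bool)
    for axis in range(3):
        other = [i for i in range(3) if i != axis]
        hit |= (p[:, other[0]] ** 2 + p[:, other[1]] ** 2) < R_VESSEL**2
    return hit


def _in_micro_blood(pts: np.ndarray) -> np.ndarray:
    # capillary along z at the center of each tiling cell
    x = np.mod(pts[:, 0], PERIOD) - PERIOD / 2
    y = np.mod(pts[:, 1], PERIOD) - PERIOD / 2
    return (x**2 + y**2) < R_CAP**2


def _in_sphere(pts: np.ndarray) -> np.ndarray:
    return ((pts - CENTER) ** 2).sum(axis=1) < R_SPHERE**2


def macro_geometry(shape=DIRECT_SHAPE) -> VoxelGeometry:
    def classify(pts):
        out = np.full(len(pts), "", dtype=object)
        ins = _in_sphere(pts)
        out[ins] = "LCTM"
        out[ins & _in_macro_vessels(pts)] = "LBM"
        return out

    return VoxelGeometry.from_classifier(classify, (0, 0, 0), (1, 1, 1), shape, {"LBM": 1, "LCTM": 2})


def reflective_macro_geometry(shape=(96, 96, 96)) -> VoxelGeometry:
    """Box-filling uniform-composition variant (no void) for reciprocity runs."""

    def classify(pts):
        return np.where(_in_macro_vessels(pts), "LBM", "LCTM")

    return VoxelGeometry.from_classifier(classify, (0, 0, 0), (1, 1, 1), shape, {"LBM": 1, "LCTM": 2})


def micro_geometry(shape=MICRO_SHAPE) -> VoxelGeometry:
    def classify(pts):
        return np.where(_in_micro_blood(pts), "LBmu", "LP")

    return VoxelGeometry.from_classifier(
        classify, (0, 0, 0), (PERIOD, PERIOD, PERIOD), shape, {"LBmu": 1, "LP": 2}
    )


def direct_geometry(shape=DIRECT_SHAPE) -> VoxelGeometry:
    def classify(pts):
        out = np.full(len(pts), "", dtype=object)
        ins = _in_sphere(pts)
        micro = _in_micro_blood(pts)
        out[ins] = "LP"
        out[ins & micro] = "LBmu"
        out[ins & _in_macro_vessels(pts)] = "LBM"
        return out

    return VoxelGeometry.from_classifier(
        classify, (0, 0, 0), (1, 1, 1), shape, {"LBM": 1, "LBmu": 2, "LP": 3}
    )


def mass_table_from_direct(direct: VoxelGeometry) -> MassTable:
    """Unit-density masses from direct-grid voxel counts (grams ~ mm^3)."""
    counts = {direct.region_names[l]: c for l, c in zip(*np.unique(direct.labels, return_counts=True)) if l != 0}
    v = direct.spacing**3
    mLBM = counts["LBM"] * v
    mLBmu = counts["LBmu"] * v
    mLP = counts["LP"] * v
    return MassTable(
        mL=mLBM + mLBmu + mLP,
        mLB=mLBM + mLBmu,
        mLP=mLP,
        mLBM=mLBM,
        mLCTM=mLBmu + mLP,
        mLBmu=mLBmu,
    )


def mass_table_for_reflective(macro_full: VoxelGeometry, micro: VoxelGeometry) -> MassTable:
    """Masses consistent with the box-filling macro grid + micro pattern."""
    v = macro_full.spacing**3
    counts = dict(zip(*np.unique(macro_full.labels, return_counts=True)))
    inv = {n: l for l, n in macro_full.region_names.items()}
    mLBM = counts[inv["LBM"]] * v
    mLCTM = counts[inv["LCTM"]] * v
    f_u = micro.region_volume_fractions()[1]  # micro blood fraction
    mLBmu = f_u * mLCTM
    mLP = mLCTM - mLBmu
    return MassTable(
        mL=mLBM + mLCTM, mLB=mLBM + mLBmu, mLP=mLP, mLBM=mLBM, mLCTM=mLCTM, mLBmu=mLBmu
    )


def _af(tally, grouping, scale, source, particle):
    return estimate_absorbed_fractions(tally, grouping, scale, source, particle)


def scale_af_tables(
    particle_kind: str,
    energy: float,
    n: int,
    seed: int,
    macro_geo: VoxelGeometry,
    micro_geo: VoxelGeometry,
    macro_mode: str = "escape",
) -> pd.DataFrame:
    """Run the four per-scale source simulations and emit one AF table."""
    p = monoenergetic(particle_kind, energy)
    frames = []
    for src in ("LBM", "LCTM"):
        cfg = TransportConfig(n=n, seed=seed, boundary_mode=macro_mode, source_region=src)
        tally = run_transport(macro_geo, p, cfg)
        frames.append(_af(tally, {"LBM": "LBM", "LCTM": "LCTM"}, "macro", src, p))
        seed += 1
    for src in ("LBmu", "LP"):
        cfg = TransportConfig(n=n, seed=seed, boundary_mode="reflective", source_region=src)
        tally = run_transport(micro_geo, p, cfg)
        frames.append(_af(tally, {"LBmu": "LBmu", "LP": "LP"}, "micro", src, p))
        seed += 1
    return pd.concat(frames, ignore_index=True)


def direct_af(particle_kind: str, energy: float, n: int, seed: int, direct_geo: VoxelGeometry):
    """Directly measured phi for LB and LP sources on the resolved geometry.

    Returns {(target, source): (af, sigma)} with target/source in {LB, LP}.
    """
    p = monoenergetic(particle_kind, energy)
    grouping = {"LBM": "LB", "LBmu": "LB", "LP": "LP"}
    out = {}
    for source_regions, src_name in ((("LBM", "LBmu"), "LB"), (("LP",), "LP")):
        cfg = TransportConfig(n=n, seed=seed, boundary_mode="escape", source_region=list(source_regions))
        tally = run_transport(direct_geo, p, cfg)
        df = _af(tally, grouping, "direct", src_name, p)
        for _, row in df.iterrows():
            out[(row["target"], src_name)] = (row["af"], row["af"] * row["rel_err"])
        seed += 1
    return out


def coupled_af(af_table: pd.DataFrame, mt: MassTable):
    """Coupled composite phi plus a quadrature sigma per combination."""
    rows = assemble_coupled_curves(af_table, mt)
    assert len(rows) == 1
    r = rows[0]

    def sig(scale, source, target):
        sel = af_table[
            (af_table["scale"] == scale) & (af_table["source"] == source) & (af_table["target"] == target)
        ]
        return float(sel["af"].iloc[0] * sel["rel_err"].iloc[0])

    # first-order error propagation through the dominant product terms
    sigma = {
        ("LP", "LB"): np.hypot(sig("macro", "LBM", "LCTM"), sig("micro", "LBmu", "LP")),
        ("LB", "LP"): np.hypot(sig("micro", "LP", "LBmu"), sig("macro", "LCTM", "LBM")),
        ("LP", "LP"): np.hypot(sig("micro", "LP", "LP"), sig("macro", "LCTM", "LCTM")),
        ("LB", "LB"): np.hypot(sig("macro", "LBM", "LBM"), sig("micro", "LBmu", "LBmu")),
    }
    phi = {
        ("LP", "LB"): r.phi_LP_LB,
        ("LB", "LP"): r.phi_LB_LP,
        ("LP", "LP"): r.phi_LP_LP,
        ("LB", "LB"): r.phi_LB_LB,
    }
    Phi = {
        ("LP", "LB"): r.Phi_LP_LB_kg,
        ("LB", "LP"): r.Phi_LB_LP_kg,
        ("LP", "LP"): r.Phi_LP_LP_kg,
        ("LB", "LB"): r.Phi_LB_LB_kg,
    }
    return phi, Phi, sigma
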