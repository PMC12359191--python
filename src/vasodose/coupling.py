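"""Coupling of macroscale and microscale absorbed fractions.

Domains: LBM (macroscale vessel blood), LCTM (composite tissue around the
macroscale vessels), LBmu (microscale blood), LP (bloodless parenchyma);
LB = LBM + LBmu.  Macroscale transport yields phi_M rows between LBM and
LCTM with particle escape; microscale transport yields phi_mu rows between
LBmu and LP under reflective (infinite-tiling) boundaries.  The coupling
multiplies each microscale result by the macroscale composite-tissue
self-absorption (accounting for energy that escapes LCTM, which the infinite
tiling cannot see), rescales subdomain targets by mass ratios, and
mass-weights the macro/micro blood source contributions.

All operations act per (particle, energy) row; specific absorbed fractions
divide by the target mass in kg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masses import MassTable

log = logging.getLogger(__name__)

G_PER_KG = 1000.0

#: photon energy (MeV) above which microscale AFs equal volume fractions
PHOTON_VOLUME_FRACTION_THRESHOLD_MEV = 0.150


def _check_unit(name: str, *values: float) -> None:
    for v in values:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}: absorbed fraction {v} outside [0, 1]")


@dataclass(frozen=True)
class CoupledRow:
    """Composite absorbed fractions / SAFs for one (particle, energy)."""

    particle: str
    energy_MeV: float
    phi_LB_LB: float
    phi_LB_LP: float
    phi_LP_LB: float
    phi_LP_LP: float
    Phi_LB_LB_kg: float
    Phi_LB_LP_kg: float
    Phi_LP_LB_kg: float
    Phi_LP_LP_kg: float


def crossfire_P_from_B(
    phiM_LCTM_LBM: float,
    phimu_LP_LBmu: float,
    phiM_LCTM_LCTM: float,
    mt: MassTable,
) -> tuple[float, float]:
    """phi(LP <- LB) and Phi(LP <- LB) [1/kg]: blood-to-parenchyma crossfire.

    The macroscale contribution scales the composite-tissue target down to
    its parenchyma subdomain by mLP/mLCTM; the microscale contribution is
    attenuated by the macroscale composite-tissue self-absorption; the two
    are then source-mass-weighted by mLBM/mLB and mLBmu/mLB.
    """
    _check_unit("crossfire_P_from_B", phiM_LCTM_LBM, phimu_LP_LBmu, phiM_LCTM_LCTM)
    phi_LP_LBM = phiM_LCTM_LBM * mt.mLP / mt.mLCTM
    phi_LP_LBmu = phimu_LP_LBmu * phiM_LCTM_LCTM
    phi = phi_LP_LBM * mt.mLBM / mt.mLB + phi_LP_LBmu * mt.mLBmu / mt.mLB
    return phi, phi / (mt.mLP / G_PER_KG)


def crossfire_B_from_P(
    phimu_LBmu_LP: float,
    phiM_LCTM_LCTM: float,
    phiM_LBM_LCTM: float,
    mt: MassTable,
) -> tuple[float, float]:
    """phi(LB <- LP) and Phi(LB <- LP): parenchyma-to-blood crossfire.

    Both blood targets share the same source geometry and are disjoint, so
    their absorbed fractions add directly.
    """
    _check_unit("crossfire_B_from_P", phimu_LBmu_LP, phiM_LCTM_LCTM, phiM_LBM_LCTM)
    phi = phimu_LBmu_LP * phiM_LCTM_LCTM + phiM_LBM_LCTM
    if phi > 1.0 + 1e-12:
        raise ValueError(f"phi(LB<-LP) = {phi} > 1: inconsistent AF inputs")
    return phi, phi / (mt.mLB / G_PER_KG)


def parenchyma_self(
    phimu_LP_LP: float,
    phiM_LCTM_LCTM: float,
    mt: MassTable,
) -> tuple[float, float]:
    """phi(LP <- LP) and Phi(LP <- LP): microscale self-dose attenuated by
    macroscale composite-tissue escape."""
    _check_unit("parenchyma_self", phimu_LP_LP, phiM_LCTM_LCTM)
    phi = phimu_LP_LP * phiM_LCTM_LCTM
    return phi, phi / (mt.mLP / G_PER_KG)


def blood_self(
    phiM_LBM_LBM: float,
    phiM_LCTM_LBM: float,
    phiM_LBM_LCTM: float,
    phimu_LBmu_LBmu: float,
    phiM_LCTM_LCTM: float,
    mt: MassTable,
) -> tuple[float, float]:
    """phi(LB <- LB) and Phi(LB <- LB): blood self-dose from both scales.

    Macroscale blood source: direct vessel self-absorption plus the slice of
    composite-tissue deposition belonging to microscale blood (mLBmu/mLCTM).
    Microscale blood source: macroscale vessel pickup from the composite
    tissue (same mass slice) plus the attenuated microscale self-term.  The
    two sources are then mass-weighted.
    """
    _check_unit(
        "blood_self", phiM_LBM_LBM, phiM_LCTM_LBM, phiM_LBM_LCTM, phimu_LBmu_LBmu, phiM_LCTM_LCTM
    )
    phi_LB_LBM = phiM_LBM_LBM + phiM_LCTM_LBM * mt.mLBmu / mt.mLCTM
    phi_LB_LBmu = phiM_LBM_LCTM * mt.mLBmu / mt.mLCTM + phimu_LBmu_LBmu * phiM_LCTM_LCTM
    phi = phi_LB_LBM * mt.mLBM / mt.mLB + phi_LB_LBmu * mt.mLBmu / mt.mLB
    if phi > 1.0 + 1e-12:
        raise ValueError(f"phi(LB<-LB) = {phi} > 1: inconsistent AF inputs")
    return phi, phi / (mt.mLB / G_PER_KG)


def whole_liver_af(row: CoupledRow) -> tuple[float, float]:
    """phi(L <- LB) and phi(L <- LP): whole-organ target sums."""
    phi_L_LB = row.phi_LB_LB + row.phi_LP_LB
    phi_L_LP = row.phi_LB_LP + row.phi_LP_LP
    for name, v in (("phi(L<-LB)", phi_L_LB), ("phi(L<-LP)", phi_L_LP)):
        if v > 1.0 + 1e-9:
            raise ValueError(f"{name} = {v} > 1: unphysical inputs")
    return phi_L_LB, phi_L_LP


def macro_only_saf(
    phiM_LCTM_LBM: float,
    phiM_LCTM_LCTM: float,
    mt: MassTable,
) -> tuple[float, float]:
    """Single-scale comparator: Phi(LP<-LP) and Phi(LP<-LB) approximated from
    macroscale-only results, with fBV the macroscale share of liver blood."""
    _check_unit("macro_only_saf", phiM_LCTM_LBM, phiM_LCTM_LCTM)
    fBV = mt.mLBM / mt.mLB
    m_kg = mt.mLCTM / G_PER_KG
    Phi_pp = phiM_LCTM_LCTM / m_kg
    Phi_pb = (fBV * phiM_LCTM_LBM + (1.0 - fBV) * phiM_LCTM_LCTM) / m_kg
    return Phi_pp, Phi_pb


# ---------------------------------------------------------------------------
# table-level assembly
# ---------------------------------------------------------------------------

REQUIRED_MACRO = (("LCTM", "LBM"), ("LCTM", "LCTM"), ("LBM", "LCTM"), ("LBM", "LBM"))
REQUIRED_MICRO = (("LP", "LBmu"), ("LBmu", "LP"), ("LP", "LP"), ("LBmu", "LBmu"))


def _af_lookup(df: pd.DataFrame, scale: str, source: str, target: str, particle: str, energy: float) -> float:
    sel = df[
        (df["scale"] == scale)
        & (df["source"] == source)
        & (df["target"] == target)
        & (df["particle"] == particle)
        & (np.isclose(df["energy_MeV"], energy, rtol=1e-9, atol=0.0))
    ]
    if len(sel) == 0:
        raise KeyError(
            f"missing AF row (scale={scale}, source={source}, target={target}, "
            f"particle={particle}, energy={energy} MeV)"
        )
    return float(sel["af"].iloc[0])


def assemble_coupled_curves(
    afs: pd.DataFrame,
    mt: MassTable,
    photon_threshold_MeV: float = PHOTON_VOLUME_FRACTION_THRESHOLD_MEV,
    region_volume_fractions: dict[str, float] | None = None,
    component_densities: dict[str, float] | None = None,
) -> list[CoupledRow]:
    """Run the four coupling operations over every (particle, energy) in a
    combined macro+micro AF table.

    For photons above the threshold the microscale AFs are replaced by the
    corresponding target-region volume fractions (``region_volume_fractions``
    keyed 'LP'/'LBmu') before coupling.  Energies must match exactly between
    the two scales; no interpolation happens here.
    """
    if component_densities:
        vals = list(component_densities.values())
        if max(vals) / min(vals) > 1.02:
            log.warning(
                "component densities differ by more than 2%%; equal-density "
                "mass scaling in the coupling is approximate"
            )
    rows = []
    for (particle, energy), _ in afs.groupby(["particle", "energy_MeV"], sort=True):
        def M(src, tgt):
            return _af_lookup(afs, "macro", src, tgt, particle, energy)

        def U(src, tgt):
            if particle == "photon" and energy > photon_threshold_MeV:
                if region_volume_fractions is None:
                    raise ValueError(
                        "photon volume-fraction substitution requires region_volume_fractions"
                    )
                return region_volume_fractions[tgt]
            return _af_lookup(afs, "micro", src, tgt, particle, energy)

        phi_pb, Phi_pb = crossfire_P_from_B(M("LBM", "LCTM"), U("LBmu", "LP"), M("LCTM", "LCTM"), mt)
        phi_bp, Phi_bp = crossfire_B_from_P(U("LP", "LBmu"), M("LCTM", "LCTM"), M("LCTM", "LBM"), mt)
        phi_pp, Phi_pp = parenchyma_self(U("LP", "LP"), M("LCTM", "LCTM"), mt)
        phi_bb, Phi_bb = blood_self(
            M("LBM", "LBM"), M("LBM", "LCTM"), M("LCTM", "LBM"), U("LBmu", "LBmu"), M("LCTM", "LCTM"), mt
        )
        rows.append(
            CoupledRow(
                particle=particle,
                energy_MeV=float(energy),
                phi_LB_LB=phi_bb,
                phi_LB_LP=phi_bp,
                phi_LP_LB=phi_pb,
                phi_LP_LP=phi_pp,
                Phi_LB_LB_kg=Phi_bb,
                Phi_LB_LP_kg=Phi_bp,
                Phi_LP_LB_kg=Phi_pb,
                Phi_LP_LP_kg=Phi_pp,
            )
        )
    return rows


def coupled_rows_to_frame(rows: list[CoupledRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def write_coupled_csv(rows: list[CoupledRow], path) -> None:
    coupled_rows_to_frame(rows).to_csv(path, index=False)


def read_coupled_csv(path) -> list[CoupledRow]:
    df = pd.read_csv(path)
    return [CoupledRow(**rec) for rec in df.to_dict("records")]
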