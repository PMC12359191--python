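"""Mass ledger and elemental-composition arithmetic for the two-scale liver model.

The liver is partitioned into pure-blood and pure-parenchyma domains at two
spatial scales.  This module holds the reference mass table for those domains,
derives the parenchyma elemental composition by mass-balance subtraction of
macroscale blood from homogenized liver, and provides the blood-partition
bookkeeping used to split total organ blood between the explicitly meshed
macroscale vessels and the microscale lobule structures.

Compositions are stored as mass fractions in [0, 1]; reference tables print
percent, so the JSON readers accept a ``percent: true`` flag and convert at the
I/O boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np

ELEMENTS = ("H", "C", "N", "O", "Na", "P", "S", "Cl", "K", "Fe")

#: Blood-carrying compartments of the lobule (narrative assignment).
BLOOD_COMPARTMENTS = ("central_vein", "portal_arteries", "portal_veins", "sinusoids")

#: The nine lobule components, in reference-table order.
LOBULE_COMPONENTS = (
    "central_vein",
    "portal_arteries",
    "portal_veins",
    "bile_ducts",
    "bile_canaliculi",
    "sinusoids",
    "space_of_disse",
    "kupffer_cells",
    "hepatocytes",
)


class MassClosureError(ValueError):
    """A mass-table identity fails beyond the closure tolerance."""


@dataclass(frozen=True)
class MassTable:
    """Masses (g) of the liver domains.

    ``mL`` whole liver, ``mLB`` total liver blood, ``mLP`` bloodless
    parenchyma, ``mLBM`` macroscale vessel blood, ``mLCTM`` macroscale
    composite tissue (parenchyma + microscale blood), ``mLBmu`` microscale
    blood.
    """

    mL: float
    mLB: float
    mLP: float
    mLBM: float
    mLCTM: float
    mLBmu: float
    sex_label: str = ""

    def __post_init__(self) -> None:
        for name in ("mL", "mLB", "mLP", "mLBM", "mLCTM", "mLBmu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"mass {name} must be > 0, got {getattr(self, name)}")

    def closure_residuals(self) -> dict[str, float]:
        """Residuals (g) of the three partition identities."""
        return {
            "mLB = mLBM + mLBmu": self.mLB - (self.mLBM + self.mLBmu),
            "mL = mLB + mLP": self.mL - (self.mLB + self.mLP),
            "mLCTM = mL - mLBM": self.mLCTM - (self.mL - self.mLBM),
        }

    def validate(self, tol: float = 0.05) -> None:
        for name, res in self.closure_residuals().items():
            if abs(res) > tol:
                raise MassClosureError(f"identity {name!r} violated by {res:.4g} g (tol {tol} g)")


@dataclass(frozen=True)
class ElementalComposition:
    """Elemental mass fractions (dimensionless, sum 1) plus a density in g/cm^3."""

    fractions: Mapping[str, float]
    density: float
    name: str = ""

    def __post_init__(self) -> None:
        fr = dict(self.fractions)
        unknown = set(fr) - set(ELEMENTS)
        if unknown:
            raise ValueError(f"unknown elements: {sorted(unknown)}")
        vals = np.array([fr.get(e, 0.0) for e in ELEMENTS])
        if (vals < -1e-12).any():
            raise ValueError("negative elemental fraction")
        total = vals.sum()
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"fractions sum to {total:.6f}, expected 1 within 1e-3")
        object.__setattr__(self, "fractions", {e: fr.get(e, 0.0) for e in ELEMENTS})

    def as_array(self) -> np.ndarray:
        return np.array([self.fractions[e] for e in ELEMENTS])

    def renormalized(self) -> "ElementalComposition":
        arr = self.as_array()
        arr = arr / arr.sum()
        return replace(self, fractions=dict(zip(ELEMENTS, arr.tolist())))

    @classmethod
    def from_array(cls, arr, density: float, name: str = "") -> "ElementalComposition":
        return cls(fractions=dict(zip(ELEMENTS, np.asarray(arr, float).tolist())), density=density, name=name)


@dataclass(frozen=True)
class LobuleMassFractions:
    """Mass fractions of the nine lobule components (sum 1) and a total mass in g."""

    fractions: Mapping[str, float]
    total_mass: float

    def __post_init__(self) -> None:
        keys = set(self.fractions)
        if keys != set(LOBULE_COMPONENTS):
            missing = set(LOBULE_COMPONENTS) - keys
            extra = keys - set(LOBULE_COMPONENTS)
            raise ValueError(f"component set mismatch: missing {sorted(missing)}, extra {sorted(extra)}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"fractions sum to {total:.6f}, expected 1 within 1e-3")
        if self.total_mass <= 0:
            raise ValueError("total_mass must be > 0")

    def blood_fraction_of_lobule(self) -> float:
        return sum(self.fractions[c] for c in BLOOD_COMPARTMENTS)


# ---------------------------------------------------------------------------
# bundled reference fixtures
# ---------------------------------------------------------------------------

def _data_text(relname: str) -> str:
    return resources.files("vasodose.data").joinpath(relname).read_text()


def reference_mass_table(sex: str = "male") -> MassTable:
    """Bundled reference mass table for ``sex`` in {'male', 'female'}."""
    tables = json.loads(_data_text("mass_tables.json"))
    if sex not in tables:
        raise KeyError(f"sex must be one of {sorted(tables)}, got {sex!r}")
    return MassTable(**tables[sex])


def reference_composition(name: str) -> ElementalComposition:
    """Bundled reference composition: liver, blood, parenchyma_derived, plasma_lymph, cell."""
    data = json.loads(_data_text("elemental_compositions.json"))
    try:
        entry = data["compositions"][name]
    except KeyError:
        raise KeyError(f"no composition {name!r}; available: {sorted(data['compositions'])}") from None
    scale = 0.01 if data.get("percent") else 1.0
    fr = {e: v * scale for e, v in entry["fractions"].items()}
    return ElementalComposition(fractions=fr, density=entry["density"], name=name)


def reference_lobule_fractions() -> LobuleMassFractions:
    data = json.loads(_data_text("lobule_components.json"))
    scale = 0.01 if data.get("percent") else 1.0
    fr = {k: v["mass_fraction"] * scale for k, v in data["components"].items()}
    return LobuleMassFractions(fractions=fr, total_mass=data["total_mass_g"])


def reference_lobule_densities() -> dict[str, float]:
    data = json.loads(_data_text("lobule_components.json"))
    return {k: v["density"] for k, v in data["components"].items()}


def lobule_component_class(component: str) -> str:
    """'blood' or 'parenchyma' for a lobule component name."""
    data = json.loads(_data_text("lobule_components.json"))
    return data["components"][component]["class"]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def derive_parenchyma_composition(
    liver: ElementalComposition,
    blood: ElementalComposition,
    mL: float,
    mLBM: float,
    mLCTM: float,
    neg_tol: float = 1e-3,
) -> ElementalComposition:
    """Subtract macroscale blood from homogenized liver, element by element.

    Per element the absolute mass ``mL * w_liver - mLBM * w_blood`` is divided
    by the composite-tissue mass and the result renormalized to sum exactly 1.
    Trace elements present in blood but absent from the homogenized liver can
    go slightly negative under rounded table inputs; deficits of at most
    ``neg_tol`` (as a fraction of mL) are clipped to zero, larger ones raise,
    naming the element (inconsistent inputs).
    """
    if mL <= mLBM:
        raise ValueError(f"mL ({mL}) must exceed mLBM ({mLBM})")
    diff = mL * liver.as_array() - mLBM * blood.as_array()
    if (diff < -neg_tol * mL).any():
        bad = [e for e, d in zip(ELEMENTS, diff) if d < -neg_tol * mL]
        raise ValueError(f"negative elemental mass after subtraction for: {bad}")
    diff = np.clip(diff, 0.0, None)
    frac = diff / mLCTM
    frac = frac / frac.sum()
    return ElementalComposition.from_array(frac, density=liver.density, name="parenchyma_derived")


def blood_partition_summary(mt: MassTable) -> dict[str, float]:
    """Percent of total liver blood held at each scale.

    Returns ``{"macro_percent": ..., "micro_percent": ...}``; the two shares
    sum to 100 exactly (micro is computed as the complement).
    """
    if mt.mLB == 0:
        raise ValueError("mLB must be nonzero")
    macro = 100.0 * mt.mLBM / mt.mLB
    return {"macro_percent": macro, "micro_percent": 100.0 - macro}


def sinusoid_blood_share(mt: MassTable, lf: LobuleMassFractions) -> float:
    """Percent of total liver blood contained in the sinusoids.

    Microscale blood is split among the lobule blood compartments in
    proportion to their mass fractions; the sinusoid slice is then expressed
    as a percentage of total liver blood.
    """
    for key in BLOOD_COMPARTMENTS:
        if key not in lf.fractions:
            raise KeyError(f"missing lobule blood compartment {key!r}")
    blood_total = sum(lf.fractions[c] for c in BLOOD_COMPARTMENTS)
    sin_share = lf.fractions["sinusoids"] / blood_total
    return 100.0 * mt.mLBmu * sin_share / mt.mLB


def validate_closure(mt: MassTable, tol: float = 0.05) -> dict[str, dict]:
    """Report per-identity residuals and whether each passes ``tol``."""
    return {
        name: {"residual_g": res, "passes": abs(res) <= tol}
        for name, res in mt.closure_residuals().items()
    }


def solve_cell_composition(
    target: ElementalComposition,
    components: Mapping[str, tuple[float, ElementalComposition | None]],
    free_components: list[str] | tuple[str, ...],
) -> tuple[ElementalComposition, dict[str, float]]:
    """Solve for the single unknown composition shared by ``free_components``.

    ``components`` maps name -> (mass fraction, composition); entries named in
    ``free_components`` share one unknown composition (their composition value
    is ignored and may be None).  Per element, the unknown fraction is the
    least-squares (here: exact, single-unknown) solution of
    ``sum_i f_i w_i(e) = target(e)``; the unknown composition is then
    renormalized to sum 1.  Returns (composition, per-element residual of the
    forward mixture against the target).
    """
    free = list(free_components)
    f_free = sum(components[n][0] for n in free)
    if f_free <= 0:
        raise ValueError("free components must carry nonzero total mass fraction")
    known = np.zeros(len(ELEMENTS))
    for name, (f, comp) in components.items():
        if name in free:
            continue
        if comp is None:
            raise ValueError(f"known component {name!r} lacks a composition")
        known += f * comp.as_array()
    raw = (target.as_array() - known) / f_free
    raw = np.clip(raw, 0.0, None)
    solved = raw / raw.sum()
    density = target.density
    comp_out = ElementalComposition.from_array(solved, density=density, name="cell_solved")
    mix = known + f_free * solved
    residual = dict(zip(ELEMENTS, (mix - target.as_array()).tolist()))
    return comp_out, residual


def mix_compositions(
    parts: list[tuple[float, ElementalComposition]],
) -> ElementalComposition:
    """Mass-weighted mixture of compositions (weights need not sum to 1)."""
    w = np.array([p[0] for p in parts], float)
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    arr = sum(wi * c.as_array() for wi, c in parts) / w.sum()
    rho = sum(wi * c.density for wi, c in parts) / w.sum()
    return ElementalComposition.from_array(arr / arr.sum(), density=rho, name="mixture")


def read_mass_table(path) -> MassTable:
    with open(path) as fh:
        return MassTable(**json.load(fh))


def write_mass_table(mt: MassTable, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {k: getattr(mt, k) for k in ("mL", "mLB", "mLP", "mLBM", "mLCTM", "mLBmu", "sex_label")},
            fh,
            indent=1,
        )
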