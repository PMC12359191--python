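"""S-values and the clinical activity-partitioning workflow.

S(rT <- rS) = sum_i E_i Y_i Phi(rT <- rS, E_i), with Phi in 1/kg, E in MeV
and yields per nuclear transformation, converted to mGy/(MBq s).  Specific
absorbed fraction curves are resampled at decay energies with shape-
preserving piecewise cubic Hermite interpolation (on log10 energy by
default, since AF curves span decades); per-radiation-class subtotals are
kept so class-specific scaling (mass, RBE) remains possible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

#: MeV -> J, MBq -> 1/s, Gy -> mGy:  (1/kg) * MeV * 1.60218e-13 * 1e6 * 1e3
MEV_PER_KG_TO_MGY_PER_MBQ_S = 1.60218e-4

RADIATION_CLASSES = ("photon", "beta", "electron", "alpha", "alpha_recoil")

#: transport kind used for each radiation class
CLASS_TO_PARTICLE = {
    "photon": "photon",
    "beta": "electron",
    "electron": "electron",
    "alpha": "alpha",
    "alpha_recoil": "alpha",
}

PAIRS = ("LB_LB", "LB_LP", "LP_LB", "LP_LP")


@dataclass(frozen=True)
class DecayScheme:
    nuclide: str
    rows: tuple  # of (radiation_class, energy_MeV, yield)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("decay scheme has no rows")
        for cls, e, y in self.rows:
            if cls not in RADIATION_CLASSES:
                raise ValueError(f"unknown radiation class {cls!r}")
            if e <= 0 or y <= 0:
                raise ValueError(f"row ({cls}, {e}, {y}): energy and yield must be positive")

    def classes(self) -> list[str]:
        return sorted({r[0] for r in self.rows})


@dataclass
class SValueRow:
    """S-values (mGy/MBq/s) for the four source-target pairs of one nuclide,
    with per-radiation-class subtotals."""

    nuclide: str
    total: dict[str, float]
    by_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for pair in PAIRS:
            subtotal = sum(v[pair] for v in self.by_class.values())
            if self.total[pair] < 0:
                raise ValueError("negative S-value")
            if abs(subtotal - self.total[pair]) > 1e-12 * max(abs(self.total[pair]), 1e-300):
                raise ValueError(f"class subtotals do not sum to total for {pair}")


def interpolate_saf(
    energies: np.ndarray,
    saf: np.ndarray,
    query: np.ndarray,
    log_energy: bool = True,
):
    """Monotone-preserving cubic Hermite resampling of a SAF curve.

    Knots must be strictly increasing in energy; queries outside the knot
    range raise (no extrapolation).  With ``log_energy`` the interpolation
    abscissa is log10(energy).
    """
    e = np.asarray(energies, float)
    y = np.asarray(saf, float)
    q = np.atleast_1d(np.asarray(query, float))
    if len(e) < 2 or (np.diff(e) <= 0).any():
        raise ValueError("need >= 2 strictly increasing energy knots")
    if (q < e[0] - 1e-15).any() or (q > e[-1] + 1e-15).any():
        bad = q[(q < e[0] - 1e-15) | (q > e[-1] + 1e-15)]
        raise ValueError(f"query energies outside knot range [{e[0]}, {e[-1]}]: {bad}")
    x = np.log10(e) if log_energy else e
    xq = np.log10(q) if log_energy else q
    out = PchipInterpolator(x, y)(np.clip(xq, x[0], x[-1]))
    return out if np.ndim(query) else float(out[0])


def s_value(scheme: DecayScheme, saf_curves: dict) -> SValueRow:
    """S-values for one nuclide from per-class SAF curves.

    ``saf_curves`` maps radiation class -> pair -> (energies, Phi) arrays
    (Phi in 1/kg); a class may fall back to the curve of its transport
    particle (e.g. 'beta' rows use the 'electron' curves if no explicit beta
    entry exists).  Raises when a row's energy is not covered.
    """
    by_class: dict[str, dict[str, float]] = {}
    for cls, e, y in scheme.rows:
        curves = saf_curves.get(cls) or saf_curves.get(CLASS_TO_PARTICLE[cls])
        if curves is None:
            raise KeyError(f"no SAF curves for radiation class {cls!r}")
        acc = by_class.setdefault(cls, {p: 0.0 for p in PAIRS})
        for pair in PAIRS:
            knots_e, knots_phi = curves[pair]
            try:
                phi = interpolate_saf(knots_e, knots_phi, e)
            except ValueError as err:
                raise ValueError(f"decay row ({cls}, {e} MeV) not covered by SAF curve: {err}") from None
            acc[pair] += e * y * phi * MEV_PER_KG_TO_MGY_PER_MBQ_S
    total = {p: sum(v[p] for v in by_class.values()) for p in PAIRS}
    row = SValueRow(scheme.nuclide, total, by_class)
    row.validate()
    return row


@dataclass(frozen=True)
class ActivityModel:
    """Imaging-derived inputs: blood and organ activity concentrations
    (MBq/mL), blood-inclusive organ volume (mL) and fractional blood content."""

    C_blood: float
    C_organ: float
    V_organ: float
    f_blood: float

    def __post_init__(self) -> None:
        for name in ("C_blood", "C_organ", "V_organ", "f_blood"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.f_blood > 1:
            raise ValueError("f_blood must be <= 1")


def activity_partition(am: ActivityModel) -> tuple[float, float]:
    """A(LB) = C_blood * V * f_blood;  A(LP) = C_organ * V - A(LB)  [MBq]."""
    a_lb = am.C_blood * am.V_organ * am.f_blood
    a_lp = am.C_organ * am.V_organ - a_lb
    if a_lp < 0:
        raise ValueError(
            f"negative parenchyma activity ({a_lp:.4g} MBq): blood and organ "
            "concentrations are inconsistent"
        )
    return a_lb, a_lp


def dose_rate_parenchyma(
    A_LB: float,
    A_LP: float,
    sv: SValueRow,
    external_terms: float = 0.0,
) -> float:
    """Parenchyma dose rate (mGy/s): the organ self-dose term replaced by the
    separate blood-source and parenchyma-source contributions."""
    return external_terms + A_LP * sv.total["LP_LP"] + A_LB * sv.total["LP_LB"]


# ---------------------------------------------------------------------------
# decay scheme I/O
# ---------------------------------------------------------------------------

def read_decay_scheme(path) -> DecayScheme:
    """CSV with header ``nuclide,class,energy_MeV,yield``."""
    df = pd.read_csv(path)
    required = {"nuclide", "class", "energy_MeV", "yield"}
    if set(df.columns) < required:
        raise ValueError(f"decay CSV needs columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError("decay scheme file has no rows")
    nuclides = df["nuclide"].unique()
    if len(nuclides) != 1:
        raise ValueError(f"expected one nuclide per file, found {list(nuclides)}")
    rows = []
    for i, rec in df.iterrows():
        cls = str(rec["class"])
        if cls not in RADIATION_CLASSES:
            raise ValueError(f"line {i + 2}: unknown radiation class {cls!r}")
        try:
            e, y = float(rec["energy_MeV"]), float(rec["yield"])
        except (TypeError, ValueError):
            raise ValueError(f"line {i + 2}: malformed energy/yield") from None
        rows.append((cls, e, y))
    return DecayScheme(str(nuclides[0]), tuple(rows))


def write_decay_scheme(scheme: DecayScheme, path) -> None:
    pd.DataFrame(
        [{"nuclide": scheme.nuclide, "class": c, "energy_MeV": e, "yield": y} for c, e, y in scheme.rows]
    ).to_csv(path, index=False)


def bundled_decay_scheme(name: str) -> DecayScheme:
    """Bundled example schemes: 'y90_mean', 'at211_simple'."""
    path = resources.files("vasodose.data.decay").joinpath(f"{name}.csv")
    import io

    return read_decay_scheme(io.StringIO(path.read_text()))


def s_value_table_to_frame(rows: list[SValueRow]) -> pd.DataFrame:
    recs = []
    for r in rows:
        rec = {"nuclide": r.nuclide}
        rec.update({f"S_{p}": r.total[p] for p in PAIRS})
        recs.append(rec)
    return pd.DataFrame(recs)
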