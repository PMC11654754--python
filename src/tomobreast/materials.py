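"""Embedded linear-attenuation tables for the materials used by the toolkit.

Mass attenuation coefficients (cm^2/g) are anchored to standard reference
data at a handful of energies per element and log-log interpolated onto
the working grid (5-50 keV, 0.5 keV bin centers).  Elements with a
K-absorption edge inside the grid (Rh at 23.22 keV, Se at 12.66 keV) are
interpolated per branch so the discontinuity is preserved; compounds and
tissues use the mass-fraction mixture rule.  Anchor values are digitized
with limited (~few percent) precision — adequate for the ranking-level
and directional claims this package makes, not for regulatory dosimetry.

The resolved per-material mu-per-mm grid also ships as a packaged CSV
(``data/attenuation_mm.csv``); the in-memory tables are authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import LookupErrorTB

__all__ = [
    "ENERGY_GRID_KEV",
    "MaterialTable",
    "material_table",
    "mu_per_mm",
    "list_materials",
    "RH_K_EDGE_KEV",
    "SE_K_EDGE_KEV",
]

#: Bin centers of the working energy grid (keV).
ENERGY_GRID_KEV = np.arange(5.25, 50.0, 0.5)

RH_K_EDGE_KEV = 23.2199
SE_K_EDGE_KEV = 12.6578

# ---------------------------------------------------------------------------
# Element anchors: energy (keV) -> mass attenuation (cm^2/g).
# K-edge elements carry one anchor list per branch.

_ELEMENT_ANCHORS = {
    "H": [(5, 0.4193), (10, 0.3854), (15, 0.3764), (20, 0.3695),
          (30, 0.3570), (40, 0.3458), (50, 0.3355)],
    "C": [(5, 19.10), (8, 4.576), (10, 2.373), (15, 0.8071), (20, 0.4420),
          (30, 0.2562), (40, 0.2076), (50, 0.1871)],
    "N": [(5, 31.20), (10, 3.879), (15, 1.236), (20, 0.6178),
          (30, 0.3066), (40, 0.2288), (50, 0.1980)],
    "O": [(5, 46.40), (8, 11.63), (10, 5.952), (15, 1.836), (20, 0.8651),
          (30, 0.3779), (40, 0.2585), (50, 0.2132)],
    "Al": [(5, 193.4), (6, 115.3), (8, 50.33), (10, 26.23), (15, 7.955),
           (20, 3.441), (30, 1.128), (40, 0.5685), (50, 0.3681)],
    "Ca": [(5, 560.0), (8, 152.0), (10, 93.40), (15, 28.00), (20, 11.80),
           (30, 3.620), (40, 1.620), (50, 0.910)],
}

_EDGE_ELEMENT_ANCHORS = {
    "Rh": (
        RH_K_EDGE_KEV,
        [(5, 698.0), (10, 100.3), (15, 32.20), (20, 14.40), (RH_K_EDGE_KEV, 9.48)],
        [(RH_K_EDGE_KEV, 55.90), (30, 27.30), (40, 12.20), (50, 6.550)],
    ),
    "Se": (
        SE_K_EDGE_KEV,
        [(5, 425.0), (10, 57.00), (SE_K_EDGE_KEV, 28.70)],
        [(SE_K_EDGE_KEV, 172.0), (20, 45.60), (30, 14.10), (40, 6.100), (50, 3.200)],
    ),
}

# ---------------------------------------------------------------------------
# Material definitions: (density g/cm^3, {element: mass fraction}).

_MATERIALS: dict[str, tuple[float, dict[str, float]]] = {
    "Al": (2.699, {"Al": 1.0}),
    "Rh": (12.41, {"Rh": 1.0}),
    "a-Se": (4.28, {"Se": 1.0}),
    "calcium": (1.55, {"Ca": 1.0}),
    "PMMA": (1.19, {"H": 0.0805, "C": 0.5998, "O": 0.3196}),
    "adipose": (0.95, {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278}),
    "glandular": (1.02, {"H": 0.106, "C": 0.332, "N": 0.030, "O": 0.527}),
}


def _loglog_interp(anchors: list[tuple[float, float]], energies: np.ndarray) -> np.ndarray:
    e = np.log(np.array([a[0] for a in anchors]))
    v = np.log(np.array([a[1] for a in anchors]))
    return np.exp(np.interp(np.log(energies), e, v))


def _element_mass_attenuation(symbol: str, energies: np.ndarray) -> np.ndarray:
    if symbol in _ELEMENT_ANCHORS:
        return _loglog_interp(_ELEMENT_ANCHORS[symbol], energies)
    edge, below, above = _EDGE_ELEMENT_ANCHORS[symbol]
    out = np.empty_like(energies)
    lo = energies < edge
    out[lo] = _loglog_interp(below, energies[lo])
    out[~lo] = _loglog_interp(above, energies[~lo])
    return out


def _mixture_mass_attenuation(fractions: dict[str, float], energies: np.ndarray) -> np.ndarray:
    total = sum(fractions.values())
    out = np.zeros_like(energies)
    for sym, w in fractions.items():
        out += (w / total) * _element_mass_attenuation(sym, energies)
    return out


@dataclass(frozen=True)
class MaterialTable:
    """Linear attenuation mu(E) (1/mm) of one material on the working grid."""

    material: str
    density_g_cm3: float
    energy_keV: np.ndarray
    mu_per_mm: np.ndarray

    def mu_at(self, energy_keV: float) -> float:
        """Log-linear interpolation of mu at an arbitrary grid-range energy."""
        return float(
            np.exp(np.interp(energy_keV, self.energy_keV, np.log(self.mu_per_mm)))
        )


def list_materials() -> list[str]:
    names = set(_MATERIALS) | {"breast_50_50"}
    return sorted(names)


@lru_cache(maxsize=None)
def material_table(material: str) -> MaterialTable:
    """Resolve a material name to its attenuation table.

    ``breast_50_50`` is a 50/50 glandular/adipose mixture by mass.
    """
    energies = ENERGY_GRID_KEV
    if material == "breast_50_50":
        g = material_table("glandular")
        a = material_table("adipose")
        rho = 0.5 * (g.density_g_cm3 + a.density_g_cm3)
        mu_rho = 0.5 * (g.mu_per_mm / (g.density_g_cm3 / 10.0)) + 0.5 * (
            a.mu_per_mm / (a.density_g_cm3 / 10.0)
        )
        return MaterialTable(material, rho, energies, mu_rho * rho / 10.0)
    if material not in _MATERIALS:
        raise LookupErrorTB(
            f"unknown material {material!r}; known: {list_materials()}"
        )
    rho, fractions = _MATERIALS[material]
    mu_rho = _mixture_mass_attenuation(fractions, energies)  # cm^2/g
    return MaterialTable(material, rho, energies, mu_rho * rho / 10.0)


def mu_per_mm(material: str) -> np.ndarray:
    """Shorthand: mu(E) in 1/mm on :data:`ENERGY_GRID_KEV`."""
    return material_table(material).mu_per_mm


def export_csv(path) -> None:
    """Write the resolved mu-per-mm tables for all materials as CSV."""
    import pandas as pd

    data = {"energy_keV": ENERGY_GRID_KEV}
    for name in list_materials():
        data[name] = mu_per_mm(name)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6g")
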