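"""Enzyme-assay analytics and chemistry utilities.

Michaelis-Menten fitting of initial-rate data (nonlinear least squares),
end-point activity percentages, exact monoisotopic adduct m/z calculation
for HRMS, and the dinuclear-metal-site distance check on PDB coordinates.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConfigError, InvalidInputError, NotFoundError
from .io import PdbAtom

# ---------------------------------------------------------------------------
# Michaelis-Menten kinetics


@dataclass(frozen=True)
class KineticsDataset:
    """Initial-rate data: substrate concentrations (uM) vs rates (uM/s)."""

    substrate_conc: tuple[float, ...]
    rate: tuple[float, ...]
    enzyme_conc_nm: float  # nM

    def __post_init__(self) -> None:
        if len(self.substrate_conc) != len(self.rate):
            raise InvalidInputError("substrate_conc and rate must align")
        if len(self.substrate_conc) < 5:
            raise InvalidInputError("need >= 5 substrate levels")
        if any(s <= 0 for s in self.substrate_conc):
            raise InvalidInputError("substrate concentrations must be > 0")
        if self.enzyme_conc_nm <= 0:
            raise InvalidInputError("enzyme concentration must be > 0")


@dataclass(frozen=True)
class MMFit:
    """Fitted Michaelis-Menten parameters with propagated catalytic constants."""

    vmax: float  # uM/s
    km: float  # uM
    kcat: float  # 1/s
    kcat_over_km: float  # 1/(M s)
    se_vmax: float
    se_km: float
    converged: bool
    message: str = ""


def michaelis_menten(s, vmax, km):
    return vmax * s / (km + s)


def fit_mm(data: KineticsDataset, max_iter: int = 500) -> MMFit:
    """Unweighted least-squares fit of v = Vmax*S/(Km+S).

    Initialized at Vmax0 = max(v) and Km0 = the substrate level whose rate
    is closest to half-maximal. Non-convergence yields a flagged result, not
    an exception.
    """
    s = np.asarray(data.substrate_conc, dtype=float)
    v = np.asarray(data.rate, dtype=float)
    vmax0 = float(v.max())
    if vmax0 <= 0:
        return MMFit(*[float("nan")] * 6, converged=False, message="no positive rates")
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2.0))])
    try:
        popt, pcov = curve_fit(
            michaelis_menten,
            s,
            v,
            p0=[vmax0, km0],
            maxfev=max_iter * 10,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
        )
    except (RuntimeError, ValueError) as exc:
        return MMFit(*[float("nan")] * 6, converged=False, message=str(exc))
    vmax, km = float(popt[0]), float(popt[1])
    se = np.sqrt(np.diag(pcov))
    enzyme_um = data.enzyme_conc_nm * 1e-3
    kcat = vmax / enzyme_um
    kcat_over_km = kcat / (km * 1e-6) if km > 0 else float("inf")
    return MMFit(vmax, km, kcat, kcat_over_km, float(se[0]), float(se[1]), converged=True)


def relative_activity(test_product: float, control_product: float) -> float:
    """Percent product in the test condition relative to control (initial rate)."""
    if control_product <= 0:
        raise InvalidInputError("control product concentration must be > 0")
    return 100.0 * test_product / control_product


def conversion_rate(variant_product: float, wt_product: float) -> float:
    """Percent product formed by a variant relative to wild type (end point)."""
    if wt_product <= 0:
        raise InvalidInputError("wild-type product concentration must be > 0")
    return 100.0 * variant_product / wt_product


# ---------------------------------------------------------------------------
# Exact adduct masses

#: monoisotopic atomic masses (IUPAC/CODATA values)
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.9897692809,
    "S": 31.9720706912,
    "P": 30.9737615120,
    "K": 38.9637064864,
    "Cl": 34.9688526820,
}
ELECTRON_MASS = 0.0005485799

_ADDUCTS: dict[str, tuple[int, dict[str, int], int]] = {
    # name -> (neutral multiplier, atoms added (negative = removed), charge)
    "[M+H]+": (1, {"H": 1}, +1),
    "[2M+H]+": (2, {"H": 1}, +1),
    "[M+Na]+": (1, {"Na": 1}, +1),
    "[2M+Na]+": (2, {"Na": 1}, +1),
    "[M-H]-": (1, {"H": -1}, -1),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula like ``C24H42NO5`` into an element-count map."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ConfigError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        element, count = m.group(1), int(m.group(2) or 1)
        counts[element] = counts.get(element, 0) + count
    if pos != len(formula) or not counts:
        raise ConfigError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class AdductSpec:
    """A neutral formula plus an adduct form, e.g. C24H41NO5 as [M+H]+."""

    formula: Mapping[str, int]
    adduct: str = "[M+H]+"

    def __post_init__(self) -> None:
        if self.adduct not in _ADDUCTS:
            raise ConfigError(f"unknown adduct {self.adduct!r}; known: {sorted(_ADDUCTS)}")
        if any(c <= 0 for c in self.formula.values()):
            raise ConfigError("element counts must be positive")


def _formula_mass(formula: Mapping[str, int]) -> float:
    mass = 0.0
    for element, count in formula.items():
        if element not in MONOISOTOPIC_MASS:
            raise ConfigError(f"no monoisotopic mass for element {element!r}")
        mass += count * MONOISOTOPIC_MASS[element]
    return mass


def ion_mz(ion_formula: Mapping[str, int] | str, charge: int) -> float:
    """m/z of a fully specified ion formula (electron mass included)."""
    if charge == 0:
        raise ConfigError("charge must be non-zero")
    if isinstance(ion_formula, str):
        ion_formula = parse_formula(ion_formula)
    return (_formula_mass(ion_formula) - charge * ELECTRON_MASS) / abs(charge)


def adduct_mz(spec: AdductSpec) -> float:
    """m/z of a neutral molecule observed as the given ESI adduct."""
    multiplier, delta, charge = _ADDUCTS[spec.adduct]
    ion: dict[str, int] = {el: multiplier * n for el, n in spec.formula.items()}
    for el, n in delta.items():
        ion[el] = ion.get(el, 0) + n
        if ion[el] < 0:
            raise ConfigError(f"adduct {spec.adduct} removes more {el} than present")
    return ion_mz(ion, charge)


# ---------------------------------------------------------------------------
# Metal-site geometry


def metal_pair_distance(
    atoms: Sequence[PdbAtom], element: str = "ZN", min_separation: float = 1e-3
) -> float:
    """Distance (A) between the closest distinct pair of metal atoms in one chain.

    Coincident duplicate atoms (separation below ``min_separation``) are not
    a valid pair. Raises :class:`NotFoundError` when no chain holds two
    distinct atoms of the element.
    """
    element = element.upper()
    by_chain: dict[str, list[PdbAtom]] = {}
    for atom in atoms:
        if atom.element.upper() == element:
            by_chain.setdefault(atom.chain, []).append(atom)
    best = None
    for chain_atoms in by_chain.values():
        for i, a in enumerate(chain_atoms):
            for b in chain_atoms[i + 1 :]:
                d = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
                if d >= min_separation and (best is None or d < best):
                    best = d
    if best is None:
        raise NotFoundError(f"no distinct pair of {element} atoms within a single chain")
    return best
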