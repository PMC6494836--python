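"""Deterministic chemistry bookkeeping for benzylisoquinoline alkaloids.

Molecular-formula parsing, average and monoisotopic masses, adduct m/z,
micromolar <-> mg/L conversions, stoichiometric molar yields, and fold
changes.  Atomic constants are embedded (IUPAC 2021 standard atomic weights
and principal-isotope monoisotopic masses) so every number is reproducible
offline.

THP (tetrahydropapaveroline) is C16H17NO4; it forms from one dopamine and
one DHPAA molecule, i.e. two L-DOPA equivalents per THP, which fixes the
default stoichiometry of the molar-yield calculation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

# IUPAC 2021 standard atomic weights (conventional values), g/mol
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "Na": 22.990, "K": 39.098, "Cl": 35.45, "Br": 79.904,
    "F": 18.998, "I": 126.904, "Fe": 55.845, "Mg": 24.305, "Ca": 40.078,
    "Zn": 65.38, "Se": 78.971, "B": 10.81, "Si": 28.085,
}

# principal-isotope monoisotopic masses, u
MONOISOTOPIC_MASSES: dict[str, float] = {
    "H": 1.0078250319, "C": 12.0, "N": 14.0030740052, "O": 15.9949146221,
    "S": 31.97207069, "P": 30.97376151, "Na": 22.98976928, "K": 38.96370649,
    "Cl": 34.96885271, "Br": 78.9183376, "F": 18.99840316, "I": 126.904473,
    "Fe": 55.93493633, "Mg": 23.98504170, "Ca": 39.96259086, "Zn": 63.92914201,
    "Se": 79.9165218, "B": 11.00930536, "Si": 27.97692653,
}

ELECTRON_MASS = 0.000548579909  # u
PROTON_MASS = MONOISOTOPIC_MASSES["H"] - ELECTRON_MASS  # 1.0072764520

# formulas used throughout the THP pathway bookkeeping
FORMULAS: dict[str, str] = {
    "THP": "C16H17NO4",
    "L-DOPA": "C9H11NO4",
    "dopamine": "C8H11NO2",
    "DHPAA": "C8H8O3",
    "reticuline": "C19H23NO4",
    "norcoclaurine": "C16H17NO3",
}


class FormulaError(ValueError):
    """Malformed molecular formula or unknown element symbol."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map with Hill-notation round-trip."""

    counts: tuple[tuple[str, int], ...]

    @property
    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return self.as_dict.get(element, 0)

    def hill(self) -> str:
        """Canonical Hill notation: C, then H, then other elements sorted."""
        d = self.as_dict
        parts = []
        for el in ("C", "H"):
            if el in d:
                parts.append(el + (str(d[el]) if d[el] > 1 else ""))
        for el in sorted(k for k in d if k not in ("C", "H")):
            parts.append(el + (str(d[el]) if d[el] > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C16H17NO4"``."""
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at {text[pos:]!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in ATOMIC_WEIGHTS:
            raise FormulaError(f"unknown element {el!r} in {text!r}")
        n = int(num) if num else 1
        if n < 1:
            raise FormulaError(f"element count must be >= 1 in {text!r}")
        counts[el] = counts.get(el, 0) + n
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at {text[pos:]!r}")
    return MolecularFormula(tuple(sorted(counts.items())))


def average_mass(f: MolecularFormula | str) -> float:
    """Average molecular mass (g/mol) from standard atomic weights."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in f.counts)


def monoisotopic_mass(f: MolecularFormula | str) -> float:
    """Neutral monoisotopic mass (u) from principal-isotope masses."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(MONOISOTOPIC_MASSES[el] * n for el, n in f.counts)


@dataclass(frozen=True)
class IonSpec:
    """Adduct specification: hydrogen change and signed charge.

    ``adduct`` is one of ``"M"``, ``"M+H"``, ``"M-H"``, ``"M-3H"``.  The
    charge sign must be consistent with the adduct: protonated/dehydrogenated
    cations are positive, deprotonated anions negative.  ``"M-3H"`` with
    charge +1 denotes loss of three H atoms followed by loss of one electron
    (the protonated quinone of a 4H-oxidised catechol, expressed relative to
    the parent) -- the species observed for oxidised THP.
    """

    adduct: str = "M"
    charge: int = 0

    _DELTA_H = {"M": 0, "M+H": +1, "M-H": -1, "M-3H": -3}

    def __post_init__(self):
        if self.adduct not in self._DELTA_H:
            raise ValueError(f"unknown adduct {self.adduct!r}")
        if self.adduct == "M+H" and self.charge <= 0:
            raise ValueError("M+H requires positive charge")
        if self.adduct == "M-H" and self.charge >= 0:
            raise ValueError("M-H requires negative charge")
        if self.adduct == "M" and self.charge != 0:
            raise ValueError("bare M is neutral")


def monoisotopic_mz(f: MolecularFormula | str, ion: IonSpec | str = "M",
                    charge: int | None = None) -> float:
    """m/z of an adduct ion from the neutral monoisotopic mass.

    Hydrogen atoms are added/removed at full atomic mass, then the electron
    mass is subtracted once per positive charge (added per negative charge).
    A neutral ``"M"`` spec returns the plain monoisotopic mass.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    if isinstance(ion, str):
        if charge is None:
            charge = {"M": 0, "M+H": 1, "M-H": -1, "M-3H": 1}[ion] if ion in (
                "M", "M+H", "M-H", "M-3H") else 0
        ion = IonSpec(ion, charge)
    d_h = IonSpec._DELTA_H[ion.adduct]
    if f["H"] + d_h < 0:
        raise FormulaError("adduct removes more hydrogens than present")
    m = monoisotopic_mass(f) + d_h * MONOISOTOPIC_MASSES["H"]
    if ion.charge == 0:
        return m
    m -= ion.charge * ELECTRON_MASS
    return m / abs(ion.charge)


def umolar_to_mgL(conc_um: float, f: MolecularFormula | str) -> float:
    """Convert µM to mg/L via the average molecular mass."""
    if conc_um < 0:
        raise ValueError("concentration must be >= 0")
    return conc_um * average_mass(f) / 1000.0


def mgL_to_umolar(conc_mgL: float, f: MolecularFormula | str) -> float:
    """Convert mg/L to µM via the average molecular mass."""
    if conc_mgL < 0:
        raise ValueError("concentration must be >= 0")
    return conc_mgL * 1000.0 / average_mass(f)


def molar_yield_pct(product_um: float, substrate_um: float,
                    stoich: float = 2.0) -> float:
    """Molar conversion yield in percent.

    ``stoich`` is the number of substrate molecules consumed per product
    molecule; THP from L-DOPA takes 2 (one via dopamine, one via DHPAA).
    """
    if substrate_um <= 0:
        raise ValueError("substrate input must be > 0")
    if stoich < 1:
        raise ValueError("stoichiometry must be >= 1")
    return 100.0 * stoich * product_um / substrate_um


def fold_change(after: float, before: float) -> float:
    """Simple titer ratio after/before (before must be positive)."""
    if before <= 0:
        raise ValueError("reference value must be > 0")
    return after / before
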