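"""Monoisotopic masses and adduct m/z for molecular formulas.

Formulas are parsed from Hill-notation strings (``C21H31NO5``) and summed
over an embedded table of IUPAC monoisotopic atomic masses.  Adduct m/z
follows high-resolution "calcd for" conventions: ``[M-H]-`` removes a proton
(the electron stays with the anion), ``[M+H]+``/``[M+Na]+`` add the cation
and subtract nothing but the electron already accounted for in the cation
mass.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Mapping

#: Monoisotopic masses of the most abundant isotope (Da), >= 6 decimals.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "Na": 22.9897692820,
    "P": 30.9737615120,
    "S": 31.9720706900,
    "Cl": 34.9688527100,
    "K": 38.9637064864,
    "Br": 78.9183376000,
    "I": 126.9044719000,
    "Se": 79.9165218000,
    "Si": 27.9769265350,
    "B": 11.0093053600,
}

ELECTRON_MASS = 0.0005485799091
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.0072764520

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    pass


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation formula string into an element -> count mapping."""
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    counts: Counter[str] = Counter()
    pos = 0
    text = formula.strip()
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.end() == pos:
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        element, digits = m.groups()
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {element!r} in {formula!r}")
        counts[element] += int(digits) if digits else 1
        pos = m.end()
    return dict(counts)


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic neutral mass (Da) of a molecular formula."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    for el in counts:
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {el!r}")
    return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items()))


#: name -> (mass delta in Da, charge); m/z = (M + delta) / |charge|
ADDUCTS: dict[str, tuple[float, int]] = {
    "[M-H]-": (-PROTON_MASS, -1),
    "[M+H]+": (+PROTON_MASS, +1),
    "[M+Na]+": (+MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, +1),
}


def adduct_mz(formula: str | Mapping[str, int], adduct: str = "[M-H]-") -> float:
    """m/z of a named adduct of the neutral formula."""
    if adduct not in ADDUCTS:
        raise FormulaError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}")
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    if adduct == "[M-H]-" and counts.get("H", 0) < 1:
        raise FormulaError("deprotonation requires at least one hydrogen")
    delta, charge = ADDUCTS[adduct]
    return (monoisotopic_mass(counts) + delta) / abs(charge)


def mz_deprotonated(neutral_formula: str | Mapping[str, int]) -> float:
    """[M-H]- m/z: monoisotopic mass minus a proton (electron retained).

    Report rounded to 4 decimals for comparison against printed HRESIMS
    "calcd" values.
    """
    return adduct_mz(neutral_formula, "[M-H]-")
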