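"""Chemical formula parsing and standard atomic weights.

Supports the formula dialect found in culture-medium recipes: element
symbols with integer counts, one level of parentheses, and a hydrate
suffix written with a middle dot (``FeSO4·7H2O``). Hydrate water is
folded into the H and O counts of the parent salt.

Atomic weights are IUPAC 2021 conventional values, used for converting
molar medium concentrations to mass concentrations. The integer masses
(12/1/16/14) used for empirical biomass formulas live in
:mod:`cellcomp.stoichiometry`, which deliberately does not use this
table.
"""

from __future__ import annotations

import re
from collections import Counter

__all__ = ["ATOMIC_WEIGHTS", "FormulaError", "parse_chemical_formula", "molar_mass"]


class FormulaError(ValueError):
    """Raised when a chemical formula string cannot be parsed."""


#: Standard atomic weights (g/mol), IUPAC 2021 conventional values.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Sc": 44.956, "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.922, "Se": 78.971, "Br": 79.904,
    "Kr": 83.798, "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224,
    "Nb": 92.906, "Mo": 95.95, "Ru": 101.07, "Rh": 102.91, "Pd": 106.42,
    "Ag": 107.87, "Cd": 112.41, "In": 114.82, "Sn": 118.71, "Sb": 121.76,
    "Te": 127.60, "I": 126.90, "Xe": 131.29, "Cs": 132.91, "Ba": 137.33,
    "La": 138.91, "Ce": 140.12, "W": 183.84, "Re": 186.21, "Os": 190.23,
    "Ir": 192.22, "Pt": 195.08, "Au": 196.97, "Hg": 200.59, "Tl": 204.38,
    "Pb": 207.2, "Bi": 208.98, "Th": 232.04, "U": 238.03,
}

# Dot characters accepted as hydrate separators.
_HYDRATE_SEPS = "·.*⋅·"

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)|(.)")


def _parse_fragment(s: str) -> Counter:
    """Parse a formula fragment (no hydrate dot) into element counts."""
    counts: Counter = Counter()
    stack: list[Counter] = []
    for m in _TOKEN.finditer(s):
        symbol, sym_count, open_p, close_p, group_count, bad = m.groups()
        if symbol:
            if symbol not in ATOMIC_WEIGHTS:
                raise FormulaError(f"unknown element symbol {symbol!r} in {s!r}")
            counts[symbol] += int(sym_count) if sym_count else 1
        elif open_p:
            stack.append(counts)
            counts = Counter()
        elif close_p:
            if not stack:
                raise FormulaError(f"unbalanced parentheses in {s!r}")
            mult = int(group_count) if group_count else 1
            outer = stack.pop()
            for el, n in counts.items():
                outer[el] += n * mult
            counts = outer
        elif bad and not bad.isspace():
            raise FormulaError(f"unexpected character {bad!r} in {s!r}")
    if stack:
        raise FormulaError(f"unbalanced parentheses in {s!r}")
    if not counts:
        raise FormulaError(f"formula {s!r} contains no elements")
    return counts


def parse_chemical_formula(formula: str) -> dict[str, int]:
    """Parse a salt formula, hydrate notation included, to element counts.

    >>> parse_chemical_formula("FeSO4·7H2O")
    {'Fe': 1, 'S': 1, 'O': 11, 'H': 14}
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula string")
    parts = re.split(f"[{re.escape(_HYDRATE_SEPS)}]", formula.strip())
    counts: Counter = Counter()
    for i, part in enumerate(parts):
        part = part.strip()
        if not part:
            raise FormulaError(f"malformed hydrate notation in {formula!r}")
        mult = 1
        if i > 0:
            # hydrate term: optional leading integer multiplier, e.g. 7H2O
            m = re.match(r"(\d+)(.*)", part)
            if m:
                mult, part = int(m.group(1)), m.group(2)
            if not part:
                raise FormulaError(f"malformed hydrate notation in {formula!r}")
        for el, n in _parse_fragment(part).items():
            counts[el] += n * mult
    return dict(counts)


def molar_mass(formula: str | dict[str, int]) -> float:
    """Molar mass (g/mol) from a formula string or element-count map."""
    counts = parse_chemical_formula(formula) if isinstance(formula, str) else formula
    try:
        return sum(ATOMIC_WEIGHTS[el] * n for el, n in counts.items())
    except KeyError as e:  # pragma: no cover - count maps come from the parser
        raise FormulaError(f"unknown element symbol {e.args[0]!r}") from e
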