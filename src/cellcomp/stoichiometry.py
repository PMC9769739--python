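"""Empirical biomass formula and respiration stoichiometry.

Bulk cell composition is summarised by the empirical formula C_nH_aO_bN_c,
conventionally normalised to one nitrogen (the textbook bacterium is
C5H7O2N). Subscripts come from combustion (CHN) analysis plus ash, with
oxygen estimated by difference:

    %O = 100 − (%C + %H + %N + %ash)

and atom ratios formed with the nominal masses 12 (C), 1 (H), 16 (O),
14 (N) — the convention of the elemental-analysis literature, kept here
so published subscripts reproduce exactly. Aerobic mineralisation of a
formula unit balances as

    CnHaObNc + (2n + 0.5a − 1.5c − b)/2 O2 → n CO2 + c NH3 + (a − 3c)/2 H2O

from which the theoretical oxygen demand (ThOD, g O2 per g biomass)
follows as 32·O2-coefficient / formula mass. For the textbook C5H7O2N
this gives the classic 160/113 ≈ 1.42 g/g.

A more reduced biomass (lipid-rich cells) shows up here as high C:O and
H:O mass ratios and a large O2 coefficient per carbon.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

__all__ = [
    "NOMINAL_MASS",
    "ElementalComposition",
    "EmpiricalFormula",
    "RespirationStoichiometry",
    "MacromolecularFractions",
    "CompositionError",
    "oxygen_by_difference",
    "empirical_formula",
    "respiration_stoichiometry",
    "formula_mass",
    "theoretical_oxygen_demand",
    "mass_ratios",
    "mass_closure",
    "composition_from_summary",
]

#: Nominal atomic masses used for empirical-formula subscripts.
NOMINAL_MASS = {"C": 12.0, "H": 1.0, "O": 16.0, "N": 14.0}


class CompositionError(ValueError):
    """Raised when mass percents are inconsistent with the closure model."""


@dataclass(frozen=True)
class ElementalComposition:
    """Mass percent of dry weight: C, H, N, ash, and (optionally) O.

    ``pctO`` may be supplied (as printed in a table) or left ``None`` and
    derived by difference with :func:`oxygen_by_difference`.
    """

    pctC: float
    pctH: float
    pctN: float
    pctAsh: float = 0.0
    pctO: float | None = None

    def __post_init__(self) -> None:
        fields = {"pctC": self.pctC, "pctH": self.pctH, "pctN": self.pctN, "pctAsh": self.pctAsh}
        if self.pctO is not None:
            fields["pctO"] = self.pctO
        for name, v in fields.items():
            if not 0 <= v <= 100:
                raise CompositionError(f"{name} = {v} outside [0, 100]")
        if self.pctC + self.pctH + self.pctN + self.pctAsh > 100 + 1e-9:
            raise CompositionError(
                "C + H + N + ash exceeds 100%: oxygen by difference impossible "
                f"({self.pctC + self.pctH + self.pctN + self.pctAsh:.2f}%)"
            )

    @property
    def oxygen(self) -> float:
        """%O: the supplied value if present, else derived by difference."""
        if self.pctO is not None:
            return self.pctO
        return oxygen_by_difference(self)

    def closure_residual(self) -> float | None:
        """100 − (sum of all five percents) when O is supplied, else None.

        A printed O column can disagree slightly with O-by-difference
        because of rounding; the residual quantifies that.
        """
        if self.pctO is None:
            return None
        return 100.0 - (self.pctC + self.pctH + self.pctN + self.pctO + self.pctAsh)


@dataclass(frozen=True)
class EmpiricalFormula:
    """Subscripts (n, a, b, c) of C_nH_aO_bN_c; c = 1 when N-normalised."""

    n: float
    a: float
    b: float
    c: float = 1.0

    def __post_init__(self) -> None:
        for name, v in (("n", self.n), ("a", self.a), ("b", self.b), ("c", self.c)):
            if v < 0:
                raise CompositionError(f"subscript {name} = {v} must be >= 0")

    def rounded(self, ndigits: int = 2) -> "EmpiricalFormula":
        return EmpiricalFormula(
            round(self.n, ndigits), round(self.a, ndigits), round(self.b, ndigits), round(self.c, ndigits)
        )

    def __str__(self) -> str:
        def sub(v: float) -> str:
            return "" if math.isclose(v, 1.0) else f"{v:g}"

        return f"C{sub(self.n)}H{sub(self.a)}O{sub(self.b)}N{sub(self.c)}"


@dataclass(frozen=True)
class RespirationStoichiometry:
    """Coefficients (mol per mol formula unit) of aerobic mineralisation."""

    o2: float
    co2: float
    nh3: float
    h2o: float


@dataclass(frozen=True)
class MacromolecularFractions:
    """Protein / lipid / carbohydrate content, mg per g dry weight."""

    protein: float
    lipid: float
    carbohydrate: float
    ash: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("protein", self.protein), ("lipid", self.lipid),
                        ("carbohydrate", self.carbohydrate), ("ash", self.ash)):
            if v < 0:
                raise CompositionError(f"{name} = {v} must be >= 0 mg/g")


def oxygen_by_difference(e: ElementalComposition) -> float:
    """%O = 100 − (%C + %H + %N + %ash).

    Combustion analysers do not measure oxygen; it is estimated as the
    complement of the measured fractions. Returns the derived percent;
    the five fractions then sum to 100 exactly.
    """
    total = e.pctC + e.pctH + e.pctN + e.pctAsh
    if total > 100 + 1e-9:
        raise CompositionError(f"C+H+N+ash = {total:.2f}% exceeds 100%")
    return 100.0 - total


def empirical_formula(
    e: ElementalComposition, *, normalize: str = "nitrogen"
) -> EmpiricalFormula:
    """N-normalised empirical biomass formula from mass percents.

    Atom amounts are %X / nominal mass (12, 1, 16, 14); with
    ``normalize="nitrogen"`` subscripts are scaled so c = 1, with
    ``normalize="mole_fraction"`` they sum to 1 instead (useful when
    %N = 0 and N-normalisation is undefined).
    """
    pctO = e.oxygen
    moles = {
        "n": e.pctC / NOMINAL_MASS["C"],
        "a": e.pctH / NOMINAL_MASS["H"],
        "b": pctO / NOMINAL_MASS["O"],
        "c": e.pctN / NOMINAL_MASS["N"],
    }
    if normalize == "nitrogen":
        if moles["c"] <= 0:
            raise CompositionError(
                "%N = 0: N-normalisation undefined; use normalize='mole_fraction'"
            )
        scale = moles["c"]
    elif normalize == "mole_fraction":
        scale = sum(moles.values())
        if scale <= 0:
            raise CompositionError("all mass percents are zero")
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return EmpiricalFormula(
        n=moles["n"] / scale, a=moles["a"] / scale, b=moles["b"] / scale, c=moles["c"] / scale
    )


def respiration_stoichiometry(f: EmpiricalFormula) -> RespirationStoichiometry:
    """Aerobic mineralisation coefficients of one formula unit.

    o2 = (2n + 0.5a − 1.5c − b) / 2, co2 = n, nh3 = c, h2o = (a − 3c) / 2.
    These conserve C, H, O, and N identically. A negative O2 or H2O
    coefficient is mathematically legal (a composition more oxidised than
    the products) and triggers a warning rather than an error.
    """
    s = RespirationStoichiometry(
        o2=(2 * f.n + 0.5 * f.a - 1.5 * f.c - f.b) / 2,
        co2=f.n,
        nh3=f.c,
        h2o=(f.a - 3 * f.c) / 2,
    )
    if s.o2 < 0 or s.h2o < 0:
        warnings.warn(
            f"negative stoichiometric coefficient for {f}: o2={s.o2:.3g}, h2o={s.h2o:.3g} "
            "(composition more oxidized than the combustion products)",
            stacklevel=2,
        )
    return s


def formula_mass(f: EmpiricalFormula) -> float:
    """Mass of one formula unit (g/mol) with nominal masses 12/1/16/14."""
    return 12 * f.n + 1 * f.a + 16 * f.b + 14 * f.c


def theoretical_oxygen_demand(f: EmpiricalFormula) -> float:
    """ThOD: g O2 required to mineralise 1 g of biomass (32·o2 / mass)."""
    mass = formula_mass(f)
    if mass <= 0:
        raise CompositionError("formula mass is zero; ThOD undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stoich = respiration_stoichiometry(f)
    thod = 32.0 * stoich.o2 / mass
    if thod < 0:
        warnings.warn(f"negative ThOD {thod:.3g} g/g for {f}", stacklevel=2)
    return thod


def mass_ratios(e: ElementalComposition) -> dict[str, float]:
    """C:N, C:O and H:O mass ratios from the mass percents."""
    pctO = e.oxygen
    if e.pctN <= 0 or pctO <= 0:
        raise CompositionError("zero N or O percent: mass ratio undefined")
    return {"C:N": e.pctC / e.pctN, "C:O": e.pctC / pctO, "H:O": e.pctH / pctO}


def mass_closure(m: MacromolecularFractions) -> float:
    """Residual mg/g after protein + lipid + carbohydrate + ash.

    The residual is the unmeasured remainder of dry biomass (nucleic
    acids and other minor pools). Components summing above 1000 mg/g
    raise a warning and return the (negative) overshoot.
    """
    total = m.protein + m.lipid + m.carbohydrate + m.ash
    residual = 1000.0 - total
    if residual < 0:
        warnings.warn(
            f"macromolecular fractions overshoot dry weight by {-residual:.1f} mg/g",
            stacklevel=2,
        )
    return residual


def composition_from_summary(summary, condition: str) -> ElementalComposition:
    """Build an :class:`ElementalComposition` from a summarize() table.

    Looks for analytes named C, H, N, ash (and O if present) with
    percent-of-dry-weight units for the given condition.
    """
    rows = summary[summary["condition"] == condition]
    vals: dict[str, float] = {}
    for _, row in rows.iterrows():
        if row["units"] == "percent_dw":
            vals[row["analyte"]] = float(row["mean"])
    missing = {"C", "H", "N"} - vals.keys()
    if missing:
        raise CompositionError(f"condition {condition!r}: missing elemental analyte(s) {sorted(missing)}")
    return ElementalComposition(
        pctC=vals["C"], pctH=vals["H"], pctN=vals["N"],
        pctAsh=vals.get("ash", 0.0), pctO=vals.get("O"),
    )
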