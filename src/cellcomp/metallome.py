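"""Medium element accounting, Liebig limitation, and basis conversions.

A culture medium recipe fixes how much of each element a batch culture can
ever draw on; the cellular quota (μg element per g dry weight) fixes how
much each gram of cells needs. Under Liebig's law of the minimum the
maximum attainable cell density is

    density_E = availability_E (μg/L) / quota_E (μg/g)     [g dw / L]

minimised over elements — no uptake kinetics, no speciation or
precipitation correction, just a mass-balance ceiling. For an
anode-respiring culture the density ceiling translates directly into a
current ceiling via the specific current (A per g dry weight).

Medium availability uses standard IUPAC atomic weights (Fe 55.845 ...),
unlike the nominal 12/1/16/14 masses of the empirical-formula module:
these are real mass concentrations, not a subscript convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import ATOMIC_WEIGHTS, parse_chemical_formula
from .composition_io import MediumRecipe

__all__ = [
    "MediumElementProfile",
    "MetallomeProfile",
    "LimitationResult",
    "QuotaError",
    "parse_chemical_formula",
    "medium_element_concentration",
    "max_cell_density",
    "limiting_nutrient",
    "per_cell_content",
    "max_current",
    "protein_basis_to_dw",
    "nmol_per_mg_protein_to_ug_per_g_dw",
]


class QuotaError(ValueError):
    """Raised for quota/availability combinations the model cannot rank."""


@dataclass
class MediumElementProfile:
    """Total element content of one litre of final medium.

    ``umol_per_L`` and ``ug_per_L`` are per-element totals summed over
    contributing components; ``provenance`` lists the component names
    that contribute each element.
    """

    medium_name: str
    umol_per_L: dict[str, float]
    ug_per_L: dict[str, float]
    provenance: dict[str, list[str]] = field(default_factory=dict)
    supplements_included: bool = False

    def __contains__(self, element: str) -> bool:
        return element in self.umol_per_L


@dataclass
class MetallomeProfile:
    """Cellular element quotas: μg element per g dry weight, mean ± SD."""

    quotas: dict[str, float]
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, q in self.quotas.items():
            if q < 0:
                raise QuotaError(f"negative quota for {el}: {q}")

    @classmethod
    def from_summary(cls, summary, condition: str) -> "MetallomeProfile":
        """Extract μg/g-dw analytes for one condition from a summarize() table."""
        rows = summary[(summary["condition"] == condition) & (summary["units"] == "ug_per_g_dw")]
        return cls(
            quotas={r["analyte"]: float(r["mean"]) for _, r in rows.iterrows()},
            sd={r["analyte"]: float(r["sd"]) for _, r in rows.iterrows()},
        )


@dataclass
class LimitationResult:
    """Liebig limitation summary for one metallome × medium pairing."""

    medium_name: str
    supplements_included: bool
    density_g_per_L: dict[str, float]  # per evaluable element
    not_evaluable: dict[str, str]  # element -> reason
    limiting_element: str
    limiting_density: float

    def sorted_densities(self) -> list[tuple[str, float]]:
        return sorted(self.density_g_per_L.items(), key=lambda kv: kv[1])


def medium_element_concentration(
    recipe: MediumRecipe, include_supplements: bool = False
) -> MediumElementProfile:
    """Per-element μmol/L and μg/L of the final medium.

    Stock components contribute stock_mM × dose_mL_per_L μmol/L; direct
    components contribute final_uM. Post-autoclave supplements are
    excluded unless ``include_supplements`` is set.
    """
    umol: dict[str, float] = {}
    ug: dict[str, float] = {}
    provenance: dict[str, list[str]] = {}
    for comp in recipe.components:
        if comp.supplement and not include_supplements:
            continue
        c = comp.final_umol_per_L
        for el, count in comp.element_counts.items():
            umol[el] = umol.get(el, 0.0) + c * count
            provenance.setdefault(el, []).append(comp.name)
    for el, v in umol.items():
        ug[el] = v * ATOMIC_WEIGHTS[el]
    return MediumElementProfile(
        medium_name=recipe.name,
        umol_per_L=umol,
        ug_per_L=ug,
        provenance=provenance,
        supplements_included=include_supplements,
    )


def max_cell_density(quota_ug_per_g: float, avail_ug_per_L: float) -> float:
    """Liebig ceiling for one element: availability / quota (g dw per L)."""
    if quota_ug_per_g <= 0:
        raise QuotaError(
            "zero quota: this element places no ceiling on growth (unbounded), "
            "report it as not-evaluable instead of dividing"
        )
    if avail_ug_per_L < 0:
        raise QuotaError(f"negative availability {avail_ug_per_L}")
    return avail_ug_per_L / quota_ug_per_g


def limiting_nutrient(
    metallome: MetallomeProfile, medium: MediumElementProfile
) -> LimitationResult:
    """Identify the growth-limiting element by the Liebig minimum.

    Elements lacking either a quota or a medium availability are reported
    under ``not_evaluable`` with a reason, never silently dropped.
    """
    densities: dict[str, float] = {}
    not_evaluable: dict[str, str] = {}
    for el in sorted(set(metallome.quotas) | set(medium.umol_per_L)):
        quota = metallome.quotas.get(el)
        avail = medium.ug_per_L.get(el)
        if quota is None:
            not_evaluable[el] = "no cellular quota measured"
        elif avail is None:
            not_evaluable[el] = "element absent from medium (availability 0: no growth possible on it)"
        elif quota == 0:
            not_evaluable[el] = "quota 0: element not required, no ceiling"
        else:
            densities[el] = max_cell_density(quota, avail)
    if not densities:
        raise QuotaError("no element present in both the metallome and the medium")
    limiting = min(densities, key=densities.__getitem__)
    return LimitationResult(
        medium_name=medium.medium_name,
        supplements_included=medium.supplements_included,
        density_g_per_L=densities,
        not_evaluable=not_evaluable,
        limiting_element=limiting,
        limiting_density=densities[limiting],
    )


def per_cell_content(
    quota_ug_per_g: float, cell_mass_pg: float | tuple[float, float]
) -> float | tuple[float, float]:
    """Element content per cell (ng) from a quota and a cell dry mass.

    μg/g is a mass fraction of 1e-6 g per g; one cell of m pg carries
    quota × 1e-6 × (m × 1e-12 g) = quota × m × 1e-18 g = quota × m × 1e-9 ng.
    Accepts a (low, high) mass range and returns the matching range.
    """
    if isinstance(cell_mass_pg, tuple):
        lo, hi = cell_mass_pg
        return (per_cell_content(quota_ug_per_g, lo), per_cell_content(quota_ug_per_g, hi))
    if quota_ug_per_g < 0 or cell_mass_pg < 0:
        raise QuotaError("quota and cell mass must be >= 0")
    return quota_ug_per_g * cell_mass_pg * 1e-9


def max_current(
    specific_current_A_per_g: float, density_g_per_L: float, volume_L: float = 1.0
) -> float:
    """Current ceiling (A) of a batch: specific current × density × volume.

    The specific current is an explicit input (A per g dry weight);
    published values differ by basis (per g cell vs per g protein), so
    no default is encoded — see :func:`protein_basis_to_dw` to move a
    per-protein figure onto the dry-weight basis.
    """
    for name, v in (("specific_current", specific_current_A_per_g),
                    ("density", density_g_per_L), ("volume", volume_L)):
        if v < 0:
            raise QuotaError(f"{name} must be >= 0, got {v}")
    return specific_current_A_per_g * density_g_per_L * volume_L


def protein_basis_to_dw(value_per_g_protein: float, protein_fraction: float) -> float:
    """Convert an amount per g protein to an amount per g dry weight.

    ``protein_fraction`` is g protein per g dry weight (or per g volatile
    solids when converting to a volatile-solids basis), in (0, 1].
    """
    if not 0 < protein_fraction <= 1:
        raise QuotaError(f"protein fraction {protein_fraction} outside (0, 1]")
    return value_per_g_protein * protein_fraction


def nmol_per_mg_protein_to_ug_per_g_dw(
    nmol_per_mg: float, element: str, protein_fraction: float
) -> float:
    """Convert a molar per-protein quota (nmol/mg protein) to μg/g dry weight.

    nmol/mg × atomic weight (ng/nmol) = ng/mg = μg/g protein, then scale
    by the protein mass fraction of dry weight.
    """
    if element not in ATOMIC_WEIGHTS:
        raise QuotaError(f"unknown element {element!r}")
    return protein_basis_to_dw(nmol_per_mg * ATOMIC_WEIGHTS[element], protein_fraction)
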