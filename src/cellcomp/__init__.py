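"""cellcomp: microbial cell-composition and trace-metal limitation analysis.

Tools for working with bulk cell-composition data of bacteria grown under
different respiratory conditions (e.g. Geobacter sulfurreducens on an
electrode vs on fumarate, E. coli in rich vs minimal medium):

- :mod:`cellcomp.composition_io` — tidy replicate tables, summaries, and
  culture-medium recipe files;
- :mod:`cellcomp.stoichiometry` — empirical biomass formulas C_nH_aO_bN_c,
  oxygen by difference, respiration stoichiometry and ThOD;
- :mod:`cellcomp.metallome` — medium element accounting, Liebig
  law-of-the-minimum growth ceilings, per-cell quotas and current ceilings;
- :mod:`cellcomp.stats_compare` — pairwise Welch t tests with
  Benjamini-Hochberg FDR control;
- :mod:`cellcomp.synthetic_data` — replicate-level synthetic datasets with
  published means and SDs.
"""

from importlib.resources import files as _files

from .chem import ATOMIC_WEIGHTS, FormulaError, molar_mass, parse_chemical_formula
from .composition_io import (
    ConditionDataset,
    IntegrityError,
    Measurement,
    MediumComponent,
    MediumRecipe,
    SchemaError,
    expand_mean_sd,
    load_medium_recipe,
    load_samples,
    summarize,
    write_samples,
)
from .metallome import (
    LimitationResult,
    MediumElementProfile,
    MetallomeProfile,
    QuotaError,
    limiting_nutrient,
    max_cell_density,
    max_current,
    medium_element_concentration,
    nmol_per_mg_protein_to_ug_per_g_dw,
    per_cell_content,
    protein_basis_to_dw,
)
from .stats_compare import TestResult, bh_adjust, pairwise_compare, results_frame, welch_t
from .stoichiometry import (
    CompositionError,
    ElementalComposition,
    EmpiricalFormula,
    MacromolecularFractions,
    RespirationStoichiometry,
    composition_from_summary,
    empirical_formula,
    formula_mass,
    mass_closure,
    mass_ratios,
    oxygen_by_difference,
    respiration_stoichiometry,
    theoretical_oxygen_demand,
)
from .synthetic_data import (
    AnalyteSpec,
    StudySpec,
    default_study_spec,
    generate_condition,
    generate_study,
    load_study_spec,
)

__version__ = "0.1.0"


def geobacter_medium_path() -> str:
    """Path to the bundled Geobacter medium (ATCC 1957 style) recipe."""
    return str(_files("cellcomp.data").joinpath("geobacter_medium.yaml"))


def geobacter_medium() -> MediumRecipe:
    """Load the bundled Geobacter medium recipe."""
    return load_medium_recipe(geobacter_medium_path())
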