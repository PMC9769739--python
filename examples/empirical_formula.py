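"""Empirical biomass formula from a CHN + ash elemental analysis.

Builds the elemental compositions of electrode- and fumarate-grown
G. sulfurreducens, derives the N-normalized formula C_nH_aO_bN, and the
respiration stoichiometry and theoretical oxygen demand that follow.
"""

from cellcomp import (
    ElementalComposition,
    empirical_formula,
    formula_mass,
    mass_ratios,
    respiration_stoichiometry,
    theoretical_oxygen_demand,
)

conditions = {
    "electrode": ElementalComposition(pctC=47.0, pctH=7.2, pctN=9.5, pctAsh=9.9, pctO=26.4),
    "fumarate": ElementalComposition(pctC=46.8, pctH=7.4, pctN=8.3, pctAsh=9.0, pctO=28.6),
}

for name, comp in conditions.items():
    f = empirical_formula(comp)
    s = respiration_stoichiometry(f)
    r = mass_ratios(comp)
    print(f"{name}: {f.rounded(2)}  (formula mass {formula_mass(f):.0f} g/mol)")
    print(
        f"  combustion: + {s.o2:.2f} O2 -> {s.co2:.2f} CO2 + {s.nh3:.2f} NH3 + {s.h2o:.2f} H2O"
    )
    print(f"  ThOD {theoretical_oxygen_demand(f):.2f} g O2/g biomass")
    print(f"  mass ratios  C:N {r['C:N']:.2f}  C:O {r['C:O']:.2f}  H:O {r['H:O']:.2f}")

print(
    "\nBoth conditions sit well above the textbook C5H7O2N in C and H per N:"
    "\nlow-protein, lipid-rich cells are more reduced, so they demand more O2"
    "\nper formula unit when fully oxidized."
)
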