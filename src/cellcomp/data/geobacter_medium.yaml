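# Geobacter medium (ATCC 1957 style) for anode-respiring G. sulfurreducens.
# Base salts are given as final concentrations; the trace-mineral mix is a
# stock dosed at 10 mL per L of medium. Post-autoclave additions (made in
# the anaerobic glove box) are flagged supplement: true so element
# accounting can include or exclude them. The vitamin mix contributes no
# metals and is omitted.
name: Geobacter medium
components:
  # --- base medium (final concentrations) ---
  - name: sodium acetate
    formula: C2H3NaO2
    final_uM: 50000
  - name: sodium bicarbonate
    formula: NaHCO3
    final_uM: 30000
  - name: ammonium chloride
    formula: NH4Cl
    final_uM: 20000
  - name: sodium phosphate monobasic
    formula: NaH2PO4
    final_uM: 4000
  - name: potassium chloride
    formula: KCl
    final_uM: 1000
  # --- trace-mineral stock, dosed 10 mL per L ---
  - name: nitrilotriacetic acid trisodium salt
    formula: C6H6NNa3O6
    stock_mM: 5.5
    dose_mL_per_L: 10
  - name: magnesium sulfate heptahydrate
    formula: MgSO4·7H2O
    stock_mM: 12
    dose_mL_per_L: 10
  - name: manganese sulfate monohydrate
    formula: MnSO4·H2O
    stock_mM: 2.9
    dose_mL_per_L: 10
  - name: sodium chloride
    formula: NaCl
    stock_mM: 17
    dose_mL_per_L: 10
  - name: ferrous sulfate heptahydrate
    formula: FeSO4·7H2O
    stock_mM: 0.36
    dose_mL_per_L: 10
  - name: calcium chloride dihydrate
    formula: CaCl2·2H2O
    stock_mM: 0.68
    dose_mL_per_L: 10
  - name: cobalt chloride hexahydrate
    formula: CoCl2·6H2O
    stock_mM: 0.42
    dose_mL_per_L: 10
  - name: zinc chloride
    formula: ZnCl2
    stock_mM: 0.95
    dose_mL_per_L: 10
  - name: copper sulfate pentahydrate
    formula: CuSO4·5H2O
    stock_mM: 0.4
    dose_mL_per_L: 10
  - name: aluminum potassium sulfate dodecahydrate
    formula: AlK(SO4)2·12H2O
    stock_mM: 0.2
    dose_mL_per_L: 10
  - name: boric acid
    formula: H3BO4          # as printed in the source recipe
    stock_mM: 0.16
    dose_mL_per_L: 10
  - name: sodium molybdate hydrate
    formula: Na2MoO4·H2O    # as printed in the source recipe
    stock_mM: 0.01
    dose_mL_per_L: 10
  - name: nickel chloride hexahydrate
    formula: NiCl2·6H2O
    stock_mM: 0.01
    dose_mL_per_L: 10
  - name: sodium tungstate dihydrate
    formula: Na2WO4·2H2O
    stock_mM: 0.0085
    dose_mL_per_L: 10
  # --- post-autoclave supplements (anaerobic glove box) ---
  - name: ferrous chloride tetrahydrate
    formula: FeCl2·4H2O
    final_uM: 20
    supplement: true
  - name: sodium sulfide nonahydrate
    formula: Na2S·9H2O
    final_uM: 54
    supplement: true
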