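# Methods

## Scope and data model

`cellcomp` operates on replicate-level composition measurements of
microbial cultures grown under defined conditions. The common container
is a tidy table of (condition, replicate, analyte, value, units) rows;
three unit systems coexist and are declared per row: trace elements in
μg/g dry weight, macromolecular fractions in mg/g dry weight, and
elemental (CHN/ash) analyses in percent of dry weight. Units must be
consistent per analyte across a dataset; duplicated (condition,
replicate, analyte) keys and negative values are rejected at load time
with row-level diagnostics rather than silently dropped.

Replicate counts are whatever the user supplies (n ≥ 1); summaries always
report n, and single-replicate groups report the sample SD as undefined
(NaN) rather than zero. Published tables that print only mean ± sample SD
can be expanded into three deterministic pseudo-replicates (m, m−s, m+s),
whose mean and n−1 SD reproduce the printed values exactly; this is a
device for driving computations from printed summaries, not a claim about
the real replicate structure.

## Empirical biomass formula

Combustion analysers measure C, H and N; ash is the residue after
combustion at 600 °C; oxygen is estimated by difference,
%O = 100 − (%C + %H + %N + %ash). When a table also prints an O column,
the printed value takes precedence over the difference and any closure
residual (typically a 0.1-point rounding artifact) is surfaced through
`ElementalComposition.closure_residual()` as a note, not an error.

Subscripts of C_nH_aO_bN_c use nominal atomic masses 12/1/16/14 — the
convention of the elemental-analysis literature — normalised so c = 1. A
mole-fraction normalisation (subscripts summing to 1) is available for
nitrogen-free material. Reporting precision defaults to 2 decimals and is
configurable; internal arithmetic is never rounded.

Aerobic mineralisation of a formula unit balances as

    CnHaObNc + (2n + 0.5a − 1.5c − b)/2 O2 → n CO2 + c NH3 + (a − 3c)/2 H2O

which conserves all four elements identically (asserted numerically on
random formulas in the test suite). Negative O2 or H2O coefficients are
mathematically legal — they indicate material more oxidised than the
products — and produce warnings rather than errors; the same policy
applies to the derived ThOD = 32·o2/(12n + a + 16b + 14c). Macromolecular
mass closure reports 1000 − (protein + lipid + carbohydrate + ash) mg/g
as unmeasured biomass (nucleic acids and minor pools); sums above 1000
warn with the overshoot.

## Medium chemistry and Liebig limitation

Medium recipes are YAML/JSON lists of components, each specified either
as a stock concentration (mM) with a dose (mL stock per L medium) or as a
direct final concentration (μM) — exactly one of the two — plus a flag
for post-autoclave supplements. Chemical formulas use salt notation with
one level of parentheses and middle-dot hydrates (`AlK(SO4)2·12H2O`);
hydrate water is folded into H and O counts. The parser and the standard
atomic-weight table (IUPAC 2021 values) live in `cellcomp.chem`; the
nominal 12/1/16/14 masses of the formula module are deliberately not
shared with it, since medium availabilities are real mass concentrations
while formula subscripts are a reporting convention.

Per-element availability is additive over components: stock components
contribute stock_mM × dose μmol/L, final-concentration components
contribute directly, and μg/L follows from the atomic weight. The growth
ceiling for an element is availability (μg/L) divided by the cellular
quota (μg/g dry weight); the limiting element is the minimum over
elements evaluable in both profiles, and elements present in only one
profile are listed as not-evaluable with a reason. The model is a pure
mass balance: no uptake kinetics, no speciation or precipitation
chemistry (metals such as Cu and Co can precipitate in sulfide-containing
media, which would make the ceiling optimistic for them — a documented
caveat, not a computation).

Post-autoclave supplements default to excluded from availability. The
rationale is operational: the supplement iron (20 μM FeCl2) is added in
the glove box and partly precipitates with sulfide, and the trace-mineral
iron alone (3.6 μM) is what reproduces the reported ~0.1 g/L ceiling for
iron-hungry electrode-grown cells. Both accountings are one flag apart
and the limitation summary records which was used.

Current ceilings multiply specific current (A per g dry weight) ×
limiting density × volume. The specific current is an explicit input:
published figures differ by basis (per g cell vs per g protein), and a
per-protein figure can be moved to the dry-weight basis with
`protein_basis_to_dw` (× protein mass fraction) or, for molar quotas,
`nmol_per_mg_protein_to_ug_per_g_dw` (× atomic weight, × fraction). When
chaining the ceiling into a current, the density is conventionally
rounded to the reported 2-decimal precision first, matching how such
numbers are chained in print; the unrounded value differs by ~2%.
Per-cell contents are quota × cell dry mass (pg), returned in ng, with
(low, high) mass ranges supported; 0.1–1 pg spans reported bacterial
cell dry masses.

## Pairwise statistics

Condition pairs are compared with two-sided t tests on replicate values.
Welch's unequal-variance variant with Welch–Satterthwaite degrees of
freedom is the default (between-condition SDs differ several-fold in this
kind of data); a pooled-variance variant is available. Degenerate input —
both groups constant and equal — reports t = 0, p = 1; constant and
unequal raises, as no finite statistic exists. Group sizes below 2 are
rejected.

Benjamini–Hochberg adjustment is applied per analyte across its condition
pairs by default, with a global family option. The implementation
delegates to statsmodels; the test suite checks it against a brute-force
step-up oracle. Note that the adjusted-value map is *not* idempotent (for
p = (0.25, 1.0), adjustment gives (0.5, 1.0) and re-adjustment (1.0,
1.0)); the invariant that does hold, and is tested, is that thresholding
adjusted values at α reproduces the classic step-up rejection set on the
raw p-values. Values are not log-transformed by default; an option
exists. α defaults to 0.05.

## Synthetic study generator

The generator exists so that every stage of the pipeline is testable from
printed summary statistics alone. The default study spec encodes four
growth conditions — G. sulfurreducens on a poised electrode and on
fumarate, E. coli in Geobacter medium and in M9 — with iron quotas for
all four and macromolecular plus elemental analytes for the three
conditions in which they were assayed. Default n = 3 replicates per
condition, chosen to mirror typical biological-triplicate practice; the
true replicate counts behind the summaries are not public, and the
generator claims to match only the configured means and SDs.

Noise is independent Gaussian per (condition, analyte), truncated at zero
by resampling (negative contents are unphysical; at the configured
parameters the truncation bias is well under the replicate SE). Elemental
analytes are drawn as C, H, N and ash, with O derived by difference, so
every synthetic replicate closes to 100% exactly — reproducing the
measurement process rather than renormalising five noisy draws. No
between-analyte covariance is modelled: none is recoverable from printed
tables. Consequences for interpretation: passing tests demonstrate
correct arithmetic and statistical behaviour under independent Gaussian
noise, not robustness to correlated assay errors, batch effects, or
non-Gaussian contamination in real measurements.

Generation is deterministic for a fixed (spec, seed); the full-study
generator spawns an independent substream per condition so conditions can
be regenerated in isolation.

## Problem sizes and numerical choices

Stochastic checks use fixed seeds throughout. Parameter-recovery tests
draw n = 1,000 replicates per cell (bound 4·SD/√n, with a 0.15-point
allowance for the O-by-difference rounding residual); the headline
generator check draws n = 10,000 iron replicates (sample mean within 1%
of the configured 1,970 μg/g); the Welch size simulation runs 10,000 null
tests at 30 per group — small enough that the Satterthwaite df
approximation is effectively exact (at n = 5 the test is measurably
conservative, empirical size ≈0.045, and a band around 0.05 would be the
wrong check). Floating-point closure identities are asserted to machine
precision; published-value reproductions are asserted at the precision
the values are printed with (2 decimals for subscripts and densities,
whole mA for currents, 1 significant figure for per-cell contents).

## Known limitations

- The Liebig ceiling ignores chelation, precipitation and uptake
  kinetics; for sulfide-containing anaerobic media it is an upper bound
  for some metals and the supplement flag only coarsely addresses this.
- The empirical formula covers C/H/O/N plus ash only; S and P are not
  resolved, and ash is treated as inert mass.
- Mean±SD pseudo-replicate expansion fixes n = 3 and symmetry; any
  statistic beyond mean and SD computed from expanded data is an
  artefact of the construction.
- The generator's independence assumptions understate the variance of
  derived quantities (e.g. formula subscripts) relative to correlated
  real-world assay noise.
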