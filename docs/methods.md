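# Methods

This note documents the models behind `syntropyr`, the assumptions they
make, and the choices taken where the design was genuinely open.

## Reaction thermodynamics (`thermo`)

The reaction network consists of six reactions: the polysulfide pathway
(eq1), the H₂S (Wächtershäuser) pathway FeS + H₂S → FeS₂ + H₂ (eq2), its
four-fold multiple (eq3), hydrogenotrophic methanogenesis CO₂ + 4 H₂ →
CH₄ + 2 H₂O (eq4), the syntrophic net reaction 4 FeS + 4 H₂S + CO₂ →
4 FeS₂ + CH₄ + 2 H₂O (eq5), and sulfide oxidation to zero-valent sulfur
H₂S → [S°] + H₂ (eq6). Standard Gibbs energies are biochemical-standard
(ΔG°′: pH 7, 25 °C, unit activities), so protons never appear in the
reaction quotient. eq1's energy is known only as a range (−75 to
−64 kJ mol⁻¹); it is stored as such with the midpoint exposed as the
scalar, and eq1 participates only in reporting, never in the eq5
coupling.

Conditions enter through ΔG = ΔG°′ + RT ln Q, with

* aqueous activities equated with molar concentrations and gas activities
  with partial pressures in bar — no activity-coefficient model, matching
  the precision of the underlying arguments;
* solids and water fixed at unit activity (a warning is logged if the
  caller supplies activities for them);
* temperature entering only through RT (no van 't Hoff enthalpy
  correction; the incubation temperature 301.15 K may be supplied but the
  default is 298.15 K).

Stoichiometric coefficients are exact rationals (`fractions.Fraction`),
so coupling reactions cancels shared intermediates (H₂ between eq3 and
eq4) exactly rather than to floating-point tolerance. The critical
activity of a species (e.g. the H₂ partial pressure at which eq6 reaches
an energy-conservation threshold) is obtained by closed-form inversion of
the ΔG expression and round-trips through `delta_g` to 10⁻⁹ kJ.

Redox potentials of couples written against H₂ use
E°′ = E°′(2H⁺/H₂, pH 7) + ΔG°′·10⁶/(nF) with E°′(2H⁺/H₂) = −414 mV by
default. This reference is configurable because literature values between
−407 and −414 mV are all consistent with the −620 mV (two significant
figures) usually quoted for the FeS₂/(H₂S + FeS) couple; the module
computes −626.5 mV with the default.

An ambiguity worth stating: the commonly cited minimum free-energy
change for microbial energy conservation is about −11 kJ mol⁻¹ (one third
of an ATP equivalent). Under the syntrophic window conditions (5 mM H₂S,
1 µM [S°], 10⁻⁴ bar H₂) the computed ΔG of eq6 is ≈ −15.9 kJ mol⁻¹,
comfortably below that level, and the critical H₂ pressure at exactly
−11 kJ mol⁻¹ is ≈ 7.3 × 10⁻⁴ bar. The module reports both the computed
ΔG and the threshold comparison instead of collapsing them.

## Serum-bottle chemistry (`geochem`)

The experimental unit is a 180-mL bottle with 70 mL of liquid (110 mL
headspace) at 301.15 K and ~1 bar. Sulfide speciation uses the first
dissociation only (pKa₁ default 7.0, configurable); S²⁻ is neglected
(pKa₂ > 12, medium pH 7.2–7.4). Headspace H₂S follows a dimensionless
Henry constant k = c_gas/c_aq = 0.093 (28 °C) applied to the **neutral**
H₂S fraction — the convention is not universal, so it is echoed in every
report. Gas amounts are ideal (n = PxV/RT); dissolved CH₄ is neglected
when converting headspace CH₄ to "mmol per L of culture" (low solubility,
and headspace gas chromatography is the reporting convention). The
default sulfide loading (350 µmol added + 1 mM reductant in 70 mL) gives
420 µmol ≙ 6.0 mM.

## Mössbauer simulation and fitting (`mossbauer`)

Each mineral phase is one Voigt site: a set of lines sharing a Lorentzian
HWHM fixed at 0.138 mm s⁻¹ and a single site-level Gaussian broadening σ.
This is a deliberate single-component reduction of Voigt-based fitting
(full hyperfine-parameter distributions are unnecessary for
phase-fraction quantification, which is the only quantity consumed
downstream). Line structures:

* singlet — one line at the center shift δ (mackinawite FeS at 5 K);
* doublet — δ ± ΔE_Q/2 at half intensity (pyrite FeS₂);
* sextet — six lines at δ + s_i·ΔE_Q/2 + B_hf·c·g_i with
  s = (+1,−1,−1,−1,−1,+1), relative splittings
  g = (−1, −0.579, −0.158, +0.158, +0.579, +1) from the ⁵⁷Fe g-factors,
  and powder intensities 3:2:1:1:2:3. The calibration constant c is fixed
  by α-Fe: B_hf = 33.0 T ↔ outer-line span 10.66 mm s⁻¹.

Simulation places unit-area Voigt profiles (scipy's `voigt_profile`) so
that each site's integrated absorption equals total area × area fraction;
Gaussian noise is seeded and optional. Fitting is bounded nonlinear least
squares (`scipy.optimize.least_squares`, trust-region reflective) over
per-site (δ, ΔE_Q, B_hf, σ) plus absolute areas and a flat baseline,
starting from the caller's template, with up to five deterministically
jittered restarts on failure; non-convergence is reported as a flag,
never an exception. Spectral area is equated with phase abundance under
the assumption of equal recoilless fractions across phases at 5 K.

The nominal site library (FeS₂ doublet δ 0.40 / ΔE_Q 0.61; FeS singlet
δ 0.45; Fe₃S₄ sextet B_hf 32 T; FeSₓ broad sextet B_hf 24 T, σ 0.9)
contains representative values chosen to give realistically shaped,
partially overlapping components — only the 32 T greigite field is a
literature-anchored number. The undefined "intermediate FeS₂−FeS" phase
has no default site; users can supply their own.

## Stoichiometry and bioenergetics (`stoich`)

Pyrite formed is computed on an Fe-molar basis (total Fe conserved across
phases in closed bottles; 1 Fe per FeS₂), so FeS₂ (mM) = total Fe (mM) ×
area fraction. The ideal syntrophic coupling fixes pyrite:methane = 4:1.

Two yield routes are kept separate because they answer differently:

1. **energy route** — energy per liter = (FeS mM / 4)·|ΔG per mol CH₄|,
   divided by the ATP synthesis cost (60–70 kJ mol⁻¹, propagated as an
   interval) and multiplied by Y_ATP = 10.5 g mol⁻¹. At 5 mM FeS and
   −295 kJ mol⁻¹ this gives 5.3–6.1 mM ATP and 55–65 mg dry mass L⁻¹.
2. **quantum route** — ~20 kJ (1/3 ATP equivalent) conserved per partial
   reaction, five partial reactions per net turnover. Because the ATP-
   equivalent accounting is ambiguous, an explicit `basis` flag selects
   either 5/3 mmol ATP L⁻¹ at full conversion ("printed", → 17.5 mg L⁻¹)
   or 5 × 1.25/3 ≈ 2.08 mmol L⁻¹ ("partial_reactions", → 21.9 mg L⁻¹);
   the flag value is always echoed.

Cell densities convert to dry mass via 1 µm³ cell volume, wet density
1 g mL⁻¹ and 33 % dry matter: 9 × 10⁶ cells mL⁻¹ ≈ 3 mg L⁻¹.

## Temperature-response discrimination (`temperature`)

Biotic-like activity is modeled by the Rosso cardinal-temperature model
(parameters T_min, T_opt, T_max, peak; zero outside [T_min, T_max]),
abiotic-like by a 3-parameter logistic. Both are fitted by bounded least
squares with a fixed, deterministic list of starts (including a
support-edge start placing the cardinal temperatures at the observed
range, which recovers noiseless cardinal data exactly). Model choice uses
AIC; the small-sample correction (AICc) is applied when n > k + 2 and
plain AIC otherwise, since 5-point profiles with the 4-parameter cardinal
model make the AICc denominator vanish. |ΔAIC| < 2 → indeterminate. A
residual-variance floor of 10⁻¹² keeps perfect fits finite. Profiles that
are all (or all but one) zero are flagged as non-fits.

## Synthetic data (`synthetic`)

The generator emulates the study's scenarios from their reported
endpoints; the kinetic shapes are its own minimal choices (the study
constrains plateaus and final states, not rate laws):

* CH₄ rises along a normalized logistic from exactly 0 to exactly the
  plateau (J5: 0.7 mmol L⁻¹; penicillin: 0.15; penicillin + 79 % H₂: 12;
  BES and abiotic: 0);
* the pyrite fraction is pinned to the methane curve by the exact 4:1
  coupling in biotic scenarios (ΔFeS₂ = 4·ΔCH₄), which places the J5
  final FeS₂ fraction at 4 × 0.7/5 = 0.56, inside the reported 53–63 %;
  Fe₃S₄ (7.5 %) and FeSₓ (36.5 %) rise along the same progress curve and
  mackinawite is the remainder, so phase fractions always sum to 1 over
  constant total iron;
* dissolved sulfide decays from 6.0 mM to the scenario's residual level
  (J5: 0.57 mM, the midpoint of the reported 0.04–1.1 range; controls:
  3.7 mM); the loss is partitioned exactly into pyrite formation (1 S per
  FeS₂ from solution) and uptake by the operationally defined FeSₓ phase,
  closing the sulfur balance identically in noiseless mode;
* cells grow exponentially between the reported initial and final
  densities (J5: 2 × 10⁵ → 4 × 10⁶ mL⁻¹, within the reported 2–9 × 10⁶);
* the temperature series evaluates the cardinal model (T_min 4, T_opt 28,
  T_max 60 °C, peak 0.56) at the five incubation temperatures, making the
  28 °C optimum an exact generating truth; an optional flag counts the
  undefined intermediate phase at 16/46 °C toward pyrite activity;
* noise is multiplicative Gaussian per observable (default 5 %,
  truncated at zero) from a single seeded generator; noisy phase
  fractions are renormalized so iron conservation is never violated.
  Replicate-to-replicate variation is modeled at the seed level.

What passing tests on these data do **not** show: real spectra have
velocity-drive nonlinearity, phase-dependent recoilless fractions and
thickness effects; real cultures have lag-phase variability, non-logistic
kinetics and sampling losses. The generator validates the analysis
chain's correctness, not its robustness to those effects.

## Problem sizes

Spectra use a 1024-point grid over ±12 mm s⁻¹; replicate studies use 20
seeded noisy spectra (noise 2 % of peak depth) and 100 seeded noisy
temperature profiles (noise 5 % of the peak activity). Trajectories use
25 time points over 207 days. These sizes resolve all line structure and
give stable replicate statistics at desk scale.
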