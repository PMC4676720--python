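# Methods

## Model

The package models inhibition of PLC by cations as *charge shielding of the
substrate*, not inhibition of the enzyme.  The water-soluble PIP₂ analog
used in the fluorogenic assay is not embedded in a membrane, so no
Gouy–Chapman surface treatment is attempted: the substrate is a point
charge at a fixed local potential Ψ.  The assumptions are:

- equilibrium everywhere (pre-incubation with cations before the reaction
  starts justifies ignoring accumulation kinetics);
- cation enhancement near the substrate follows the Boltzmann factor
  exp(−z·Y·q·Ψ/k_B·T); monovalent ions are neglected (their enhancement is
  an order of magnitude below the divalent one and they are part of the
  background ionic strength);
- screening follows a Hill-type isotherm in the effective concentration
  with coefficient 1 (as written, no cooperativity);
- chemical binding multiplies an independent 1/(1 + K·C_eff) occupancy
  term — binding and screening are treated as separable;
- enzyme velocity is Michaelian in free substrate, v = S/(S + K_d), with
  the catalytic constant unaffected by cations.

**Normalization.**  Measured activity is normalized to the cation-free
condition, so the model output is v(C)/v(0).  This removes the scale
constants (enzyme amount × k_cat) from the equations entirely; they are
unidentifiable from normalized data and never appear as parameters.

**Identifiability of Ψ.**  The transformation Ψ → Ψ′, L → L·f′/f,
K → K·f/f′ (f the Boltzmann factor) leaves every model curve unchanged, so
Ψ cannot be estimated from dose–response data.  It is fixed at −25 mV (the
molecular-dynamics / monolayer estimate for PIP₂) and k_BT/q is evaluated
from physical constants at T = 295.15 K (≈ 25.4 mV), not hard-coded as
25 mV.

**Valence scaling of L.**  L is calibrated with Mg²⁺ (z_ref = 2) and scaled
as L_z = L_ref·z_ref/z for other cations, using the nominal valence z (not
z·Y).  This is the literal reading of "reduced proportionally to valence";
the rule is pluggable (`l_scaling="constant"` disables it), which the
property tests use to isolate pure-charge effects.

**W (neomycin plateau).**  W is interpreted as a residual unshieldable
substrate concentration in the same units as [S]_tot (µM).  With W = 4.1 µM,
[S]_tot = 30 µM and K_d = 50 µM the saturating-dose activity is
(W/(W+K_d))/([S]_tot/([S]_tot+K_d)) ≈ 0.20, consistent with the observed
~20% plateaus.  W is a free parameter only for plateau-capable cations
(neomycin); it is 0 otherwise.

**Single-cation treatment.**  The 16.4 µM background free Ca²⁺ of the assay
solution is ignored in the shielding model (its K·C_eff contribution is
~2%).  An optional multiplicative multi-cation mode
(`multi_cation_activity`) multiplies the per-cation suppression factors for
exploratory use; all fitting is single-cation.

## Reference parameters

| parameter | default | units | role |
|-----------|---------|-------|------|
| Ψ | −25 | mV | local potential; fixed, never fitted |
| T | 295.15 | K | room temperature |
| L_ref | 32 | mM | half-maximal effective concentration at z_ref = 2 |
| [S]_tot | 30 | µM | substrate concentration of the assay |
| K_d | 50 | µM | effective enzyme–substrate dissociation constant; fixed for all isoforms |
| K (Mg/Ca/Ba) | 1 / 190 / 460 | M⁻¹ | chemical binding (1/K = 1000 / 5.2 / 2.1 mM) |
| K (put/spd/spm/neo) | 0.278 / 52.6 / 100 / 1000 | M⁻¹ | (1/K = 3600 / 19 / 10 / 1 mM) |
| Y (organics) | 0.12 | – | crowding / charge-separation factor, shared |
| W (neomycin) | 4.1 | µM | unshieldable substrate |

## Chelator speciation

Free-ion concentrations of EGTA-buffered solutions are computed the way
Ca²⁺-buffer calculators (Maxchelator family) do:

- ligand protonation is folded into an apparent association constant per
  metal–ligand pair, K_app = (K_ML + K_MHL·[HL]/[L]) / α_H, referenced to
  the pooled free ligand;
- ionic strength is adjusted with the Davies equation
  (log γ = −A(T)·z²·(√I/(1+√I) − 0.3·I)) applied per reaction charge
  balance, with the Debye–Hückel A evaluated from the temperature-dependent
  dielectric constant of water;
- temperature is adjusted by van't Hoff when reaction enthalpies are
  tabulated (the shipped table is referenced to 20 °C, so these are inert
  at the assay temperature).

The coupled mass-action/mass-balance system is solved on log₁₀ free
concentrations: a damped fixed-point pass (500 geometric-damping
iterations, positivity preserving) seeds a Powell hybrid Newton solve,
followed if necessary by damped Newton polish; convergence requires every
relative mass-balance residual ≤ 10⁻¹². Failure raises an error carrying
the last residual.  A brute-force log-grid residual scan serves as the
independent oracle in the tests.

**Stability constants.**  Critically evaluated EGTA constants differ by up
to ~0.15 log unit between compilations and ionic media (e.g. pKa₁ spans
9.40–9.58; log K_CaL spans 10.86–10.97), and different calculator versions
ship different selections — enough to move computed free Ca²⁺ by tens of
percent.  The packaged table (pKa 9.54/8.93/2.66/2.00; Ca 10.97, Mg 5.28,
Ba 8.41 for ML, with MHL species; I = 0.1, 20 °C) adopts the within-range
selection that best matches the calculator outputs the assay conditions
were designed with.  Speciation results should therefore be read with a
~10% tolerance where the constant-set version is unknown.

**pH.**  The assay buffer is reported as pH 7.3 (titrated with KOH); the
package default is 7.3.  HEPES, DTT, BSA, K⁺ and Cl⁻ are treated as inert
except through the stated ionic strength (0.073), matching standard
calculator practice.

## Staged fitting

The staged order L → K → Y → W mirrors how the parameters are defined:

1. **L** on reference-divalent (Mg²⁺) curves, one L per enzyme, averaged.
   Mg²⁺'s own K stays at its small reference value.
2. **K** per cation, L frozen.
3. **Y** jointly with putrescine's K against a same-enzyme Mg²⁺ reference,
   then frozen for all organic polycations.  Y and K are only weakly
   separable for a divalent organic, so the start point comes from a 2-D
   (Y × K) grid scan; without it the optimizer can collapse onto a bound
   under noise.
4. **W** on neomycin curves, bounds [0, [S]_tot).  In the full pipeline
   (`staged_fit`) neomycin's K and W are estimated jointly in this stage,
   since a K fitted with W clamped to 0 would be biased.

Optimizer: bounded trust-region least squares (`scipy.optimize.
least_squares`, trf) with tolerances 10⁻¹⁴, coarse log-grid starting
values, and Jacobian-based scaling.  Residuals are unweighted by default
(1/SD² weighting available).  Estimates that land on a bound are reported
with an explicit boundary flag rather than silently clipped; flat
(no-signal) curves yield NaN plus a warning, never a silent estimate.
Objective values at the grid start and at convergence are logged in the
diagnostics.  A global simultaneous `joint_fit` is provided for comparison;
the staged fit is canonical.

**Bootstrap.**  Case-resampling over the replicate values within each dose
level, refitting each resample; percentile intervals; n_boot ≥ 100
enforced; fully determined by the seed.

## Synthetic data

The dose–response generator emulates the normalized-activity measurements:
the model curve plus i.i.d. Gaussian replicate noise (default SD 0.05 on
normalized activity, 6 replicates per dose, emulating the 4–8 replicates
of the assay), clipped below at −0.05.  Dose grids default to log-spaced
ranges matching the experiments: 10 µM–100 mM for divalents (including
putrescine, which inhibits only at tens of mM), 1 µM–30 mM for tri/tetra-
valent polyamines, 0.1 µM–10 mM for neomycin.  The progress-curve generator
solves the irreversible Michaelis–Menten ODE in closed form (Lambert-W) and
maps product to fluorescence through a linear standard curve.

What the generator does *not* emulate: dose-dependent (heteroscedastic)
noise, plate effects and drift, inner-filter/photobleaching artifacts,
enzyme instability over incubation, or deviations of real curves from the
model family itself.  Passing recovery tests therefore demonstrates the
estimator's correctness and conditioning under the model's own assumptions,
not the model's adequacy for any particular experimental data set.

Published specific activities for the PLC isoforms are dimensionally
inconsistent with the observed substrate-depletion timescales
("mmol/min/mg" would exhaust 30 µM substrate in milliseconds), so the
generator treats specific activity as a free field and hard-codes no
literature value.

## Rate extraction

Fluorescence → product via the inverse of an OLS standard curve (intercept
fitted, not forced through zero, since blank fluorescence is nonzero);
specific activity is the product slope over a configurable window times
reaction volume divided by enzyme mass.  Default windows mirror the assay
protocol (slope at 10 min for the fast PLCγ1, 30 min for PLCβ1/δ1;
endpoint incubations 90/60/12 min for β1/δ1/γ1).  Early-window slopes
approximate V_max·S₀/(K_m+S₀) when < 5% of substrate is consumed; both
slope-based and endpoint readouts are supported, slope being the default.

## Problem sizes and tolerances

The recovery and acceptance computations use 12-point Mg²⁺ grids
(0.1–300 mM) for three enzymes, a 12-point putrescine grid and a 14-point
neomycin grid (0.1 µM–10 mM); noiseless round-trips recover L, K, Y, W to
better than 10⁻³ relative.  The bootstrap coverage study uses 100
simulation repeats × 100 bootstrap resamples at noise SD 0.05.  IC₅₀ is
found by bracketing + Brent bisection to 10⁻⁶ relative, returning "none"
when the plateau activity exceeds 0.5.

## Known limitations

- No spatially resolved electrostatics (Poisson–Boltzmann / Gouy–Chapman);
  the point-charge treatment is only appropriate for the soluble substrate
  analog, not membrane-embedded PIP₂.
- The chelator table covers Ca/Mg/Ba–EGTA; other metals or ligands (ATP,
  BAPTA, HEDTA) require extending the TSV, and activity-coefficient theory
  beyond Davies is out of scope.
- Model-predicted IC₅₀ values under the reference parameters are internally
  consistent but are not calibrated to reproduce any particular published
  per-enzyme IC₅₀; per-enzyme differences enter only through K_d, which is
  deliberately fixed.
- The stated "2.7× increase of L per two-fold potential increase" relation
  is not reproduced by the z = 2 Boltzmann factor alone (~7×) and is not
  used anywhere in the package.
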