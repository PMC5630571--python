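# Methods

This note documents the models, conventions and numerical choices behind
`mixobal`, and what the synthetic-data round trips do and do not
demonstrate about real fermentation data.

## Stoichiometric framework

Everything is booked per C-mol. Degrees of reduction use the ammonia
nitrogen basis, γ = 4 + h/c − 2 o/c − 3 n/c; for carbon-free H₂ the value
is 2 electrons per mole, and N₂ is treated as inert (0). The biomass
elemental composition is not measurable in-line; we adopt the standard
pseudo-formula CH₁.₈O₀.₅N₀.₂ (γₓ = 4.2, 24.63 g per C-mol) and make it
configurable through the registry table. Every registry entry is validated
against its molar mass to 1 %, and each γ is cross-checked in the test
suite against an independent electron count from the balanced combustion
half-reaction (O₂ demand × 4).

The printed electron-balance formula for fermentations lists only product
and biomass terms; molecular hydrogen must nevertheless be carried as a
product at 2 electrons per mole (and as an electron input when consumed),
otherwise no acidogenic stoichiometry can close at 1. `mixobal` always
includes the H₂ term and says so in its report notes.

**Apparent vs net recoveries.** Apparent yields divide by sugar C-mol only
— never by consumed gas carbon — because that is what makes values above
the heterotrophic ceiling (2/3, reported truncated as 0.66) diagnostic of
inorganic carbon capture. A perfectly measured conservative dataset,
however, closes at exactly 1 if the condition's *own* net CO₂/H₂ evolution
enters the balance: whatever the culture recaptures simply vanishes from
the evolved-gas term. The package therefore credits the endogenous CO₂ and
H₂ terms *per C-mol of sugar from the N₂-sparged control run* (the same
baseline-subtraction logic used for the consumption arithmetic). With this
convention the heterotrophic control closes at exactly 1 and capture
appears as a percent excess over the control, which is also the default
baseline for `excess_recovery` (the theoretical maximum is available as an
alternative). The *net closures* — products + biomass + net evolved CO₂ +
net CO over sugar, and the electron analogue with net H₂ — are reported
alongside; they equal 1 for any conservative dataset and serve as a data-
quality check, not a capture diagnostic. Whether dissolved CO₂/bicarbonate
carbon belongs in the carbon balance is ambiguous in practice; the default
excludes it and reports the Henry-law dissolved inventory separately.

## Gas calculations

Volumetric fractions are converted to molar flows by the ideal-gas law at
a stated reference (default 37 °C, 1 atm — reactor conditions; 0 °C/25 °C
standards are a parameter away). Henry's law C = k·p uses the tabulated
37 °C constants (g/L per atm): CO 0.0225, CO₂ 1, O₂ 0.033, H₂ 0.0014. The
CO₂ value is kept as tabulated even though handbook values differ, so that
the package's arithmetic reproduces the source method's; all constants are
overridable. N₂ and Ar have no constant and are rejected.

Net consumption is C = I + E − O, positive = consumed. A published variant
writes C = (O − I + E)·(−1), which contradicts its own zero case (O = I + E
must give 0); we treat the sign on E there as a typo and implement the
self-consistent form. Dissolved gas is an equilibrium inventory only: at
steady state it does not enter the rates (no kLa/mass-transfer dynamics
are modeled), and it is always below the gas fed per residence time (a
property test).

## Steady-state detection

A window is accepted when, for every monitored variable, |OLS slope ×
window length| < rel_tol × |window mean|, with rel_tol = 2 % by default —
the source protocol "verifies" steadiness without stating a criterion, so
the tolerance is an artifact choice, documented and configurable. Windows
never start earlier than 3 residence times (1/D) after the last
perturbation marker (markers are explicit inputs, not inferred), and must
span at least one residence time so that a slowly drifting signal cannot
qualify via a short quiet tail. Variables with near-zero means (absent
gases) fall back to 5 % of their overall range as the tolerance scale.
Summaries report mean, SE = s/√n and n per variable; at least 3 samples
are required, matching the sampling protocol.

## Oscillation and growth-break analysis

Oscillations are characterised phenomenologically: moving-median
detrending (window 6 h default, > the expected period), peak picking with
prominence ≥ 3× the local noise MAD (noise estimated from median absolute
successive differences), period = median inter-peak interval, amplitude =
half the median peak-to-trough. Two robustness guards are applied: the
prominence floor is never below 35 % of the detrended signal's robust
spread (suppressing median-filter residue around ramp kinks in smooth
data), and peaks within half a detrend window of the series edges are
excluded (boundary region of the filter). Synchrony is the zero-lag
Pearson correlation of the detrended pair (exactly 1 for identical
series, −1 for mirrored ones); the lag is the argmax of the normalised
cross-correlation within ±1 period. "In phase" means |lag| < 10 % of the
period and synchrony ≥ 0.8 — thresholds chosen as artifact conventions,
configurable, since the phenotype is reported graphically in the source
literature. No Fourier/wavelet decomposition is attempted. Onset is the
first upward threshold crossing (default 3 % v/v) by linear interpolation.
The diauxic break is a two-segment least-squares fit on log biomass over
all admissible breakpoints; a break is significant when the two-segment
RSS is below half the single-line RSS *and* the slope difference exceeds
twice its combined SE, in which case the two specific growth rates are
reported (otherwise the common rate is reported on both sides).

## Nitrite-pulse analysis

Each response is an integral of the deviation of a gas uptake rate from
its pre-pulse steady baseline: displaced CO = ∫(baseline − observed),
extra H₂ = ∫(observed − baseline). The integration window — unstated in
the source protocol — runs from the pulse to the first post-peak return of
both deviations within max(2 SE, 1 % of the peak deviation), capped at one
residence time and at the next event; unfinished transients are flagged.
This truncation under-measures an exponential-tailed transient by well
under 1 %, visible in the worked example (2.486 vs 2.5). The biomass
response is the post-transient plateau minus the pre-pulse mean, times the
culture volume (0.7 L default). Dose-response slopes are ordinary least
squares with a fitted, reported intercept (the source regressions are not
forced through the origin); a forced-origin mode exists. Doses above 24 mM
are washout events: flagged, excluded from regression, never analyzed.

## The synthetic generator

Chemostat steady states are generated **algebraically** from configured
fluxes, not by ODE integration — the analysis consumes steady windows and
transients, not mechanisms. The reference heterotrophic spectrum (C-mol
per sugar C-mol: butanol 0.20, acetone 0.06, ethanol 0.04, acetate 0.08,
butyrate 0.15, biomass 0.10, CO₂ 0.37, H₂ 0.375 mol/C-mol) closes both
balances exactly and is fully configurable. Default operating conditions
are the study's: D = 0.135 h⁻¹, 0.7 L, 12.48 L/h sparge, 30 g/L sucrose +
15 g/L fructose feed, 37 °C, pH-controlled; syngas blends are fractions of
a 20/20/10/50 CO/CO₂/H₂/N₂ full-strength mix (a measured inlet such as
11.17/11.01/4.40 % can be supplied instead of the nominal one).

The carbon-electron flow logic: below a 5 % v/v CO₂ switch threshold the
culture oxidizes CO (CO + H₂O → CO₂ + H₂, one-for-one); above it, C-1
assimilation routes captured CO₂/CO carbon into butanol and butyrate
(70/30 default) without changing biomass. The regime is decided on the
**inlet** CO₂ fraction (the outlet fraction depends on the regime itself);
an explicit override exists. At the canonical blends this lands the 9 %
condition in the oxidation regime (inlet CO₂ 1.8 %) and the 32/60 %
conditions in the C-1 regime (6.4/12 %). Capture is parameterised by two
fractions — extra product carbon per sugar carbon (0.17 at high syngas,
0.11 at medium) and extra product electrons per sugar electron (0.27 and
0.19) — and the generator realises the electron target by a carbon-neutral
acetate→butanol shift, with the required electrons drawn from consumed H₂
and the CO share of captured carbon. Both balances then hold to machine
precision before noise (a 100-random-scenario property test), and the
analysis pipeline recovers the configured fractions exactly in the
noise-free limit.

Fed-batch runs use a two-rate exponential biomass rise (defaults μ₁ = 0.30,
μ₂ = 0.10 h⁻¹, break at 10 h, cap 4 g/L), gas ramps proportional to
biomass, and a **phenomenological bounded limit cycle** (default period
2 h, amplitude 0.5 % v/v) superimposed once *both* gases have crossed the
3 % onset — the oscillation is a described phenotype, not a mechanism, so
no feedback model is fitted or simulated. Nitrite pulses superimpose
unit-area alpha-shaped transients (τ = 0.75 h) scaled by the configured
stoichiometries (2.5 mol H₂ and 1.0 mol CO per mol NO₂⁻, 0.05 g biomass
per mmol) on the steady outlet flows; overlapping schedules are rejected,
and washout doses decay biomass at rate D. Measurement noise is iid
Gaussian per channel, truncated at physical bounds, bit-reproducible under
the scenario seed.

**What the round trips show — and don't.** Passing tests demonstrate that
the analysis chain is self-consistent: it recovers exactly the quantities
the generator encodes, under the generator's assumptions (ideal gas,
equilibrium solubility, constant flows, iid noise, exact conservation).
Real data violate several of these — analyzer drift, kLa-limited gas
transfer, evaporation and volume changes, correlated noise — so the round
trips validate the arithmetic and its conventions, not instrument
behaviour.

## Problem sizes

Default series use a 0.1 h grid over 60 h (chemostat) and 0.02 h over 30 h
(fed-batch); the nitrite coverage study uses 200 replicates of a
three-pulse schedule at low analyzer noise (SD 0.02 % v/v on fractions,
0.02 g/L on biomass). These sizes keep the full suite and the acceptance
script to a few seconds while leaving ≥ 50 samples in every steady window.

## Known limitations

* No kinetic rate laws, mass-transfer dynamics or thermodynamic
  feasibility checks; steady states are algebraic constructs.
* The endogenous-credit convention assumes the condition's fermentative
  CO₂/H₂ production per C-mol of sugar equals the control's; a culture
  whose decarboxylation stoichiometry shifts under syngas would bias the
  apparent recoveries.
* Oscillation metrics assume a uniform sampling grid and a single
  dominant period.
* The dose-response CIs at three doses rest on one residual degree of
  freedom; they are honest but very wide, which is why coverage (not CI
  width) is the tested property.
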