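# Models and methods

This note documents the models the package implements, the conventions and
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the known limitations. All thermodynamic quantities are
per mole of subunit unless stated otherwise; energies in kcal/mol,
temperatures in kelvin internally (°C at the user-facing boundaries), gas
constant R = 1.9872×10⁻³ kcal/(mol·K), standard state 1 M. Identities
involving tabulated 25 °C parameters are evaluated at T = 298.15 K.

## Oligomer ⇌ monomer equilibrium

The assembly Aₙ ⇌ n·A (n = 16 for the chaperonin hexadecamer) is
parameterized by a *per-subunit* dissociation constant K_d with

    [A]ⁿ / [Aₙ] = K_d^(n−1).

This convention is deliberate: the raw mass-action quotient has units
M^(n−1), and only the per-subunit root makes ΔG_d = RT·ln(K_d/1 M) a
per-subunit quantity directly comparable across stoichiometries. At n = 2
it reduces to the familiar dimer convention. Mass balance over total
subunit concentration C gives

    a + n·aⁿ/K_d^(n−1) = C,

whose left side is strictly increasing in the free-monomer concentration
*a*, so the physical root on [0, C] is unique. It is found by Brent's
method at machine-precision relative tolerance, with the aⁿ/K_d^(n−1)
term evaluated in the log domain (aⁿ underflows naive evaluation long
before the physics becomes uninteresting). At C = 0 the all-monomer limit
(fraction 1) is returned by continuity.

The critical transition concentration — the total concentration at which
half the subunits are free — has the closed form CTC = 2·K_d·n^(−1/(n−1))
(substitute a = C/2); the implementation brackets with the closed form and
refines by bisection on the monotone fraction-vs-concentration curve, and
the tests verify both against an independent grid-refinement oracle. Note
that at n = 2 this gives CTC = K_d exactly.

Intermediate species (dimers … octamers) are excluded: the two-state
hexadecamer–monomer model is the stated analysis model, and dilution data
superimpose on it without intermediates. Only equilibrium speciation is
modelled, not assembly/disassembly kinetics.

## Dilution ITC

Each injection of volume v into a fixed-volume perfusion cell (V₀ = 1 mL
default) (1) dilutes the pre-injection contents by (1 − v/V₀), expelling
displaced liquid at pre-injection composition, (2) mixes in the aliquot at
syringe-equilibrium composition, (3) re-equilibrates speciation at the new
total concentration, and (4) releases heat

    q = ΔH_d · V₀ · ([A]_equilibrated − [A]_mixed).

The perfusion convention is the de facto standard for overflow cells; a
growing-volume (no-displacement) variant is available via a flag and
differs by ≲ 2–3% at the default 5 μL/1 mL ratio, peaking at the steep
transition injection.

Default protocol: 18 × 5 μL injections; the syringe concentration is
*computed* so the cell trajectory crosses the CTC after half the
injections, placing the informative sigmoid inflection mid-series. Fitting
minimizes unweighted least squares on the per-injection heats over
(log₁₀K_d, ΔH_d) via Levenberg–Marquardt (lmfit), with stoichiometry fixed;
K_d's standard error is delta-method-propagated from the log parameter.
ΔG_d and ΔS_d are attached as derived quantities. Flat-signal series and
non-convergence attach explicit warnings. A constant per-injection offset
(blank-titration correction) can optionally be co-fitted; by default heats
are assumed baseline-subtracted.

At the default noise model the ΔH_d estimate is limited by the few
high-signal early injections: its scatter at the wild-type-like truth is
≈ 3 kcal/mol (≈ 0.9%), with no detectable bias. Recovery-rate checks
against a ± 5 kcal/mol band therefore sit near a 90% per-replicate pass
probability; this is the information content of an 18-injection series at
this noise, not an optimizer artifact.

## Binding ITC ("one set of sites")

The hexadecamer carries 16 identical, independent nucleotide sites — one
per subunit — so the isotherm is bookkept per subunit: site concentration
= n_sites × subunit concentration, and n_sites ≈ 1 corresponds to a molar
ratio of 16 per complex. Bound ligand comes from the site-conservation
quadratic in the cancellation-free form 2·L_t·S_t/(b + √(b² − 4·L_t·S_t)),
b = L_t + S_t + K_d, verified against a free-ligand bisection oracle to
1e-10. Titration simulation uses the same perfusion displacement as the
dilution cell. Assembly state is assumed constant during the titration
(binding is not coupled to the dissociation equilibrium): the analysis
model is a pure one-set-of-sites fit, and coupling would contradict it.

The fit optimizes (n_sites, log₁₀K_d, ΔH); ΔS = (ΔH − RT·ln K_d)/T is
derived and reported in cal/(mol·K) to match binding-table convention. A
Wiseman c-value (n·[M]/K_d) outside [0.01, 1000] attaches an
identifiability warning. Default protocol: 5 μM subunit in the cell
(c ≈ 15–30 for the built-in scenarios), 20 × 5 μL injections, syringe
ligand concentration computed to reach a final molar ratio ≈ 2.2 per
subunit. At the default noise, n and ΔH are recovered to ~1–2%, while a
single titration determines K_d only to ~10% — binding-constant precision
beyond that requires replicate experiments, regardless of fitter.

## DSC

**Two-state model.** Excess heat capacity
Cp(T) = ΔH_cal·ΔH_vH/(R·T²) · K/(1+K)², with K following van't Hoff around
Tm (K(Tm) = 1). Peak height ΔH_cal·ΔH_vH/(4·R·Tm²) at Tm; area ΔH_cal.

**Dissociative model.** Aₙ ⇌ n·U with unfolded fraction α at total subunit
concentration C:

    K(T) = n·αⁿ·C^(n−1)/(1−α),

K van't Hoff in T, anchored at α = ½ at the stated midpoint Tm (optionally
at a reference concentration, which makes the apparent midpoint rise with
C — the experimental signature of dissociation-coupled unfolding). α(T) is
solved per grid point by a vectorized, bracketed bisection (110
iterations; tails beyond floating-point brackets use the asymptotic forms
α ≈ e^(rhs/n) and 1−α ≈ e^(−rhs), accurate to < 1e-13). Cp = ΔH_cal·dα/dT
with the *exact implicit derivative*

    dα/dT = (ΔH_vH/(R·T²)) / (n/α + 1/(1−α)),

chosen over finite differences because it is exact to solver tolerance,
needs no step-size tuning, and makes the n = 1 case reduce to the
analytic two-state expression to better than 1e-6 of peak height.

**Peak position and skew.** Because dα/dT is maximal where n/α + 1/(1−α)
is minimal, the peak sits at α = √n/(1+√n) — e.g. 0.8 at n = 16, and the
classic 2−√2 ≈ 0.586 for dissociating dimers — i.e. *above* the
half-conversion temperature. The curve rises slowly (scale n·R·T²/ΔH_vH,
≈ 20 K at the built-in parameters) and drops sharply (scale R·T²/ΔH_vH,
≈ 1.3 K): the broad skewed wing lies at temperatures below the peak, which
is the observed hallmark of dissociation-coupled unfolding. The package
reports the α = ½ temperature as Tm for the dissociative model with the
peak-maximum temperature alongside; for the two-state model the two
coincide. Tests assert the skew as the low-side half-width exceeding the
high-side half-width and the α = ½ midpoint lying inside the broad wing.

**Enthalpies.** ΔH_cal is always model-free trapezoidal integration of the
baselined trace. ΔH_vH comes either from a least-squares model fit (with
ΔH_cal held at its integrated value) or from the peak-shape formula
ΔH_vH = 4·R·Tm²·Cp_max/ΔH_cal; both are provided because published tables
rarely state which was used. R = ΔH_cal/ΔH_vH is attached. The visibly
biphasic appearance of some experimental traces is *not* modelled as two
independent transitions — the dissociative model's intrinsic asymmetry
stands in; no second-transition parameters exist to reproduce. Scan-rate
effects are ignored (equilibrium assumption); the rate is metadata.

**Baselines.** `linear` draws one line through pre- and post-transition
windows; `progress` interpolates between separate pre/post lines weighted
by the running normalized integral (the sigmoidal chemical baseline),
iterated 8 times to self-consistency. Windows default to the outer 12% of
the grid (≥ 10 points); a window is accepted as flat when its net
line-fit rise and its detrended scatter are each below 5% of the trace's
peak-to-peak range — windows riding the transition are rejected with the
candidates named. Steeper instrumental ramps than that envelope require
explicit windows.

**Concentration dependence.** The apparent calorimetric enthalpy at load
concentration C is fraction-assembled(C) × ΔH_full, with speciation
evaluated at the scan-start state: only assembled material contributes the
dissociation-coupled heat, so ΔH_app rises monotonically with C.

## Synthetic data

Generators produce the model curves above plus additive, independent
Gaussian noise: DSC σ = 1% of peak height; ITC σ = 1% of the largest
|injection heat| + a 0.1 μcal floor — representative of low-volume
calorimeters. Optionally a linear instrumental ramp is added to DSC traces
for exercising baseline subtraction. Identical seed and configuration give
bit-identical output (`numpy.random.default_rng`); every generator returns
a ground-truth record alongside the data. Scenario tables embed the
published central parameter values for the three protein variants; the
exothermic binding scenario uses the tabulated −26.7 kcal/mol.

Not emulated: 1/f baseline drift (handled by the baseline operations, not
the generator), scan-rate-dependent irreversibility, titrant heats of
mechanical injection, instrument binary formats, and inter-injection
kinetic lag. Passing recovery tests therefore demonstrates estimator
correctness and precision under the stated noise structure — not
robustness to every instrument pathology.

Default problem sizes — 18-injection dilution series, 20-injection
titrations, ~1000-point thermograms, 50-replicate recovery batches — keep
any single fit below ~0.1 s and the full validation suite a few seconds,
while matching the scale of the experiments they emulate.

## Design choices made where the design was open

* Per-subunit K_d root convention (above) rather than the M^(n−1)
  mass-action constant: dimensional consistency plus direct per-subunit
  ΔG_d.
* The DSC generation window defaults to 20–125 °C: wide enough that the
  slow low-temperature wing of the n = 16 dissociative trace integrates
  to ΔH_cal within ~1% on a physically scannable range.
* Report-table comparisons round half away from zero (the convention of
  printed tables) and treat "agreement at printed precision" as within
  one unit in the last printed digit, since the compared quantities are
  ratios/differences of numbers that are themselves rounded.
* kd is optimized as log₁₀(kd) in all fitters (positivity + conditioning),
  reported in mol/L with delta-method errors.

## Known limitations

* No ΔCp of unfolding or binding: van't Hoff extrapolations assume
  temperature-independent enthalpies.
* The dissociative DSC model shares no K_d with the 25 °C dilution
  equilibrium — it is anchored by its own midpoint temperature; linking
  the two would require a ΔCp model.
* Asymptotic (not bootstrap) standard errors from the least-squares
  covariance.
* The binding model ignores hydrolysis and inter-ring allostery by
  construction.
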