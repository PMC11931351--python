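# Methods

## Scope and model overview

`nsdquant` treats a eukaryotic (CHO-like) cell as two metabolite
compartments: the cytoplasm (CP), where nucleotide sugar donors (NSDs) are
synthesized, and the Golgi apparatus (GA), standing in for the secretory
organelles where they are consumed.  Every analysis stage operates on tidy
tables; every table can be produced by the synthetic generator, which
encodes the statistical structure the analysis assumes.  The package makes
no claim about mechanisms — the release curve is empirical, the
degradation cascade is the simplest scheme with the right ordering, and
the glycan coupling is a saturating summary map.

## Digitonin release

The supernatant ("CP fraction") share of an analyte's total pool is
modelled as

    supernatant(x) = pool_cp * [a + b/(1 + exp((c - x)/d))]
                   + pool_ga * 1/(1 + exp((c_leak - x)/d))

with digitonin concentration `x` in µg/mL.  The first logistic is the
plasma-membrane release curve; defaults a = 0.09805, b = 0.91998,
c = 91.1277 µg/mL, d = 22.1166 µg/mL describe metabolite release.  The
second logistic models organelle leakage; its midpoint (`c_leak`, default
340 µg/mL for metabolites) must exceed the release midpoint because
organelle membranes carry less cholesterol and resist digitonin longer.
Protein release defaults (c = 150 µg/mL, d = 38 µg/mL) sit later and
shallower than the metabolite curve: small pores pass metabolites before
they pass proteins.  The organelle fraction is the remainder of the total
pool, so the two fractions conserve the pool exactly before noise.

A note on curve orientation: the increasing parameterization
`y = a + b/(1+exp((c-x)/d))` is the only standard logistic whose midpoint
and steepness match the default coefficient magnitudes while rising with
digitonin; the package uses it throughout, with the closed-form inverse
`x = c − d·ln(b/(y−a) − 1)` defined on the open range (a, a+b).

### Fitting

`fit_release_sigmoid` runs unweighted least squares (scipy `curve_fit`) on
replicate means per digitonin level (replicate-level fitting is an
option).  Initialization follows the data shape — floor = min(y),
span = max(y) − min(y), midpoint = level nearest mid-range,
steepness = quarter of the gradient span — with up to five jittered
restarts from a fixed sub-seed; the best sum of squares wins.  At least
four distinct digitonin levels are required; a constant response is
rejected as degenerate rather than returned with span ≈ 0.  R² is
1 − SS_res/SS_tot on the fitted points.

Normalization divides each analyte by the maximum over the gradient of its
replicate-mean total (CP + organelle) amount.  Under noise the maximum of
noisy means is biased slightly high, which biases the fitted floor and
span slightly low; the effect is a few percent at 10 % CV with
triplicates and does not move the design point across a grid cell.

### Design point

Literature relative compartment amounts n_i = c_i · V_i (defaults:
GA concentration 40 at volume fraction 0.022; CP concentration 1 at
volume fraction 0.55) give shares of 61.5 % GA / 38.5 % CP.  Inverting
the release curve at the CP share and taking the **largest grid
concentration not exceeding** the exact solution picks the working
digitonin level; rounding down deliberately under-permeabilizes to protect
the organelle fraction, at the cost of slightly under-capturing the
cytoplasm.  An exact solution below the whole grid returns the smallest
grid value with a warning flag.

Note that the full two-pool simulation produces a supernatant curve that
is a mixture of the release and leakage logistics; fitted on the default
grid (which ends at 400 µg/mL, before the leak component saturates), the
single-sigmoid fit tracks the late mixture rise and the design point lands
high (~300 µg/mL).  Parameter-recovery guarantees therefore refer to
single-compartment (pool_ga = 0) titrations, where the normalized
supernatant share *is* the release logistic; the acceptance script uses
the same setup to reproduce the classical release-curve design workflow.

## Standard addition and back-calculation

Peak area is regressed on spiked concentration by OLS (closed-form normal
equations; the sets can be as small as three points, so degrees of freedom
are handled explicitly and the standard error of the native concentration
comes from first-order propagation of the parameter covariance).  The
native vial concentration is intercept/slope.  Negative extrapolations,
possible under noise, are flagged and propagated rather than clipped so
that replicate averages stay unbiased.  A non-positive slope is an error.

Unit algebra is exact: 1 nM × 1 µL = 1000 amol.  The dilution chain is a
first-class object — ordered transfer fractions (material losses) and
reconstitutions (volume changes only) plus the originating cell count.
Default chain: 900 µL biphasic extraction with 650 µL aqueous phase
carried forward (fraction 650/900), dried and reconstituted in 100 µL,
from 8×10⁶ cells.  Back-calculation divides the vial amount by the
product of transfer fractions and by the cell count; it is linear in the
vial concentration and multiplicative in the chain fractions.

MDL flags use the median method detection limit of 12 nM: `below` under
the MDL, `near` within threefold, `pass` at ≥ 3× — the margin that keeps
the lowest quantified levels comfortably above the limit.

## Degradation and QC

Nucleotide degradation during sample concentration is a sequential
first-order cascade NTP → NDP → NMP with a common rate constant

    k = k0 * method_factor * 2^((T - 299.15 K)/10)

with k0 = ln(4/3)/24 h⁻¹ at the 26 °C reference, so the mild reference
method (lyophilization, factor 1) keeps 75 % of the initial triphosphate
after a 24 h run.  The evaporation factor 3.4758 was calibrated once so
that the mean energy charge after evaporation is exactly 63 % of the
lyophilized reference on the default fresh panels; it is a generator
constant, not a fitted quantity.  Default fresh pools are
triphosphate-dominant (74–80 % NTP across the four bases), so the
lyophilized triphosphate fraction stays above 0.54 per base.  The NMP
amount is computed as total − NTP − NDP, making per-base conservation
exact by construction.

Energy charge uses the standard Atkinson convention
(NTP + ½·NDP)/(NTP + NDP + NMP), applied per base and averaged with equal
weights across bases for method comparisons.  The Q10 budget uses
t_cold = t_warm · q10^(ΔT/10) with q10 = 2 by default; headline values are
rounded to 0.1 min (total) and whole minutes (per step), with exact values
carried alongside.  A proper Arrhenius ratio
exp(−Ea/R·(1/T_cold − 1/T_warm)) is available as an alternative
parameterization for users with an activation-energy estimate.

## Pulse time courses and glycan coupling

The compartment response to a nutrient pulse at 80.5 h is a causal
difference of exponentials,

    trace(t) = baseline + A * [e^(-kd (t-tp)) - e^(-kr (t-tp))] / g_max,

normalized so the maximum equals baseline + A at the requested peak time;
`PulseKernel.from_peak` solves the rise rate kr from the decay rate kd and
the peak delay (solvable when the delay is below 1/kd).  Default Golgi
UDP-Glc/Gal kernels: condition C (galactose pulse) peaks at 2150 amol/cell
at 120 h, condition B (fructose pulse) at 1400 amol/cell at 150.5 h,
condition A (medium-only control) is a weak late response; cytoplasmic
kernels respond quickly but weakly (homeostasis).  Baselines (~0.5
fmol/cell) were chosen so peak absolute levels match the peak values
above.  The default sampling schedule is daily plus denser post-pulse
points and the two anchor times 120 h and 150.5 h.

Cumulative Golgi UDP-Gal availability ("exposure", fmol·h/cell) is the
trapezoidal integral of the replicate-mean Golgi trace over the sampled
window.  Exposure maps to a per-arm galactosylation probability through a
Hill function p = p_max·Eʰ/(Kʰ + Eʰ) with p_max = 0.92, K = 88.2448
fmol·h/cell, h = 4.7426 — calibrated once so the default condition B and C
exposures map to I_G of 75 % and 88 %.  The two arms are independent, so
FA2/FA2G1/FA2G2 fractions are binomial: (1−p)², 2p(1−p), p².  Under this
coupling the arm-normalized I_G equals 100·p, making its monotonicity in
exposure transparent.  A monotone map cannot rank the medium-only control
between the two supplemented conditions; condition A lands at the bottom
of the ordering by construction.

The galactosylation index defaults to the arm-normalized convention
(bounded by [0, 100]); the literal variant without the factor 2 in the
denominator (reaching 200 for pure FA2G2) is selectable and recorded in
the output.  Glucose-unit calibration is piecewise-linear and exact at the
ladder nodes, with linear extrapolation beyond the ladder flagged.
Glycan assignment takes the nearest library entry within a 0.3 GU
tolerance (configurable); equidistant ties go to the lower-GU entry with a
warning.

## Noise model and seeding

All measurement noise is multiplicative lognormal with unit mean and a
configurable CV (default 10 % for amounts, 5 % for standard-addition
areas): amounts are positive, and relative errors dominate in LC-MS
readouts.  Replicates are independent; no inter-replicate or
inter-analyte correlation is modelled.  The pipeline derives one named
substream per stage from the root seed via `numpy` `SeedSequence` spawn
keys, so runs are bit-reproducible and stages are independently
perturbable.

## What the generator does and does not emulate

It reproduces the *shape* assumptions the analysis relies on: sigmoidal
release with late leakage, linear detector response, first-order
degradation ordering, delayed-peak pulse responses, donor-limited
galactosylation.  It does not emulate chromatographic artefacts, isobaric
co-elution (UDP-Glc/Gal and UDP-GlcNAc/GalNAc are carried as single mixed
pools), transporter kinetics, inter-replicate correlation, or cell-count
variability.  Passing tests therefore demonstrate the correctness and
statistical behaviour of the *analysis* under its stated assumptions, not
the fidelity of those assumptions to any particular instrument or cell
line.

## Problem sizes

Monte-Carlo guarantees in the test suite use 100 seeds (release-curve
midpoint recovery at 10 % CV), 200 seeds (quantification bias at 5 % CV)
and 500 seeds (standard-addition bias); the acceptance script runs one
full pipeline realization plus a 17-level triplicate titration fit.  These
sizes make the whole suite run in well under a minute while leaving the
Monte-Carlo acceptance margins (≥ 90/100 hits, < 3 % bias) far from their
thresholds.

## Known limitations

* The release sigmoid is empirical; no pore-formation mechanism is
  modelled, and the leakage logistic shares the release steepness for
  parsimony.
* Quantification at the design point treats the fractions as
  compartment-pure; the residual cross-contamination at the selected
  digitonin level is visible in the titration tables but is not
  deconvolved into the per-compartment estimates.
* The degradation cascade uses one rate for both dephosphorylation steps;
  real nucleotidase kinetics differ per base and per step.
* Glycan coupling compresses the whole galactosylation machinery into a
  single exposure statistic; enzyme abundance effects are out of scope.
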