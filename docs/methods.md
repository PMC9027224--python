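# Methods

This note documents the models behind `mirdkit`, the defaults and why they
were chosen, the numerical choices, and what the synthetic data do and do
not establish.

## Time base, units and decay

All times are minutes post-injection with injection at t = 0; the scan time
point of a whole-body acquisition is its start time.  Concentrations are
kBq/mL, activities fractions of injected, TIACs hours, doses mGy/MBq (and
mSv/MBq for the effective dose; the radiation weighting factor for
positrons and photons is 1, so the two coincide numerically).

The radionuclide is a parameter everywhere (default Ga-68, T½ = 68 min,
λ = ln2/68 ≈ 0.010194 /min).  A half-life of infinity gives λ = 0 and is
used in limiting-case tests of the integrators.  Decay correction is
C/e^(−λt); its inverse restores measured values exactly.

## SUV

SUV = C·W/A₀ with body-weight normalization and tissue density 1 g/mL.
Lean-mass or BSA variants are not provided.

## Organ activity and TIAC

The VOI concentration of an organ is converted to a fraction of injected
activity with the reference phantom's organ mass (1 g = 1 mL) scaled by the
patient/phantom *total*-mass ratio — i.e. organ volumes are assumed to
scale proportionally with body mass.  The TIAC integral uses:

* **lead-in [0, t₁]:** linear rise from zero at injection.  This is the
  conservative standard when first imaging is ~10 min p.i. and the true
  uptake shape is unknown.  For a curve that is already maximal at t = 0
  (pure decay) it *under*estimates the lead-in area by up to ~50 % of that
  segment (~3–4 % of the total for Ga-68 sampled at 10/60/120 min);
* **[t₁, tₙ]:** trapezoidal rule.  On a dense (≤ 0.1 min) grid this matches
  analytic mono-/bi-exponential integrals to better than 0.1 %; on the
  3-point clinical schedule it systematically overestimates convex decay by
  2–9 % depending on curvature;
* **tail [tₙ, ∞):** A(tₙ)/λ — physical decay only, no biologic clearance
  extrapolated beyond the last measurement.

Cohort TIACs are arithmetic means per region over the patients reporting
that region (missing regions are absent, not zero; per-region n is
recorded and partial coverage logged).

**Remainder of body.** Every decay happens somewhere: of the 1/λ = 1.6350 h
total (Ga-68), decays occurring in voided urine outside the body are
subtracted, then all explicit organ TIACs and the bladder-contents TIAC;
the rest is the remainder source, floored at zero with a warning if the
balance fails.  Blood-pool activity measured in the heart-contents VOI is
treated as its own source region; circulating blood outside that VOI ends
up in the remainder.

## Urinary excretion and the voiding bladder

Cumulative decay-corrected urine fractions are fitted (pooled over patients
by default, per-patient for diagnostics) to U(t) = F·(1 − e^(−kt)) by
bounded least squares (F ∈ [0, 1], k ∈ (0, 1] /min; start values F₀ = max
observed, k₀ = ln2/60).  An all-zero series short-circuits to F = 0 with a
degenerate flag.  The fitted F is used as-is (no renormalization to total
eventual excretion 1).

The bladder is voided completely and instantaneously every T_v (default
60 min, first void at T_v).  Contents at t since the last void at t_v are
e^(−λt)·[U(t) − U(t_v)]; cycle integrals (adaptive quadrature) are summed
until the bound on all future cycles falls below 0.01 % of the running
total.  Closed forms for instant excretion (T_v hours at λ = 0;
(1 − e^(−λT_v))/λ for a decaying nuclide) are matched to 0.1 %.

## Dose engine

D(r_T) = Σ_S ã(r_S)·S(r_T ← r_S), linear in the TIACs, with an explicit
alias table for region-name resolution; an unresolvable source is a hard
error listing the offending names, so no contribution can be dropped
silently.  Effective dose is the ICRP-103 tissue-weighted sum of
male/female-averaged organ doses; the thirteen ICRP remainder tissues are
aggregated into the single `remainder` target.  A single-sex dose map is
accepted with a logged caveat.  Report tables print to 6 significant
digits; comparisons in tests always use unrounded values.

**S-values are synthetic.**  Proprietary phantom S-matrices are not
redistributable, so the packaged `smatrix_synthetic.csv` is built from a
documented toy model: the mean β⁺ energy per decay (0.836 MeV × 89 % yield)
absorbed locally in the source; annihilation photons (1.022 MeV × 89 %)
treated as a uniform whole-body bath with a bulk absorbed fraction of 0.33
plus a self-absorption term 1 − e^(−μr) (μ = 0.096 /cm at 511 keV) in the
source organ; and a surface term of half the β⁺ energy from bladder
contents to bladder wall.  This keeps the right orders of magnitude and the
self-dose ≥ cross-dose ordering, but absolute organ coefficients from it
are illustrative, not reference dosimetry.  The two packaged phantoms
(`phantom_adult_{male,female}_synthetic.json`) are likewise synthetic
stand-ins with textbook-scale organ masses, not copies of any reference
phantom.

## Plasma pharmacokinetics

Per-patient nonlinear least squares of C(t) = C₀·e^(−kt), initialized by
log-linear regression; half-life = ln2/k.  Series are decay-corrected
before fitting, so the fitted half-life is biologic clearance.  Non-decaying
data are flagged and excluded from the cohort summary with a warning.  The
cohort value is the arithmetic mean of per-patient half-lives — deliberately
not ln2 over the mean rate and not a pooled fit; for heterogeneous cohorts
these differ.

## Lesion statistics

Group summaries are mean ± SEM with the n−1 sample SD (SEM = 0, flagged,
for n = 1; exactly 0 for identical values).  Tumor-to-organ ratios are
lesion SUVmax over organ SUVmean computed per patient first, then averaged
within group (mean of ratios).  Where several lesions share an organ, the
one with the highest SUVmax is reported, ties broken by lesion id.
Report rounding is decimal half-up to 2 d.p. and applied only at report
time.  The packaged per-patient lesion table covers a 5 NEN + 5 BC cohort
at three time points; one NEN patient's values refer to a liver metastasis
(flagged in the table) and are included in group means.

## Synthetic cohort

The generator emulates the structure of the study the pipeline targets:

* 5 + 5 patients in two disease groups; urine and plasma in a 7-patient
  subset; whole-body imaging at {10, 60, 120} min; voids at
  {15, 70, 130, 180} min; plasma samples at {2 … 40} min;
* organ kinetics A_r(t) = f_r·k_u/(k_u−k_w)·(e^(−k_w t) − e^(−k_u t))·e^(−λt)
  (decay-uncorrected fraction of injected), with closed-form TIACs for
  ground truth.  Defaults give kidney-dominant parenchymal retention,
  moderate liver/spleen/intestine uptake, near-zero brain and low lung and
  muscle *concentrations* (muscle's fraction budget is sizeable only
  through its ~29 kg mass);
* a declining heart-contents blood pool (fraction 0.02 of injected in the
  VOI, clearing at 0.012 /min);
* excretion truth F = 0.45, k = 0.02 /min, ≥ 80 % renal (declared renal
  fraction 0.9), chosen as typical of a fast renally-cleared peptide
  tracer that plateaus within ~2–3 h;
* plasma half-lives uniform on [3.9, 14.0] min;
* lesion SUVmax log-normal per group (medians ≈ 6.8 NEN / 4.8 BC at the
  first time point, σ = 0.30, rising ~30–35 % by 1 h then flat), bracketing
  the observed per-patient ranges;
* 5 % multiplicative log-normal noise on all measured concentrations, 8 %
  per-patient log-normal jitter on organ fractions (rescaled if a draw
  would break the mass-balance budget Σf + blood + F ≤ 1).

A single `numpy` Generator keyed by the seed drives all draws in a fixed
(patient, region, time) order, so identical (config, seed) pairs produce
byte-identical files.

**What the synthetic data do not show.**  They contain no image-domain
effects (partial volume, scatter, reconstruction bias), no VOI delineation
error, no inter-organ kinetic correlations, no bi-exponential plasma
phases, and the noise is idealized i.i.d. log-normal.  Passing recovery
tests therefore demonstrates correctness of the estimators under the
generating model, not robustness to real-data artifacts.  Likewise, organ
dose coefficients produced with the synthetic S-matrix are order-of-
magnitude realistic but not comparable to reference phantom software.

## Problem sizes and tolerances

Default analyses use the 10-patient cohort; Monte-Carlo recovery checks use
200 replicates (500 for the plasma fit distribution test) at fixed seeds,
asserting median recovery within 5 % (noisy) and 10⁻⁶ (noiseless).  The
TIAC integrator is validated at 0.1 % on dense grids; zero-noise pipeline
recovery of analytic TIACs is asserted within 3 % on a dense sampling
schedule, while the 3-point clinical schedule is asserted to give a
positive, bounded (< 12 %) trapezoid bias.  The bladder integrator uses a
0.01 % cycle-extension convergence criterion.
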