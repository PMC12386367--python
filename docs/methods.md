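# Methods

This note documents the models implemented in `nlsbind`, their assumptions,
the defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that matter when reproducing a
fit.

## Fluorescence titration with ligand depletion

The titration model assumes a single 1:1 binding equilibrium between a
receptor R (importin α, concentration R_T fixed, protomer units) and a
peptide ligand L (concentration L_T varied), with the fluorescence change
proportional to the fraction of receptor in complex:

F(L_T) = F0 + (ΔFmax / 2R_T) · [(R_T + L_T + Kd) − √((R_T + L_T + Kd)² − 4 R_T L_T)]

The bracket is twice the complex concentration from the exact mass balance —
no excess-ligand approximation — which matters because R_T (3 μM) is
comparable to the Kd values of interest (1–15 μM). ΔFmax is negative for
quenching. Blank (peptide-only) intensities are subtracted first; the
optional inner-filter correction multiplies by 10^((A_ex+A_em)/2), the
standard short-pathlength approximation, and is off by default because most
datasets arrive pre-corrected.

Fitting is Levenberg–Marquardt (lmfit) over (F0, ΔFmax, Kd > 0), initialized
at the first-point intensity, the last-minus-first change, and the median
titrated concentration. A fit is flagged:

* `out_of_range` when the fitted Kd exceeds the largest titrated ligand
  concentration or its relative standard error exceeds 1 (both configurable)
  — weak binders cannot be quantified inside a 0–35 μM window;
* `unidentifiable` when the signal change is indistinguishable from zero or
  smaller than its own standard error.

The range check runs before the identifiability check because a
beyond-range Kd inflates the ΔFmax uncertainty as a side effect; the
distal cause is reported.

## BLI kinetics

The sensorgram model is 1:1 Langmuir binding to immobilized receptor under
pseudo-first-order conditions (peptide in large excess over binding sites on
the tip). Per phase, re-referenced to zero at the phase start:

* association: R(t) = Req (1 − e^{−kobs τ}) − R′eq τ, τ = t − t0,
  kobs = kon[L] + koff, Req = Rmax [L]/([L] + Kd);
* dissociation: R(t) = R1 e^{−koff τ} − R″eq τ.

The linear drift terms absorb slow baseline wander; t0 is computed from the
phase schedule (default 30/120/30/120/120 s baseline/loading/baseline/
association/dissociation, so association starts at 180 s and dissociation at
300 s), never hard-coded. Only the association and dissociation segments are
analyzed; loading and baselines are synthesized by the generator for realism
but carry no kinetic information in this model.

Analysis is deliberately two-step: each curve is fitted independently, then
kobs is regressed on [L] (the pseudo-first-order plot). The regression is
weighted by 1/SE(kobs)² when every point carries a positive standard error,
unweighted otherwise. The slope gives kon; the intercept gives koff **only
when positive** — a non-positive intercept means the dissociation rate is
smaller than the plot can resolve, so koff and Kd are reported as not
determined while kon is still taken from the slope. Kd = koff/kon with the
standard error propagated in quadrature,
SE(Kd) = Kd √((SE(kon)/kon)² + (SE(koff)/koff)²). No global ODE fit across
concentrations is attempted; a two-step analysis keeps per-curve diagnostics
interpretable and matches how such data are normally processed.

The quadrature propagation is first-order; the test suite cross-checks it
against a Monte-Carlo resampling oracle using the half-width of the central
68% of resampled ratios, which agrees within 10% for relative errors up to
30% (the plain standard deviation of a normal ratio is tail-dominated and is
not a fair oracle).

## ITC single set of sites

The perfusion-cell forward model tracks, per injection of volume dV into a
cell of volume V0 (default 1.4 mL): dilution of both cell species by
(1 − dV/V0), accumulation of injected ligand, the bound concentration from
the 1:1 mass-balance quadratic with n identical sites per protomer,
cumulative heat Q_i = bound_i · ΔH · V0, and the measured per-injection heat

q_i = Q_i − Q_{i−1} + (dV_i/V0)(Q_i + Q_{i−1})/2,

whose last term accounts for heat in the displaced volume. Consequently the
summed heats at saturation approach n·ΔH·V0·[M]_cell referenced to the
*initial* cell concentration (verified to 1% at ~20× ligand excess in the
tests). Units are μcal internally, ΔH in kcal mol⁻¹, R = 1.9872×10⁻³
kcal mol⁻¹ K⁻¹; with μM concentrations and mL volumes the product
μM·kcal mol⁻¹·mL is exactly μcal.

Fitting is least squares over (n, log10 Kd, ΔH) — Kd log-transformed for
positivity — initialized at n = 1, Kd = [M]/5 and ΔH from the total heat.
ΔG = RT ln Kd(M) and −TΔS = ΔG − ΔH are derived identities, exact by
construction. Fits with a Wiseman c-value [M]/Kd outside [0.01, 10⁴] are
flagged low-confidence (outside that range the isotherm shape barely
constrains Kd). Dilution heats are corrected by element-wise blank
subtraction when a buffer-injection run exists, or by subtracting the mean
of the last three (near-saturation) injections as a fallback. The first
injection is retained by default; a discard flag exists because vendor
practice often drops it.

Defaults mirror the study design: 15 μM cell concentration, 175 μM syringe
(midpoint of the stated 150–200 μM range), 28 × 10 μL injections, 25 °C.

## DOSY hydrodynamics

Intensity decays follow the Stejskal–Tanner law
I(g) = I0 e^{−D γ² g² δ² (Δ − δ/3)} with γ(¹H) = 26 752 rad s⁻¹ G⁻¹,
default δ = 2.5 ms, Δ = 250 ms and a 16-step gradient ramp over 2–95% of
coil power. The maximum gradient strength is instrument-specific and must be
supplied (the generator defaults to 40 G cm⁻¹, a typical z-gradient coil,
chosen so the deepest point of a peptide decay stays well above the default
noise floor). The nonlinear fit is seeded by log-linear regression of ln I
on the gradient factor; the two agree to solver precision on clean data.

Rh follows two routes: (i) ratio to the dioxane internal reference,
Rh = 2.12 Å × D_dioxane/D_peptide (Stokes–Einstein, same temperature and
viscosity by construction); (ii) the empirical random-coil scale law
Rh = 0.027 · MW^0.50 in nm, converted to Å. The nm reading of the
coefficient is the only one consistent with the reported per-peptide radii
(e.g. MW 2815 Da → 14.3 Å). Molecular weights use average residue masses
(Bio.SeqUtils) plus one water and modification deltas; terminal caps are
excluded by default, matching how the scale law was applied.

The verdict compares the two radii within a window of 2× the combined
quadrature uncertainty: reported pairs such as 10 ± 1 Å versus 14 ± 2 Å are
treated as comparable (monomeric, disordered), which a 1σ window would not
reproduce; the width is configurable. Missing uncertainties give
`indeterminate` unless the radii agree exactly.

## NMR disorder metrics

Conformational shifts Δδ = observed Hα − random-coil reference use a bundled
per-residue table of random-coil Hα shifts with one nearest-neighbor
correction: +0.29 ppm for the residue preceding a proline. The table is a
deliberate, documented choice (Wishart-style values); swapping in another
reference set only requires replacing the CSV. D-peptides are scored against
the same (L-residue) table, since chemical shifts are invariant under global
mirror inversion of the chain.

Classification: all |Δδ| ≤ 0.1 ppm ⇒ random coil; a run of ≥ 3 consecutive
residues beyond the threshold with a common sign ⇒ structured regions
(min_run = 3 guards against isolated assignment noise and is configurable
down to 1); fewer than 5 assigned residues ⇒ insufficient. The NOE
classifier calls a chain disordered when every unambiguous contact is
sequential (|j−i| = 1); any contact at |j−i| ≥ 2 flags medium- or long-range
structure, and an empty table is indeterminate. Ambiguously assigned
contacts are excluded by default. Assignment coverage is reported alongside
the verdict rather than enforced as a hard threshold, because partially
assignable peptides are common (glutamine/glutamate/lysine-rich sequences).

## Synthetic data

Each generator evaluates its technique's forward model and adds Gaussian
noise from a `numpy` generator seeded per call — no global random state, so
every dataset is a pure function of (parameters, seed). Default noise:
fluorescence σ = 1% of F0, BLI σ = 0.005 RU, ITC σ = 0.1 μcal, DOSY σ = 0.5%
of I0. Default designs are the study conditions listed above per technique;
the BLI concentration grid is {1, 2, 3, 5, 10} μM sampled at 5 Hz.

What the generators emulate: the signal model, additive white noise, linear
sensorgram drift, constant ITC dilution heats. What they do not: correlated
instrument noise, injection spikes, buffer-mismatch jumps, nonlinear
baseline wander, mass-transport limitation in BLI, or convection artifacts
in ITC. Passing recovery tests therefore demonstrates the correctness of the
estimators under their stated models, not robustness to every artifact real
instruments produce.

## Problem sizes and numerical choices

The recovery studies in the tests and in `scripts/acceptance.py` use 100
replicates for the ITC and fluorescence simulations and 50 for the BLI sets
(each BLI replicate is five 2101-point sensorgrams with two nonlinear fits
each); medians are reported because single-fit Kd distributions are mildly
right-skewed. All optimizations are Levenberg–Marquardt with analytic-free
residuals; discriminants of the binding quadratics are clipped at zero to
absorb round-off at the Kd → 0 boundary; flat inputs short-circuit to
flagged, non-converged results rather than letting the optimizer wander.

## Known limitations

* BLI assumes a clean two-state interaction; apparent Kd values from
  biphasic or transport-limited sensorgrams will be model-dependent.
* The ITC model handles one set of identical sites only — no sequential or
  multi-site schemes.
* The fluorescence model operates on a single intensity per titration point;
  spectral deconvolution is out of scope.
* The scale-law coefficient carries a large published uncertainty (±0.01 on
  0.027); radii derived from it are order-of-magnitude anchors, not precise
  measurements.
* Gradient-strength calibration for DOSY must come from the instrument; the
  package takes max_gradient as given.
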