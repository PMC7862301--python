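# Methods

This note documents the models implemented in `gatekit`, the choices made
where the analysis was genuinely open, and what the synthetic data do and
do not emulate.

## Constants and conventions

All energies are in kcal/mol at T = 293.15 K (recordings at 20 °C), with
R = 1.987 × 10⁻³ kcal mol⁻¹ K⁻¹, so RT = 0.5825 kcal/mol, and
F = 23.061 kcal mol⁻¹ V⁻¹. The permeant ion is chloride (z = −1).
Concentrations are µM for Ca²⁺ and mM for the permeant ion; voltages are
accepted in mV and converted to V inside the permeation math. Positive
current is outward (Cl⁻ influx), so outward rectification means
|I(+80 mV)| > |I(−80 mV)|.

## Hill analysis

Normalized responses are fitted to I/I_max = 1/(1 + (EC₅₀/[Ca²⁺])ʰ) with
fixed asymptotes 0 and 1. Fits are unweighted by default, matching fits
of patch-averaged relations; 1/SEM² weighting is available behind a flag.
EC₅₀ and h are fitted as natural logs to enforce positivity. A point at
zero Ca²⁺ records basal activity and is excluded from the fit — the Hill
form has no basal term, so forcing it through that point would bias both
parameters; the basal level is reported alongside instead. Initial
values are data-driven (the concentration nearest half-maximum; h = 1).

## Permeation model

The open pore is treated as n sequential Eyring barriers; n = 3 by
default (outermost, middle, innermost — the smallest number consistent
with the three named barriers), but n is kept symbolic since the current
expression holds for general n. The middle-barrier term has a removable
singularity at V = 0 handled by its analytic limit (→ n − 2), with
`expm1` keeping the ratio accurate at small voltages; the current is
exactly zero at the Nernst potential for any positive rates. Defaults are
symmetric 150 mM permeant on both sides.

Fitting estimates (A, σ_h, σ_β) in log space from four deterministic
starts. The logs are bounded to ±15 around the data-driven scale guess:
when a barrier is far from rate-limiting its σ is unidentifiable, and the
bound turns a runaway estimate into a boundary value with an honestly
enormous confidence interval instead of a singular Jacobian. Zero- and
saturating-Ca²⁺ conditions are fitted independently, not jointly.

The single-occupancy I-V prediction interpolates the barrier energies
ΔE_a = −RT ln σ linearly at their midpoint between the apo and doubly
occupied fits. The scale factor A is interpolated on a log scale, which
treats it symmetrically with the rate parameters (a "reuse the
saturating A" mode is available); sub-conductance ratios are read out at
+80 mV: i/k = I_zero/I_sat and j/k = I_single/I_sat, clipped to [0, 1]
with a warning if scatter pushes them outside.

## MWC gating model

Six states: closed/open at Ca²⁺ occupancy 0, 1, 2, with equal macroscopic
binding constants per conformation. The binding polynomials are the
sequential-binding trinomials Q = 1 + x/K + (x/K)², not the
statistical-factor binomial (1 + x/K)² — the two differ in the weight of
the singly bound state, and the trinomial form is what the printed state
scheme with two identical binding steps implies. L₀ is never a free
parameter; it is always derived from microscopic reversibility,
L₀ = L₂ (K_d(O)/K_d(C))², and this identity is preserved through every
chemical transformation of L₂.

L₂WT is a required configuration input (in the source study it comes from
non-stationary noise analysis). The synthetic default is L₂WT = 10,
i.e. a saturating open probability of ~0.91 — a deliberate placeholder on
the physiological scale, not a measured value.

The model EC₅₀ is defined as the concentration where the normalized
response crosses halfway between its basal value (response at zero Ca²⁺)
and the saturating value 1, which handles basally active constructs; it
is found by bracketing root search on log₁₀ concentration over
[10⁻⁴, 10⁴] µM with 10⁻⁶ tolerance. A flat parameterization (no dynamic
range) raises rather than returning an arbitrary number. Inside the
global chemical fit a vectorized bisection computes all panel EC₅₀s per
objective evaluation; it is tested to agree with the scalar root search.

### Chemical parameterizations and the global fit

The methyl route assigns residue methyl(ene) counts I = 3, V = 2, A = 0 —
the counts fixed by the mutagenesis logic (Ile→Val removes one group,
Ile→Ala three). Other residues require explicit user entries; the package
refuses to guess. The hydration route uses the Kyte–Doolittle hydropathy
scale with ΔG_hydration(res) = −(index). The sign convention is the
package's own choice (the mapping is not uniquely fixed by the scale):
with it, hydrophilic substitutions carry positive ΔΔG_hydration and a
positive fitted δ produces the observed left-shifted EC₅₀. The
convention is flag-invertible (`HydropathyTable(invert_sign=True)`).

`fit_chemical_global` minimizes the summed squared difference between
log₁₀ model and log₁₀ experimental EC₅₀s over the methyl and hydration
series jointly, with free parameters {K_d(C), K_d(O), ΔG_Me, δ} (the
binding constants in log space, shared across both series) and L₂WT
fixed. Eight seeded multi-starts over log-spaced binding constants guard
against local minima. Per-mutant ΔG_mut values are then fitted one at a
time to full curves (not EC₅₀s alone) with the shared binding constants
frozen — the total sum of squares separates, so the per-mutant fits are
exact coordinate-wise minimizers of the joint objective.

## Uncertainties

Parameter variances are diag((JᵀJ)⁻¹) · SSR/(n_data − n_params) with the
Jacobian taken at the optimum in the optimizer's internal (log)
coordinates, where the rank check is well conditioned; variances transfer
to the natural scale by the delta method (SE_θ = θ · SE_lnθ). A genuinely
rank-deficient Jacobian raises an error naming the null-space direction.
95% intervals use the Student-t quantile at n − p degrees of freedom —
marginally wider than ±1.96·SE at the study's n, and conservative.

Cycle energies propagate SEs in quadrature for sums/differences and in
relative quadrature for products/quotients. The t-test degrees of freedom
for a coupling are not defined by the algebra itself; the package uses
the smallest dof among the contributing corner fits (conservative,
flag-overridable).

## Synthetic data

The generators emulate: per-mutant sigmoidal normalized responses from
the forward MWC model (with basal activity whenever L₀ is large),
outwardly/inwardly rectifying I-V curves from the barrier model, additive
Gaussian response scatter truncated at [−0.05, 1.1] reported as
mean ± SEM over n_patches replicates, multiplicative current noise, and
log-normal EC₅₀ scatter (0.05 decades) for panel-level analyses. Defaults:
13 log-spaced Ca²⁺ points over 0.02–20 µM plus 0 and 1000 µM; voltages
−100…+100 mV in 20 mV steps (covering the ±80 mV readout); response sd
0.03 over 6 patches; ground truth ΔG_Me = 0.83 kcal/mol and δ = 0.37 at
K_d(C) = 20 µM, K_d(O) = 0.2 µM. One RNG stream per scenario, consumed in
a fixed order, makes every output bit-reproducible from the seed.

Not emulated: raw current traces and capacitance transients, rundown,
liquid-junction or series-resistance errors, patch-to-patch EC₅₀
heterogeneity beyond the log-normal scatter, and Ca²⁺-buffering errors in
the bath solutions. Passing recovery tests therefore demonstrates the
identifiability and correctness of the estimators under the stated noise
model, not robustness to every artefact of real recordings.

The methyl series is generated through the methyl route only and the
hydration series through the hydration route only, mirroring the
two-series design of the experiment; pairwise interaction energies can be
injected into double/triple mutants to exercise the cycle analysis end to
end.

## Problem sizes

The recovery study uses 20 independently seeded panels of
27 + 16 constructs each; invariant checks use 10⁴-point random parameter
grids; the high-precision oracle for the permeation current uses 100
random (parameter, voltage) points at 30-digit arithmetic. These sizes
keep the full test suite and the acceptance script in the tens of
seconds while leaving the statistical conclusions unchanged at larger n.

## Known limitations

* The gating model is purely equilibrium; no kinetics.
* Only two identical binding sites; no more-than-two-site schemes.
* The permeation model is single-ion; no multi-occupancy conduction or
  conductance-saturation analysis.
* L₂WT must be supplied externally; EC₅₀-only data cannot identify it
  jointly with the binding constants.
* Cycle p-values use the package's propagated SEs and conservative dof;
  they are not comparable to per-patch-resampled p-values.
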