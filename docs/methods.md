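# Methods

## Signal model

The label-control difference signal uses the single-compartment general
kinetic model for PCASL with a well-mixed tissue compartment: zero before
the labeled bolus arrives (t < Δt), an inflow phase while the bolus of
duration τ delivers label, and post-bolus decay with the apparent tissue
relaxation time T1′, where 1/T1′ = 1/T1t + f/λ accounts for venous outflow
of label.  Times are measured from the start of labeling, so a
post-labeling delay p is sampled at t = τ + p (+ slice offset).  Breakpoint
ownership: t = Δt belongs to the inflow branch and t = τ + Δt to the decay
branch; the signal is continuous at both, and only the ATT derivative
(which jumps at the end of inflow) notices the convention.

Default constants (overridable through `AcquisitionConstants` or the CLI
config): τ = 1.4 s, α = 0.85, λ = 0.9 mL/g, T1b = 1.65 s, T1t = 1.445 s,
M0B = 1, readout 1.275 s, slice duration 53.125 ms, 5 slices, 300 s budget.
User-facing CBF is mL/100g/min; the model rate is f = CBF/6000 s⁻¹ so that
f/λ is a rate with λ in mL/g.

## Sensitivity functions and the fixed-outflow approximation

The design criteria use ∂ΔM/∂CBF and ∂ΔM/∂ATT.  With T1′ frozen at a
nominal outflow of 50 mL/100g/min the signal is exactly linear in CBF, the
CBF sensitivity is CBF-independent, and (because the ATT sensitivity is
merely proportional to CBF) every design criterion depends on the CBF
point value only through an overall scale - hence optimal designs need no
CBF prior.  The exact derivative, including dT1′/df = −T1′²/λ through the
chain rule, is implemented separately (`cbf_sensitivity_complete`) and is
verified against central finite differences to < 1e-6 relative error.

The cost of freezing T1′ is quantified by
`fixed_outflow_max_relative_error`: the maximum pointwise relative
deviation between frozen and exact CBF sensitivity over CBF in
[0, 100] mL/100g/min and times from bolus arrival through the signal peak,
which evaluates to 1.65% (worst at CBF = 100, at the peak).  The window
stops at the peak deliberately: past it the two expressions decay at
different exponential rates, so their pointwise ratio grows without bound
while both vanish, and any larger window is an arbitrary choice.

## Fisher information, criteria, and units

For A label-control pair averages with per-difference-image noise variance
σ², the 2×2 information matrix over sample times is
F = (A/σ²) Σ_i s_i s_iᵀ with s = [∂ΔM/∂CBF, ∂ΔM/∂ATT] in user units, so
the CRLB diagonal reads directly as variances in (mL/100g/min)² and s².
σ² here is the variance of one *difference* image; one acquired image has
variance σ²/2.  D-optimality minimizes det F⁻¹, L-optimality [F⁻¹]₁₁; an
arbitrary PSD-weighted trace is also available.  A 2×2 matrix with
condition number above 1e8 is treated as singular
(`SingularInformationError`) - for PCASL this signals a lack of ATT
information rather than something to regularize away.

## Prior-averaged design and slice handling

The criterion is averaged over a discretized ATT prior: uniform on the
core range (default 0.5-1.8 s, the grey-matter range in healthy adults)
with 0.3 s linear tapers to zero on both sides to avoid hard-edge effects,
discretized at 1 ms (criterion averages are stable well below 0.1% versus
a 0.5 ms grid).  Each slice of the 2D readout sees effective PLD
p + k·(slice duration).  A slice contributes to the average at an ATT
sample only if it can identify both parameters there: at least one sample
strictly inside the inflow phase and at least two samples after arrival.
The first condition is the classic per-slice truncation (an ATT at or
below the slice's shortest effective PLD leaves every sample on the
post-bolus decay, where the two sensitivities are collinear); the second
handles ATTs near the top of the prior for very sparse designs, where all
but one sample may precede arrival and the matrix is rank-1.  Comparisons
carry 1 ns guard bands so the mask agrees with floating-point branch
assignment when an ATT grid point collides exactly with a PLD.  Surviving
(slice, ATT) terms are combined as a mass-weighted mean,
Σ φ(slice, θ) p(θ) / Σ p(θ) over contributing pairs; the alternative
normalization (mean over contributing slices per ATT) is available as
`slice_weighting="mean_over_slices"`.

## Exchange optimization

`optimize_plds` initializes N PLDs equally spaced on [0.25, 1.5] s, then
cyclically replaces each PLD with the best candidate on a 25 ms grid
between its neighbors (bounds 0.2-3.0 s; monotonicity is enforced by the
candidate interval), recomputing for every candidate the averages
A = floor(budget / (2 Σ (τ + PLD + readout))) - the factor 2 counts the
label and control images of a pair.  Accepted exchanges strictly reduce
the cost, so the cost history is non-increasing; convergence is a full
pass with no change (cap 50 passes).  Ties keep the incumbent PLD.  Noise
variance is a pure scale factor and is fixed at 1 during optimization.
The implementation is vectorized: per coordinate, the Gram entries of the
remaining PLDs are cached and each candidate is a rank-one update, making
a full 40-PLD optimization a matter of seconds.  An infeasible *initial*
design (infinite cost) is tolerated - the first pass can rescue it - and
the search fails only if a complete pass finds no feasible candidate.

Small designs (N ≲ 6) have genuinely initialization-dependent local
optima (cost spreads of several percent); at N = 40 the spread across
reasonable initializations is under 1%.  Multi-start is therefore left to
the caller (`init_plds`); the default single start reproduces the standard
procedure.

## Noise calibration

Absolute scanner noise is site-specific, and none of the design decisions
depend on it (criteria scale uniformly with σ²).  To report errors in
physiological units the default `calibrated_noise` anchors σ so that the
reference 6-PLD protocol's slice-averaged CBF CRLB SD equals 10% of a
typical grey-matter CBF (50 mL/100g/min) at a mid-range ATT of 1.15 s.
Quantities that are ratios or rankings are invariant to this choice; the
single-PLD assumed-ATT optimum is the notable exception (its bias term is
σ-independent), and shifts by about one 0.05 s grid step per factor ~2 in
σ - with the default calibration the optimum is 1.30 s.

## Voxelwise (per-slice) error accounting

A voxel of a 2D multi-slice acquisition is sampled only at its own slice's
delays.  All error predictions and simulations therefore work per slice:
`predict_errors` averages per-slice CRLB SDs over contributing slices, the
Monte Carlo fits each slice's data independently and pools the estimates,
and the single-PLD theory solves the mismatch bias and CRLB variance per
slice before averaging.  Protocol summary errors are uniform means over
the prior's core ATT range (0.5-1.8 s).

Single-PLD protocols cannot bound both parameters, so their predicted CBF
error is RMSE = sqrt(CRLB variance + bias²), where the variance is the
one-parameter (CBF-only) bound at the *assumed* ATT and the bias is the
noiseless model-mismatch error of fixing ATT (default 1.25 s).

## Simulation and fitting

`simulate_dataset` draws Gaussian noise in the difference domain with
variance 2σ²/A per averaged point (equivalent to A independent
label/control pairs, which can also be simulated explicitly, e.g. for the
optional per-PLD noise-scale vector).  All randomness flows through an
explicit seed; per-ATT child seeds derive from one `SeedSequence`.

Fitting is maximum likelihood under the Gaussian model: bounded
trust-region least squares on the exact kinetic model
(0 ≤ CBF ≤ 200 mL/100g/min, 0 ≤ ATT ≤ 2.5 s, ftol = xtol = 1e-10, ≤ 200
model evaluations) with analytic Jacobians, initialized by an exhaustive
coarse lattice search (CBF step 10, ATT step 0.1).  Residual variance is
normalized by degrees of freedom (n − 2, or n − 1 for the single-parameter
fit).  Non-converged fits are flagged and counted, never dropped.  Error
metrics: bias = mean error, SD with ddof = 1, RMSE = sqrt(mean squared
error), so RMSE² = bias² + SD²·(n−1)/n.

## What the synthetic data do and do not show

The simulator reproduces the idealized measurement process: exact kinetic
model means, white Gaussian noise identical across PLDs, no motion,
no background-suppression effects, no dispersion of the bolus, no
macrovascular contamination, and a single tissue compartment with known
T1s.  Passing tests therefore demonstrate correctness of the design theory
and estimation machinery under the model's assumptions - not robustness to
physiological model violations in vivo.  At the calibrated noise level the
two-parameter ML fit carries roughly 5-10% excess RMSE over the CRLB
(more near the ATT range edges where bounds clip); rankings between
protocols whose predicted errors differ by less than that excess can
differ between prediction and simulation.  Desk-scale test settings (200
repeats on a 0.05 s ATT grid) are chosen to keep the full suite fast while
leaving Monte Carlo standard errors near half a percent; the CLI defaults
(2000 × 0.01 s) match common practice for publication-grade curves.

## Known limitations

- PCASL only; pulsed-ASL sensitivity functions are not implemented.
- Fixed label duration; τ is not a design variable.
- Gaussian noise (no Rician floor), uniform across slices.
- The two-parameter model omits tissue-T1 and dispersion uncertainty.
- The exchange search is a local method on a discrete grid; for very small
  N, supplying several `init_plds` starts is advisable.
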