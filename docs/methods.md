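# Methods

This note records the models implemented in `tdtkinetics`, the parameter
choices behind the synthetic-data generators, the numerical conventions,
and the limits of what the test suite demonstrates.

## Kinetic model

All mechanisms are elementary mass-action networks in µM and s; bimolecular
rate constants are µM⁻¹ s⁻¹. Nucleotide binding is two-step — encounter
(k₁/k₋₁) then conformational adjustment of the active site (k₂/k₋₂) —
followed, where chemistry occurs, by an irreversible incorporation step
(k_pol) and, in the multi-turnover analogue mechanism, a first-order
transformation of the post-catalytic complex (k_t) that licenses the next
binding cycle. Design choices:

* The second binding cycle reuses cycle-1 rate constants by default
  (`shared_second_cycle=True`); no separate constants are published for it
  and parsimony keeps the model identifiable. Independent cycle-2
  constants (`k1_2`, ...) are available.
* In the ddNTP mechanism the second cycle is binding-only: a
  2′,3′-dideoxy-terminated primer cannot be extended. Whether that cycle
  also includes the conformational stage is switchable
  (`second_cycle_conformational`).
* The post-catalytic transformation is modelled as a single irreversible
  first-order step — the minimal reading of a process whose only kinetic
  signature here is the delay before the second incorporation.
* The overall dissociation constant of two-step binding is reported as
  K_d = 1/(K₁(1+K₂)), the thermodynamically exact value when both bound
  states count as "bound" (at equilibrium X₁+X₂ = [E][N]·K₁(1+K₂)). The
  alternative convention 1/(K₁K₂) — the limit where only the final complex
  counts — is selectable (`convention="product"`).

Conservation of enzyme, primer and nucleotide moieties is carried as
explicit per-species composition counts and verified analytically against
every reaction's stoichiometry, independent of any solver.

## Observable model and photobleaching

Fluorescence is a linear readout F_ideal = F₀ + Σ rᵢ cᵢ(t), attenuated by
photobleaching: F_obs = (F_ideal − F₀)e^(−k_bleach t) + F₀. The correction
multiplies the background-subtracted signal by e^(+k_bleach t); correction
and forward model are exact inverses (tested to 1e−10). k_bleach is
calibrated per concentration from chemically static traces and held fixed
during fitting; co-fitting it is deliberately not the default because it
trades against slow kinetic phases.

Simulated observation starts at the stopped-flow dead time (1.38 ms);
integration always starts at the mixing instant.

## Global fitting and identifiability

`fit_global_multi` minimises the unweighted summed squared residuals of
all traces of one or more concentration series. Response coefficients and
backgrounds enter linearly and are profiled out by linear least squares at
every objective evaluation (variable projection), so the nonlinear search
runs only over rate constants in log₁₀ space. Multi-start: one start at
the geometric centre of the bounds plus seeded log-uniform draws (default
bounds 10⁻²–10² in the native units); a coarse search (ODE rtol 1e−6,
finite-difference step 1e−3) is followed by one high-accuracy polish of
the best start (rtol 1e−8, step 1e−5). Finite-difference steps are kept
two or more orders of magnitude above the ODE tolerance so numerical
gradients are not dominated by solver noise. Fits are deterministic given
the seed. Standard errors come from the Gauss–Newton covariance of the
profiled objective, mapped from log to natural units.

Identifiability required two structural decisions:

* **Fluorophore response basis.** For the analogue channel the reporter is
  the nucleotide itself, so species responses are constrained to sums over
  fluorophore environments: free, bound in the encounter site, bound in
  the catalytic site, first incorporated residue, and each further
  incorporated residue (kept separate because stacked neighbouring
  fluorophores quench non-additively). Without this constraint the
  second-cycle species give the fit enough linear freedom to compensate
  wrong rate constants down to the noise floor. For the tryptophan channel
  each enzyme-containing species keeps an independent response (the
  reporter is the protein environment) and the free nucleotide is dark.
* **Scale normalization.** One response per channel is pinned — the free
  analogue for the C^Py channel, the unbound enzyme–primer complex for the
  Trp channel — representing an independently calibrated intensity scale.

Even so, the six-constant incorporation mechanism is sloppy when fitted
from its own series alone: k₂ and k_pol trade along a ridge (profiled
standard error tens of percent at 1% noise). The with-primer and
without-primer experiments watch the same fluorophore environments, so the
package fits them jointly with shared response groups; the (highly
identifiable) binding-only series then pins the responses and the
incorporation constants decorrelate (k₂ standard error ≈3% at 1% noise).
This mirrors the experimental practice of characterising analogue binding
without primer before analysing the full cycle. One residual degeneracy is
documented rather than removed: the chemistry and transformation steps
(k_pol, k_t) are sequential first-order steps whose intermediate and
product share the `inc` response, so the fit determines the pair but not
their order.

## Quench-flow analysis

Product accumulation is fitted to P(t) = A(1−e^(−k_obs t)) with the
amplitude fitted (not fixed), and k_obs(c) to the saturation hyperbola
k_obs = k_pol·c/(K_d+c). The printed association-constant form
(K = 1/K_d) is exposed for round-tripping because it is the
dimensionally consistent reading of the published equation. Degenerate
designs are flagged: `kd_lower_bound_only` when only the linear regime was
sampled, `kd_unidentifiable` under full saturation. Note that in a
two-step-binding mechanism the phenomenological saturating rate is
k_pol·K₂/(1+K₂), not the microscopic k_pol; the consistency test uses the
rapid-equilibrium closed form.

## Lifetime analysis

Decays are fitted by iterative reconvolution: the candidate
multi-exponential is convolved with the measured IRF on the uniform bin
grid, with a fitted IRF-to-decay time shift and total intensity.
Parameter estimation minimises the Poisson-weighted chi-square with
per-bin variance max(count, 1) (the floor handles empty tail bins). The
*reported* reduced chi-square uses model-based (Pearson) variance, whose
expectation is one per bin at any count level; the count-based statistic
is biased below 1 in sparse tails and would flag correct models. Model
selection (1 vs 2 components) uses an F-test on the fit statistic at
α = 0.01, with a collapse guard (lifetime ratio < 1.2 or a component
amplitude < 1%); information-poor histograms default to one component.

Known limitation: Neyman (count-based) weighting biases the short lifetime
of the equal-amplitude biexponential preset low by ≈3% at 10⁶ counts
(fits of noiseless expected-value histograms are exact, isolating the bias
to the weighting convention). This is within every stated tolerance and is
retained as the conventional estimator.

## Conservation profiling

Positions use 1-based residue numbering on the ungapped reference (human
TdT). Redundancy filtering removes exact ungapped duplicates and records
shorter than 80% of the reference's ungapped length; true isoform
detection needs database metadata and is approximated by these two
filters. Ambiguity codes (X/B/Z) count as their own symbols and stay in
the percentage denominator unless excluded by flag. Gaps never enter the
denominator and are reported separately.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of a ground-truth record and a seed.
Defaults follow the published designs: Trp series at 2 µM enzyme / 1 µM
primer / 1–10 µM ddNTP; analogue series at 1 µM primer / 3 µM analogue /
0.5–5 µM enzyme; 400-point logarithmic time grid from 1.38 ms to 10 s;
quench sampling 0.05–30 s; TCSPC 0.016 ns bins over 0–25 ns with a
0.05 ns FWHM Gaussian IRF (the excitation pulse is ~16 ps, so the IRF is
dominated by detection); 10⁶ counts per decay.

Generating rate constants use the two published conformational-step values
(k₂ = 1.6 s⁻¹ without primer, 4.2 s⁻¹ with primer). The remaining
constants are fixed realistic choices consistent with the published
qualitative constraints: the primer leaves the encounter on-rate
unchanged (k₁ = 20 µM⁻¹s⁻¹ in both) but stabilises the encounter complex
~3-fold via k₋₁ (30 → 10 s⁻¹) and lowers K₂ ~6-fold (16 → 2.5);
chemistry and transformation (k_pol = 2.5 s⁻¹, k_t = 1 s⁻¹) are slow
enough that the catalytic complex accumulates, reproducing the
well-separated growth stages and the late fluorescence decrease that
coincides with the second incorporation. Analogue responses rise from
free (1.0) through encounter (3.0) to catalytic site (5.0), stay bright on
the first incorporation (4.5) and are quenched per further stacked residue
(0.5). Lifetime presets are 2.2 ns (free) and 0.85/3.6 ns with equal
amplitudes (bound); the real amplitude ratio is not published and the
equal split is a synthetic choice, not a claim about the sample.
Alignment compositions use the published column frequencies where stated
(position 395: 72.3% D / 27.3% E with a rare-residue remainder bucket;
404 and 449 strictly conserved; 456: 76.3% E / 20% G) and plausible
high-conservation splits elsewhere; exact per-column counts follow
largest-remainder rounding so requested fractions are met exactly.

Noise models: additive Gaussian at a fraction of each trace's span
(default 1%) for fluorescence; Gaussian absolute fraction (2%) or optional
binomial for gel-derived product fractions; Poisson for photon counts.
The generators do not emulate mixing artifacts, inner-filter effects,
detector afterpulsing, correlated (1/f) noise, or real response
spectra — so passing recovery tests demonstrates estimator correctness
under the stated noise model, not robustness to instrument systematics.

## Problem sizes

Default test and acceptance runs use the full 5-trace designs at 400
points per trace for the noisy recovery checks, 150-point grids for the
noise-free recovery property (where information is not limiting), and
10⁶-count decays; the multi-start budget is 6–8 starts for the noisy fits
and 24 for the noise-free six-constant mechanism, with early stopping once
the residual reaches the known noise floor of the generated dataset.
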