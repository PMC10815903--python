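# tdtkinetics

Pre-steady-state kinetic analysis of terminal deoxynucleotidyl transferase
(TdT), the template-independent DNA polymerase that extends single-stranded
3′ DNA ends during V(D)J recombination.

The package is for enzymologists analysing rapid-kinetics data on
nucleotide incorporation: stopped-flow fluorescence transients (intrinsic
tryptophan or a fluorescent cytosine analogue, pyrrolocytosine dC^Py^TP),
rapid chemical-quench product time courses, time-correlated single-photon
counting (TCSPC) fluorescence decays, and multiple sequence alignments of
the TdT family. Because raw instrument records for this system are not
publicly deposited, a first-class synthetic-data module generates every
input the pipeline consumes, at the published experimental designs and with
known ground truth, so the whole analysis is testable end to end.

## The models

**Kinetic schemes.** Nucleotide binding by TdT is a two-step process — an
encounter complex followed by a conformational adjustment of the active
site — optionally followed by chemistry and product transformation:

* `scheme1` (ddNTP, single incorporation):
  E·D + N ⇌(k₁/k₋₁) C₁ ⇌(k₂/k₋₂) C₂ →(k_pol) E·D₁, plus a binding-only
  second cycle on the dideoxy-terminated product.
* `scheme2` (no primer): E + N ⇌ X₁ ⇌ X₂.
* `scheme3` (fluorescent dNTP analogue, multi-turnover):
  E·D + N ⇌ C₁ ⇌ C₂ →(k_pol) P* →(k_t) E·D₁, with an identical second
  binding/catalysis cycle producing E·D₂.

Schemes compile to mass-action ODEs (µM, s units) with analytic Jacobians
and exactly conserved enzyme/primer/nucleotide moieties. The overall
dissociation constant of two-step binding is K_d = 1/(K₁(1+K₂)) with
K₁ = k₁/k₋₁, K₂ = k₂/k₋₂ (the 1/(K₁K₂) convention is available by flag).

**Fluorescence readout.** F_obs(t) = (F₀ + Σᵢ rᵢ cᵢ(t) − F₀)·e^(−k_bleach·t) + F₀,
i.e. a linear per-species response attenuated by photobleaching;
`correct_photobleach` inverts the attenuation. Global fitting
(`fit_global`, `fit_global_multi`) minimises the summed squared residuals
of all traces of one or several concentration series simultaneously,
searching only over rate constants (log-scale, seeded multi-start) while
response coefficients and backgrounds are profiled out linearly.

**Quench flow.** Product accumulation fits P(t) = A·(1−e^(−k_obs t)); the
concentration dependence k_obs(c) = k_pol·c/(K_d + c) yields K_d and k_pol.

**Lifetimes.** TCSPC histograms are fitted by iterative reconvolution of a
1- or 2-exponential decay with the measured instrument response, Poisson
weighted; an F-test selects the number of components. The free analogue
decays mono-exponentially (≈2.2 ns); bound to TdT it shows two
environments (≈0.85 and ≈3.6 ns).

**Conservation profiling.** Aligned TdT-family sequences are stripped of
duplicates and fragments, columns are addressed in human-TdT residue
numbering, and per-column residue percentages profile the dNTP-binding
pocket (positions 395, 397, 404, 449, 453, 456, 457).

## Worked example

```python
from tdtkinetics import synthdata
from tdtkinetics.transient import (
    Experiment, fit_global_multi, fluorophore_response_basis)

# seeded synthetic stopped-flow series at the published designs:
# with primer (1 µM primer, 3 µM analogue, 0.5–5 µM enzyme, scheme3)
# and without primer (scheme2); 1% Gaussian noise
t3 = synthdata.scheme3_truth(noise_sigma=0.01, seed=20)
t2 = synthdata.scheme2_truth(noise_sigma=0.01, seed=21)
tr3, _ = synthdata.gen_stopped_flow(t3)
tr2, _ = synthdata.gen_stopped_flow(t2)
m3, m2 = t3.mechanism(), t2.mechanism()

res = fit_global_multi(
    [Experiment(m3, tr3, prefix="p.",
                response_basis={"CPy": fluorophore_response_basis(m3)}),
     Experiment(m2, tr2, prefix="f.",
                response_basis={"CPy": fluorophore_response_basis(m2)})],
    n_starts=8, seed=3, fix_responses={"CPy": {"free": 1.0}},
)
print(f"k2 (with primer)    = {res.parameters['p.k2']:.2f} s^-1")
print(f"k2 (without primer) = {res.parameters['f.k2']:.2f} s^-1")
```

Output:

```
k2 (with primer)    = 4.35 s^-1
k2 (without primer) = 1.61 s^-1
```

The two numbers are the conformational-adjustment rate constants of the
analogue-binding step with and without a DNA primer, recovered from the
noisy synthetic series; the generating values are 4.2 and 1.6 s⁻¹. The
joint fit shares the fluorophore-environment response coefficients between
the two experiments (both watch free, site-bound and incorporated
pyrrolocytosine), which is what makes the six-constant incorporation
mechanism identifiable; the free-analogue response is pinned to its
calibration value to fix the intensity scale.

A command-line interface `tdtkin` exposes the same stages
(`generate`, `simulate`, `fit-transient`, `fit-quench`, `fit-lifetime`,
`profile-alignment`) driven by YAML configs; every run logs its seed and
tolerances and fails non-zero on non-convergence.

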