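# phenoflux

Fluorescence-based light-response phenotyping of coral photosymbionts
(Symbiodiniaceae), from raw single-turnover chlorophyll-*a* fluorescence
transients to phenotype clusters and trait correlation networks.

The package is written for photophysiologists and coral-reef biologists who
use fast-repetition-rate / single-turnover fluorometry to characterize
symbionts *in hospite*, and for methodologists who want a fully synthetic,
ground-truthed test bed for such pipelines. Because raw instrument data of
this kind are rarely portable, phenoflux ships a first-class synthetic
cohort generator that emulates the whole study design — 20 coral colonies ×
3 replicate fragments, six dominant ITS2 symbiont types, four light-response
phenotype archetypes — so every analysis stage can be validated against a
known truth.

## The model

A train of 1.3 µs excitation flashlets (3.4 µs dark gaps; 32 flashlets at
420/442/458 nm, 40 at 505/520 nm) drives the closed fraction *C* of PSII
reaction centers from 0 toward 1. Fluorescence yield follows the
connectivity-corrected curve

    F(C) = Fo + (Fm − Fo) · C(1 − ρ) / (1 − ρC)

where σ_PSII (Å² quanta⁻¹) sets how fast closure accumulates with photon
dose and ρ ∈ [0, 1) is the probability that an exciton arriving at a closed
center migrates to an open neighbour. Each flashlet advances closure by
exactly σ·dose in the integrated dose coordinate
g(C) = −(1 − ρ)ln(1 − C) + ρC. A 300 ms relaxation phase (probe flashes at
geometrically growing dark intervals, first gap 59 µs) reopens centers as a
double exponential with time constants τ₁ (Qa → Qb reoxidation) and τ₂
(plastoquinone-pool reoxidation).

Each sample is measured at 34 timepoints of an 11-minute variable actinic
light protocol (dark 30 s → 300 → 50 → 600 µmol photons m⁻² s⁻¹ → dark
recovery), five sequential repeats per timepoint, at five excitation
wavelengths. Two-stage weighted nonlinear least squares recovers
(Fo, Fm, σ_PSII, ρ, C₀) from the induction and (α, τ₁, τ₂) from the
relaxation; the dark-acclimated first timepoint anchors the quenching
metrics

    Φ_PSII = (Fm′ − F′)/Fm′          NPQ = (Fm,dark − Fm′)/Fm′
    qP  = (Fm′ − F′)/(Fm′ − Fo′)     ABQ = (σ_dark − σ′)/σ_dark

with Fo′ = Fo/(Fv/Fm + Fo/Fm′) (Oxborough–Baker). Eight metrics × 5
wavelengths × 34 timepoints give the 1,360-value metric cube per sample.
Downstream, metrics are screened across dominant symbiont types
(ANOVA/Kruskal–Wallis gate, p < 0.05), Z-scored, and samples are clustered
(1 − Pearson distance, average linkage) with multiscale-bootstrap node
support (1,000 replicates); the dendrogram is cut into four light-response
phenotypes. ITS2 read counts are copy-number normalized
(Cladocopium : Durusdinium = 2119 : 362 rDNA copies per cell) before
dominant-type calling (> 70%), and colony-mean metrics are correlated with
cellular traits (C:N:P, cell size, granularity, chl-*a*, neutral lipids),
keeping edges with |Pearson r| > 0.6.

## Worked example

Simulate one dark-acclimated acquisition at 505 nm with 1% instrument noise
and fit it:

```python
import numpy as np
import phenoflux as pf

params = pf.STParams(F0=1000, Fm=3000, sigma_PSII=500, rho=0.40,
                     alpha=0.6, tau1_us=600, tau2_us=12000)
rng = np.random.default_rng(0)
trace = pf.simulate_trace_pair(params, wavelength_nm=505, noise_rel=0.01, rng=rng)
fit = pf.fit_single_turnover(trace, c0_fixed=0.0)
p = fit.params
print(f"converged = {fit.converged}")
print(f"Fv/Fm       = {fit.phi_PSII:.3f}")
print(f"sigma_PSII  = {p.sigma_PSII:.0f} A^2 quanta^-1")
print(f"rho         = {p.rho:.3f}")
print(f"tau1, tau2  = {p.tau1_us:.0f} us, {p.tau2_us/1000:.1f} ms")
```

prints

```
converged = True
Fv/Fm       = 0.668
sigma_PSII  = 490 A^2 quanta^-1
rho         = 0.374
tau1, tau2  = 620 us, 12.0 ms
```

i.e. the true quantum yield 2/3, cross-section 500 Å² quanta⁻¹,
connectivity 0.40 and reoxidation constants 600 µs / 12 ms are recovered to
within a few percent from a single noisy trace pair.

The full pipeline runs from the command line:

```bash
phenoflux run-all --seed 1 --outdir runs/demo
```

which simulates the 60-fragment cohort, fits all 10,200 transient pairs,
assembles the metric cubes, calls dominant symbiont types, clusters the
samples into four phenotypes with bootstrap support, compares trajectories
and cellular traits across phenotypes, and writes the trait–metric network
(GraphML + edge list) together with a manifest of file hashes. Individual
stages are available as `simulate`, `fit`, `cube`, `type`, `cluster`,
`stats` and `network` subcommands over plain tab-delimited tables.

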