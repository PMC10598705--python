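# Methods

This note documents the models, conventions and design choices behind
phenoflux: what is simulated, how transients are fitted, what the synthetic
cohort does and does not emulate, and where the genuinely open decisions
were made.

## Single-turnover forward model

The closed fraction *C* of PSII reaction centers obeys
dC/dφ = σ(1 − C)/(1 − ρC) in cumulative photon dose φ, with functional
absorption cross-section σ (Å² quanta⁻¹) and excitonic connectivity ρ.
This integrates exactly in the dose coordinate
g(C) = −(1 − ρ)ln(1 − C) + ρC, which advances by σ·dose per flashlet; the
forward model inverts g by Newton iteration rather than applying a
single-jump per-flashlet update, because at realistic per-flashlet doses
the jump approximation deviates by several percent from the continuous
limit. Fluorescence follows the connectivity-corrected yield curve
F(C) = Fo + (Fm − Fo)·C(1 − ρ)/(1 − ρC).

Digitization convention: each flashlet's fluorescence is read at the pulse
leading edge, before its own dose closes centers. The first induction
reading therefore observes F(C₀) directly — in the dark, Fo itself. This
choice is what keeps the light-adapted baseline F′ observable; reading
after the dose makes Fo/F′ an extrapolation and the light-adapted fit
nearly unidentifiable.

Relaxation: C(t) = C_end·(α e^(−t/τ₁) + (1 − α) e^(−t/τ₂)). The sparse
1.3 µs probe flashes are treated as non-actinic (their total dose over the
300 ms window is ≪ one saturating train), so the relaxation trace is
monotone non-increasing. Reopening during the ~150–190 µs induction train
is off by default (it contributes < 3% at τ₁ ≥ 400 µs) and available via a
flag; this keeps the induction fit five-parameter.

Instrument constants: flashlet duration 1.3 µs, induction gap 3.4 µs,
32/40 induction flashlets by wavelength, 40 relaxation flashlets whose
geometric gap ratio is solved so the first gap is 59 µs and the train spans
300 ms. The excitation dose per flashlet defaults to 2.5×10⁻⁴ quanta Å⁻²:
large enough that even strongly quenched cross-sections (σ′ down to
~150 Å² quanta⁻¹) saturate closure within the train, small enough that the
sigmoidal rise retains the flashlets that identify σ and ρ. Wavelengths
are the canonical {420, 442, 458, 505, 525} nm set, with 520 accepted as an
alias of 525 (both spellings occur in instrument output).

## Fitting

Two-stage weighted least squares (scipy trust-region-reflective), residuals
relative (weights 1/F), matching the multiplicative instrument noise model.

Stage 1 (induction) estimates Fo, Fm, σ, ρ and, when free, C₀.
Initialization: Fo ← first reading, Fm ← 1.05 × max, σ ← normalized initial
slope / dose, ρ ← 0.3, C₀ ← 0.05. Bounds: ρ ∈ [0, 0.8], σ ∈ [1, 8000],
Fm ∈ [0.7·max, 5·max] — the Fm lower bound sits below the observed maximum
because noise places individual readings above the true Fm. Stage 2
(relaxation) fixes the closed fraction at induction end (propagated through
the closure model from the stage-1 estimate) and fits α, τ₁, τ₂ with
τ₁ ∈ [50 µs, 10 ms], τ₂ ∈ [50 µs, 300 ms]. If the fitted components are
exchangeable they are relabeled so τ₁ < τ₂; if τ₂ < 2τ₁ the relaxation is
refit as a single exponential and τ₂ reported missing, avoiding
label-switching artifacts. A fit is flagged non-converged when the
optimizer fails, a key parameter lands on its bound, or the trace is flat
(no induction signal); non-converged fits propagate as missing metric
values, never fabricated numbers.

Timepoint conventions in the pipeline: at dark-acclimated timepoints
(before first actinic exposure) C₀ is pinned to 0. During the final dark
recovery the closed fraction is still relaxing, so C₀ stays free there.
At light-adapted timepoints two ties borrowed from standard practice keep
the fit identifiable: ρ is pinned to the dark-reference value at the same
wavelength, and Fo′ is tied to the Oxborough–Baker estimate
Fo′ = Fo/(Fv/Fm + Fo/Fm′) inside the fit. Without these ties the
F₀–C₀–σ–ρ trade renders σ′ and τ₂ at light timepoints unusable (errors of
tens of percent at 1% noise); with them the light-state parameters are
recovered to ~1%. `fit_single_turnover` keeps everything free by default;
the ties are explicit options.

The five sequential repeats per timepoint are averaged flashlet-wise and
fitted once (signal accumulation); per-repeat fitting is available for
diagnostics.

## Metrics

Φ_PSII = (Fm′ − F′)/Fm′ with F′ the fitted baseline F(C₀); NPQ is
Stern–Volmer (Fm,dark − Fm′)/Fm′; qP = (Fm′ − F′)/(Fm′ − Fo′) with the
Oxborough–Baker Fo′ (the instrument protocol has no far-red Fo′
measurement); ABQ is operationalized as the fractional decline of σ′
relative to the dark σ — antenna-bed quenching manifests as cross-section
loss, and no closed formula is otherwise fixed by convention. σ′, ρ, τ₁,
τ₂ pass through from the fit. Φ_PSII at light timepoints is Fq′/Fm′ (not
(Fm′ − Fo′)/Fm′). The cube is ordered metric-major, wavelength ascending,
timepoint ascending; the default protocol yields 8 × 5 × 34 = 1,360 values
per sample. The 34 timepoints are evenly spaced over the 660 s protocol
(the count is fixed by the acquisition design; the spacing is not, so even
spacing is adopted).

## Synthetic cohort

The generator emulates the study design: 20 colonies × 3 fragments, each
colony assigned one of four light-response archetypes (cycled) and a
dominant ITS2 type from {C1, C3, C15, C21, C26, D1} with a
type-by-archetype map that mirrors the qualitative type/phenotype
association (C15 with archetype 1, D1 dominating archetype 2, etc.).

An archetype is a set of per-wavelength parameter trajectories: each
quenching state (NPQ, antenna-bed σ loss, closure, τ shifts) relaxes as a
first-order response toward an irradiance-dependent asymptote
amp·E/(E + E½) with separate onset and recovery time constants — the
simplest dynamics that reproduce the qualitative trajectory shapes
(archetype 1: largest NPQ amplitude and slowest PQ-pool reoxidation;
archetype 2: smallest NPQ but deepest, most sustained closure; 3 and 4
intermediate with distinct ABQ and τ profiles). The numeric defaults are
package choices, not published curves. Blue/green spectral modifiers scale
σ and Fm per wavelength. The quenched Fo′ is generated exactly
Oxborough–Baker-consistent, so the pipeline's estimator is unbiased with
respect to the generator's own truth.

Noise model: 1% multiplicative Gaussian on every flashlet reading
(default), lognormal colony and fragment random effects on the archetype
parameters (CVs 5% and 2%). The truth sidecar (colony map, archetypes,
dominant types, cell fractions) is written separately and never consumed
by analysis stages.

Cellular traits are linear-Gaussian on the log scale. Per-colony
photophysiology summaries (mean Φ_PSII, NPQ amplitude, mean τ₂, qP
depression) are standardized; N:P is planted with marginal Pearson −0.75
on Φ_PSII and +0.75 on τ₂ (the 2×2 system is solved on the empirical
latent covariance, so the marginals are exact up to the independent noise
draw); C:P carries the target correlation on NPQ amplitude plus a fixed
+0.2 loading on qP depression — NPQ amplitude and qP depression are
strongly anti-correlated across the archetypes, so both marginals cannot
be at +0.75 simultaneously; granularity loads broadly on all four
summaries; neutral lipids are an independent negative control. C, N, P per
cell are generated from a free P draw and the planted atomic ratios —
ratios are always computed from elements, never stored. ITS2 read counts
are multinomial with probabilities ∝ cell proportion × genus rDNA copies
(Cladocopium 2119, Durusdinium 362), so copy-number normalization is
required to recover cell-level composition; a Durusdinium-dominated colony
with a Cladocopium background type is miscalled from raw read shares.

What the generator does not emulate: mechanistic electron-transport
dynamics, host-tissue optics, photoinhibition/recovery hysteresis beyond
first-order responses, wavelength-dependent connectivity, non-multinomial
sequencing artifacts (chimeras, index hopping), and any indoor/outdoor
light-history effect (the environment label is generated with zero effect).
Passing tests therefore demonstrate that the pipeline recovers the truth of
this generative family at realistic noise — not that real corals satisfy
first-order quenching dynamics.

## Screening, clustering, statistics, network

The metric screen is univariate and uncorrected by design (a filter, not
inference): Shapiro–Wilk on the group-mean residuals at α = 0.05 gates
one-way ANOVA vs Kruskal–Wallis; keep p < 0.05. Kept metrics are Z-scored
(missing-aware). Samples are clustered on 1 − Pearson correlation between
their metric vectors with average linkage — the conventional pvclust-style
family; the distance and linkage are not fixed by any published choice, so
these defaults are declared here. Node support comes from multiscale
bootstrap over metric resampling: scale factors 0.5–1.4 (10 values), the
1,000 replicates split evenly, Φ⁻¹(1 − BP_r) regressed on
(√r, 1/√r) by weighted least squares, AU = 1 − Φ(v − c). Samples with
> 20% missing metrics are excluded; correlations are pairwise-complete.
The tree is cut so exactly k = 4 groups remain, labels ordered by cluster
size. Driver metrics are ranked by the one-way F statistic of their
Z-scores across phenotype labels, aggregated into metric families — a
transparent, testable stand-in for unspecified "custom scripts".

Trajectory contrasts use a repeated-measures linear mixed model
value ~ group + timepoint with a per-fragment random intercept (REML),
all pairwise group contrasts Bonferroni-adjusted within each
(metric, wavelength) family — the stricter reading of a redundant
"Tukey with Bonferroni" prescription. Timepoint enters as a fixed
categorical effect with no group × time interaction by default (available
behind a flag); the minimal model is a declared substitute for an
unstated specification. Singular fits fall back to fragment-mean pairwise
Welch tests, flagged. Cellular traits get the same normality gate
(ANOVA + Tukey HSD vs Kruskal–Wallis + Bonferroni pairwise Mann–Whitney)
and a compact letter display computed by insert-and-absorb, guaranteeing
that phenotypes sharing a letter are pairwise non-significant.

The trait network correlates colony-mean metrics (n = 20 colonies, the
replication unit) with colony-mean traits; edges require |r| strictly
above 0.6 (the Methods-level threshold; a 0.55 display threshold is also
exposed as config). No multiplicity correction is applied across the
1,360 × traits family — a documented limitation of the screening-style
analysis, inherited deliberately.

## Numerical choices and degenerate inputs

Newton inversion of g(C) converges in a handful of iterations (monotone,
convex); closure is clipped to [0, 1 − 10⁻¹⁵]. Optimizer tolerances are
10⁻¹⁰; with them the noiseless round trip is exact to ~10⁻¹³ relative.
Flat traces (range below 2% of the median) short-circuit to a
non-converged result. Empty ITS2 profiles, abundance vectors not summing
to one, dominance exactly at 0.70 (strict inequality → mixed), duplicate
cube cells, zero-variance metrics after screening, k larger than the leaf
count, unknown colonies, and empty networks without an explicit
allow-empty flag are all rejected with specific errors. An unknown
symbiont genus falls back to 1,000 rDNA copies with a loud warning.
Bootstrap probabilities are clipped away from {0, 1} before the normal
quantile transform; nodes at exactly 0 or 1 across all scales get
AU = 0 or 1 directly.

## Problem sizes

The default cohort (60 fragments × 5 wavelengths × 34 timepoints × 5
repeats) generates 51,000 trace pairs and 10,200 averaged fits; a full fit
of the cohort takes a few minutes on one CPU. The test suite and the
acceptance script use this default scale for the cohort-level checks and
smaller cohorts (4–5 colonies, 4–8 timepoints) for pipeline plumbing
tests; Monte-Carlo calibrations use 20–100 seeded draws as noted in each
test.

## Known limitations

ABQ's definition as fractional σ′ loss is a declared stand-in for an
instrument-specific formula that is not publicly fixed. τ₂ is weakly
identified from a 300 ms window when it exceeds ~50 ms, and is reported
missing when the two relaxation components are not separated. ρ at
light-adapted timepoints is pinned, so genuine light-driven connectivity
changes would be absorbed into σ′. The mixed model omits random slopes.
The bootstrap AU approximation uses weighted least squares rather than
full maximum likelihood; at very small replicate counts per scale the AU
values are noisy.
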