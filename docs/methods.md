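# Methods

This note records the models the package implements, the defaults it ships
with and why, the numerical choices that were genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Task and synthetic data

The relevance-modulation task is generated exactly as specified by its
design: eight blocks in the fixed order B–L–L–B–L–B–B–L, 40 stimuli per
block alternating butterfly/ladybird (20 + 20), 800 ms stimulus duration,
onset-to-onset intervals drawn from Normal(1930, 40) ms (jittered to avoid
entraining oscillations), a 30 s rest period after each block, and targets
drawn i.i.d. with probability 0.05 on relevant trials only. The design
fixes only the marginal target probability; i.i.d. placement is the
simplest generator satisfying it. Targets never occur on irrelevant trials
— a stimulus the participant is instructed to ignore cannot require a
response. A 2 s instruction gap opens each block. All time axes are
0-based samples at 600 Hz; a trial's onset is sample 0 of its epoch.

Trial-averaged beta envelopes are simulated directly as
`amplitude_local · f(t; a_loc, 3) + amplitude_int · f(t; a_int, b_int) +
AR(1) noise`. Amplitudes are parametrized as *peak deflection* in envelope
units so they are commensurable with the noise SD. Defaults, chosen to
represent a realistic trial-averaged MEG envelope study:

| parameter | default | rationale |
| --- | --- | --- |
| local scale / shape / amplitude | 350 ms / 3 / −1 | early ERD dip, mode ≈ 335 ms |
| integrative scale / shape | 900 ms / 3 | ERS peak ≈ 786 ms, inside the fit box |
| integrative amplitude | 1–2 by condition | crossover pattern below |
| noise SD (stationary) | 0.3 | envelope SNR 3.3–6.7 at the default amplitudes |
| AR(1) coefficient | 0.9 at 600 Hz | envelopes of band-limited noise are strongly autocorrelated; white noise would understate bin-to-bin correlation, the very thing the step-change permutation is designed around |

The study-pattern generator (`default_study_params`) plants the qualitative
finding the pipeline must be able to detect: in the insula, controls have
integrative amplitude 2 for relevant vs 1 for irrelevant stimuli and
patients the reverse; in the motor network both groups share a modest
relevance effect (1.8 vs 1.2); the local component is identical everywhere.
Subject heterogeneity is log-normal (σ = 0.2) on amplitudes — shared within
subject across conditions, so condition contrasts come from condition means
— and uniform jitter on scales/shape clipped to the constraint boxes, which
keeps every simulated best fit inside the search grid.

The raw-signal generator produces a phase-continuous carrier whose
amplitude is baseline plus the injected deflection in every trial epoch;
rest periods carry the baseline-amplitude carrier. The sensor-array
generator drives an ideal radial-magnetometer helmet (Fibonacci lattice on
the upper hemisphere, 12 cm radius) through the forward model below.
Coupled gamma envelopes are `r·z + sqrt(1−r²)·noise` mixtures of the
standardized integrative curve, so the population correlation is exactly
the target.

What the generators deliberately do not emulate: visual stimulus content,
head movement, artefacts, third-order synthetic gradiometry, the 150 Hz
antialiasing chain, or a realistic 275-channel CTF layout. Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
on data with known truth, not robustness to real-world MEG artefacts.

## Forward model and beamformer

The forward model is the Sarvas closed form for a current dipole in a
homogeneous conducting sphere. Published work of this kind typically uses
per-channel local-spheres models; the single sphere is a deliberate
simplification — every algorithmic contract tested here (linearity, null
radial dipole, inverse-crime recovery) is geometry-independent, and all
synthetic data are generated with the same model. This is a fidelity gap
for real data, not for the tests.

The spatial filter is a scalar LCMV beamformer. Covariance is computed
over the whole recording within 1–150 Hz and regularized as `C + λI` with
`λ = 4 × min-eigenvalue(C)` — λ is always derived from the original
covariance, never from an already-regularized one. Dipole orientation
maximizes the output SNR (pseudo-Z, `(uᵀLᵀC⁻¹Lu)/(uᵀLᵀC⁻²Lu)`), solved
analytically as the top generalized eigenvector of the reduced 3×3 problem
after projecting out numerically null leadfield directions (the radial
direction in a sphere). Tests verify the analytic solution dominates a
dense random orientation search; note that with near-noiseless data the
pseudo-Z surface is plateau-like away from the null direction even though
its argmax sits at the true orientation, so "nearby in pseudo-Z" does not
imply "nearby in angle".

Numerical choices: the applied inverse is computed through an
eigendecomposition with eigenvalues floored at 10⁻⁶ of the largest
(a bounded-condition truncated inverse). This leaves well-conditioned
covariances untouched and keeps the noiseless rank-deficient case — where
λ collapses to machine epsilon — finite and exact in the signal subspace.
The generalized eigenproblem is assembled scale-free (`L` and `C` each
normalized by their largest singular value/eigenvalue) with
`B = (C⁻¹L)ᵀ(C⁻¹L)` so it is positive semidefinite by construction; a
whitening fallback handles near-singular `B`.

Voxel polarity is arbitrary after orientation estimation. Sign alignment
iterates (≤ 10 passes): flip every voxel whose series correlates negatively
with the map-weighted mean of the currently signed series. If the
reference cancels exactly (e.g. two voxels in perfect antiphase) the
strongest voxel seeds the reference. The network time-course is the exact
map-weighted sum over voxels with map weights ≥ 0.3.

## Spectrograms and binning

Band filtering is a zero-phase (forward–backward) 4th-order-per-pass
Butterworth band-pass applied to the *whole* recording, and the Hilbert
transform likewise, before any epoching — transients then live at the
recording edges, not at every trial. The default band set is the 15
printed bands between 1 and 70 Hz; the band list is configurable
everywhere (the companion text claims 17 bands but prints 15; the two
unprinted bands are unknown, so the printed list is the default). Epochs
are [0, 1500 ms) — 900 samples, half-open — from each non-target onset.
The rest baseline pools all eight 30 s rest windows into one mean per band;
subtracting it yields the TFD spectrogram, and adding it back reconstructs
the raw average (to float rounding). The beta series averages the three
beta sub-bands (13–20, 15–25, 20–30 Hz) and is binned by a plain averaging
kernel into 18 bins of 50 samples, which preserves the grand mean exactly.

## Dual-Weibull decomposition

The grid: local scale 283–450 ms in steps of 25/3 ms (5 samples), shape
fixed at 3; integrative scale 500–1700 ms in steps of 50/3 ms (10 samples),
shape 2–4 in steps of 0.25. Step sizes are a design choice (the source
design does not state them) set so the curve changes well under 1% per
step; they are configurable. The later-peak constraint is enforced on the
analytic modes with strict inequality. Each candidate pair is fitted by
ordinary least squares *with an intercept* — per-subject baseline
subtraction is imperfect and the curve family must not absorb offsets.
Among fits with a strictly negative local coefficient the smallest SSR
wins; exact ties break toward smaller local scale, then smaller integrative
scale, then smaller shape. If no pair yields a negative local coefficient
the unconstrained best fit is returned flagged `constraint_unsatisfied`
rather than raising, so group analyses can exclude or inspect such series;
constant series return a flagged `degenerate` result. The per-pair solve
is reduced to cached 2×2 normal equations, making a full ~14,000-pair grid
fit take milliseconds per series.

AUC is the *signed* coefficient times the unit-curve integral over
0–1500 ms (the analysis window, not 0–∞), computed in closed form from the
Weibull CDF `1 − exp(−(1500/a)^b)` and verified against quadrature in
tests. The sign convention (negative local AUC) is deliberate and recorded
in the output schema. A note on notation: the Weibull shape is positive
(> 1 for a peaked curve); descriptions of this family sometimes misprint
the shape's sign constraint.

## Statistics

The mixed repeated-measures ANOVA uses the orthonormal-contrast
multi-stratum formulation: per within-effect contrast scores per subject,
a between-subjects GLM per score (intercept, effect-coded group, optional
centred covariate), Type III (coefficient) sums of squares pooled across
the effect's contrasts. With q contrasts, N subjects and p between-subject
parameters this gives df (q, q(N − p)): (17, 357) for the time effect in a
pooled 22-subject design, (1, 21) for its polynomial contrasts, (17, 340)
with a group factor, (17, 323) with group plus the age covariate. Type III
(unweighted-means) tests are used because the groups are unbalanced (12 vs
10); for balanced designs the implementation agrees exactly with pingouin's
mixed ANOVA and statsmodels' AnovaRM, which serve as independent oracles in
the test suite. No sphericity correction is applied — permutation
calibration replaces distributional assumptions. Polynomial trend
contrasts (linear/quadratic/cubic) are reported with signs; a biphasic
ERD–ERS series shows a negative cubic and positive quadratic term.

Permutation p values are the fraction of null F values ≥ the observed F
(ties counted as extreme; an add-one smoothing option exists). Scheme per
effect: effects involving group permute group labels over subjects without
replacement; within-only effects containing a two-level factor flip that
factor's pair per subject with a fair coin (implemented in contrast space:
flipping negates the factor's odd contrast scores); the pure time effect
uses the step-change permutation — shuffle the 17 first differences of each
series and re-accumulate from the series mean, preserving the step-size
multiset exactly. The time permutation is applied per subject-and-condition
series, the only choice that yields subject-level exchangeability. The age
covariate, when present, is simply refitted in every permutation (naive
scheme, not Freedman–Lane). d′ is `Φ⁻¹(hit) − Φ⁻¹(fa)` with an optional
log-linear correction for boundary rates (off by default); the group t is
the pooled-variance Student t.

## Coupling

Coupling is the Pearson correlation, over the 900 post-stimulus samples,
between the fitted integrative beta curve (coefficient × unit curve, no
intercept or local part) and each gamma-band envelope, Fisher-transformed.
`|r| = 1` maps to `atanh(1 − 10⁻¹²)` with a `boundary` flag so records stay
finite for the ANOVA; constant envelopes yield `undefined` records that are
excluded before fitting. The default gamma set is the six printed bands
(25–35 … 60–70 Hz), configurable. The grand-mean ("(Intercept)") effect of
the mixed ANOVA on z tests overall positivity of coupling. The
cross-specificity check computes the full source-network × target-network
mean-z matrix with a per-cell one-sample F.

## Validation experiments and problem sizes

`megbeta.experiments` runs each study end to end at sizes chosen to give
stable estimates in minutes on one core: exact grid-point recovery on 50
noise-free series; noisy recovery on 200 series at the study defaults
(median integrative-scale error ≈ 1.2–1.5 grid steps, 100% coefficient-sign
recovery); type-I error of the Group × Relevance permutation test over 200
null experiments at 500 resamples (rate statistically compatible with
0.05 — note the literal ≥-counting rule makes the exact rejection
probability (k+1)/(N+1) ≈ 0.052 at N = 500); power over 100 runs of the
crossover scenario (≈ 100%); a 7-voxel beamformer inverse crime (correct
voxel, time-course correlation ≈ 1); spectrogram recovery of an injected
biphasic envelope (NRMSE ≈ 0.006, normalized by the RMS of the injected
curve, using a 20 Hz carrier inside the 15–25 Hz band); and coupling
recovery (mean z within a few 10⁻³ of atanh(r) for r ∈ {0, 0.3, 0.5}).

## Known limitations

* Single-sphere forward model and ideal magnetometers; no gradiometry,
  no realistic head geometry, no coregistration.
* The ANOVA supports one two-level between-subject factor and one
  covariate — the designs used here — not arbitrary between-subject
  structures, and no mixed-effects (multilevel) modelling.
* The network maps are treated as given inputs; the ICA procedure that
  produces them is out of scope.
* Integrative-scale estimates degrade with envelope autocorrelation: at
  AR(1) = 0.9 the effective sample size of a 900-sample series is ~47, so
  recovery precision is noise-limited near SNR 2 even though the estimator
  is exact at zero noise.
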