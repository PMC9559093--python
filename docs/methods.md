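# Methods

## Data model and conventions

Measurements are long-format records (subject, eye, time in years from the
subject's first retained visit, superpixel, GCC thickness in μm). Superpixels
are labelled "row.col" with row 1 the most superior and column 1 the most
temporal, i.e. right-eye (OD) orientation; left eyes can be mirrored
left–right into this orientation (`mirror_left_eyes`, applied by the CLI by
default but never silently on `read_long_table`, so that write∘read is an
exact identity). Analyses use the 7×7 subgrid of the exported 8×8 array,
dropping row 8 and column 8. The fovea sits between rows 4–5 and columns
4–5 and is marked on grid-map figures only.

## Cleaning

The pipeline applies, in order: (1) visit rules — visits under
`min_visit_gap` = 0.2 y after the previously retained visit are dropped,
visits after `max_followup` = 4.2 y are dropped, then subjects with fewer
than 4 visits or under 2.0 y of follow-up are removed; (2) zeros — thickness
exactly 0 is an export failure; (3) spike rule per (subject, superpixel)
profile — an interior point is flagged when it differs from *both*
neighbours by more than δ = 10 μm in the same direction, an endpoint when it
differs from its only neighbour by more than 2δ. Flags are computed in one
pass on the original sequence. Profiles with ≥ 2 flags are removed whole;
one flag removes just that observation.

The spike rule is this package's own concrete definition of
"large increases/decreases between consecutive measurements". δ = 10 μm is
several times the typical residual SD (~2 μm) yet far below real
glaucomatous change over one visit interval; the endpoint factor 2 exists
because endpoints cannot show the two-sided signature. The rule has an exact
guarantee: if every clean consecutive change is < δ/2 and every injected
spike exceeds 2δ (placed away from endpoint-adjacent positions), detection
has 100% sensitivity and zero false positives, including across splices left
by removed zeros. That precondition is a property of low-noise profiles, not
of every cohort: with the reference log-normal residual SDs (mean 1.95, SD
0.74 μm) the right tail of σ_i produces occasional genuine double-exceedance
patterns, which the rule removes just as it would in real data. Recovery
tests therefore construct their fixtures with scaled-down residual SDs
(σ_m = 0.5, ω = 0) and assert the precondition before asserting perfect
recovery.

## Hierarchical model, priors, sampler

Model: `y_ijk = α0_k + α1_k t + β0_ik + β1_ik t + ε_ijk`, `ε ~ N(0, σ_ik²)`,
`(β0, β1)_ik ~ N₂(0, D_k)`, `log σ_ik ~ N(ν_k, ω_k²)`. The transformed
parameter vector is θ = (α0, log D00, log D11.0, α1, b, ν, log ω) with
b = D01/D00 and D11.0 = D11 − D01²/D00: (θ2, θ3, b) is a log-Cholesky-style
parameterization of D (any finite θ back-maps to positive variances and
|ρ| < 1), and the log-normal law for σ_ik turns its population mean/SD
(σ_m, σ_s) into the unconstrained pair (ν, log ω) via exact log-normal
moment identities. θ4–θ7 forms are this package's choices; the guiding
criterion is unconstrained real parameters for which normal hierarchical
priors are appropriate.

Across superpixels, (θ1, θ2, θ3) ~ N₃(μ_c, Σ_c) — these three are strongly
correlated empirically, which is why they share a correlated block — and
θj ~ N(μ_j, τ_j²) independently for j = 4..7 (the full 7-variate correlated
hyperprior is a non-goal; it is known to converge poorly). Hyperpriors
(defaults, all overridable, with a `widened(10)` variant for sensitivity
runs): μ_c ~ N((75, log 150, log 0.25), 10⁴·I), Σ_c ~ Inv-Wishart(5, 0.1·I),
μ_j ~ N(0, 10⁴), τ_j ~ half-normal(10).

Sampling is a blocked Gibbs sweep over per-(subject, superpixel) sufficient
statistics (n, Σt, Σt², Σy, Σty, Σy²), so cost per sweep is a few dozen
vectorized operations on (n_subjects × 49) arrays regardless of visit count.
Conjugate normal draws update (β0, β1)_ik, (α0, α1)_k (with θ1's prior
conditioned on θ2, θ3 inside the trivariate block), b_k, ν_k, μ_c, Σ_c
(inverse-Wishart) and μ_j; adaptive random-walk Metropolis on the log scale
updates log σ_ik, θ2, θ3, θ7 and log τ_j. Step sizes adapt toward 44%
acceptance in batches of 100 during burn-in only, so the kept chain is a
fixed Markov kernel; the slow-mixing log-variance blocks take 2 (θ-level) or
5 (τ-level) kernel repeats per sweep. Chains start from per-cell least
squares with chain-indexed jitter. Cells emptied by cleaning keep their
latent (β, log σ) as exact prior draws, which leaves the joint posterior of
everything else unchanged. Defaults: 3 chains × (1500 burn-in + 3000 kept),
a desk-scale setting that fits 111×49 in ~20 s; the publication-scale
3 × 150 000/50 000/thin-50 configuration is `MCMCConfig.publication_scale()`.
Split-chain R-hat and bulk ESS (via arviz) are reported for all
hyperparameters; R-hat > 1.1 logs a warning, never an error.

Known sampler limitation: the centered parameterization mixes poorly when
the true across-superpixel spread is ~0 (the funnel — μ_c and the θ_k lock
together). Realistic cohorts are far from this regime; degenerate test
fixtures should not assert on hyperparameter diagnostics.

`summarize_global` back-transforms all 49 superpixels per draw and
summarizes empirically across superpixels (mean, SD, and the three
correlations intercept~RI-SD, intercept~RS-SD, RI-SD~RS-SD), reporting
posterior mean/SD/2.5%/97.5% of each; degenerate draws with zero
across-superpixel SD yield missing correlations rather than errors. The
hyperparameter-based alternative definition was considered and not used —
the empirical definition is what the printed tables correspond to most
directly and is well defined draw by draw.

## Synthetic cohorts

The generator emulates the study design: 111 subjects; visit count
round(N(7.3, 1.1)) clipped to [4, 10]; follow-up N(3.59, 0.44) truncated to
[2.0, 4.2] years with visits evenly spaced plus 0.1-y jitter and ≥ 0.25-y
gaps. (Spacing-first designs can generate subjects who fail the eligibility
rules they are meant to pass; targeting follow-up directly matches the
published follow-up and visit-count summaries and guarantees eligibility.)
Superpixel parameters default to draws from the hierarchy calibrated to the
reference cohort's global posterior summaries: θ-scale means are the exact
transform of the interpretable means (73.05, 14.84, −0.357, 0.845, −0.266,
1.947, 0.741), θ-scale covariance comes from the numerical delta method
applied to the interpretable SDs (13.29, 5.50, 0.266, 0.317, 0.198, 0.249,
0.171) with the three reported correlations (0.812, 0.739, 0.845) in the
(θ1, θ2, θ3) block. Plug-in-plus-delta is first-order (Jensen inflation of a
few percent on lognormal-scale parameters); recovery tests always compare
against the *realized* empirical summary of the drawn superpixels, so this
approximation never enters a pass/fail decision.

Spatial structure: correlation r^d in grid distance d with r = 0.8 / 0.5 /
0.35 / 0.3 for intercepts / slopes / log residual SDs / residuals, times an
attenuation factor 0.5 for pairs straddling the temporal horizontal meridian
(between rows 4–5, columns 1–4) — qualitative mimicry of the raphe, not
estimates. The attenuated matrix is projected to the nearest unit-diagonal
PSD matrix by eigenvalue clipping (the raw product is very slightly
indefinite at r = 0.8; the repair changes entries by < 0.001). Random slopes
couple to intercepts via β1 = b·β0 + √D11.0·z with z correlated by C_slope;
consequently cross-superpixel intercept–slope correlations are
ρ_k'·C_int(k,k') and slope–slope correlations are the implied mixture
ρ_k ρ_k' C_int + √(1−ρ_k²)√(1−ρ_k'²) C_slope (≈ C_slope at |ρ| ≈ 0.27).
Simulated thickness is floored at 0.5 μm (the Gaussian tail is unbounded;
truncation is vanishingly rare at the default scale).

What the generator does *not* emulate: scan-quality covariates, floor
effects near perimetric blindness, segmentation failures beyond simple
zero/spike artifacts, visit-level correlated dropout, or nonlinear
trajectories. Passing recovery tests therefore demonstrates internal
consistency of model + estimator under the stated design, not robustness to
those real-data features.

Artifact injection places exact-zero records and isolated spikes (uniform
magnitude in [25, 40] μm by default, random sign) at interior positions not
adjacent to profile endpoints — an endpoint-adjacent 2δ spike would trip the
endpoint rule and silently convert a single-spike profile into a
whole-profile removal; double-spike profiles get two spikes ≥ 2 positions
apart. Every corruption is returned as ground truth.

## Cross-superpixel correlation and PCA

Per stored posterior draw, effect matrices are subjects×49 (β0, β1, log σ —
log SD is stored; correlations of log variance are identical by affine
invariance) or visits×49 (residuals ε = y − fit). Cells removed by cleaning
are absent; covariance across rows uses exact pairwise-complete computation,
columns with < 3 complete pairs are flagged missing. The posterior-mean
covariance (average over draws, then projected to the PSD cone — pairwise
completion can leave it slightly indefinite; a no-op for complete data)
yields the reported correlation matrix; averaging per-draw correlations
instead is available via `method="mean_correlation"`. Subject-level effects
are stored for a thinned subset of draws (`effect_thin`, default every 10th
kept draw) to bound memory; ~300+ draws are ample for these averages.

PCA operates on the posterior-mean covariance matrices (primary), with the
correlation-matrix variant behind `matrix_type="correlation"` (trace 49, so
fractions are eigenvalues/49). Eigenvectors use a deterministic sign
convention: nonnegative loading sum, ties broken by making the
largest-magnitude loading positive. Tiny negative eigenvalues (≥ −10⁻⁶ ×
trace) are clamped to zero; larger ones are an error. Scree output is the
cumulative fraction of total variance by rank. The PCA test fixture builds a
population covariance whose first three eigenvectors are a uniform global
vector, a superior-vs-inferior contrast and a nasal-vs-temporal contrast,
with prescribed leading eigenvalue fractions and the remainder spread
equally.

## Numerical choices and test-scale decisions

- Transform round-trips are exact to 1e−10; back-transform clips |ρ| at
  1 − 1e−12 so validity survives floating-point rounding at extreme θ; σ_m,
  σ_s can overflow to +inf for θ7 ≳ 3.5 (the log-scale parameters stay
  finite), which is documented rather than masked.
- Posterior intervals for across-grid means are calibrated when effects are
  spatially independent (the model's own assumption). Under spatially
  correlated effects the realized across-grid mean of subject effects does
  not average out, so recovery-to-truth comparisons at 3-posterior-SD
  tolerance are run on independent-effects cohorts; correlated cohorts are
  used for the correlation/PCA analyses, where that dependence is the object
  of study rather than a nuisance.
- Test problem sizes are desk-scale by design: the full acceptance fit is
  111 subjects × 49 superpixels at 3 × 3000 kept draws; property suites use
  3×3 subgrids, 35–110 subjects and short chains, sizes at which every
  asserted property is already decisive.
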