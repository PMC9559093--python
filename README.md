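# macula-hbm

Multivariate Bayesian hierarchical modelling of longitudinal macular
ganglion-cell-complex (GCC) thickness on a superpixel grid.

## The problem

Glaucoma slowly thins the inner retinal layers. Spectral-domain OCT of the
macula yields, per visit, an 8×8 array of 3°×3° "superpixels" of averaged GCC
thickness (μm); progression analyses keep the 7×7 subarray obtained by
dropping the most inferior row and the nasal-most column. Estimating each
eye's *rate of change* per superpixel from 4–10 visits over ≤4.2 years is
noisy, and the 49 series per eye are strongly interrelated: neighbouring
superpixels share anatomy (nerve-fibre bundles that do not cross the temporal
horizontal raphe), scan placement and segmentation error. This package
implements, for researchers in ophthalmic biostatistics, a single joint model
of all 49 superpixels, plus the surrounding pipeline: data cleaning,
posterior estimation of cross-superpixel correlations of the fitted effects,
and principal-component analysis of those matrices — and a synthetic-cohort
generator that emulates the study design for testing and calibration.

## The model

For subject *i*, visit time *t<sub>ij</sub>* (years), superpixel *k*:

```
y_ijk = α0_k + α1_k t_ij + β0_ik + β1_ik t_ij + ε_ijk,   ε_ijk ~ N(0, σ_ik²)
(β0_ik, β1_ik) ~ N₂(0, D_k),       log σ_ik ~ N(ν_k, ω_k²)
```

Each superpixel has 7 interpretable population parameters: intercept α0_k,
slope α1_k, random-intercept SD √D00_k, random-slope SD √D11_k, their
correlation ρ_k, and the mean σ_mk and SD σ_sk of the subject residual SDs.
Inference uses an unconstrained reparameterization
θ_k = (α0, log D00, log D11.0, α1, D01/D00, ν, log ω) with
D11.0 = D11(1 − ρ²); (θ1, θ2, θ3) get a correlated trivariate-normal
hierarchical prior across superpixels and θ4–θ7 independent normal priors,
with proper vague hyperpriors. Posterior sampling is a vectorized blocked
Gibbs sampler (conjugate draws for all linear/normal blocks,
adaptive random-walk Metropolis for log-variance parameters); it runs the
desk-scale default of 3 chains × 3000 kept draws in well under a minute for
111 subjects × 49 superpixels on one CPU.

Downstream, per posterior draw the subject random intercepts, slopes, log
residual SDs and the visit residuals each form a (rows × 49) matrix; sample
covariance across rows, averaged over draws, gives four 49×49 matrices whose
correlations and eigenstructure (scree fractions, eigenvector grid maps)
summarize the spatial dependence the model itself does not capture.

## Worked example

```python
import macula_hbm as mh
from macula_hbm.model import MCMCConfig

model = mh.SpatialEffectModel.default(seed=11)          # reference-calibrated truth
table, truth = mh.simulate_cohort(model, mh.CohortDesign(n_subjects=111), seed=12)
cleaned, report = mh.apply_cleaning(table)
draws = mh.fit_mcmc(cleaned, MCMCConfig(chains=2, burn_in=800, draws=1000), seed=13)
print(mh.summarize_global(draws))
ec = mh.cross_superpixel_correlation(draws, "intercept")
print(mh.adjacent_mean_correlation(ec))
pc = mh.eigendecompose(ec.covariance, kind="intercept")
```

This run simulates 39 445 measurements from 111 subjects, removes 94 of them
(26 single spike outliers and 9 outlying profiles — the spike rule firing on
the heavy right tail of the log-normal residual SDs), and prints global
posterior summaries such as:

```
                                                  mean     sd    q2.5   q97.5
global_mean_population_intercept                75.903  0.122  75.631  76.108
global_mean_population_slope                    -0.242  0.015  -0.271  -0.213
global_mean_random_intercept_sd                 15.296  0.156  14.998  15.599
global_mean_residual_sd_mean                     1.936  0.014   1.908   1.964
global_sd_population_intercept                  13.472  0.159  13.164  13.766
corr_population_intercept__random_intercept_sd   0.709  0.025   0.658   0.757
```

i.e. an average GCC of ~76 μm thinning at ~−0.24 μm/year, large stable
between-subject spread (random-intercept SD ~15 μm), and strongly correlated
intercept level and intercept spread across the macula. The recovered
adjacent-pair mean correlation of random intercepts is 0.76 (generator truth
0.78) and the intercept covariance PCA gives leading components of 47.6%,
14.7% and 6.0% — a single-sign "global thickness" component first, as in the
cohort the generator is calibrated to.

A command-line interface mirrors the pipeline:

```
macula-hbm simulate --seed 1 --out cohort.csv --truth truth.json
macula-hbm clean    --in cohort.csv --out cleaned.csv --report report.json
macula-hbm fit      --in cleaned.csv --seed 2 --out posterior/
macula-hbm residuals --posterior posterior/ --out matrices/
macula-hbm pca      --matrices matrices/ --out pca/
```

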