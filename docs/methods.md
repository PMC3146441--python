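# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `ordscale`, in the order the pipeline uses them.

## Measurement model

Every analysis treats an observed 4-category item `X_i ∈ {0,1,2,3}` as a
discretised latent normal response

    y*_i = Σ_k λ_ik θ_k + e_i,   e_i ~ N(0, δ_i),   δ_i = 1 − communality,

cut at strictly increasing thresholds `τ_i1 < τ_i2 < τ_i3`:
`X_i = k ⟺ τ_ik < y*_i ≤ τ_i,k+1` (with τ_i0 = −∞, τ_i4 = +∞). The latent
responses are standardized (delta parameterization), so all loadings,
factor correlations and residual correlations are on the correlation
metric and thresholds are directly interpretable as IRT severity
parameters `b_ik = τ_ik / λ_i` on the trait metric. Category codes are
assumed oriented so that higher = more of the trait; a reversal map at the
I/O layer flips reverse-keyed items (`x → 3 − x`).

## Polychoric statistics

Thresholds are estimated per item as standard-normal quantiles of the
cumulative category proportions; unobserved leading/trailing categories
produce ±∞ open bounds. Each pairwise correlation then maximises the
bivariate-normal likelihood of the 4×4 cross-table with thresholds fixed
(two-step ML), a bounded 1-D search with `xatol 1e-8`. Rectangle
probabilities come from an Owen's-T based bivariate normal CDF (absolute
accuracy ≈ 1e-14, comfortably below the 1e-10 design budget); cell
probabilities are floored at 1e-12 inside the log-likelihood. All-zero
margin categories are collapsed before fitting; a constant item is an
error naming the item.

The asymptotic covariance Γ of the stacked J(J−1)/2 estimates
(column-major lower triangle) is an empirical influence-function estimate:
per respondent and pair, the score of the cell log-probability w.r.t. ρ
(central differences, h = 1e-5) divided by the empirical information; Γ is
the covariance of these per-respondent vectors scaled by 1/n. First-step
threshold uncertainty is deliberately ignored in Γ — only the diagonal
weights the fitter, the second-step score dominates the full-Γ adjustment
terms, and the simplification keeps the estimate distribution-free. Its
diagonal shrinks at the 1/n rate (tested).

Non-positive-definite correlation matrices are repaired by eigenvalue
flooring at 1e-6 with re-standardisation to unit diagonal, iterated to
convergence; the adjustment is logged and flagged on the result, and PD
inputs pass through unchanged.

## DWLS fitting and robust statistics

Free parameters (loadings under a pattern matrix, factor correlations,
residual correlations) minimise

    F(ϑ) = Σ_p (s_p − σ_p(ϑ))² / Γ_pp,   σ = off-diag(ΛΦΛ′ + Θ),

by L-BFGS-B with analytic gradients, bounds (−0.999, 0.999) on all
parameters (standardized loadings are correlations), `gtol 1e-6`, 500
iterations (2000 for exploratory blocks). Start values: 0.6/0.3 heuristics
for confirmatory and bifactor patterns; an eigendecomposition rotated to
echelon form for exploratory blocks. Non-convergence is reported on the
solution (flag + gradient norm), not raised. Negative uniquenesses
(Heywood cases) are flagged, never truncated, in the estimates; the MAP
scorer floors δ at 0.01 for numerical use only.

The test statistic is the scaled-and-shifted transform of `T_raw = n·F̂`:
with `U = W⁻¹ − W⁻¹Δ(Δ′W⁻¹Δ)⁻¹Δ′W⁻¹`, `M = UΓ`, `a = √(df/tr M²)`,
`b = df − a·tr M`, the reported `T = a·T_raw + b` is referred to df — a
mean-and-variance adjustment in the WLSMV tradition. Equivalence with any
particular proprietary implementation is claimed only at the level of the
tested properties (misfit detection rates, parameter recovery), not to the
third decimal. Standard errors use the full-Γ sandwich
`(Δ′W⁻¹Δ)⁻¹ Δ′W⁻¹ Γ W⁻¹Δ (Δ′W⁻¹Δ)⁻¹ / n`.

Fit indices follow the standard formulas: `RMSEA = √(max(T−df,0)/(df·n))`
(n, not n−1) with a 90% CI by noncentral-χ² inversion (bisection to
1e-8); `CFI = 1 − max(T−df,0)/max(T_b−df_b, T−df, 0)`;
`TLI = ((T_b/df_b)−(T/df))/((T_b/df_b)−1)` capped at 1. The baseline model
is zero correlations with free thresholds (df = J(J−1)/2), adjusted by the
same mean/variance transform. Decision bands used by the pipeline: RMSEA
< 0.06 close, 0.06–0.10 marginal, > 0.10 poor; CFI/TLI ≥ 0.9 adequate.

Scaled difference tests between nested fits use the mean-scaling factors
`c = tr M / df` of both models:
`T_Δ = (T_raw,nested − T_raw,full) / c_d`,
`c_d = (df₀c₀ − df₁c₁)/(df₀ − df₁)`. A negative scaled statistic — a known
pathology of the correction — is reported as 0 with a warning flag.

Modification indices are univariate score tests at the constrained
optimum: with gradient `g_j` and profiled curvature `c_jj` of the
Gauss–Newton Hessian `2Δ′W⁻¹Δ`, `MI = n·g_j²/(2c_jj)` (the expected drop
in T_raw) and `EPC = −g_j/c_jj`. Candidates are fixed loadings
(confirmatory specs) and absent residual correlations; singular candidates
are skipped with a log entry. The MI ≥ 10 screening threshold is applied
by the pipeline, not the estimator.

## Geomin rotation

Exploratory solutions are rotated obliquely by gradient projection on the
geomin criterion `Σ_i (Π_k (λ_ik² + ε))^{1/K}` with ε = 0.01. Small ε with
K ≥ 3 makes the criterion multimodal, so 30 random starts (plus identity)
are run and the best converged solution kept; no start converging is an
error carrying the best criterion value. Factors are aligned to a target
(sign/permutation maximising Tucker congruence) for reporting; rotation
leaves the implied correlation matrix unchanged to machine precision
(tested at 1e-8). Rotated-solution standard errors, when requested, are
numeric delta-method propagations of the unrotated sandwich covariance
through the rotation and are flagged approximate.

## Construct validity

AVE per congeneric factor is the mean squared standardized loading;
convergent validity asks AVE ≥ 0.50, discriminant validity √AVE ≥ |ϕ| for
every correlation involving the factor, preferably without CI overlap.
Bootstrap CIs resample respondents (the only defensible unit here), rerun
thresholds + polychoric correlations per replicate, and refit starting
from the full-sample solution; replicate weights reuse the full-sample
variances (the weight matrix is ancillary to the point estimates and
refreezing it stabilises replicates). Percentile intervals are used —
simpler than BCa and adequate for plain reporting. Failed replicates are
dropped and counted; more than 20% failing is an error. Default B = 1000;
the test suite exercises B = 200 and B = 60 variants.

The bifactor variance partition uses squared-loading accounting on the
standardized scale: each item contributes an equal 100/J share, split into
general (λ_G²), specific (λ_spec²) and error (δ) parts, so the three shares
add exactly. The headline ratio is the general factor's share of all
*explained* variance, `100·Σλ_G²/(Σλ_G² + Σλ_spec²)` — for the packaged
reference bifactor loadings this is 79.0%. Absolute percentage tables
published elsewhere can rest on other normalisations; only the λ²-based
accounting is implemented, and only the ratio is treated as comparable.

## Factor scores

MAP scores are the posterior mode of θ given a response pattern: ordinal
likelihood as above plus a N(0, Φ) prior, maximised per unique pattern by
L-BFGS-B from the prior mode with analytic gradients, `gtol 1e-8`, bounds
±8 (far outside any realistic posterior mode; they exist to stop line
searches overflowing on near-Heywood solutions). Identical patterns get
identical scores by construction. EAP scores (importance-weighted prior
sampling, 4096 fixed draws) are available behind a flag for sensitivity
checks; MAP is the method of record. The score table assembles factor
scores, raw sub-scores and the total (sub-scores add to the total when the
item sets partition the scale) with Pearson correlations; zero-variance
columns are NaN-flagged, never silently zeroed.

## Nonparametric IRT

Loevinger's H divides observed pairwise covariances by the maximum
attainable given both margins (comonotone rearrangement, computed by a
two-pointer greedy coupling; verified against a transportation-LP oracle).
Item and scale coefficients aggregate numerators and denominators.
The scale-level standard error is a leave-one-respondent-out jackknife,
computed efficiently from the ≤ 16 distinct per-pair removals. Benchmarks:
H > 0.3 acceptable scalability; error-free Guttman data give H = 1
exactly.

Monotonicity: per item, respondents are grouped by restscore (adjacent
scores merged to ≥ minsize; default n/10 with floor 50 for n ≥ 500, n/5
otherwise; minimum 10); each of the 3 ISRFs is compared over every ordered
group pair, and a decrease beyond `minvi = 0.03` is a violation with a
pooled two-proportion z. Double monotonicity: for each item pair, on
restscore groups excluding both items, every step pair (k, l) is checked
for sign reversals of `p_i,k − p_j,l` across group pairs with both sides
beyond minvi; the z is the weaker of the two McNemar-style discordant
statistics. Violations are attributed to both items.

The composite `crit` diagnostic is recomputed here because its exact
published weighting is not available in this environment. It combines the
components the MSP tradition uses — scalability deficit max(0, 0.3 − H_j),
violation count, violated fraction of active comparisons, maximum and sum
of violation magnitudes, maximum and sum of z statistics — as

    crit = 50·deficit + √#vi + 100·(#vi/#ac) + 100·max vi
           + 10·√Σvi + 5·max z + 10·√Σz,   crit = 0 when #vi = 0,

with every component exposed separately so the composite can be
recalibrated. The weights were fixed against constructions: clean monotone
data score 0, a single reversed item scores far above 80. The 40/80 bands
are therefore read qualitatively (negligible / inspect / doubtful), which
is also how the decision log uses them.

Severity ordering ranks items by mean threshold location, converted to the
trait metric `b = τ̄/λ` when general-factor loadings are supplied; ties
keep input order.

## Synthetic data generator

The generator draws θ ~ N(0, Φ) (independent standard normals for
orthogonal/bifactor specs), forms y* with residual variance 1 − communality
(specs implying non-positive residual variance are rejected), and
discretises at the spec thresholds. It is seeded and bitwise reproducible.
Two reference parameter sets for the 10-item EPDS are built in: a
three-correlated-factor solution (ϕ = .74/.80/.81) and an orthogonal
bifactor solution (g loadings .51–.81), both estimated on n = 811
postpartum respondents; the default simulated sample size is 811.

Threshold calibration targets two published sample moments — mean total
7.8 and P(total ≥ 12) = 24.3% — through a single two-parameter affine map
`τ → a·τ + b` of the symmetric quartile grid applied to every item.
Per-item calibration is rejected as unidentifiable from two scalar
targets. The objective is evaluated on a fixed set of 60,000 latent draws
(common random numbers, seed 777), minimised by a coarse grid search
(the simulated objective has plateaus) followed by Nelder–Mead, and the
result must match the targets within ±0.2 points and ±2 percentage points
or a `CalibrationError` is raised.

What the generator does *not* emulate — and hence what passing tests do
not show about real data:

- **Item-specific threshold locations.** The common affine family gives
  every item identical thresholds. Consequently (a) the severity ordering
  in calibrated simulations is driven by 1/λ_g alone and does not
  reproduce real-data severity sequences, which mostly reflect per-item
  threshold differences — the ordering test therefore checks recovery of
  the *generating* model's ordering; and (b) between-item ISRF
  intersections are *over*-produced relative to real data (identical
  thresholds with heterogeneous discriminations force cross-step
  crossings), so the nonintersection checker is validated against
  constructions (Guttman data, duplicated items, planted crossings)
  rather than against published violation counts.
- **Residual dependence, missingness, non-normal traits, longitudinal
  structure** — all out of scope by design.
- The power of the general-factor difference test at n = 811 is moderate
  (~55% at α = 0.001 across seeds) because a correlated three-factor model
  approximates the reference bifactor structure closely; real data can
  misfit the three-factor model more strongly.

## Problem sizes and determinism

All stochastic procedures take explicit seeds (package default 20070101)
and are reproducible to the byte, including the pipeline's CSV/JSON
bundle. Simulation-based checks use n = 811 with 20 seeds for
sampling-level properties, n = 10,000 for null/independence checks, and
n = 50,000 for consistency checks at tolerance 0.02; the bootstrap is
exercised at B = 60–200 in the suite with B = 1000 as the analysis
default. These sizes were chosen so each property is measured at the scale
the claim refers to while the full suite stays desk-scale.
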