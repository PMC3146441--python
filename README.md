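# ordscale

Dimensionality analysis of short ordinal rating scales: polychoric
correlations, ordinal factor models (confirmatory, exploratory-within-CFA,
bifactor), AVE-based construct validity, model-based factor scores, and
Mokken-type nonparametric IRT checks — with a synthetic-data generator for
threshold-crossing factor models.

## The problem

Screening questionnaires such as the Edinburgh Postnatal Depression Scale
(EPDS; 10 items scored 0–3, total 0–30) are routinely summed into a single
raw score and cut at a threshold, yet factor-analytic studies repeatedly
find two or three correlated factors (anhedonia, anxiety, depression).
Whether the items should be scored as one scale or several is an empirical
question about *discriminant validity* and the presence of a *general
factor*, and answering it for ordinal items requires the right machinery:

- **Polychoric correlations.** Each item is treated as a discretised latent
  normal response `y* = λ'θ + e`, cut at thresholds τ (the IRT severity
  parameters *b*). Pairwise correlations of the latent responses are
  estimated by two-step maximum likelihood from the 4×4 cross-tables.
- **DWLS / WLSMV-style factor models.** Models are fitted by diagonally
  weighted least squares, `F(ϑ) = Σ_p (s_p − σ_p(ϑ))² / Γ_pp`, with a
  mean-and-variance adjusted test statistic referred to the model df,
  sandwich standard errors from the full asymptotic covariance Γ, and
  RMSEA / CFI / TLI fit indices. Exploratory blocks use geomin oblique
  rotation; nested models are compared with a Satorra–Bentler-style scaled
  difference test; score-test modification indices (MI/EPC) screen for
  residual correlations.
- **Construct validity.** Average variance extracted per factor,
  `AVE = mean(λ²)` (convergent benchmark ≥ 0.50), and the Fornell–Larcker
  criterion `√AVE ≥ |ϕ|` with bootstrap confidence intervals.
- **Bifactor analysis.** One general factor over all items plus orthogonal
  specific factors, with a variance partition showing how much of the
  explained variance the general factor carries.
- **Scores.** Maximum-a-posteriori (MAP) factor scores under the ordinal
  measurement model, correlated against raw sub-scores and the total.
- **Nonparametric IRT.** Loevinger's H scalability coefficients
  (benchmark > 0.3), manifest monotonicity and between-item ISRF
  nonintersection checks with MSP-style composite `crit` diagnostics
  (bands 40/80), restscore traces, and item severity ordering.

Because response data of this kind are rarely shareable, the package ships
a generator for threshold-crossing factor models, including reference
parameter sets for the EPDS (a three-correlated-factor solution and a
bifactor solution estimated on n = 811 postpartum respondents) with
thresholds calibratable to published sample moments (mean total 7.8, 24.3%
of totals ≥ 12).

## Worked example

```python
from ordscale import (EPDS_ITEM_SETS, bifactor_spec, epds_spec, fit_model,
                      generate_responses, polychoric_matrix, score_table)

matrix = generate_responses(epds_spec("bifactor", "calibrated", n=811, seed=5))
stats = polychoric_matrix(matrix)
solution, fit = fit_model(bifactor_spec(EPDS_ITEM_SETS, matrix.item_labels), stats)
scores = score_table(matrix, solution, EPDS_ITEM_SETS)
print(round(fit.rmsea, 3), round(scores.correlations.loc["score_g", "raw_total"], 3))
```

prints

```
0.0 0.974
```

— the bifactor model fits the simulated scale essentially perfectly (RMSEA
0.0, under the 0.06 close-fit band), and the MAP general-factor score correlates
0.974 with the plain 10-item sum: the raw total is an almost perfect
empirical proxy for the general dimension, which is the model-based
justification for using the summed score in practice. The same data yield
a scale Loevinger H around 0.39–0.41 (acceptable scalability, > 0.3).

The `examples/` directory walks through each capability (model comparison,
validity, variance partition, scoring, Mokken checks, and the full
pipeline); `ordscale run-all` runs the whole sequence from the shell and
writes a report bundle with a decision log.

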