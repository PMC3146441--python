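"""Simulate ordinal responses and compare one-factor vs three-factor fits.

Generates n=811 responses from the three-correlated-factor EPDS reference
model, estimates the polychoric correlation matrix, and fits both a
one-factor and a three-factor CFA.  The printed RMSEA values show why a
single factor is rejected for such data (RMSEA above the 0.06 close-fit
band) while the generating structure fits well.
"""

from ordscale import (
    EPDS_ITEM_SETS,
    cfa_spec,
    epds_spec,
    fit_model,
    generate_responses,
    one_factor_spec,
    polychoric_matrix,
)

spec = epds_spec("three_factor", "symmetric", n=811, seed=20070101)
matrix = generate_responses(spec)
stats = polychoric_matrix(matrix)

for label, model in [
    ("one-factor", one_factor_spec(matrix.item_labels)),
    ("three-factor", cfa_spec(EPDS_ITEM_SETS, matrix.item_labels)),
]:
    solution, fit = fit_model(model, stats)
    print(
        f"{label:>12}: T={fit.T:6.1f} df={fit.df}  "
        f"RMSEA={fit.rmsea:.3f} ({fit.rmsea_ci[0]:.3f}; {fit.rmsea_ci[1]:.3f})  "
        f"CFI={fit.cfi:.3f} TLI={fit.tli:.3f}"
    )
print(
    "\nRMSEA < 0.06 indicates close fit; 0.06-0.10 is marginal; > 0.10 poor.\n"
    "The one-factor model lands in the marginal band on data generated with\n"
    "three correlated factors, while the generating model fits closely."
)
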