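"""Nonparametric IRT checks of the raw total score.

Computes Loevinger's H scalability coefficients, manifest-monotonicity and
between-item nonintersection (double monotonicity) diagnostics for
simulated calibrated data.  H above 0.3 indicates an ordinally scalable
item set; composite crit values below 40 mean observed violations are
compatible with sampling noise.
"""

from ordscale import epds_spec, generate_responses
from ordscale.mokken import mokken_report, severity_ordering

matrix = generate_responses(epds_spec("bifactor", "calibrated", n=811, seed=9))
report = mokken_report(matrix)

print(f"scale H = {report.scalability.H:.4f} "
      f"(jackknife se {report.scalability.H_se:.4f}; benchmark > 0.3)")
print("\nper-item summary:")
print(report.to_frame().round(4).to_string(index=False))
print(
    "\ncrit bands: < 40 attributable to sampling variation, 40-80 inspect,\n"
    "> 80 doubtful.  Monotone-homogeneous data should show few or no\n"
    "monotonicity violations; between-item intersections gauge whether all\n"
    "respondents interpret the item difficulty ordering the same way."
)
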