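"""Fit the age-dependent responsiveness line and extrapolate its end point.

The input is three group-mean observations: the fraction of a BrdU-birthdated
cohort of granule cells that expressed Arc after spatial exploration, measured
when the cohort was 30, 45 and 150 days old.
"""

import dgrecruit as dg

model = dg.fit_responsiveness(dg.DEFAULT_RESPONSE_POINTS)

print(f"P(age) = {model.intercept_at_birth:.5f} {model.slope_per_day:+.3e} * age")
print(f"R^2 = {model.r_squared:.4f}, slope p = {model.slope_p_value:.4f}")
print(f"zero crossing: {dg.zero_crossing_age(model):.2f} d "
      f"-> reported {round(dg.zero_crossing_age(model))} d")
print(f"P(30 d) = {dg.response_probability(model, 30):.4f}")

# The line says ~5% of a newly matured cohort responds to a spatial
# exploration, falling by ~0.0186 percentage points per day; extrapolated,
# neurons older than ~301 days are no longer recruited by this behaviour.
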