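"""Early non-specific Arc expression: how much of the unstimulated Arc
signal comes from neurons born in the previous month?
"""

import dgrecruit as dg

early = dg.EarlyExpressionModel.default_calibration()
survival = dg.default_survival_model()

curve = dg.early_background_curve(early, survival, granule_total=231_000, t_max=400)
peak = dg.peak_recruitment(curve)

print(f"max background: {100 * peak.count:.3f}% of granule cells "
      f"(animal age {peak.age_days} d)")
print(f"  = {dg.background_share_of_cc(peak.count, 0.0031):.0f}% of the 0.31% "
      "cage-control Arc fraction")
print(f"  = {dg.background_share_of_cc(peak.count, 0.015):.0f}% of the 1.5% "
      "exploration response")

# Neurons aged 1-30 d express Arc at ~1.5-2.5% regardless of behaviour.
# Convolved with the standing size of those young cohorts, this accounts
# for roughly half of the unstimulated Arc signal but only ~10% of the
# exploration-driven response.
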