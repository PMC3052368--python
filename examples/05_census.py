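"""Census arithmetic: from one animal's sampled counts to the population."""

import dgrecruit as dg

region = dg.scale_to_region(80_000, 450, 1300, round_to_thousand=True)
print(f"sampled 80,000 cells / 450 um -> {region:,.0f} cells in the 1300 um region")

responding = dg.responding_population(region, 0.015)
print(f"1.5% respond to exploration: {responding:,} cells")

daily = dg.responding_population(1_200_000, 0.0015)
print(f"whole DG (1.2M cells) x 0.15% one-day survival: ~{daily:,} cells/day")

died = dg.survival_decline(0.0035, 0.0015)
print(f"BrdU fraction fell 0.35% -> 0.15% between days 7 and 45: "
      f"{died:.1f}% of day-7 cells died")
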