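"""Sulfate reduction rates, per-cell rates, turnover times, generations.

Builds a 50-cm synthetic core, converts 35S tracer incubations to
sulfate reduction rates, anchors them to dsrB-derived sulfate-reducer
abundances, and prints the resulting energetics summary.
"""

import numpy as np

from sedmix import (ScenarioConfig, biomass_turnover, cs_srr,
                    cumulative_generations, fraction_generations_above,
                    gen_qpcr_tcc, gen_srr_and_sulfate, srm_cells, srr_profile)

cfg = ScenarioConfig(seed=7)
depths = np.arange(0.5, 50.0, 1.0)

srr_true, sulfate, tracer = gen_srr_and_sulfate(cfg, depths)
srr = srr_profile(tracer, bins=srr_true)          # nmol SO4 / cm^3 / d
qpcr, _ = gen_qpcr_tcc(cfg, depths)
srm = srm_cells(qpcr["dsrb"])                     # 7% extraction efficiency

css = cs_srr(srr, srm, bulk_density=1.0)          # fmol SO4 / cell / d
tb = biomass_turnover(css)                        # years
prof = cumulative_generations(tb, cssrr=css.value)
frac = fraction_generations_above(prof, 6.0)

print(f"SRR peak: {srr.value.max():.0f} nmol/cm3/d at "
      f"{srr.midpoint[np.argmax(srr.value)]:.1f} cm; "
      f"{srr.value[-1]:.2f} nmol/cm3/d at {srr.midpoint[-1]:.1f} cm")
print(f"csSRR peak: {np.nanmax(css.value):.3f} fmol/cell/d")
print(f"turnover: {np.nanmin(tb.value):.2f} yr near the surface -> "
      f"{np.nanmax(tb.value):.1f} yr at depth (mean {np.nanmean(tb.value):.1f} yr)")
print(f"total generations over the core: {prof.cumulative_generations[-1]:.0f}; "
      f"{100 * frac:.0f}% of them above the 6-cm mixed-layer bottom")
print("Fast turnover inside the bioturbated zone concentrates most cell divisions")
print("in the top centimeters; below it, energy limitation stretches generation times.")
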