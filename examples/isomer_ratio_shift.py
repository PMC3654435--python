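"""Detect the oral-secretion-driven (Z)-3 -> (E)-2 isomer shift.

Generates a synthetic GLV emission table for water-treated (w+w) and oral
secretion-treated (w+OS) wounded leaves, computes per-sample
(Z)-3/(E)-2 ratios (displayed as negative reciprocals below 1) and tests
the treatment effect per compound family with the exact Mann-Whitney U.
"""

import numpy as np

from glvchoice import synthgen
from glvchoice.npstats import mann_whitney_u
from glvchoice.quant import ratio_table

truth = synthgen.GroundTruthEmissions(isomerase_conversion=0.6, seed=1)
table = synthgen.generate_emission_dataset(
    truth, treatments=["w+w", "w+OS"], time_blocks=["day"], n_per_cell=5)

ratios, excluded = ratio_table(table)
print(f"{len(ratios)} per-sample ratios ({excluded} excluded for bld/zero "
      "(E)-2 denominators)\n")
print(f"{'family':<10} {'median w+w':>11} {'median w+OS':>12} "
      f"{'display w+OS':>13} {'U':>5} {'p':>8}")
for fam, sub in ratios.groupby("family"):
    ww = sub.loc[sub.treatment == "w+w", "ratio"].to_numpy()
    wos = sub.loc[sub.treatment == "w+OS", "ratio"].to_numpy()
    disp = np.median(sub.loc[sub.treatment == "w+OS", "display_value"])
    res = mann_whitney_u(ww, wos)
    print(f"{fam:<10} {np.median(ww):>11.2f} {np.median(wos):>12.2f} "
          f"{disp:>13.2f} {res.statistic:>5.0f} {res.p_two_sided:>8.4f}")
# w+w leaves emit (Z)-3-dominant blends (ratios >> 1); applying larval oral
# secretions converts ~60% of the (Z)-3 pool, pushing ratios toward or
# below 1 (negative display values mean (E)-2 dominance).  Small p-values
# flag families where the shift is detectable at n = 5 per group.
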