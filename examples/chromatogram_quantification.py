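"""GC-MS SIM quantification round trip with internal-standard calibration.

Simulates selected-ion-monitoring chromatograms, builds per-compound
calibration curves from standards at the six laboratory levels
(33, 10, 5, 1, 0.5, 0.1 ng), then quantifies an unknown sample by
integrating quantifier-ion peaks, normalizing to the 320 ng tetralin
internal standard and inverting the curve.
"""

from glvchoice import synthgen
from glvchoice.quant import (CALIBRATION_LEVELS_NG, IS_SPIKE_LAB_NG, TETRALIN,
                             fit_calibration, integrate_sim_peak,
                             quantify_amount)

compounds = ["(Z)-3-hexenal", "(E)-2-hexenal", "(Z)-3-hexenyl acetate"]

curves = {}
for name in compounds:
    points = []
    for ng in CALIBRATION_LEVELS_NG:
        chrom = synthgen.generate_sim_chromatogram({name: ng})
        points.append((ng, integrate_sim_peak(chrom, name)
                       / integrate_sim_peak(chrom, TETRALIN)))
    curves[name] = fit_calibration(points, compound=name)
    print(f"calibration {name}: slope {curves[name].slope:.4f} /ng, "
          f"r^2 = {curves[name].r_squared:.6f}")

sample = {"(Z)-3-hexenal": 12.0, "(E)-2-hexenal": 3.5,
          "(Z)-3-hexenyl acetate": 22.0}
chrom = synthgen.generate_sim_chromatogram(sample)
is_area = integrate_sim_peak(chrom, TETRALIN)
print()
for name, true_ng in sample.items():
    q = quantify_amount(integrate_sim_peak(chrom, name), is_area,
                        IS_SPIKE_LAB_NG, curves[name])
    print(f"{name:<24} constructed {true_ng:5.1f} ng -> "
          f"quantified {q.ng:7.3f} ng (bld={q.bld})")
# Noiseless round-trip recovery is exact to well under 1%; amounts under
# the lowest calibration level (0.1 ng) would carry the bld flag.
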