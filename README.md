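# glvchoice

A toolkit for analyzing how herbivore-induced shifts in green-leaf-volatile
(GLV) isomer composition are produced, perceived and acted upon. It bundles
the three analysis tracks of that kind of study — plant chemistry, insect
neurophysiology and field behavior — as one tested Python library:

* **Calcium-imaging pipeline** — antennal-lobe (AL) movie preprocessing
  (background, photobleaching, rigid motion, spatial median filter), ΔF/F
  computation, ROI time traces and response amplitudes with per-animal
  normalization, activation maps and pattern-similarity correlation.
* **GC-MS SIM quantification** — quantifier-ion peak integration,
  tetralin internal-standard normalization, linear calibration,
  emission-rate bases (per g leaf fresh mass or per cm² leaf area),
  paired control subtraction, per-sample (Z)-3/(E)-2 isomer ratios and
  solvent-balanced lure recipe arithmetic.
* **Nonparametric statistics** — Mann–Whitney U and Wilcoxon signed-rank
  with *exact* small-sample enumeration (ties handled exactly),
  tie-corrected Kruskal–Wallis and Dunn's Bonferroni-adjusted post-hoc
  test with compact-letter display.
* **Paired-choice behavior** — per-plant oviposition differences with
  zero-pair exclusion and the signed-rank choice test.
* **Synthetic data generators** — ground-truthed AL movies, emission
  tables, SIM chromatograms and egg-count tables that emulate the raw
  data each analysis consumes, so every stage can be benchmarked against
  known truth.

## The science in brief

Wounded leaves release (Z)-3-configured C6 volatiles (hexenal, hexenol,
hexenyl esters). An isomerase in lepidopteran larval oral secretions
converts part of the (Z)-3 pool to (E)-2 isomers, so the emitted
(Z)-3/(E)-2 ratio encodes *who* damaged the plant. The toolkit's central
statistics are:

* **ΔF/F response amplitude** — per ROI, the post-stimulus maximum of the
  3-frame-smoothed trace averaged with its neighbours, normalized per
  animal to the maximal response ("% norm ΔF/F") with a ≥ 30 % inclusion
  criterion.
* **Isomer ratio with negative-reciprocal display** — per sample,
  r = (Z)-3 amount / (E)-2 amount; for display, T(r) = r if r ≥ 1 else
  −1/r, so both dominance directions scale symmetrically away from ±1.
* **Exact rank tests** — two-sided p-values by enumerating all C(n+m, n)
  group labelings (U) or 2ⁿ sign patterns (signed rank) for small n.

## Worked example

```bash
python examples/imaging_recovery.py
```

```
motion: 100% of per-frame shifts recovered exactly
ROI1: recovered dF/F amplitude 0.0146 (ground truth 0.0173, error 15.6%)
ROI3: recovered dF/F amplitude 0.0276 (ground truth 0.0289, error 4.4%)
```

A synthetic AL movie is corrupted with photobleaching (τ = 25 s), random
rigid shifts up to ±5 px and 5 % sensor noise; the correction chain
re-aligns every frame exactly and recovers the glomerular ΔF/F response
amplitudes (here 1.5–3 % ΔF/F) close to their ground truth — individual
small-amplitude ROIs scatter more, the median error over many movies
stays below 10 %.

```bash
python examples/oviposition_choice.py
```

```
(Z)-3 side: 1.10 +/- 0.11 eggs per plant
(E)-2 side: 0.48 +/- 0.08 eggs per plant
zero-egg pairs excluded: 9 (51 informative pairs kept)
Wilcoxon signed-rank: W = 109.0, two-sided p = 0.0002 (approx)
```

Moths offered a (Z)-3- vs an (E)-2-scented side of the same plant
(Poisson means 1.0 vs 0.5 eggs) show a clear preference for the (Z)-3
side once uninformative zero-egg plants are excluded.

The other examples cover the isomer-ratio shift with exact U tests
(`isomer_ratio_shift.py`), the GC-MS calibration round trip
(`chromatogram_quantification.py`) and blend-dose / solvent-balance
arithmetic (`field_mix_recipes.py`).

A thin CLI wraps the same functions:

```bash
glvchoice simulate eggs --seed 5 --n-plants 30 --out pairs.csv
glvchoice eggs --in pairs.csv --report report.json
glvchoice run --seed 1 --out runs/demo     # end-to-end synthetic pipeline
```

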