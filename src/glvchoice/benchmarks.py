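"""Ground-truth recovery and calibration benchmarks.

Each routine generates synthetic inputs with the package's own generators,
runs the analysis chain on them and returns measured metrics.  They are
the quantitative evidence behind the package's accuracy claims: amplitude
and motion recovery of the imaging chain, oracle agreement of the exact
rank tests, type-I calibration of the paired signed-rank analysis, and
the GC-MS quantification round trip.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import synthgen
from .behavior import oviposition_test
from .imaging import correct_bleaching, median_filter_movie, preprocess, subtract_background
from .movie import AcquisitionGeometry, MovieStack
from .npstats import mann_whitney_u, wilcoxon_signed_rank
from .quant import (CALIBRATION_LEVELS_NG, COMPOUND_REGISTRY, IS_SPIKE_LAB_NG,
                    TETRALIN, fit_calibration, integrate_sim_peak,
                    quantify_amount, ratio_table)
from .response import (Roi, ResponseTrace, activation_map, extract_trace,
                       pattern_correlation, response_amplitude, smooth_trace)

__all__ = [
    "imaging_recovery_suite",
    "bleach_flatness",
    "rank_test_oracle_agreement",
    "median_filter_oracle_agreement",
    "signed_rank_type1_error",
    "quantification_roundtrip",
    "isomer_ratio_recovery",
    "pattern_similarity_study",
]

_SCORING_ODOR = "(Z)-3-hexenyl acetate"
_MIN_TRUE_AMP = 0.01  # ROIs below the noise floor are not scored


def imaging_recovery_suite(n_movies: int = 20, seed: int = 0,
                           noise_frac: float = 0.05,
                           max_shift_px: int = 5) -> dict:
    """Full-chain ground-truth recovery on seeded corrupted movies.

    Each movie gets a bleach time constant drawn from 10-40 s, random
    integer shifts up to ``max_shift_px`` and Gaussian noise with SD
    ``noise_frac`` of the baseline.  The preprocess + ROI-extraction chain
    is scored against the noiseless ROI dF/F ground truth on every ROI
    whose true amplitude exceeds the noise floor.
    """
    geometry = AcquisitionGeometry()
    rng = np.random.default_rng(seed)
    rel_errors: list[float] = []
    shifts_total = 0
    shifts_exact = 0
    onset = geometry.stimulus_onset_frame
    for i in range(n_movies):
        truth = synthgen.default_al_truth(seed=int(rng.integers(2 ** 31)),
                                          geometry=geometry)
        truth.noise_sd = noise_frac * truth.baseline_level
        truth.bleach_tau_s = float(rng.uniform(10.0, 40.0))
        shifts = np.zeros((geometry.n_frames, 2), dtype=int)
        shifts[1:] = rng.integers(-max_shift_px, max_shift_px + 1,
                                  (geometry.n_frames - 1, 2))
        truth.shifts = shifts
        movie, _ = synthgen.generate_al_movie(truth, geometry,
                                              odor=_SCORING_ODOR)
        result = preprocess(movie)
        shifts_exact += int(np.sum(np.all(result.shifts == shifts, axis=1)))
        shifts_total += geometry.n_frames
        for g in truth.glomeruli:
            if g.amplitude(_SCORING_ODOR) < _MIN_TRUE_AMP:
                continue
            roi = Roi("spot", g.center_row_px, g.center_col_px)
            trace = smooth_trace(extract_trace(result.dff, roi))
            est = response_amplitude(trace, onset)
            clean = synthgen.noiseless_roi_dff(
                truth, geometry, (g.center_row_px, g.center_col_px),
                roi.side_px(geometry.pixel_size_um), odor=_SCORING_ODOR)
            true_amp = response_amplitude(
                smooth_trace(ResponseTrace(clean, "spot")), onset)
            rel_errors.append(abs(est - true_amp) / true_amp)
    return {
        "median_rel_error": float(np.median(rel_errors)),
        "shift_exact_fraction": shifts_exact / shifts_total,
        "n_movies": n_movies,
        "n_amplitudes": len(rel_errors),
    }


def bleach_flatness(n_movies: int = 5, seed: int = 0) -> dict:
    """Residual slope of corrected pure-bleach baselines (noiseless)."""
    geometry = AcquisitionGeometry()
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_movies):
        truth = synthgen.GroundTruthMovie(
            glomeruli=[], bleach_tau_s=float(rng.uniform(10.0, 40.0)),
            bleach_fraction=float(rng.uniform(0.1, 0.4)), noise_sd=0.0)
        movie, _ = synthgen.generate_al_movie(truth, geometry)
        movie, _ = subtract_background(movie)
        corrected, _ = correct_bleaching(movie)
        trace = corrected.frames.mean(axis=(1, 2))
        slope = np.polyfit(np.arange(len(trace)), trace, 1)[0]
        worst = max(worst, abs(slope) / trace.mean())
    return {"max_rel_slope_per_frame": worst, "n_movies": n_movies}


def rank_test_oracle_agreement(n_instances: int = 200, seed: int = 0) -> dict:
    """Exact p-values vs an independent enumeration oracle (scipy exact).

    Tie-free continuous inputs with n + m <= 10 (two-sample) and n <= 10
    (signed rank).
    """
    rng = np.random.default_rng(seed)
    worst_u = 0.0
    worst_w = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(2, 6))
        m = int(rng.integers(2, 11 - n))
        x, y = rng.normal(size=n), rng.normal(size=m)
        mine = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        worst_u = max(worst_u, abs(mine.p_two_sided - ref.pvalue))

        d = rng.normal(size=int(rng.integers(3, 11)))
        mine_w = wilcoxon_signed_rank(d)
        ref_w = sps.wilcoxon(d, alternative="two-sided", method="exact")
        worst_w = max(worst_w, abs(mine_w.p_two_sided - ref_w.pvalue))
    return {"max_abs_dp_mann_whitney": worst_u,
            "max_abs_dp_wilcoxon": worst_w,
            "n_instances": n_instances}


def median_filter_oracle_agreement(seed: int = 0, kernel_px: int = 5) -> dict:
    """Median filter vs a per-pixel brute-force median."""
    rng = np.random.default_rng(seed)
    geometry = AcquisitionGeometry(height=40, width=48)
    frames = rng.uniform(0, 100, (geometry.n_frames, 40, 48))
    movie = MovieStack(frames=frames, geometry=geometry)
    filtered, _ = median_filter_movie(movie, kernel_px=kernel_px)
    padded = np.pad(frames[0], kernel_px // 2, mode="symmetric")
    expected = np.empty_like(frames[0])
    for i in range(40):
        for j in range(48):
            expected[i, j] = np.median(padded[i:i + kernel_px, j:j + kernel_px])
    return {"all_pixels_equal": bool(np.array_equal(filtered.frames[0],
                                                    expected))}


def signed_rank_type1_error(runs: int = 2000, n_plants: int = 15,
                            alpha: float = 0.05, seed: int = 0) -> dict:
    """Type-I rate of the paired-choice analysis on null Poisson data.

    Both plant sides share the field-scale mean of 1.0 egg per side; the
    zero-pair exclusion rule and the exact signed-rank test are applied
    exactly as in the real analysis.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    effective = 0
    for _ in range(runs):
        truth = synthgen.GroundTruthOviposition(
            mean_eggs_a=1.0, mean_eggs_b=1.0, n_plants=n_plants,
            seed=int(rng.integers(2 ** 31)))
        pairs = synthgen.generate_oviposition_dataset(truth)
        try:
            report = oviposition_test(pairs)
        except ValueError:  # no informative pairs drawn
            continue
        effective += 1
        if report.test.p_two_sided <= alpha:
            rejections += 1
    return {"type1_rate": rejections / effective, "runs": effective,
            "alpha": alpha}


def quantification_roundtrip(seed: int = 0) -> dict:
    """Construct -> integrate -> IS-normalize -> calibrate, noiseless.

    Builds per-compound calibration curves from synthetic standards at the
    six laboratory levels, then quantifies a synthetic sample of all eight
    GLVs and reports the worst relative recovery error.
    """
    rng = np.random.default_rng(seed)
    rfs = {name: float(rng.uniform(5, 15)) for name in COMPOUND_REGISTRY}
    curves = {}
    for name in COMPOUND_REGISTRY:
        pts = []
        for ng in CALIBRATION_LEVELS_NG:
            chrom = synthgen.generate_sim_chromatogram(
                {name: ng}, response_factors=rfs)
            pts.append((ng, integrate_sim_peak(chrom, name)
                        / integrate_sim_peak(chrom, TETRALIN)))
        curves[name] = fit_calibration(pts, compound=name)
    amounts = {name: float(rng.uniform(1.0, 30.0))
               for name in COMPOUND_REGISTRY}
    chrom = synthgen.generate_sim_chromatogram(amounts, response_factors=rfs)
    is_area = integrate_sim_peak(chrom, TETRALIN)
    worst = 0.0
    for name, true_ng in amounts.items():
        q = quantify_amount(integrate_sim_peak(chrom, name), is_area,
                            IS_SPIKE_LAB_NG, curves[name])
        worst = max(worst, abs(q.ng - true_ng) / true_ng)
    return {"max_rel_error": worst, "n_compounds": len(amounts)}


def isomer_ratio_recovery(n_samples: int = 2000, seed: int = 0) -> dict:
    """Median per-sample ratio vs the transfer-model closed form."""
    truth = synthgen.GroundTruthEmissions(
        base_amounts={"acetate": (10.0, 1.0)}, lognormal_sigma=0.4,
        isomerase_conversion=0.6, seed=seed)
    table = synthgen.generate_emission_dataset(truth, treatments=["w+OS"],
                                               n_per_cell=n_samples)
    ratios, _ = ratio_table(table)
    expected = synthgen.expected_median_ratio(truth, "acetate")
    measured = float(np.median(ratios["ratio"]))
    return {"measured_median_ratio": measured,
            "expected_median_ratio": expected,
            "rel_error": abs(measured - expected) / expected,
            "n_samples": n_samples}


def pattern_similarity_study(n_repeats: int = 3, seed: int = 0,
                             noise_frac: float = 0.05) -> dict:
    """Within-truth repeats vs cross-truth pairs of activation maps.

    Two AL scenes with different glomerular layouts are each imaged
    ``n_repeats`` times with fresh noise; activation-map correlations of
    same-scene repeats should exceed cross-scene correlations.  Maps are
    masked to the AL outline (solid-tissue pixels, f0 above a quarter of
    the baseline level), as in the real analysis, so the low-baseline rim
    of the preparation does not enter the correlation.
    """
    geometry = AcquisitionGeometry()
    rng = np.random.default_rng(seed)
    truth_a = synthgen.default_al_truth(geometry=geometry)
    truth_b = synthgen.default_al_truth(geometry=geometry)
    # second scene: swap row positions to displace the spots
    truth_b.glomeruli = [
        synthgen.Glomerulus(geometry.height - 1 - g.center_row_px,
                            g.center_col_px, g.sigma_um, g.amplitude_dff)
        for g in truth_b.glomeruli]
    maps = {"a": [], "b": []}
    for label, truth in (("a", truth_a), ("b", truth_b)):
        for _ in range(n_repeats):
            truth.noise_sd = noise_frac * truth.baseline_level
            truth.seed = int(rng.integers(2 ** 31))
            movie, _ = synthgen.generate_al_movie(truth, geometry,
                                                  odor=_SCORING_ODOR)
            result = preprocess(movie, motion=False)
            al_mask = result.dff.f0 > 0.25 * truth.baseline_level
            maps[label].append(activation_map(result.dff, mask=al_mask))
    within = [pattern_correlation(m1, m2)
              for group in maps.values()
              for i, m1 in enumerate(group)
              for m2 in group[i + 1:]]
    cross = [pattern_correlation(m1, m2)
             for m1 in maps["a"] for m2 in maps["b"]]
    return {"median_within_r": float(np.median(within)),
            "median_cross_r": float(np.median(cross)),
            "n_within_pairs": len(within), "n_cross_pairs": len(cross)}
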