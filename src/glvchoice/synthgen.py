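"""Ground-truthed synthetic inputs for the analysis pipeline.

Four generators emulate the raw data the downstream analyses consume:

* antennal-lobe (AL) calcium-imaging movies with glomerular activity spots,
  photobleaching, rigid frame-to-frame motion and sensor noise;
* green-leaf-volatile (GLV) emission tables with the oral-secretion-driven
  (Z)-3 -> (E)-2 isomer conversion;
* selected-ion-monitoring (SIM) chromatograms with internal-standard spikes;
* paired oviposition egg counts.

Every generator is seed-deterministic and returns (or serializes) its
ground truth alongside the data so recovery can be scored exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .movie import AcquisitionGeometry, MovieStack
from .quant import COMPOUND_REGISTRY, Chromatogram, CompoundSpec, TETRALIN

__all__ = [
    "Glomerulus",
    "GroundTruthMovie",
    "GroundTruthEmissions",
    "GroundTruthOviposition",
    "generate_al_movie",
    "generate_emission_dataset",
    "generate_sim_chromatogram",
    "generate_oviposition_dataset",
    "default_al_truth",
    "stimulus_dff_timecourse",
    "noiseless_roi_dff",
    "write_truth",
]

DETECTION_LIMIT_DEFAULT = 0.001  # amounts below this are flagged "bld"


@dataclass(frozen=True)
class Glomerulus:
    """One activity spot: Gaussian profile with per-odor peak dF/F."""

    center_row_px: int
    center_col_px: int
    sigma_um: float = 25.0
    amplitude_dff: dict[str, float] = field(default_factory=dict)

    def amplitude(self, odor: str) -> float:
        return float(self.amplitude_dff.get(odor, 0.0))


@dataclass
class GroundTruthMovie:
    """Scene model behind a synthetic AL movie.

    The scene is a bright tissue disk (the AL) on a dark surround, plus a
    constant camera offset.  Fluorescence bleaches mono-exponentially;
    glomerular spots modulate it multiplicatively by (1 + dF/F(t)); rigid
    integer shifts and additive Gaussian noise corrupt each frame.

    bleach(t) = (1 - bleach_fraction) + bleach_fraction * exp(-t / tau),
    so bleach(0) = 1 and the dye decays towards 1 - bleach_fraction.
    """

    glomeruli: list[Glomerulus] = field(default_factory=list)
    baseline_level: float = 400.0
    camera_offset: float = 50.0
    bleach_tau_s: float = 20.0
    bleach_fraction: float = 0.2
    shifts: np.ndarray | None = None  # (T, 2) integer (drow, dcol), 0 if None
    noise_sd: float = 0.0
    tissue_radius_frac: float = 0.42  # disk radius as fraction of min(H, W)
    decay_tau_s: float = 2.0  # post-stimulus response decay
    seed: int = 0

    def validate(self, geometry: AcquisitionGeometry) -> None:
        if self.bleach_tau_s <= 0:
            raise ValueError("bleach_tau_s must be > 0")
        if not 0 <= self.bleach_fraction < 1:
            raise ValueError("bleach_fraction must be in [0, 1)")
        if self.baseline_level < 0 or self.camera_offset < 0 or self.noise_sd < 0:
            raise ValueError("levels and noise SD must be non-negative")
        for g in self.glomeruli:
            if any(a < 0 for a in g.amplitude_dff.values()):
                raise ValueError("amplitude_dff must be >= 0")
            if not (0 <= g.center_row_px < geometry.height
                    and 0 <= g.center_col_px < geometry.width):
                raise ValueError(
                    f"glomerulus center ({g.center_row_px}, {g.center_col_px}) "
                    "outside frame bounds"
                )
        if self.shifts is not None:
            s = np.asarray(self.shifts)
            if s.shape != (geometry.n_frames, 2):
                raise ValueError("shifts must be (n_frames, 2)")


def default_al_truth(seed: int = 0,
                     geometry: AcquisitionGeometry | None = None
                     ) -> GroundTruthMovie:
    """Four-glomerulus AL scene mirroring the observed response layout.

    ROI 2 responds to both hexenal/hexenol isomers ((E)-2 stronger);
    ROI 3 is (Z)-3-hexenyl-acetate specific, ROI 4 (E)-2-specific and
    ROI 1 isomer-unspecific.  Centers are placed at fixed fractional frame
    positions inside the tissue disk so the scene scales with geometry.
    """
    geometry = geometry or AcquisitionGeometry()
    h, w = geometry.height, geometry.width
    zha, eha = "(Z)-3-hexenyl acetate", "(E)-2-hexenyl acetate"
    glomeruli = [
        Glomerulus(int(0.385 * h), int(0.41 * w), 25.0,
                   {zha: 0.030, eha: 0.030}),                            # ROI 1
        Glomerulus(int(0.35 * h), int(0.64 * w), 25.0,
                   {"(Z)-3-hexenal": 0.020, "(E)-2-hexenal": 0.045}),    # ROI 2
        Glomerulus(int(0.635 * h), int(0.38 * w), 25.0,
                   {zha: 0.050, eha: 0.005}),                            # ROI 3
        Glomerulus(int(0.60 * h), int(0.65 * w), 25.0,
                   {zha: 0.005, eha: 0.050}),                            # ROI 4
    ]
    return GroundTruthMovie(glomeruli=glomeruli, seed=seed)


def stimulus_dff_timecourse(geometry: AcquisitionGeometry, amplitude: float,
                            decay_tau_s: float = 2.0) -> np.ndarray:
    """Canonical response time course at the spot center.

    Linear rise over the stimulus window reaching ``amplitude`` on the last
    stimulus frame, then exponential decay with time constant
    ``decay_tau_s``.  Zero before stimulus onset.
    """
    t = np.zeros(geometry.n_frames)
    on = geometry.stimulus_onset_frame
    off = geometry.stimulus_offset_frame  # first post-stimulus frame
    n_stim = max(off - on, 1)
    for f in range(on, min(off, geometry.n_frames)):
        t[f] = amplitude * (f - on + 1) / n_stim
    rate = geometry.frame_rate_hz
    for f in range(off, geometry.n_frames):
        t[f] = amplitude * np.exp(-(f - (off - 1)) / (decay_tau_s * rate))
    return t


def _tissue_mask(truth: GroundTruthMovie, geometry: AcquisitionGeometry) -> np.ndarray:
    rr, cc = np.mgrid[0:geometry.height, 0:geometry.width]
    r0, c0 = geometry.height / 2, geometry.width / 2
    radius = truth.tissue_radius_frac * min(geometry.height, geometry.width) * 1.0
    # soft edge (2 px) keeps the scene band-limited enough for registration
    d = np.hypot(rr - r0, cc - c0)
    return np.clip((radius - d) / 2.0 + 0.5, 0.0, 1.0)


def _spot_profile(g: Glomerulus, geometry: AcquisitionGeometry) -> np.ndarray:
    rr, cc = np.mgrid[0:geometry.height, 0:geometry.width]
    sigma_px = g.sigma_um / geometry.pixel_size_um
    d2 = (rr - g.center_row_px) ** 2 + (cc - g.center_col_px) ** 2
    return np.exp(-d2 / (2.0 * sigma_px ** 2))


def _shift_frame(frame: np.ndarray, drow: int, dcol: int) -> np.ndarray:
    """Integer translation with edge replication of vacated margins."""
    out = frame
    if drow:
        out = np.roll(out, drow, axis=0)
        if drow > 0:
            out[:drow, :] = out[drow, :][None, :]
        else:
            out[drow:, :] = out[drow - 1, :][None, :]
    if dcol:
        out = np.roll(out, dcol, axis=1)
        if dcol > 0:
            out[:, :dcol] = out[:, dcol][:, None]
        else:
            out[:, dcol:] = out[:, dcol - 1][:, None]
    return out


def generate_al_movie(truth: GroundTruthMovie,
                      geometry: AcquisitionGeometry | None = None,
                      odor: str = "stimulus",
                      animal_id: str = "animal0",
                      dose_ng: float = 250.0) -> tuple[MovieStack, dict]:
    """Render a synthetic AL calcium movie from its ground-truth scene.

    Frame model (before noise)::

        F(t) = offset + bleach(t) * baseline * tissue * (1 + sum_g spot_g * dff_g(t))

    shifted rigidly by the per-frame (drow, dcol) offsets.  Returns the
    movie and a JSON-serializable ground-truth record.
    """
    geometry = geometry or AcquisitionGeometry()
    geometry.validate()
    truth.validate(geometry)
    rng = np.random.default_rng(truth.seed)
    T = geometry.n_frames

    tissue = _tissue_mask(truth, geometry)
    scene0 = truth.baseline_level * tissue

    times = np.arange(T) / geometry.frame_rate_hz
    bleach = (1 - truth.bleach_fraction) + truth.bleach_fraction * np.exp(
        -times / truth.bleach_tau_s)

    spots = []
    for g in truth.glomeruli:
        amp = g.amplitude(odor)
        if amp > 0:
            spots.append((_spot_profile(g, geometry),
                          stimulus_dff_timecourse(geometry, amp, truth.decay_tau_s)))

    shifts = (np.zeros((T, 2), dtype=int) if truth.shifts is None
              else np.asarray(truth.shifts, dtype=int))

    frames = np.empty((T, geometry.height, geometry.width))
    for f in range(T):
        mod = np.ones_like(scene0)
        for profile, course in spots:
            if course[f] != 0.0:
                mod = mod + profile * course[f]
        frame = truth.camera_offset + bleach[f] * scene0 * mod
        frame = _shift_frame(frame.copy(), shifts[f, 0], shifts[f, 1])
        frames[f] = frame
    if truth.noise_sd > 0:
        frames = frames + rng.normal(0.0, truth.noise_sd, frames.shape)
    frames = np.clip(frames, 0.0, None)

    movie = MovieStack(frames=frames, geometry=geometry,
                       animal_id=animal_id, odor_label=odor, dose_ng=dose_ng)
    record = {
        "odor": odor,
        "animal_id": animal_id,
        "dose_ng": dose_ng,
        "baseline_level": truth.baseline_level,
        "camera_offset": truth.camera_offset,
        "bleach_tau_s": truth.bleach_tau_s,
        "bleach_fraction": truth.bleach_fraction,
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "shifts": shifts.tolist(),
        "glomeruli": [
            {"center_row_px": g.center_row_px, "center_col_px": g.center_col_px,
             "sigma_um": g.sigma_um, "amplitude_dff": g.amplitude(odor)}
            for g in truth.glomeruli
        ],
    }
    return movie, record


def noiseless_roi_dff(truth: GroundTruthMovie, geometry: AcquisitionGeometry,
                      center_px: tuple[int, int], side_px: int,
                      odor: str = "stimulus") -> np.ndarray:
    """Clean dF/F trace a square ROI would see, absent all corruptions.

    This is the ground truth of what the correction + extraction chain
    estimates: the spatial mean of the spot dF/F profile over the ROI,
    modulated by the stimulus time course.  No bleach, shift or noise.
    """
    r0, c0 = center_px
    h = side_px // 2
    rows = slice(max(r0 - h, 0), min(r0 - h + side_px, geometry.height))
    cols = slice(max(c0 - h, 0), min(c0 - h + side_px, geometry.width))
    trace = np.zeros(geometry.n_frames)
    for g in truth.glomeruli:
        amp = g.amplitude(odor)
        if amp > 0:
            profile = _spot_profile(g, geometry)[rows, cols]
            trace += profile.mean() * stimulus_dff_timecourse(
                geometry, amp, truth.decay_tau_s)
    return trace


def write_truth(record: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(record, indent=2))
    return path


# ---------------------------------------------------------------------------
# GLV emissions
# ---------------------------------------------------------------------------

#: default per-family base amounts (arbitrary mass units per sample), chosen
#: to mirror the day-time growth-chamber profile: (Z)-3-dominant emissions
#: with minor (E)-2 components.
DEFAULT_BASE_AMOUNTS = {
    # family: (mean_Z, mean_E)
    "aldehyde": (0.64, 0.22),
    "alcohol": (1.30, 0.058),
    "acetate": (1.59, 0.017),
    "butyrate": (0.028, 0.010),
}


@dataclass
class GroundTruthEmissions:
    """Transfer model behind a synthetic GLV emission table.

    Per sample, each compound amount is drawn lognormally around its family
    base mean (times treatment and time-block multipliers).  Under the
    herbivory-mimic treatment (w+OS), a fraction ``isomerase_conversion``
    of the drawn (Z)-3 amount is moved to the paired (E)-2 compound —
    mass-conserving, applied before measurement noise.
    """

    base_amounts: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASE_AMOUNTS))
    lognormal_sigma: float = 0.4
    isomerase_conversion: float = 0.6
    treatment_multipliers: dict[str, float] = field(
        default_factory=lambda: {"w+w": 1.0, "w+OS": 1.0, "control": 0.05})
    time_multipliers: dict[str, float] = field(
        default_factory=lambda: {"day": 1.0, "sunset": 1.3, "night": 1.5})
    detection_limit: float = DETECTION_LIMIT_DEFAULT
    seed: int = 0

    def validate(self) -> None:
        for fam, (mz, me) in self.base_amounts.items():
            if mz <= 0 or me <= 0:
                raise ValueError(f"base means for {fam} must be > 0")
        if not 0 <= self.isomerase_conversion <= 1:
            raise ValueError("isomerase_conversion must be in [0, 1]")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")


def expected_median_ratio(truth: GroundTruthEmissions, family: str) -> float:
    """Median per-sample (Z)-3/(E)-2 ratio under the transfer model (w+OS).

    With independent lognormal draws Z0, E0 the converted ratio
    R = (1-c) Z0 / (E0 + c Z0) = (1-c) / (1/R0 + c) is a monotone map of
    the lognormal ratio R0, whose median is mean_Z / mean_E (medians of the
    draws are set to the configured means).  Hence
    median(R) = (1-c) / (mean_E/mean_Z + c).
    """
    mz, me = truth.base_amounts[family]
    c = truth.isomerase_conversion
    return (1 - c) / (me / mz + c)


def generate_emission_dataset(truth: GroundTruthEmissions,
                              treatments: list[str] | None = None,
                              time_blocks: list[str] | None = None,
                              n_per_cell: int = 5) -> pd.DataFrame:
    """Draw a per-sample GLV emission table.

    Returns a long-format DataFrame with one row per sample x compound:
    columns sample_id, treatment, time_block, family, isomer, compound,
    amount, bld.  Lognormal draws have median equal to the configured
    (multiplied) mean; sigma is on the log scale.
    """
    truth.validate()
    treatments = treatments or ["w+w", "w+OS"]
    time_blocks = time_blocks or ["day"]
    for tr in treatments:
        if tr not in truth.treatment_multipliers:
            raise ValueError(f"unknown treatment label {tr!r}")
    for tb in time_blocks:
        if tb not in truth.time_multipliers:
            raise ValueError(f"unknown time block label {tb!r}")
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")

    rng = np.random.default_rng(truth.seed)
    rows = []
    sample_counter = 0
    for tb in time_blocks:
        for tr in treatments:
            mult = truth.treatment_multipliers[tr] * truth.time_multipliers[tb]
            for _ in range(n_per_cell):
                sample_id = f"S{sample_counter:04d}"
                sample_counter += 1
                for fam, (mean_z, mean_e) in truth.base_amounts.items():
                    if truth.lognormal_sigma > 0:
                        z0 = mean_z * mult * rng.lognormal(0.0, truth.lognormal_sigma)
                        e0 = mean_e * mult * rng.lognormal(0.0, truth.lognormal_sigma)
                    else:
                        z0, e0 = mean_z * mult, mean_e * mult
                    if tr == "w+OS":
                        moved = truth.isomerase_conversion * z0
                        z, e = z0 - moved, e0 + moved
                    else:
                        z, e = z0, e0
                    for isomer, amount in (("(Z)-3", z), ("(E)-2", e)):
                        rows.append({
                            "sample_id": sample_id,
                            "treatment": tr,
                            "time_block": tb,
                            "family": fam,
                            "isomer": isomer,
                            "compound": f"{isomer}-{fam}",
                            "amount": amount,
                            "bld": amount < truth.detection_limit,
                        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SIM chromatograms
# ---------------------------------------------------------------------------

def generate_sim_chromatogram(true_amounts_ng: dict[str, float],
                              response_factors: dict[str, float] | None = None,
                              is_spike_ng: float = 320.0,
                              is_response_factor: float = 10.0,
                              registry: dict[str, CompoundSpec] | None = None,
                              peak_sigma_s: float = 2.0,
                              baseline: float = 5.0,
                              noise_sd: float = 0.0,
                              dt_s: float = 0.25,
                              seed: int = 0) -> Chromatogram:
    """Simulate selected-ion-monitoring traces for a GLV sample.

    Each compound contributes a Gaussian peak on its quantifier-ion trace at
    its registry retention time, with integrated area
    ``amount * response_factor``.  The tetralin internal standard is always
    spiked (laboratory default 320 ng per trap; field traps use 240 ng).
    """
    registry = registry or COMPOUND_REGISTRY
    response_factors = response_factors or {}
    rng = np.random.default_rng(seed)

    specs = []
    for name, amount in true_amounts_ng.items():
        if amount < 0:
            raise ValueError(f"negative amount for {name}")
        if name not in registry:
            raise ValueError(f"unknown compound {name!r}")
        specs.append((registry[name], float(amount),
                      float(response_factors.get(name, 10.0))))
    specs.append((TETRALIN, float(is_spike_ng), float(is_response_factor)))

    rts = [s.retention_time_min for s, _, _ in specs]
    order = np.argsort(rts)
    for a, b in zip(order[:-1], order[1:]):
        gap_s = abs(rts[b] - rts[a]) * 60.0
        if 0 < gap_s < 4 * peak_sigma_s and specs[a][0].name != specs[b][0].name:
            warnings.warn(
                f"retention windows of {specs[a][0].name} and "
                f"{specs[b][0].name} overlap", stacklevel=2)

    t_max = (max(rts) + 2.0) * 60.0
    times = np.arange(0.0, t_max, dt_s)
    traces: dict[float, np.ndarray] = {}
    for spec, amount, rf in specs:
        mz = spec.quantifier_mz
        trace = traces.setdefault(mz, np.full_like(times, baseline))
        area = amount * rf
        if area > 0:
            rt_s = spec.retention_time_min * 60.0
            trace += (area / (peak_sigma_s * np.sqrt(2 * np.pi))
                      * np.exp(-((times - rt_s) ** 2) / (2 * peak_sigma_s ** 2)))
    if noise_sd > 0:
        for mz in traces:
            traces[mz] = np.clip(traces[mz] + rng.normal(0, noise_sd, times.shape),
                                 0, None)
    return Chromatogram(times_s=times, traces=traces)


# ---------------------------------------------------------------------------
# Oviposition
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthOviposition:
    """Poisson model behind a paired-choice egg-count table.

    Defaults mirror the isomerically pure field comparison: mean eggs per
    plant side 1.0 on the (Z)-3-scented side and 0.5 on the (E)-2 side.
    """

    mean_eggs_a: float = 1.0
    mean_eggs_b: float = 0.5
    n_plants: int = 15
    treatment_a: str = "(Z)-3-mix"
    treatment_b: str = "(E)-2-mix"
    seed: int = 0

    @property
    def preference_ratio(self) -> float:
        if self.mean_eggs_b == 0:
            return float("inf") if self.mean_eggs_a > 0 else 1.0
        return self.mean_eggs_a / self.mean_eggs_b

    def validate(self) -> None:
        if self.mean_eggs_a < 0 or self.mean_eggs_b < 0:
            raise ValueError("side means must be >= 0")
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")


def generate_oviposition_dataset(truth: GroundTruthOviposition) -> pd.DataFrame:
    """Draw per-plant paired egg counts: two independent Poisson sides."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    eggs_a = rng.poisson(truth.mean_eggs_a, truth.n_plants)
    eggs_b = rng.poisson(truth.mean_eggs_b, truth.n_plants)
    return pd.DataFrame({
        "plant_id": [f"P{i:03d}" for i in range(truth.n_plants)],
        "date": "2010-06-01",
        "treatment_a": truth.treatment_a,
        "eggs_a": eggs_a,
        "treatment_b": truth.treatment_b,
        "eggs_b": eggs_b,
    })
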