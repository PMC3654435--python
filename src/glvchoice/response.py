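"""ROI time traces, response amplitudes and activation-pattern statistics.

An activity spot (putative glomerulus) is analyzed over a square region of
interest (ROI) of 60 x 60 um centered at the spot — 24 x 24 px at the
default 2.5 um pixel size.  The per-ROI dF/F trace is smoothed with a
3-frame moving mean, the response amplitude is the maximum after stimulus
onset averaged with its neighbours, and amplitudes are normalized per
animal to the strongest response (with a >= 30 % inclusion criterion).

Because no glomerular atlas exists for this species, activation patterns
are compared within animals via pixel-wise correlation of response maps,
and isomer selectivity via the ratio of (Z)-3- to (E)-2-specific ROI
activation, displayed with the negative-reciprocal transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .movie import DffMovie
from .transforms import display_transform

__all__ = [
    "Roi",
    "ResponseTrace",
    "ResponseAmplitude",
    "ActivationMap",
    "extract_trace",
    "smooth_trace",
    "response_amplitude",
    "normalize_amplitudes",
    "activation_map",
    "pattern_correlation",
    "roi_activation_ratio",
    "display_transform",
]


@dataclass(frozen=True)
class Roi:
    """Square region of interest centered on an activity spot."""

    label: str
    center_row_px: int
    center_col_px: int
    side_um: float = 60.0

    def side_px(self, pixel_size_um: float) -> int:
        return int(round(self.side_um / pixel_size_um))

    def bounds(self, pixel_size_um: float, height: int, width: int
               ) -> tuple[slice, slice]:
        side = self.side_px(pixel_size_um)
        half = side // 2
        r0 = self.center_row_px - half
        c0 = self.center_col_px - half
        if r0 < 0 or c0 < 0 or r0 + side > height or c0 + side > width:
            raise ValueError(f"ROI {self.label!r} extends outside the frame")
        return slice(r0, r0 + side), slice(c0, c0 + side)


@dataclass
class ResponseTrace:
    """Per-frame mean dF/F of one ROI."""

    values: np.ndarray
    roi_label: str
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")


@dataclass
class ResponseAmplitude:
    """Scalar response score of one ROI to one stimulus."""

    animal_id: str
    roi_label: str
    odor_label: str
    dose_ng: float
    raw_dff: float
    normalized_pct: float | None = None
    included: bool | None = None


@dataclass
class ActivationMap:
    """Spatial mean dF/F over the response window, with inclusion mask."""

    map: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.map.shape != self.mask.shape:
            raise ValueError("map and mask shapes differ")

    def masked_values(self) -> np.ndarray:
        return self.map[self.mask]


def extract_trace(dff: DffMovie, roi: Roi) -> ResponseTrace:
    """Per-frame mean dF/F over the ROI square."""
    h, w = dff.f0.shape
    rows, cols = roi.bounds(dff.geometry.pixel_size_um, h, w)
    block = dff.dff[:, rows, cols]
    values = np.nanmean(block.reshape(block.shape[0], -1), axis=1)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"ROI {roi.label!r} covers only masked pixels")
    return ResponseTrace(values=values, roi_label=roi.label)


def smooth_trace(trace: ResponseTrace, window: int = 3) -> ResponseTrace:
    """Centered moving mean over ``window`` frames, shrinking at the ends.

    With the default 3-frame window the first and last frame average only
    two values.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    v = trace.values
    half = window // 2
    out = np.empty_like(v)
    for i in range(len(v)):
        lo = max(i - half, 0)
        hi = min(i + half + 1, len(v))
        out[i] = v[lo:hi].mean()
    return ResponseTrace(values=out, roi_label=trace.roi_label, smoothed=True)


def response_amplitude(trace: ResponseTrace, onset_frame: int) -> float:
    """Post-onset peak dF/F averaged with its neighbouring frames.

    The maximum of the (smoothed) trace at frames >= onset is located
    (earliest frame on ties) and averaged with the pre- and post-maximum
    values, restricted to existing frames at the boundaries.
    """
    v = trace.values
    if not 0 <= onset_frame < len(v) - 1:
        raise ValueError("onset frame beyond trace")
    k = onset_frame + int(np.argmax(v[onset_frame:]))
    lo = max(k - 1, 0)
    hi = min(k + 2, len(v))
    return float(v[lo:hi].mean())


def normalize_amplitudes(amplitudes: list[ResponseAmplitude],
                         threshold_pct: float = 30.0
                         ) -> list[ResponseAmplitude]:
    """Normalize one animal's amplitudes to its maximal response.

    normalized_pct = 100 * raw / max(raw over the animal's responses);
    exactly one response attains 100.  A stimulus (odor, dose) is included
    iff any of its ROIs reaches ``threshold_pct`` of the animal maximum.
    """
    if not amplitudes:
        raise ValueError("no amplitudes to normalize")
    animals = {a.animal_id for a in amplitudes}
    if len(animals) != 1:
        raise ValueError("normalization is per animal; got several animal_ids")
    max_raw = max(a.raw_dff for a in amplitudes)
    if max_raw <= 0:
        raise ValueError("all amplitudes are non-positive; normalization undefined")
    normalized = [replace(a, normalized_pct=100.0 * a.raw_dff / max_raw)
                  for a in amplitudes]
    by_stim: dict[tuple[str, float], list[ResponseAmplitude]] = {}
    for a in normalized:
        by_stim.setdefault((a.odor_label, a.dose_ng), []).append(a)
    out = []
    for stim_amps in by_stim.values():
        included = any(a.normalized_pct >= threshold_pct for a in stim_amps)
        out.extend(replace(a, included=included) for a in stim_amps)
    return out


def amplitude_frame(amplitudes: list[ResponseAmplitude]) -> pd.DataFrame:
    """Tabular view of response amplitudes."""
    return pd.DataFrame([a.__dict__ for a in amplitudes])


def activation_map(dff: DffMovie,
                   response_window: tuple[int, int] | None = None,
                   mask: np.ndarray | None = None) -> ActivationMap:
    """Per-pixel mean dF/F over the response window.

    The default window spans the stimulus frames plus the following second
    (frames 8-19 at the default geometry).  ``mask`` restricts the map to
    an antennal-lobe outline; by default all finite pixels are used.
    """
    g = dff.geometry
    if response_window is None:
        stop = min(g.stimulus_offset_frame + int(round(g.frame_rate_hz)),
                   dff.n_frames)
        response_window = (g.stimulus_onset_frame, stop)
    start, stop = response_window
    if not 0 <= start < stop <= dff.n_frames:
        raise ValueError("response window empty or outside the recording")
    with warnings.catch_warnings():
        # off-tissue pixels are all-NaN by design; they end up masked
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(dff.dff[start:stop], axis=0)
    if mask is None:
        mask = np.isfinite(m)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(m)
    return ActivationMap(map=np.where(np.isfinite(m), m, 0.0), mask=mask)


def pattern_correlation(map_a: ActivationMap, map_b: ActivationMap,
                        method: str = "pearson") -> float:
    """Pixel-wise correlation between two activation maps.

    A relative similarity measure for within-animal pattern comparison
    (isomer vs isomer, repeat vs repeat).  Pearson by default; Spearman
    behind ``method="spearman"``.
    """
    if map_a.map.shape != map_b.map.shape:
        raise ValueError("maps have different shapes")
    mask = map_a.mask & map_b.mask
    if mask.sum() < 3:
        raise ValueError("need at least 3 shared masked pixels")
    a = map_a.map[mask]
    b = map_b.map[mask]
    if method == "spearman":
        a = np.argsort(np.argsort(a)).astype(float)
        b = np.argsort(np.argsort(b)).astype(float)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in an activation map")
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def roi_activation_ratio(z_amp: float, e_amp: float) -> float:
    """Ratio of (Z)-3-specific to (E)-2-specific ROI activation.

    1 is the equal-activation reference.  Undefined for a non-positive
    (E)-2 amplitude.
    """
    if e_amp <= 0:
        raise ValueError("(E)-2 ROI amplitude must be > 0 for a ratio")
    ratio = z_amp / e_amp
    if ratio <= 0:
        raise ValueError("activation ratio must be > 0")
    return ratio
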