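"""Movie-level corrections applied before dF/F analysis.

The fixed pipeline order is: background subtraction -> bleaching correction
-> rigid motion correction -> spatial median filter -> dF/F.  Each step
returns a new movie and a log entry with the parameters used, so a run can
be reproduced bit-for-bit.

Models:

* background: a scalar camera/tissue offset, estimated as the 1st
  percentile of all pixel intensities (robust against the bright tissue);
* bleaching: a global mono-exponential-plus-constant fitted to the
  whole-frame mean trace, excluding the stimulus-response window, applied
  as a multiplicative correction;
* motion: per-frame integer rigid translation maximizing cross-correlation
  with a reference frame within +-10 px;
* shot-noise suppression: a per-frame square spatial median filter
  (default 5 x 5 px).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .movie import DffMovie, MovieStack

__all__ = [
    "BleachFitError",
    "estimate_background",
    "subtract_background",
    "correct_bleaching",
    "correct_motion",
    "median_filter_movie",
    "compute_dff",
    "preprocess",
]

EPS_F0 = 1e-6  # dF/F is undefined where the baseline is below this


class BleachFitError(RuntimeError):
    """Exponential bleach fit failed; carries the fallback that applies."""

    def __init__(self, message: str, fallback: str = "linear"):
        super().__init__(message)
        self.fallback = fallback


def estimate_background(movie: MovieStack) -> float:
    """Scalar background offset: 1st percentile of pixel intensities.

    The percentile is taken over the temporal-mean image rather than over
    raw frames: time-averaging shrinks the sensor noise by sqrt(T), so the
    estimate tracks the true dark offset instead of the noise tail of the
    darkest pixels.
    """
    if movie.frames.size == 0:
        raise ValueError("empty movie")
    return float(np.percentile(movie.frames.mean(axis=0), 1.0))


def subtract_background(movie: MovieStack, offset: float | None = None
                        ) -> tuple[MovieStack, dict]:
    """Subtract the scalar background offset, clipping at 0."""
    if offset is None:
        offset = estimate_background(movie)
    frames = np.clip(movie.frames - offset, 0.0, None)
    return movie.copy_with(frames), {"step": "background", "offset": offset}


def _default_exclude(movie: MovieStack) -> tuple[int, int]:
    """Frames excluded from the bleach fit: stimulus onset to onset + 4 s."""
    g = movie.geometry
    start = g.stimulus_onset_frame
    stop = min(start + int(round(4.0 * g.frame_rate_hz)), movie.n_frames)
    return start, stop


def correct_bleaching(movie: MovieStack,
                      exclude_window: tuple[int, int] | None = None,
                      strict: bool = False) -> tuple[MovieStack, dict]:
    """Divide out dye bleaching fitted on the whole-frame mean trace.

    b(t) = a*exp(-t/tau) + c is fitted to the mean trace using only frames
    outside ``exclude_window`` (default: stimulus onset to onset + 4 s,
    protecting the odor response from being flattened).  Every frame is
    divided by b(t)/b(0).  On fit failure a linear detrend is applied
    instead (with a warning), unless ``strict`` is set, in which case a
    :class:`BleachFitError` naming the fallback is raised.
    """
    if exclude_window is None:
        exclude_window = _default_exclude(movie)
    start, stop = exclude_window
    times = movie.times_s()
    mean_trace = movie.frames.mean(axis=(1, 2))
    keep = np.ones(movie.n_frames, dtype=bool)
    keep[start:stop] = False
    if keep.sum() < 6:
        raise ValueError("need at least 6 frames outside the exclude window")

    t_fit, y_fit = times[keep], mean_trace[keep]

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    y0, y1 = y_fit[0], y_fit[-1]
    a0 = max(y0 - y1, 1e-3 * max(abs(y0), 1.0))
    p0 = (a0, max(times[-1] / 2.0, 1.0), y1)
    method = "exponential"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, t_fit, y_fit, p0=p0,
                bounds=([0.0, 1e-3, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=5000)
        b = model(times, *popt)
        if np.any(b <= 0):
            raise RuntimeError("fitted bleach curve non-positive")
        params = {"a": float(popt[0]), "tau_s": float(popt[1]), "c": float(popt[2])}
    except (RuntimeError, ValueError) as exc:
        if strict:
            raise BleachFitError(f"bleach fit failed: {exc}", fallback="linear") from exc
        warnings.warn(f"bleach fit failed ({exc}); applying linear detrend",
                      stacklevel=2)
        slope, intercept = np.polyfit(t_fit, y_fit, 1)
        b = slope * times + intercept
        b = np.where(b <= 0, np.max(b) if np.max(b) > 0 else 1.0, b)
        method = "linear"
        params = {"slope": float(slope), "intercept": float(intercept)}

    correction = b / b[0]
    frames = movie.frames / correction[:, None, None]
    log = {"step": "bleach", "method": method, "params": params,
           "exclude_window": [int(start), int(stop)]}
    return movie.copy_with(frames), log


def _estimate_shift(ref_fft_conj: np.ndarray, shape: tuple[int, int],
                    frame: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Integer (drow, dcol) moving the reference onto ``frame``.

    FFT cross-correlation of mean-subtracted images; the maximum is
    restricted to shifts within +-max_shift.  ``ref_fft_conj`` is the
    conjugated rfft2 of the mean-subtracted reference.
    """
    frm = frame - frame.mean()
    corr = np.fft.irfft2(np.fft.rfft2(frm) * ref_fft_conj, s=shape)
    h, w = shape
    rows = np.concatenate([np.arange(0, max_shift + 1),
                           np.arange(h - max_shift, h)])
    cols = np.concatenate([np.arange(0, max_shift + 1),
                           np.arange(w - max_shift, w)])
    window = corr[np.ix_(rows, cols)]
    i, j = np.unravel_index(np.argmax(window), window.shape)
    drow, dcol = int(rows[i]), int(cols[j])
    if drow > h // 2:
        drow -= h
    if dcol > w // 2:
        dcol -= w
    return drow, dcol


def _apply_shift(frame: np.ndarray, drow: int, dcol: int) -> np.ndarray:
    """Integer translation filling vacated margins with edge values."""
    return ndimage.shift(frame, (drow, dcol), order=0, mode="nearest")


def correct_motion(movie: MovieStack, reference_frame: int = 0,
                   max_shift_px: int = 10) -> tuple[MovieStack, np.ndarray, dict]:
    """Rigid integer realignment of every frame to a reference frame.

    Returns the realigned movie, the estimated per-frame (drow, dcol)
    shifts, and a log entry.  A shift estimated at the search bound
    triggers a warning (motion may exceed the search range).
    """
    if not 0 <= reference_frame < movie.n_frames:
        raise ValueError("reference frame out of range")
    ref = movie.frames[reference_frame]
    ref_fft_conj = np.conj(np.fft.rfft2(ref - ref.mean()))
    shifts = np.zeros((movie.n_frames, 2), dtype=int)
    frames = np.empty_like(movie.frames)
    at_bound = []
    for f in range(movie.n_frames):
        if f == reference_frame:
            frames[f] = movie.frames[f]
            continue
        drow, dcol = _estimate_shift(ref_fft_conj, ref.shape,
                                     movie.frames[f], max_shift_px)
        shifts[f] = (drow, dcol)
        if max(abs(drow), abs(dcol)) >= max_shift_px:
            at_bound.append(f)
        frames[f] = _apply_shift(movie.frames[f], -drow, -dcol)
    if at_bound:
        warnings.warn(
            f"estimated shift at search bound for frames {at_bound}; "
            "motion may exceed the search range", stacklevel=2)
    log = {"step": "motion", "reference_frame": int(reference_frame),
           "max_shift_px": int(max_shift_px), "shifts": shifts.tolist()}
    return movie.copy_with(frames), shifts, log


def median_filter_movie(movie: MovieStack, kernel_px: int = 5
                        ) -> tuple[MovieStack, dict]:
    """Per-frame square spatial median filter with reflected edges."""
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValueError("kernel size must be an odd integer >= 1")
    if kernel_px == 1:
        return movie.copy_with(movie.frames.copy()), {"step": "median", "kernel_px": 1}
    frames = np.empty_like(movie.frames)
    for f in range(movie.n_frames):
        frames[f] = ndimage.median_filter(movie.frames[f],
                                          size=kernel_px, mode="reflect")
    return movie.copy_with(frames), {"step": "median", "kernel_px": int(kernel_px)}


def compute_dff(movie: MovieStack, on_nonpositive: str = "raise") -> DffMovie:
    """Relative fluorescence change against the pre-stimulus baseline.

    f0 is the per-pixel mean over the pre-stimulus frames
    (frames [0, pre_s * rate), i.e. 0-7 at defaults); dff = (F - f0)/f0.
    Pixels with f0 <= 1e-6 have undefined dF/F: with
    ``on_nonpositive="raise"`` an error naming the affected pixel count is
    raised; with ``"mask"`` those pixels become NaN.
    """
    g = movie.geometry
    n_base = g.stimulus_onset_frame
    if n_base < 1:
        raise ValueError("no pre-stimulus frames to define a baseline")
    baseline_frames = np.arange(n_base)
    f0 = movie.frames[:n_base].mean(axis=0)
    bad = f0 <= EPS_F0
    n_bad = int(bad.sum())
    if n_bad and on_nonpositive == "raise":
        raise ValueError(
            f"baseline fluorescence non-positive at {n_bad} pixels; "
            "dF/F undefined there (use on_nonpositive='mask' to proceed)")
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (movie.frames - f0) / f0
    if n_bad:
        dff[:, bad] = np.nan
    return DffMovie(dff=dff, f0=f0, baseline_frames=baseline_frames,
                    geometry=g, animal_id=movie.animal_id,
                    odor_label=movie.odor_label, dose_ng=movie.dose_ng)


@dataclass
class PreprocessResult:
    """Output of the full correction chain with its step log."""

    dff: DffMovie
    corrected: MovieStack
    shifts: np.ndarray
    log: list[dict] = field(default_factory=list)


def preprocess(movie: MovieStack, kernel_px: int = 5, motion: bool = True,
               reference_frame: int = 0, on_nonpositive: str = "mask",
               bleach_exclude: tuple[int, int] | None = None) -> PreprocessResult:
    """Run the fixed correction chain and compute dF/F.

    Order: background -> bleach -> motion -> median -> dF/F.  Dark pixels
    (zero baseline after background subtraction) are masked in the dF/F
    output by default, since a scalar-offset-subtracted movie legitimately
    contains off-tissue pixels.
    """
    log: list[dict] = []
    m, entry = subtract_background(movie)
    log.append(entry)
    m, entry = correct_bleaching(m, exclude_window=bleach_exclude)
    log.append(entry)
    if motion:
        m, shifts, entry = correct_motion(m, reference_frame=reference_frame)
        log.append(entry)
    else:
        shifts = np.zeros((movie.n_frames, 2), dtype=int)
    m, entry = median_filter_movie(m, kernel_px=kernel_px)
    log.append(entry)
    dff = compute_dff(m, on_nonpositive=on_nonpositive)
    log.append({"step": "dff", "baseline_frames": dff.baseline_frames.tolist()})
    return PreprocessResult(dff=dff, corrected=m, shifts=shifts, log=log)
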