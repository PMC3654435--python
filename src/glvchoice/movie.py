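"""Fluorescence movie containers and TIFF + JSON sidecar I/O.

A recording is a short multi-frame fluorescence movie of the antennal lobe
(AL) taken while an odor pulse is delivered.  The acquisition geometry used
throughout the package defaults to the standard wide-field protocol: 4 Hz
frame rate, 40 frames covering 2 s pre-stimulus, 2 s odor stimulation and
6 s post-stimulus, 344 x 260 px after binning with 2.5 um pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "AcquisitionGeometry",
    "MovieStack",
    "DffMovie",
    "read_movie",
    "write_movie",
    "write_dff",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Acquisition parameters of an AL imaging recording.

    Defaults correspond to 4-fold binned CCD frames (344 x 260 px,
    2.5 um/px) recorded at 4 Hz over a 2/2/6 s pre/stimulus/post protocol,
    i.e. 40 frames.
    """

    frame_rate_hz: float = 4.0
    pixel_size_um: float = 2.5
    pre_s: float = 2.0
    stimulus_s: float = 2.0
    post_s: float = 6.0
    height: int = 260
    width: int = 344

    @property
    def duration_s(self) -> float:
        return self.pre_s + self.stimulus_s + self.post_s

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def stimulus_onset_frame(self) -> int:
        """First frame of odor stimulation (0-based)."""
        return int(round(self.pre_s * self.frame_rate_hz))

    @property
    def stimulus_offset_frame(self) -> int:
        """First frame after odor stimulation ends."""
        return int(round((self.pre_s + self.stimulus_s) * self.frame_rate_hz))

    def validate(self) -> None:
        if self.frame_rate_hz <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame rate and pixel size must be positive")
        if min(self.pre_s, self.stimulus_s, self.post_s) < 0:
            raise ValueError("segment durations must be non-negative")
        if self.height < 1 or self.width < 1:
            raise ValueError("frame dimensions must be positive")


@dataclass
class MovieStack:
    """Raw fluorescence frames F with acquisition metadata.

    ``frames`` is a (T, H, W) float array of fluorescence counts.  The
    frame count must be consistent with the geometry
    (T = round(duration * rate)).
    """

    frames: np.ndarray
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    animal_id: str = "animal0"
    odor_label: str = "stimulus"
    dose_ng: float = 250.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        t, h, w = self.frames.shape
        if t != self.geometry.n_frames:
            raise ValueError(
                f"frame count {t} inconsistent with geometry "
                f"({self.geometry.n_frames} expected)"
            )
        if (h, w) != (self.geometry.height, self.geometry.width):
            raise ValueError(
                f"frame shape {(h, w)} does not match geometry "
                f"{(self.geometry.height, self.geometry.width)}"
            )
        if np.any(self.frames < 0):
            raise ValueError("fluorescence counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def times_s(self) -> np.ndarray:
        """Frame start times in seconds from recording start."""
        return np.arange(self.n_frames) / self.geometry.frame_rate_hz

    def copy_with(self, frames: np.ndarray) -> "MovieStack":
        return MovieStack(
            frames=frames,
            geometry=self.geometry,
            animal_id=self.animal_id,
            odor_label=self.odor_label,
            dose_ng=self.dose_ng,
        )


@dataclass
class DffMovie:
    """Relative fluorescence change dF/F per pixel over time.

    ``f0`` is the per-pixel pre-stimulus baseline; ``dff`` = (F - f0)/f0.
    Pixels where the baseline is not positive are masked (NaN in ``dff``,
    False in ``valid``).
    """

    dff: np.ndarray
    f0: np.ndarray
    baseline_frames: np.ndarray
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    animal_id: str = "animal0"
    odor_label: str = "stimulus"
    dose_ng: float = 250.0

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        self.baseline_frames = np.asarray(self.baseline_frames, dtype=int)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.dff).all(axis=0)

    @property
    def n_frames(self) -> int:
        return self.dff.shape[0]


def _meta_path(tiff_path: Path) -> Path:
    p = Path(tiff_path)
    return p.with_name(p.stem + ".meta.json")


def write_movie(movie: MovieStack, tiff_path: str | Path) -> Path:
    """Write a movie as 16-bit multi-page TIFF plus a JSON metadata sidecar.

    Intensities are clipped at 0 and rounded to the nearest count.
    """
    tiff_path = Path(tiff_path)
    data = np.clip(np.round(movie.frames), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(tiff_path, data.astype(np.uint16))
    meta = {
        "geometry": asdict(movie.geometry),
        "animal_id": movie.animal_id,
        "odor_label": movie.odor_label,
        "dose_ng": movie.dose_ng,
    }
    _meta_path(tiff_path).write_text(json.dumps(meta, indent=2))
    return tiff_path


def read_movie(tiff_path: str | Path, meta_path: str | Path | None = None) -> MovieStack:
    """Read a multi-page TIFF movie with its JSON sidecar metadata."""
    tiff_path = Path(tiff_path)
    if meta_path is None:
        meta_path = _meta_path(tiff_path)
    try:
        frames = tifffile.imread(tiff_path).astype(float)
    except Exception as exc:  # corrupted / unreadable stack
        raise IOError(f"cannot read TIFF movie {tiff_path}: {exc}") from exc
    meta = json.loads(Path(meta_path).read_text())
    return MovieStack(
        frames=frames,
        geometry=AcquisitionGeometry(**meta["geometry"]),
        animal_id=meta.get("animal_id", "animal0"),
        odor_label=meta.get("odor_label", "stimulus"),
        dose_ng=meta.get("dose_ng", 250.0),
    )


def write_dff(dff: DffMovie, tiff_path: str | Path) -> Path:
    """Write a dF/F movie as 32-bit float TIFF; baseline map alongside."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, dff.dff.astype(np.float32))
    f0_path = tiff_path.with_name(tiff_path.stem + ".f0.tif")
    tifffile.imwrite(f0_path, dff.f0.astype(np.float32))
    meta = {
        "geometry": asdict(dff.geometry),
        "animal_id": dff.animal_id,
        "odor_label": dff.odor_label,
        "dose_ng": dff.dose_ng,
        "baseline_frames": dff.baseline_frames.tolist(),
    }
    _meta_path(tiff_path).write_text(json.dumps(meta, indent=2))
    return tiff_path
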