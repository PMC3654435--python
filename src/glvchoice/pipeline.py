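"""End-to-end pipeline runs: synthetic generation through statistics.

A run is driven by a single JSON-serializable :class:`PipelineConfig`.
Every stage logs its parameters into a run manifest written next to the
outputs, and the whole run is deterministic given the seed.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthgen
from .behavior import oviposition_test
from .imaging import preprocess
from .movie import AcquisitionGeometry
from .npstats import mann_whitney_u
from .quant import ratio_table
from .response import (Roi, activation_map, extract_trace, normalize_amplitudes,
                       pattern_correlation, response_amplitude,
                       ResponseAmplitude, smooth_trace)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Resolved configuration of one demo pipeline run."""

    seed: int = 0
    n_animals: int = 2
    odors: tuple[str, str] = ("(Z)-3-hexenyl acetate", "(E)-2-hexenyl acetate")
    noise_sd: float = 10.0
    inclusion_threshold_pct: float = 30.0
    alpha: float = 0.05
    median_kernel_px: int = 5
    emission_n_per_cell: int = 5
    oviposition_n_plants: int = 15
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        geo = AcquisitionGeometry(**raw.pop("geometry", {}))
        if "odors" in raw:
            raw["odors"] = tuple(raw["odors"])
        return cls(geometry=geo, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["odors"] = list(self.odors)
        return d


def _imaging_stage(config: PipelineConfig, out: Path, manifest: dict) -> None:
    geometry = config.geometry
    rng = np.random.default_rng(config.seed)
    amp_rows: list[dict] = []
    corr_rows: list[dict] = []
    for animal_idx in range(config.n_animals):
        animal = f"animal{animal_idx}"
        truth = synthgen.default_al_truth(seed=int(rng.integers(2 ** 31)),
                                          geometry=geometry)
        truth.noise_sd = config.noise_sd
        rois = [Roi(f"ROI{i + 1}", g.center_row_px, g.center_col_px)
                for i, g in enumerate(truth.glomeruli)]
        maps = {}
        amplitudes: list[ResponseAmplitude] = []
        for odor in config.odors:
            movie, record = synthgen.generate_al_movie(
                truth, geometry, odor=odor, animal_id=animal)
            result = preprocess(movie, kernel_px=config.median_kernel_px)
            onset = geometry.stimulus_onset_frame
            for roi in rois:
                trace = smooth_trace(extract_trace(result.dff, roi))
                amplitudes.append(ResponseAmplitude(
                    animal_id=animal, roi_label=roi.label, odor_label=odor,
                    dose_ng=movie.dose_ng,
                    raw_dff=response_amplitude(trace, onset)))
            maps[odor] = activation_map(result.dff)
        amplitudes = normalize_amplitudes(
            amplitudes, threshold_pct=config.inclusion_threshold_pct)
        amp_rows.extend(a.__dict__ for a in amplitudes)
        r = pattern_correlation(maps[config.odors[0]], maps[config.odors[1]])
        corr_rows.append({"animal_id": animal,
                          "pair": f"{config.odors[0]} vs {config.odors[1]}",
                          "r": r})
    pd.DataFrame(amp_rows).to_csv(out / "response_amplitudes.csv", index=False)
    pd.DataFrame(corr_rows).to_csv(out / "pattern_correlations.csv", index=False)
    manifest["stages"].append({"stage": "imaging",
                               "n_animals": config.n_animals,
                               "odors": list(config.odors)})


def _emissions_stage(config: PipelineConfig, out: Path, manifest: dict) -> None:
    truth = synthgen.GroundTruthEmissions(seed=config.seed + 1)
    table = synthgen.generate_emission_dataset(
        truth, treatments=["w+w", "w+OS"], time_blocks=["day"],
        n_per_cell=config.emission_n_per_cell)
    table.to_csv(out / "emissions.csv", index=False)
    ratios, excluded = ratio_table(table)
    ratios.to_csv(out / "isomer_ratios.csv", index=False)
    tests = []
    for fam, sub in ratios.groupby("family"):
        ww = sub.loc[sub["treatment"] == "w+w", "ratio"]
        wos = sub.loc[sub["treatment"] == "w+OS", "ratio"]
        res = mann_whitney_u(ww.to_numpy(), wos.to_numpy())
        tests.append({"family": fam, "method": res.method,
                      "statistic": res.statistic, "p": res.p_two_sided,
                      "mode": res.mode})
    pd.DataFrame(tests).to_csv(out / "ratio_tests.csv", index=False)
    manifest["stages"].append({"stage": "emissions",
                               "n_per_cell": config.emission_n_per_cell,
                               "ratio_samples_excluded": excluded})


def _behavior_stage(config: PipelineConfig, out: Path, manifest: dict) -> None:
    truth = synthgen.GroundTruthOviposition(
        n_plants=config.oviposition_n_plants, seed=config.seed + 2)
    pairs = synthgen.generate_oviposition_dataset(truth)
    pairs.to_csv(out / "oviposition_pairs.csv", index=False)
    report = oviposition_test(pairs)
    summary = {
        "method": report.test.method,
        "statistic": report.test.statistic,
        "p_two_sided": report.test.p_two_sided,
        "mode": report.test.mode,
        "n_pairs_used": report.n_pairs_used,
        "n_zero_pairs_excluded": report.n_zero_pairs_excluded,
        "mean_sem_a": report.mean_sem_a,
        "mean_sem_b": report.mean_sem_b,
        "mean_difference": report.mean_difference,
    }
    (out / "oviposition_test.json").write_text(json.dumps(summary, indent=2))
    manifest["stages"].append({"stage": "behavior",
                               "n_plants": config.oviposition_n_plants})


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run synthetic generation -> preprocessing -> statistics end to end.

    Writes numeric tables, test results, the resolved config and a run
    manifest into ``out_dir``.  Raises :class:`StageError` (naming the
    failing stage) on any stage failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    for name, stage in (("imaging", _imaging_stage),
                        ("emissions", _emissions_stage),
                        ("behavior", _behavior_stage)):
        try:
            stage(config, out, manifest)
        except Exception as exc:
            manifest["stages"].append({"stage": name, "error": str(exc)})
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(name, f"{exc}\n{traceback.format_exc()}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
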