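"""GC-MS SIM quantification and emission/ratio statistics for GLVs.

Quantification follows the standard internal-standard workflow: integrate
the quantifier-ion peak, normalize its area to the tetralin internal
standard (IS), and convert to mass through a per-compound linear calibration
curve.  Emission rates are expressed per gram leaf fresh mass (FM) or per
cm^2 leaf area over the 2 h trapping window; the rough field conversion is
50 cm^2 of leaf ~ 1 g FM.

The (Z)-3/(E)-2 isomer ratio is computed per sample by dividing the (Z)-3
amount by its (E)-2 counterpart; ratios below 1 are displayed as their
negative reciprocal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .transforms import display_transform

__all__ = [
    "CompoundSpec",
    "COMPOUND_REGISTRY",
    "TETRALIN",
    "Chromatogram",
    "CalibrationCurve",
    "EmissionRecord",
    "RatioRecord",
    "integrate_sim_peak",
    "fit_calibration",
    "quantify_amount",
    "emission_rate",
    "convert_mass_to_moles",
    "subtract_paired_control",
    "isomer_ratio",
    "ratio_table",
    "ratio_of_means",
    "mixture_component_dose",
    "recipe_solvent_total",
    "check_recipe_balance",
    "CM2_PER_G_FM",
    "IS_SPIKE_LAB_NG",
    "IS_SPIKE_FIELD_NG",
    "CALIBRATION_LEVELS_NG",
]

#: tetralin spike per trap: SuperQ (laboratory) and charcoal (field) traps.
IS_SPIKE_LAB_NG = 320.0
IS_SPIKE_FIELD_NG = 240.0

#: approximate leaf-area to fresh-mass conversion.
CM2_PER_G_FM = 50.0

#: calibration standard levels (ng), three replicates each.
CALIBRATION_LEVELS_NG = (33.0, 10.0, 5.0, 1.0, 0.5, 0.1)


@dataclass(frozen=True)
class CompoundSpec:
    """Registry entry: identity, SIM quantifier ion and polar-column RT."""

    name: str
    family: str
    isomer: str  # "(Z)-3" | "(E)-2" | "" for the IS
    retention_time_min: float
    quantifier_mz: float
    molar_mass_g_per_mol: float


# Quantifier ions: hexenals m/z 83; hexenols and hexenyl acetates m/z 82.
# The butyrates share the m/z 82 fragment (documented stand-in).  Retention
# times are the polar-column values of the emission tables (minutes).
_SPECS = [
    CompoundSpec("(Z)-3-hexenal", "aldehyde", "(Z)-3", 8.54, 83, 98.14),
    CompoundSpec("(E)-2-hexenal", "aldehyde", "(E)-2", 10.49, 83, 98.14),
    CompoundSpec("(Z)-3-hexenol", "alcohol", "(Z)-3", 14.98, 82, 100.16),
    CompoundSpec("(E)-2-hexenol", "alcohol", "(E)-2", 15.57, 82, 100.16),
    CompoundSpec("(Z)-3-hexenyl acetate", "acetate", "(Z)-3", 13.28, 82, 142.20),
    CompoundSpec("(E)-2-hexenyl acetate", "acetate", "(E)-2", 13.75, 82, 142.20),
    CompoundSpec("(Z)-3-hexenyl butyrate", "butyrate", "(Z)-3", 17.07, 82, 170.25),
    CompoundSpec("(E)-2-hexenyl butyrate", "butyrate", "(E)-2", 17.44, 82, 170.25),
]

COMPOUND_REGISTRY: dict[str, CompoundSpec] = {s.name: s for s in _SPECS}

TETRALIN = CompoundSpec("tetralin", "internal_standard", "", 20.0, 132, 132.20)


@dataclass
class Chromatogram:
    """SIM traces: per monitored ion, intensity sampled on a shared time axis."""

    times_s: np.ndarray
    traces: dict[float, np.ndarray]

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        for mz, trace in self.traces.items():
            trace = np.asarray(trace, dtype=float)
            if trace.shape != self.times_s.shape:
                raise ValueError(f"trace for m/z {mz} has wrong length")
            if np.any(trace < 0):
                raise ValueError(f"negative intensities on m/z {mz}")
            self.traces[mz] = trace

    def to_frame(self) -> pd.DataFrame:
        """Long-format (time_s, mz, intensity) table."""
        parts = [pd.DataFrame({"time_s": self.times_s, "mz": mz, "intensity": tr})
                 for mz, tr in sorted(self.traces.items())]
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Chromatogram":
        times = np.sort(df["time_s"].unique())
        traces = {}
        for mz, sub in df.groupby("mz"):
            sub = sub.sort_values("time_s")
            traces[float(mz)] = sub["intensity"].to_numpy()
        return cls(times_s=times, traces=traces)


def integrate_sim_peak(chrom: Chromatogram, compound: CompoundSpec | str,
                       rt_window_s: float = 12.0,
                       registry: dict[str, CompoundSpec] | None = None) -> float:
    """Trapezoidal peak area above a linear endpoint baseline.

    The integration window is ``retention_time +- rt_window_s`` on the
    compound's quantifier-ion trace.  A straight baseline is drawn between
    the window endpoints and subtracted; the area is clipped at 0.
    """
    if isinstance(compound, str):
        registry = registry or COMPOUND_REGISTRY
        if compound == TETRALIN.name:
            compound = TETRALIN
        elif compound in registry:
            compound = registry[compound]
        else:
            raise KeyError(f"unknown compound {compound!r}")
    mz = compound.quantifier_mz
    if mz not in chrom.traces:
        raise KeyError(f"no trace for quantifier ion m/z {mz}")
    rt_s = compound.retention_time_min * 60.0
    t = chrom.times_s
    sel = (t >= rt_s - rt_window_s) & (t <= rt_s + rt_window_s)
    if sel.sum() < 2:
        raise ValueError("integration window contains fewer than two samples")
    tw = t[sel]
    y = chrom.traces[mz][sel]
    baseline = np.interp(tw, [tw[0], tw[-1]], [y[0], y[-1]])
    area = np.trapezoid(y - baseline, tw)
    return float(max(area, 0.0))


@dataclass
class CalibrationCurve:
    """Linear IS-normalized response curve: normalized area = slope*ng + intercept."""

    compound: str
    slope: float
    intercept: float
    r_squared: float
    levels_ng: tuple[float, ...] = CALIBRATION_LEVELS_NG
    is_spike_ng: float = IS_SPIKE_LAB_NG

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")


def fit_calibration(standards: pd.DataFrame | list[tuple[float, float]],
                    compound: str = "", is_spike_ng: float = IS_SPIKE_LAB_NG,
                    force_origin: bool = False) -> CalibrationCurve:
    """Ordinary least squares of IS-normalized area on standard mass (ng).

    ``standards`` holds (ng, normalized_area) replicate pairs.  The
    intercept is retained by default; ``force_origin=True`` fits through
    the origin instead.
    """
    if isinstance(standards, pd.DataFrame):
        ng = standards["ng"].to_numpy(dtype=float)
        area = standards["normalized_area"].to_numpy(dtype=float)
    else:
        arr = np.asarray(standards, dtype=float)
        ng, area = arr[:, 0], arr[:, 1]
    if len(np.unique(ng)) < 2:
        raise ValueError("need at least two distinct calibration levels")
    if force_origin:
        slope = float(np.sum(ng * area) / np.sum(ng * ng))
        intercept = 0.0
        resid = area - slope * ng
        ss_tot = np.sum(area ** 2)
    else:
        fit = sps.linregress(ng, area)
        slope, intercept = float(fit.slope), float(fit.intercept)
        resid = area - (slope * ng + intercept)
        ss_tot = np.sum((area - area.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(compound=compound, slope=slope, intercept=intercept,
                            r_squared=r2, levels_ng=tuple(sorted(set(ng), reverse=True)),
                            is_spike_ng=is_spike_ng)


@dataclass
class QuantResult:
    ng: float
    bld: bool
    normalized_area: float


def quantify_amount(analyte_area: float, is_area: float, is_spike_ng: float,
                    curve: CalibrationCurve) -> QuantResult:
    """IS-normalize an analyte peak area and invert the calibration curve.

    If the sample's IS spike differs from the one used for the calibration
    standards (laboratory 320 ng vs field 240 ng), the normalized area is
    rescaled to the curve's spike reference.  Amounts below the lowest
    calibration level are flagged below-detection (``bld``); negative
    back-calculated masses are clipped to 0.
    """
    if is_area <= 0:
        raise ValueError("internal-standard area must be > 0")
    norm = analyte_area / is_area * (is_spike_ng / curve.is_spike_ng)
    ng = (norm - curve.intercept) / curve.slope
    ng = max(ng, 0.0)
    bld = ng < min(curve.levels_ng)
    return QuantResult(ng=float(ng), bld=bool(bld), normalized_area=float(norm))


@dataclass
class EmissionRecord:
    """One quantified GLV emission sample."""

    sample_id: str
    treatment: str  # control | w+w | w+OS
    time_block: str  # day | sunset | night
    compound: str
    isomer: str
    family: str
    amount: float
    basis: str = "per g FM"  # or "per cm2"
    duration_h: float = 2.0
    bld: bool = False

    def __post_init__(self) -> None:
        if self.amount < 0 and not self.bld:
            raise ValueError("amount must be >= 0 unless flagged bld")


@dataclass
class RatioRecord:
    """Per-sample (Z)-3/(E)-2 pair with ratio and display value."""

    sample_id: str
    family: str
    z_amount: float
    e_amount: float
    ratio: float
    display_value: float


def emission_rate(ng: float, basis_value: float, basis_kind: str = "g_fm",
                  duration_h: float = 2.0) -> tuple[float, str]:
    """Emission rate per basis unit over the trapping window.

    ``basis_kind`` is ``"g_fm"`` (leaf fresh mass, g) or ``"cm2"`` (leaf
    area).  Returns (rate, unit string).
    """
    if basis_value <= 0:
        raise ValueError("basis value must be > 0")
    if basis_kind not in ("g_fm", "cm2"):
        raise ValueError(f"unknown basis kind {basis_kind!r}")
    rate = ng / basis_value
    unit = ("ng g^-1 FM " if basis_kind == "g_fm" else "ng cm^-2 ") + \
        f"{duration_h:g}h^-1"
    return rate, unit


def convert_mass_to_moles(ng: float, molar_mass_g_per_mol: float) -> float:
    """ng -> nmol (numerically ng / molar mass, since ng/(g/mol) = nmol)."""
    if molar_mass_g_per_mol <= 0:
        raise ValueError("molar mass must be > 0")
    return ng / molar_mass_g_per_mol


def subtract_paired_control(treated: EmissionRecord,
                            control: EmissionRecord) -> EmissionRecord:
    """Net emission of a treated leaf minus the same plant's control leaf.

    Both records must describe the same compound on the same basis.  The
    net amount may be negative (flagged via ``bld=False`` but negative
    amount is permitted on net records).
    """
    if (treated.compound != control.compound
            or treated.basis != control.basis
            or treated.sample_id.split("/")[0] != control.sample_id.split("/")[0]):
        raise ValueError("paired subtraction requires matching plant, compound and basis")
    net = EmissionRecord.__new__(EmissionRecord)
    net.sample_id = treated.sample_id
    net.treatment = f"{treated.treatment}-net"
    net.time_block = treated.time_block
    net.compound = treated.compound
    net.isomer = treated.isomer
    net.family = treated.family
    net.amount = treated.amount - control.amount
    net.basis = treated.basis
    net.duration_h = treated.duration_h
    net.bld = treated.bld
    return net


def isomer_ratio(z_amount: float, e_amount: float, sample_id: str = "",
                 family: str = "", e_bld: bool = False) -> RatioRecord | None:
    """Per-sample (Z)-3/(E)-2 ratio with negative-reciprocal display value.

    Returns None when the (E)-2 denominator is non-positive or below the
    detection limit — such samples are excluded from ratio statistics
    rather than imputed.
    """
    if e_bld or e_amount <= 0:
        return None
    ratio = z_amount / e_amount
    if ratio <= 0:
        return None
    return RatioRecord(sample_id=sample_id, family=family,
                       z_amount=z_amount, e_amount=e_amount,
                       ratio=ratio, display_value=display_transform(ratio))


def ratio_table(emissions: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-sample isomer ratios from a long-format emission table.

    Expects columns sample_id, family, isomer, amount (and optionally bld,
    treatment, time_block).  Returns (ratio DataFrame, excluded count);
    samples whose (E)-2 amount is bld or non-positive are excluded.
    """
    excluded = 0
    rows = []
    keys = ["sample_id", "family"]
    for (sample, fam), sub in emissions.groupby(keys):
        z = sub[sub["isomer"] == "(Z)-3"]
        e = sub[sub["isomer"] == "(E)-2"]
        if z.empty or e.empty:
            continue
        z_amt = float(z["amount"].iloc[0])
        e_amt = float(e["amount"].iloc[0])
        e_bld = bool(e["bld"].iloc[0]) if "bld" in e else False
        rec = isomer_ratio(z_amt, e_amt, sample_id=sample, family=fam, e_bld=e_bld)
        if rec is None:
            excluded += 1
            continue
        row = {"sample_id": sample, "family": fam, "z_amount": z_amt,
               "e_amount": e_amt, "ratio": rec.ratio,
               "display_value": rec.display_value}
        for extra in ("treatment", "time_block"):
            if extra in sub:
                row[extra] = sub[extra].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows), excluded


def ratio_of_means(z_amounts, e_amounts) -> float:
    """Ratio of group means — distinct from the per-sample ratio summary.

    Dividing printed group means generally disagrees with summarizing
    per-sample ratios; this helper exists for comparisons against tabulated
    means and is never the default ratio statistic.
    """
    z_mean = float(np.mean(z_amounts))
    e_mean = float(np.mean(e_amounts))
    if e_mean <= 0:
        raise ValueError("mean (E)-2 amount must be > 0")
    return z_mean / e_mean


def mixture_component_dose(total_ng: float, z_percent: float) -> tuple[float, float]:
    """Split a total odor dose into (Z)-3 and (E)-2 masses by blend percent.

    E.g. a 250 ng total at 20/80 (Z/E) gives 50 ng (Z)-isomer.
    """
    if not 0 <= z_percent <= 100:
        raise ValueError("z_percent must be in [0, 100]")
    if total_ng < 0:
        raise ValueError("total dose must be >= 0")
    z = total_ng * z_percent / 100.0
    return z, total_ng - z


def recipe_solvent_total(derived_ul: float, added_ul: float) -> float:
    """Total triacetin per 10 mL mix: carried in with (Z)-3-hexenal + added."""
    if derived_ul < 0 or added_ul < 0:
        raise ValueError("recipe entries must be >= 0")
    return derived_ul + added_ul


def check_recipe_balance(totals_ul, tol_ul: float = 0.05) -> bool:
    """Solvent-balance check: paired mixes must carry equal triacetin totals."""
    totals = np.asarray(totals_ul, dtype=float)
    return bool(np.max(totals) - np.min(totals) <= tol_ul)
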