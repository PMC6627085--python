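"""Voltage-sensitive-dye plate-reader analytics.

Raw well fluorescence is normalized against dye-only background wells,
``dff0 = (F - F0) / F0``, and converted to a membrane-potential change

    dE = (R * T / (z' * F_faraday)) * ln(1 / (dff0 + 1))    [reported in mV]

where z' is the empirically calibrated dye-sensitivity exponent (negative
for this dye, so depolarization — dff0 > 0 — maps to positive dE).  The
module also provides the KCl-titration calibration of z', per-well COV QC,
and the pooled/paired t comparisons used for group statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DomainError,
    EmptyGroupError,
    InsufficientPointsError,
    LogDomainError,
    MissingBackgroundError,
    NonPositiveBackgroundError,
    ZeroMeanError,
)

__all__ = [
    "EphysConstants",
    "WellRecord",
    "PlateRead",
    "NormalizedWell",
    "TitrationSeries",
    "CalibrationFit",
    "GroupComparison",
    "DensityFit",
    "AnalysisPlan",
    "PlateReport",
    "background_f0",
    "normalize_well",
    "delta_e",
    "inverse_delta_e",
    "well_cov",
    "calibrate_z_prime",
    "compare_groups",
    "density_linearity",
    "analyze_plate",
]

READS_PER_WELL = 25  # 5x5 area scan, row-major

Role = Literal["sample", "dye_only_background"]
Condition = Literal["rest", "stimulated"]


@dataclass(frozen=True)
class EphysConstants:
    """Physical constants for the voltage conversion.

    Defaults give RT/F = 25.43 mV at 22 degC and the assumed z' = -0.64.
    """

    gas_constant: float = 8.314  # J / (mol K)
    faraday: float = 96485.0  # C / mol
    temperature: float = 295.15  # K
    z_prime: float = -0.64

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise DomainError(f"temperature must be positive, got {self.temperature}")
        if self.z_prime == 0:
            raise DomainError("z_prime must be nonzero")

    @property
    def rt_over_f_mV(self) -> float:
        """Thermal voltage R*T/F in millivolts."""
        return self.gas_constant * self.temperature / self.faraday * 1000.0


@dataclass
class WellRecord:
    """One well: 25 raw reads plus plate-map annotations."""

    reads: np.ndarray  # shape (25,), row-major 5x5
    role: str = "sample"
    group: str = ""
    condition: str = "rest"
    density: float | None = None  # cells/well

    def __post_init__(self) -> None:
        self.reads = np.asarray(self.reads, dtype=float)
        if self.role == "sample" and self.reads.shape != (READS_PER_WELL,):
            raise DomainError(
                f"sample well needs exactly {READS_PER_WELL} reads, got {self.reads.shape}"
            )
        if np.any(self.reads < 0):
            raise DomainError("fluorescence reads must be non-negative")


@dataclass
class PlateRead:
    """A plate: well id -> record.  At least one background well expected."""

    plate_id: str
    wells: dict[str, WellRecord]

    def wells_by_role(self, role: str) -> dict[str, WellRecord]:
        return {w: r for w, r in self.wells.items() if r.role == role}


@dataclass(frozen=True)
class NormalizedWell:
    """Per-well normalized fluorescence, voltage change, and QC."""

    well_id: str
    group: str
    condition: str
    density: float | None
    dff0: np.ndarray
    mean_dff0: float
    delta_e_mV: np.ndarray
    mean_delta_e_mV: float
    cov_percent: float
    cov_flag: str  # "<=5%", "<=10%", ">10%"


@dataclass
class TitrationSeries:
    """KCl titration: per concentration, dff0 observations across cells."""

    points: list[tuple[float, np.ndarray]]  # (Kx mM, dff0 values)
    reference_K: float = 5.4  # mM

    def __post_init__(self) -> None:
        if self.reference_K <= 0:
            raise DomainError("reference_K must be positive")
        self.points = [(float(k), np.asarray(v, dtype=float)) for k, v in self.points]
        for k, v in self.points:
            if np.any(v <= -1):
                raise LogDomainError(f"dff0 <= -1 at Kx={k} mM")


@dataclass(frozen=True)
class CalibrationFit:
    """z' calibration regression output."""

    z_prime: float
    intercept: float
    r_squared: float
    fit_space: str
    n_points: int
    residuals: np.ndarray


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    df: int
    p_value: float
    paired: bool
    alternative: str


@dataclass(frozen=True)
class DensityFit:
    pearson_r: float
    slope: float
    intercept: float
    n: int


@dataclass(frozen=True)
class AnalysisPlan:
    """What to compute on a plate.

    ``pair_conditions`` runs a paired t between the two conditions (wells
    matched by sorted well id within each group); ``group_pairs`` runs
    pooled-variance unpaired comparisons between group labels at the
    ``restrict_condition`` condition.  Wells with COV above
    ``exclude_cov_above`` (percent) are dropped from statistics when set.
    """

    pair_conditions: tuple[str, str] | None = ("stimulated", "rest")
    group_pairs: tuple[tuple[str, str], ...] = ()
    restrict_condition: str = "rest"
    alternative: str = "greater"
    exclude_cov_above: float | None = None
    fit_density: bool = True
    cov_on: str = "raw"  # "raw" or "dff0"


@dataclass
class PlateReport:
    plate_id: str
    f0: float
    wells: list[NormalizedWell]
    condition_comparisons: dict[str, GroupComparison]
    group_comparisons: list[GroupComparison]
    density_fit: DensityFit | None

    def to_dict(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "f0": self.f0,
            "wells": [
                {
                    "well_id": w.well_id,
                    "group": w.group,
                    "condition": w.condition,
                    "density": w.density,
                    "mean_dff0": w.mean_dff0,
                    "mean_delta_e_mV": w.mean_delta_e_mV,
                    "cov_percent": w.cov_percent,
                    "cov_flag": w.cov_flag,
                }
                for w in self.wells
            ],
            "condition_comparisons": {
                g: _comparison_dict(c) for g, c in self.condition_comparisons.items()
            },
            "group_comparisons": [_comparison_dict(c) for c in self.group_comparisons],
            "density_fit": (
                None
                if self.density_fit is None
                else {
                    "pearson_r": self.density_fit.pearson_r,
                    "slope": self.density_fit.slope,
                    "intercept": self.density_fit.intercept,
                    "n": self.density_fit.n,
                }
            ),
        }


def _comparison_dict(c: GroupComparison) -> dict:
    return {
        "label_a": c.label_a,
        "label_b": c.label_b,
        "n_a": c.n_a,
        "n_b": c.n_b,
        "mean_a": c.mean_a,
        "mean_b": c.mean_b,
        "t_statistic": c.t_statistic,
        "df": c.df,
        "p_value": c.p_value,
        "paired": c.paired,
        "alternative": c.alternative,
    }


def background_f0(plate: PlateRead) -> float:
    """Pooled mean of every read across all dye-only background wells."""
    bg = plate.wells_by_role("dye_only_background")
    if not bg:
        raise MissingBackgroundError(f"plate {plate.plate_id!r} has no background wells")
    all_reads = np.concatenate([r.reads for r in bg.values()])
    return float(all_reads.mean())


def normalize_well(reads: np.ndarray, f0: float) -> np.ndarray:
    """Element-wise (F - F0) / F0."""
    if f0 <= 0:
        raise NonPositiveBackgroundError(f"F0 must be positive, got {f0}")
    return np.asarray(reads, dtype=float) / f0 - 1.0


def delta_e(dff0, constants: EphysConstants = EphysConstants()):
    """Convert normalized fluorescence change to membrane-potential change (mV).

    ``dE = (RT / (z' F)) * ln(1 / (dff0 + 1))``; accepts scalars or arrays.
    """
    arr = np.asarray(dff0, dtype=float)
    if np.any(arr <= -1):
        raise LogDomainError("dff0 <= -1: log argument non-positive")
    out = constants.rt_over_f_mV / constants.z_prime * np.log1p(arr) * -1.0
    return float(out) if np.isscalar(dff0) else out


def inverse_delta_e(delta_e_mV, constants: EphysConstants = EphysConstants()):
    """Generative inverse of :func:`delta_e`: dff0 = exp(-z' F dE / (R T)) - 1."""
    arr = np.asarray(delta_e_mV, dtype=float)
    out = np.expm1(-constants.z_prime / constants.rt_over_f_mV * arr)
    return float(out) if np.isscalar(delta_e_mV) else out


def well_cov(values: np.ndarray) -> float:
    """Coefficient of variation, ``100 * sample SD / mean``, in percent."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DomainError("COV needs at least 2 reads")
    mean = arr.mean()
    if mean == 0:
        raise ZeroMeanError("COV undefined: mean of reads is zero")
    return float(100.0 * arr.std(ddof=1) / abs(mean))


def cov_flag(cov_percent: float) -> str:
    if cov_percent <= 5.0:
        return "<=5%"
    if cov_percent <= 10.0:
        return "<=10%"
    return ">10%"


def calibrate_z_prime(
    series: TitrationSeries, fit_space: str = "loglog"
) -> CalibrationFit:
    """Estimate z' from a KCl titration.

    ``loglog`` (default, exact under the Nernst-type model): OLS of
    ``ln(1/(dff0+1))`` on ``ln(Kx/Kr)``, slope = z'.  ``linear``: OLS of
    ``1/(dff0+1)`` on ``Kx/Kr``, slope = z'.
    """
    if fit_space not in ("loglog", "linear"):
        raise DomainError(f"unknown fit space {fit_space!r}")
    kx = np.concatenate([np.full(v.size, k) for k, v in series.points])
    dff0 = np.concatenate([v for _, v in series.points])
    if np.unique(kx).size < 3:
        raise InsufficientPointsError(
            f"need >=3 distinct Kx values, got {np.unique(kx).size}"
        )
    ratio = kx / series.reference_K
    inv = 1.0 / (dff0 + 1.0)
    if fit_space == "loglog":
        if np.any(ratio <= 0) or np.any(inv <= 0):
            raise DomainError("non-positive ratio in loglog space")
        x, y = np.log(ratio), np.log(inv)
    else:
        x, y = ratio, inv
    res = stats.linregress(x, y)
    residuals = y - (res.slope * x + res.intercept)
    return CalibrationFit(
        z_prime=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        fit_space=fit_space,
        n_points=int(x.size),
        residuals=residuals,
    )


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool,
    alternative: str = "greater",
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Student t comparison of per-well dE means.

    Unpaired: pooled-variance two-sample t with df = n1 + n2 - 2.
    Paired: one-sample t on differences, df = n - 1.  One-sided p by default
    (``alternative`` in {"greater", "less", "two-sided"}, direction a vs b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if alternative not in ("greater", "less", "two-sided"):
        raise DomainError(f"unknown alternative {alternative!r}")
    if a.size < 2 or b.size < 2:
        raise DomainError("need n >= 2 per group")
    if paired:
        if a.size != b.size:
            raise DomainError(f"paired groups must match in size: {a.size} vs {b.size}")
        diff = a - b
        df = a.size - 1
        sd = diff.std(ddof=1)
        if sd == 0:
            if diff.mean() == 0:
                t = 0.0
            else:
                warnings.warn(
                    "paired differences have zero variance; t is infinite", stacklevel=2
                )
                t = math.copysign(math.inf, diff.mean())
        else:
            t = float(diff.mean() / (sd / math.sqrt(a.size)))
    else:
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        se = math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
        if se == 0:
            if a.mean() == b.mean():
                t = 0.0
            else:
                warnings.warn("zero pooled variance; t is infinite", stacklevel=2)
                t = math.copysign(math.inf, a.mean() - b.mean())
        else:
            t = float((a.mean() - b.mean()) / se)
    if alternative == "greater":
        p = float(stats.t.sf(t, df))
    elif alternative == "less":
        p = float(stats.t.cdf(t, df))
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t_statistic=t,
        df=int(df),
        p_value=p,
        paired=paired,
        alternative=alternative,
    )


def density_linearity(points: Sequence[tuple[float, float]]) -> DensityFit:
    """Least-squares line and Pearson r of mean dE against cell density."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("points must be (density, mean_dE) pairs")
    densities = arr[:, 0]
    if np.unique(densities).size < 3:
        raise InsufficientPointsError(
            f"need >=3 distinct densities, got {np.unique(densities).size}"
        )
    res = stats.linregress(densities, arr[:, 1])
    return DensityFit(
        pearson_r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=int(arr.shape[0]),
    )


def analyze_plate(
    plate: PlateRead,
    constants: EphysConstants = EphysConstants(),
    plan: AnalysisPlan = AnalysisPlan(),
) -> PlateReport:
    """Per-well normalization + QC, then the planned group statistics."""
    f0 = background_f0(plate)
    samples = plate.wells_by_role("sample")
    if not samples:
        raise EmptyGroupError(f"plate {plate.plate_id!r} has no sample wells")

    normalized: list[NormalizedWell] = []
    for well_id in sorted(samples):
        rec = samples[well_id]
        dff0 = normalize_well(rec.reads, f0)
        de = delta_e(dff0, constants)
        cov = well_cov(rec.reads if plan.cov_on == "raw" else dff0)
        normalized.append(
            NormalizedWell(
                well_id=well_id,
                group=rec.group,
                condition=rec.condition,
                density=rec.density,
                dff0=dff0,
                mean_dff0=float(dff0.mean()),
                delta_e_mV=de,
                mean_delta_e_mV=float(de.mean()),
                cov_percent=cov,
                cov_flag=cov_flag(cov),
            )
        )

    usable = [
        w
        for w in normalized
        if plan.exclude_cov_above is None or w.cov_percent <= plan.exclude_cov_above
    ]

    condition_comparisons: dict[str, GroupComparison] = {}
    if plan.pair_conditions is not None:
        cond_a, cond_b = plan.pair_conditions
        for group in sorted({w.group for w in usable}):
            wa = [w for w in usable if w.group == group and w.condition == cond_a]
            wb = [w for w in usable if w.group == group and w.condition == cond_b]
            if len(wa) >= 2 and len(wa) == len(wb):
                condition_comparisons[group] = compare_groups(
                    [w.mean_delta_e_mV for w in sorted(wa, key=lambda w: w.well_id)],
                    [w.mean_delta_e_mV for w in sorted(wb, key=lambda w: w.well_id)],
                    paired=True,
                    alternative=plan.alternative,
                    label_a=f"{group}:{cond_a}",
                    label_b=f"{group}:{cond_b}",
                )

    group_comparisons: list[GroupComparison] = []
    for ga, gb in plan.group_pairs:
        va = [
            w.mean_delta_e_mV
            for w in usable
            if w.group == ga and w.condition == plan.restrict_condition
        ]
        vb = [
            w.mean_delta_e_mV
            for w in usable
            if w.group == gb and w.condition == plan.restrict_condition
        ]
        if not va or not vb:
            raise EmptyGroupError(f"group pair ({ga!r}, {gb!r}) has an empty side")
        group_comparisons.append(
            compare_groups(
                va, vb, paired=False, alternative=plan.alternative, label_a=ga, label_b=gb
            )
        )

    density_fit = None
    if plan.fit_density:
        pts = [
            (w.density, w.mean_delta_e_mV)
            for w in usable
            if w.density is not None and w.condition == plan.restrict_condition
        ]
        if len(pts) >= 3 and len({p[0] for p in pts}) >= 3:
            density_fit = density_linearity(pts)

    return PlateReport(
        plate_id=plate.plate_id,
        f0=f0,
        wells=normalized,
        condition_comparisons=condition_comparisons,
        group_comparisons=group_comparisons,
        density_fit=density_fit,
    )
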