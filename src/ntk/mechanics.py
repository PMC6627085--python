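"""Sphere-indentation elastography of soft gel films.

A rigid sphere resting on a gel under its own (buoyancy-corrected) weight
indents the surface by ``delta``.  The half-space Hertz solution gives

    E_hertz = 3 (1 - nu^2) F / (4 R^(1/2) delta^(3/2)),

and a frictionless thin-film correction rescales it for finite thickness
``h`` through the confinement parameter ``omega = sqrt(R * delta) / h``:

    E_mod = E_hertz * (1 + 2.3 w) / (1 + 1.15 w^(1/3) + a*w + b*w^2).

The coefficient expressions ``a(h/R)`` and ``b(h/R)`` come in two groupings
(see :func:`film_coefficients`); the correction is only trusted inside the
published validity domain ``delta/h <= min(0.6, R/h)`` and
``0.3 <= R/h <= 12.7``.  All quantities are SI (m, N, Pa) in this module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import (
    DomainError,
    FloatingIndenterError,
    NonPositiveDenominatorError,
    NoRootInValidityDomainError,
)

__all__ = [
    "IndenterSpec",
    "MediumSpec",
    "GelMeasurement",
    "ElasticityConfig",
    "ValidityReport",
    "ModulusResult",
    "ReplicateSummary",
    "INDENTER_CATALOG",
    "buoyant_load",
    "hertz_modulus",
    "omega",
    "film_coefficients",
    "modified_hertz_modulus",
    "check_validity",
    "modulus_from_measurement",
    "invert_indentation",
    "summarize_replicates",
]

_INCH = 0.0254

Grouping = Literal["printed", "fraction"]


@dataclass(frozen=True)
class IndenterSpec:
    """Rigid spherical indenter: geometry plus material density."""

    name: str
    diameter: float  # m
    density: float  # kg/m^3

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise DomainError(f"indenter diameter must be positive, got {self.diameter}")
        if self.density <= 0:
            raise DomainError(f"indenter density must be positive, got {self.density}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class MediumSpec:
    """Immersion medium (water by default) and local gravity."""

    density: float = 1000.0  # kg/m^3
    gravity: float = 9.81  # m/s^2

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise DomainError(f"medium density must be positive, got {self.density}")


#: Built-in indenter catalog (bearing-ball stock sizes, densities in kg/m^3).
INDENTER_CATALOG: dict[str, IndenterSpec] = {
    "si3n4_1_32": IndenterSpec("si3n4_1_32", _INCH / 32, 3184.0),
    "zro2_1_32": IndenterSpec("zro2_1_32", _INCH / 32, 5680.0),
    "wc_1_8": IndenterSpec("wc_1_8", _INCH / 8, 15630.0),
}


@dataclass(frozen=True)
class GelMeasurement:
    """One (thickness, indentation depth) observation, SI meters."""

    thickness_h: float
    indentation_delta: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.thickness_h <= 0:
            raise DomainError(f"thickness_h must be positive, got {self.thickness_h}")
        if not 0 <= self.indentation_delta < self.thickness_h:
            raise DomainError(
                "indentation_delta must satisfy 0 <= delta < h, got "
                f"delta={self.indentation_delta}, h={self.thickness_h}"
            )


@dataclass(frozen=True)
class ElasticityConfig:
    """Model options for the thin-film correction.

    ``poisson_ratio`` defaults to 0.5 (incompressible, water-dominated gel).
    ``coefficient_grouping`` selects how the correction coefficients are
    grouped ("printed" literal token order vs "fraction");
    ``denominator_floor`` guards the correction denominator.
    """

    poisson_ratio: float = 0.5
    coefficient_grouping: Grouping = "printed"
    denominator_floor: float = 1e-9

    def __post_init__(self) -> None:
        if not 0 <= self.poisson_ratio < 0.5 + 1e-12:
            raise DomainError(f"poisson_ratio outside [0, 0.5], got {self.poisson_ratio}")
        if self.coefficient_grouping not in ("printed", "fraction"):
            raise DomainError(f"unknown coefficient grouping {self.coefficient_grouping!r}")


@dataclass(frozen=True)
class ValidityReport:
    """Pass/fail per validity constraint plus the computed ratios."""

    r_over_h: float
    delta_over_h: float
    checks: dict[str, bool]
    valid: bool

    @property
    def violations(self) -> list[str]:
        return [name for name, ok in self.checks.items() if not ok]


@dataclass(frozen=True)
class ModulusResult:
    """Full audit record of one modulus evaluation."""

    E_hertz: float
    E_modified: float
    force: float
    omega: float
    alpha: float
    beta: float
    R_over_h: float
    delta_over_h: float
    valid: bool
    violations: tuple[str, ...]
    grouping: str
    poisson_ratio: float
    replicate_id: str = ""

    def to_dict(self) -> dict:
        return {
            "E_hertz_Pa": self.E_hertz,
            "E_modified_Pa": self.E_modified,
            "force_N": self.force,
            "omega": self.omega,
            "alpha": self.alpha,
            "beta": self.beta,
            "R_over_h": self.R_over_h,
            "delta_over_h": self.delta_over_h,
            "valid": self.valid,
            "violations": list(self.violations),
            "grouping": self.grouping,
            "poisson_ratio": self.poisson_ratio,
            "replicate_id": self.replicate_id,
        }


def buoyant_load(indenter: IndenterSpec, medium: MediumSpec = MediumSpec()) -> float:
    """Net downward force on an immersed sphere, ``(4/3) pi R^3 (rho_s - rho_m) g``.

    Raises :class:`FloatingIndenterError` when the sphere is neutrally or
    positively buoyant (no indentation possible).
    """
    drho = indenter.density - medium.density
    if drho <= 0:
        raise FloatingIndenterError(
            f"indenter density {indenter.density} kg/m^3 does not exceed medium "
            f"density {medium.density} kg/m^3; sphere floats"
        )
    return (4.0 / 3.0) * math.pi * indenter.radius**3 * drho * medium.gravity


def hertz_modulus(force: float, radius: float, delta: float, nu: float = 0.5) -> float:
    """Half-space Hertz modulus ``3 (1 - nu^2) F / (4 sqrt(R) delta^(3/2))``."""
    if force <= 0:
        raise DomainError(f"force must be positive, got {force}")
    if radius <= 0:
        raise DomainError(f"radius must be positive, got {radius}")
    if delta <= 0:
        raise DomainError(f"delta must be positive, got {delta}")
    if not 0 <= nu < 1:
        raise DomainError(f"nu must be in [0, 1), got {nu}")
    return 3.0 * (1.0 - nu**2) * force / (4.0 * math.sqrt(radius) * delta**1.5)


def omega(radius: float, delta: float, thickness_h: float) -> float:
    """Confinement parameter ``sqrt(R * delta) / h`` (dimensionless)."""
    if radius <= 0:
        raise DomainError(f"radius must be positive, got {radius}")
    if thickness_h <= 0:
        raise DomainError(f"thickness_h must be positive, got {thickness_h}")
    if delta < 0:
        raise DomainError(f"delta must be non-negative, got {delta}")
    return math.sqrt(radius * delta) / thickness_h


def film_coefficients(
    radius: float, thickness_h: float, grouping: Grouping = "printed"
) -> tuple[float, float]:
    """Frictionless thin-film coefficients ``(alpha, beta)`` as functions of h/R.

    ``printed`` grouping (literal token order):
        alpha = 10.05 - 0.63 * (h/R) * (3.1 + (h/R)^2)
    ``fraction`` grouping (alternative reading of the same expression):
        alpha = (10.05 - 0.63 * h/R) / (3.1 + (h/R)^2)
    beta = 4.8 - 4.23 * (h/R)^2 under both.
    """
    if radius <= 0 or thickness_h <= 0:
        raise DomainError("radius and thickness_h must be positive")
    hr = thickness_h / radius
    if grouping == "printed":
        alpha = 10.05 - 0.63 * hr * (3.1 + hr**2)
    elif grouping == "fraction":
        alpha = (10.05 - 0.63 * hr) / (3.1 + hr**2)
    else:
        raise DomainError(f"unknown grouping {grouping!r}")
    beta = 4.8 - 4.23 * hr**2
    return alpha, beta


def modified_hertz_modulus(
    E_hertz: float,
    omega_value: float,
    alpha: float,
    beta: float,
    floor: float = 1e-9,
) -> float:
    """Apply the thin-film correction factor to a Hertz modulus.

    Returns ``E_hertz`` exactly at ``omega == 0``.  Raises
    :class:`NonPositiveDenominatorError` when the denominator polynomial is
    not safely positive (out-of-model input); never returns a negative value.
    """
    if E_hertz <= 0:
        raise DomainError(f"E_hertz must be positive, got {E_hertz}")
    if omega_value < 0:
        raise DomainError(f"omega must be non-negative, got {omega_value}")
    if omega_value == 0.0:
        return E_hertz
    w = omega_value
    denominator = 1.0 + 1.15 * w ** (1.0 / 3.0) + alpha * w + beta * w**2
    if denominator <= floor:
        raise NonPositiveDenominatorError(
            f"correction denominator {denominator:.6g} <= floor {floor:.3g} at "
            f"omega={w:.6g}, alpha={alpha:.6g}, beta={beta:.6g}"
        )
    return E_hertz * (1.0 + 2.3 * w) / denominator


def check_validity(radius: float, delta: float, thickness_h: float) -> ValidityReport:
    """Evaluate the published validity inequalities; pure and total (never raises).

    Constraints (inclusive, as printed): ``delta/h <= min(0.6, R/h)`` and
    ``0.3 <= R/h <= 12.7``.  Non-positive or non-finite inputs simply fail.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        rh = float(np.divide(radius, thickness_h)) if thickness_h else math.inf
        dh = float(np.divide(delta, thickness_h)) if thickness_h else math.inf
    finite = math.isfinite(rh) and math.isfinite(dh) and thickness_h > 0 and radius > 0 and delta >= 0
    checks = {
        "R/h >= 0.3": finite and rh >= 0.3,
        "R/h <= 12.7": finite and rh <= 12.7,
        "delta/h <= min(0.6, R/h)": finite and dh <= min(0.6, rh),
    }
    return ValidityReport(r_over_h=rh, delta_over_h=dh, checks=checks, valid=all(checks.values()))


def modulus_from_measurement(
    indenter: IndenterSpec,
    medium: MediumSpec,
    meas: GelMeasurement,
    config: ElasticityConfig = ElasticityConfig(),
) -> ModulusResult:
    """Full pipeline: load -> Hertz -> confinement -> thin-film correction -> validity.

    Validity violations are reported on the result, not raised; numeric-domain
    problems (delta == 0, non-positive denominator) propagate as errors.
    """
    R = indenter.radius
    force = buoyant_load(indenter, medium)
    e_h = hertz_modulus(force, R, meas.indentation_delta, config.poisson_ratio)
    w = omega(R, meas.indentation_delta, meas.thickness_h)
    alpha, beta = film_coefficients(R, meas.thickness_h, config.coefficient_grouping)
    e_m = modified_hertz_modulus(e_h, w, alpha, beta, config.denominator_floor)
    report = check_validity(R, meas.indentation_delta, meas.thickness_h)
    return ModulusResult(
        E_hertz=e_h,
        E_modified=e_m,
        force=force,
        omega=w,
        alpha=alpha,
        beta=beta,
        R_over_h=report.r_over_h,
        delta_over_h=report.delta_over_h,
        valid=report.valid,
        violations=tuple(report.violations),
        grouping=config.coefficient_grouping,
        poisson_ratio=config.poisson_ratio,
        replicate_id=meas.replicate_id,
    )


def _forward_modulus(
    delta: float,
    indenter: IndenterSpec,
    medium: MediumSpec,
    thickness_h: float,
    config: ElasticityConfig,
) -> float:
    meas = GelMeasurement(thickness_h=thickness_h, indentation_delta=delta)
    return modulus_from_measurement(indenter, medium, meas, config).E_modified


def invert_indentation(
    E_target: float,
    indenter: IndenterSpec,
    medium: MediumSpec,
    thickness_h: float,
    config: ElasticityConfig = ElasticityConfig(),
    *,
    delta_min: float = 1e-12,
    grid_size: int = 400,
) -> float:
    """Find the indentation depth producing ``E_target`` under the forward model.

    The bracket is ``delta in [delta_min, h * min(0.6, R/h)]`` restricted to
    the strictly-decreasing prefix of the forward model (the thin-film
    denominator can change sign inside the validity domain; beyond its
    singularity the model is not invertible and is excluded by a pre-scan).
    """
    if E_target <= 0:
        raise DomainError(f"E_target must be positive, got {E_target}")
    R = indenter.radius
    delta_max = thickness_h * min(0.6, R / thickness_h)
    # delta < h is required by GelMeasurement; min(0.6, R/h)*h <= h always.
    delta_max = min(delta_max, thickness_h * (1 - 1e-12))
    if delta_min >= delta_max:
        raise DomainError("empty inversion bracket")

    def fwd(d: float) -> float:
        return _forward_modulus(d, indenter, medium, thickness_h, config)

    grid = np.geomspace(delta_min, delta_max, grid_size)
    values = np.full(grid_size, np.nan)
    for i, d in enumerate(grid):
        try:
            values[i] = fwd(float(d))
        except NonPositiveDenominatorError:
            break  # singular beyond this point; truncate the scan
    # strictly-decreasing prefix of the computable part
    last = 0
    while last + 1 < grid_size and np.isfinite(values[last + 1]) and values[last + 1] < values[last]:
        last += 1
    if last == 0:
        raise NoRootInValidityDomainError("forward model has no monotone bracket")
    e_hi, e_lo = values[0], values[last]
    if not (e_lo <= E_target <= e_hi):
        raise NoRootInValidityDomainError(
            f"E_target={E_target:.6g} Pa outside reachable range "
            f"[{e_lo:.6g}, {e_hi:.6g}] Pa on the monotone bracket"
        )
    # bracketing pair around the target on the (decreasing) grid values
    idx = int(np.clip(np.searchsorted(-values[: last + 1], -E_target), 1, last))
    lo, hi = float(grid[idx - 1]), float(grid[idx])
    root = brentq(
        lambda d: math.log(fwd(d) / E_target),
        lo,
        hi,
        xtol=1e-18,
        rtol=8.9e-16,
        maxiter=200,
    )
    return float(root)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean / sample SD / SEM of replicate modulus results."""

    n: int
    mean_E_modified: float
    sd_E_modified: float
    sem_E_modified: float
    mean_E_hertz: float
    sd_E_hertz: float
    sem_E_hertz: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_E_modified_Pa": self.mean_E_modified,
            "sd_E_modified_Pa": self.sd_E_modified,
            "sem_E_modified_Pa": self.sem_E_modified,
            "mean_E_hertz_Pa": self.mean_E_hertz,
            "sd_E_hertz_Pa": self.sd_E_hertz,
            "sem_E_hertz_Pa": self.sem_E_hertz,
        }


def summarize_replicates(results: Sequence[ModulusResult]) -> ReplicateSummary:
    """Mean and sample SD (n-1 denominator) over replicate modulus results."""
    if len(results) == 0:
        raise DomainError("no replicates to summarize")
    em = np.array([r.E_modified for r in results], dtype=float)
    eh = np.array([r.E_hertz for r in results], dtype=float)
    n = len(results)
    if n == 1:
        warnings.warn("single replicate: SD/SEM undefined (NaN)", stacklevel=2)
        sd_m = sd_h = sem_m = sem_h = math.nan
    else:
        sd_m = float(np.std(em, ddof=1))
        sd_h = float(np.std(eh, ddof=1))
        sem_m = sd_m / math.sqrt(n)
        sem_h = sd_h / math.sqrt(n)
    return ReplicateSummary(
        n=n,
        mean_E_modified=float(em.mean()),
        sd_E_modified=sd_m,
        sem_E_modified=sem_m,
        mean_E_hertz=float(eh.mean()),
        sd_E_hertz=sd_h,
        sem_E_hertz=sem_h,
    )
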