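"""Ground-truth-known synthetic inputs for every pipeline stage.

Each generator is deterministic given (parameters, seed) and is the exact
inverse of the corresponding analyzer's model: indentation scenes are built
from a target modulus by inverting the thin-film contact model; plate reads
invert the fluorescence-to-voltage map; titrations follow the Nernst-type
calibration relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import flipr, mechanics
from .errors import DomainError
from .flipr import EphysConstants, PlateRead, TitrationSeries, WellRecord
from .mechanics import ElasticityConfig, GelMeasurement, IndenterSpec, MediumSpec
from .stacks import ZStack

__all__ = [
    "SceneTruth",
    "GroupTruth",
    "PlateTruth",
    "simulate_indentation_scene",
    "simulate_plate",
    "simulate_titration",
    "WELL_IDS_96",
]


# ---------------------------------------------------------------------------
# indentation scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneTruth:
    """Everything needed to build (and audit) one indentation scene."""

    E_true: float  # Pa
    indenter: IndenterSpec
    h_true_um: float
    delta_true_um: float
    noise_cv: float
    seed: int
    config: ElasticityConfig = ElasticityConfig()
    medium: MediumSpec = MediumSpec()

    @classmethod
    def from_modulus(
        cls,
        E_true: float,
        indenter: IndenterSpec,
        h_um: float,
        noise_cv: float = 0.0,
        seed: int = 0,
        config: ElasticityConfig = ElasticityConfig(),
        medium: MediumSpec = MediumSpec(),
    ) -> "SceneTruth":
        """Solve the forward model for delta and refuse invalid geometry."""
        delta_m = mechanics.invert_indentation(
            E_true, indenter, medium, h_um * 1e-6, config
        )
        delta_um = delta_m * 1e6
        if delta_um <= 0:
            raise DomainError("inverted indentation depth is non-positive")
        report = mechanics.check_validity(indenter.radius, delta_m, h_um * 1e-6)
        if not report.valid:
            raise DomainError(
                f"scene violates validity constraints: {report.violations}"
            )
        return cls(
            E_true=E_true,
            indenter=indenter,
            h_true_um=h_um,
            delta_true_um=delta_um,
            noise_cv=noise_cv,
            seed=seed,
            config=config,
            medium=medium,
        )


def _cap_depression(r_um: np.ndarray, radius_um: float, delta_um: float) -> np.ndarray:
    """Spherical-cap depression depth at in-plane radius r (um)."""
    under = np.clip(radius_um**2 - r_um**2, 0.0, None)
    d = delta_um - (radius_um - np.sqrt(under))
    return np.clip(d, 0.0, None)


def simulate_indentation_scene(
    truth: SceneTruth,
    *,
    z_step_um: float = 2.0,
    xy_pixel_um: float = 16.0,
    field_px: int = 72,
    gel_intensity: float = 1000.0,
    bead_intensity: float = 3000.0,
    bead_sigma_um: float = 2.0,
    bottom_margin_um: float = 10.0,
    top_margin_um: float = 30.0,
    center_yx: tuple[float, float] | None = None,
) -> tuple[ZStack, dict]:
    """Render a two-channel z-stack for one indentation scene.

    Green: gel slab from z0 to the (cap-depressed) surface.  Red: a thin
    Gaussian bead layer riding on the surface.  Multiplicative Gaussian
    noise with coefficient ``truth.noise_cv`` on both channels.
    """
    report = mechanics.check_validity(
        truth.indenter.radius, truth.delta_true_um * 1e-6, truth.h_true_um * 1e-6
    )
    if not report.valid:
        raise DomainError(f"refusing invalid scene: {report.violations}")
    if truth.delta_true_um <= 0:
        raise DomainError("delta_true must be positive to render a depression")

    rng = np.random.default_rng(truth.seed)
    radius_um = truth.indenter.radius * 1e6
    z0 = bottom_margin_um
    z_extent = z0 + truth.h_true_um + top_margin_um
    nz = int(math.ceil(z_extent / z_step_um)) + 1
    ny = nx = field_px

    z = (np.arange(nz) * z_step_um)[:, None, None]
    ys = (np.arange(ny) - (ny - 1) / 2.0) * xy_pixel_um
    xs = (np.arange(nx) - (nx - 1) / 2.0) * xy_pixel_um
    if center_yx is None:
        cy = cx = 0.0
    else:
        cy, cx = center_yx
    r = np.sqrt((ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2)

    surface = z0 + truth.h_true_um - _cap_depression(r, radius_um, truth.delta_true_um)
    green = np.where((z >= z0) & (z <= surface[None]), gel_intensity, 0.0)
    red = bead_intensity * np.exp(-0.5 * ((z - surface[None]) / bead_sigma_um) ** 2)

    if truth.noise_cv > 0:
        green = green * (1.0 + truth.noise_cv * rng.standard_normal(green.shape))
        red = red * (1.0 + truth.noise_cv * rng.standard_normal(red.shape))
        green = np.clip(green, 0.0, None)
        red = np.clip(red, 0.0, None)

    stack = ZStack(
        green=green,
        red=red,
        xy_pixel_size=xy_pixel_um,
        z_step_nominal=z_step_um,
    )
    truth_record = {
        "E_true_Pa": truth.E_true,
        "indenter": truth.indenter.name,
        "h_true_um": truth.h_true_um,
        "delta_true_um": truth.delta_true_um,
        "noise_cv": truth.noise_cv,
        "seed": truth.seed,
        "grouping": truth.config.coefficient_grouping,
        "z_step_um": z_step_um,
        "xy_pixel_um": xy_pixel_um,
        "z0_um": z0,
    }
    return stack, truth_record


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------

WELL_IDS_96 = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


@dataclass(frozen=True)
class GroupTruth:
    """One experimental group on a synthetic plate."""

    name: str
    delta_e_mV: float
    n_wells: int
    condition: str = "rest"
    density: float | None = None


@dataclass(frozen=True)
class PlateTruth:
    groups: tuple[GroupTruth, ...]
    f0: float = 1000.0
    noise_cv: float = 0.02
    n_background: int = 3
    constants: EphysConstants = EphysConstants()
    seed: int = 0
    plate_id: str = "synthetic"


def simulate_plate(truth: PlateTruth) -> tuple[PlateRead, dict]:
    """Render a plate whose reads invert exactly to the group dE means.

    Generative map per read: ``dff0 = exp(-z' F dE / (R T)) - 1`` then
    ``F = F0 (dff0 + 1)(1 + eps)``, eps ~ N(0, noise_cv), 25 reads/well.
    """
    rng = np.random.default_rng(truth.seed)
    n_wells = truth.n_background + sum(g.n_wells for g in truth.groups)
    if n_wells > len(WELL_IDS_96):
        raise DomainError(f"plate needs {n_wells} wells, only 96 available")
    ids = iter(WELL_IDS_96)
    wells: dict[str, WellRecord] = {}
    for _ in range(truth.n_background):
        reads = truth.f0 * (
            1.0 + truth.noise_cv * rng.standard_normal(flipr.READS_PER_WELL)
        )
        wells[next(ids)] = WellRecord(
            reads=np.clip(reads, 0.0, None), role="dye_only_background"
        )
    for group in truth.groups:
        dff0 = flipr.inverse_delta_e(group.delta_e_mV, truth.constants)
        if dff0 <= -1:
            raise DomainError(
                f"group {group.name!r}: dE {group.delta_e_mV} mV maps to dff0 <= -1"
            )
        for _ in range(group.n_wells):
            eps = truth.noise_cv * rng.standard_normal(flipr.READS_PER_WELL)
            reads = truth.f0 * (dff0 + 1.0) * (1.0 + eps)
            if np.any(reads / truth.f0 - 1.0 <= -1):
                raise DomainError("noise drove a read to dff0 <= -1; lower noise_cv")
            wells[next(ids)] = WellRecord(
                reads=reads,
                role="sample",
                group=group.name,
                condition=group.condition,
                density=group.density,
            )
    plate = PlateRead(plate_id=truth.plate_id, wells=wells)
    truth_record = {
        "plate_id": truth.plate_id,
        "f0": truth.f0,
        "noise_cv": truth.noise_cv,
        "seed": truth.seed,
        "z_prime": truth.constants.z_prime,
        "temperature_K": truth.constants.temperature,
        "groups": [
            {
                "name": g.name,
                "delta_e_mV": g.delta_e_mV,
                "n_wells": g.n_wells,
                "condition": g.condition,
                "density": g.density,
            }
            for g in truth.groups
        ],
    }
    return plate, truth_record


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

def simulate_titration(
    z_prime: float,
    kx_list_mM: list[float],
    kr_mM: float = 5.4,
    n_cells: int = 50,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """KCl titration following ``1/(dff0+1) = (Kx/Kr)^z' * (1 + eps)``."""
    if z_prime == 0:
        raise DomainError("z_prime must be nonzero")
    if kr_mM not in kx_list_mM:
        raise DomainError("Kx list must contain the reference concentration")
    rng = np.random.default_rng(seed)
    points = []
    for kx in kx_list_mM:
        inv = (kx / kr_mM) ** z_prime * (
            1.0 + noise_cv * rng.standard_normal(n_cells)
        )
        if np.any(inv <= 0):
            raise DomainError("noise drove 1/(dff0+1) non-positive; lower noise_cv")
        points.append((kx, 1.0 / inv - 1.0))
    return TitrationSeries(points=points, reference_K=kr_mM)
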