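"""Extract gel thickness and indentation depth from two-channel z-stacks.

Green channel: fluorescein-stained gel slab -> thickness ``h`` from the
extremal first differences of the axial mean-intensity profile.  Red
channel: surface beads -> per-column surface elevation map, whose central
depression relative to the field periphery gives the indentation depth
``delta``.  All lengths are micrometres here; callers convert to metres at
the mechanics boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    DomainError,
    EdgeDepressionError,
    EmptySurfaceError,
    FlatProfileError,
    InvertedBoundaryError,
)

__all__ = [
    "ZStack",
    "AxialProfile",
    "ThicknessResult",
    "SurfaceMap",
    "IndentationDepthResult",
    "StackConfig",
    "axial_scale",
    "axial_profile",
    "thickness_from_profile",
    "surface_map",
    "indentation_depth",
    "cross_section",
    "measure_stack",
]


@dataclass
class ZStack:
    """Two co-registered (z, y, x) volumes plus voxel metadata (um).

    Slice 0 is closest to the objective (bottom of the well).
    """

    green: np.ndarray
    red: np.ndarray
    xy_pixel_size: float  # um
    z_step_nominal: float  # um
    refractive_index: float = 1.33

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.green.shape != self.red.shape:
            raise DomainError(
                f"channel shapes differ: {self.green.shape} vs {self.red.shape}"
            )
        if self.green.ndim != 3:
            raise DomainError(f"expected (z, y, x) volumes, got ndim={self.green.ndim}")
        if self.z_step_nominal <= 0:
            raise DomainError("z_step_nominal must be positive")
        if self.refractive_index < 1:
            raise DomainError("refractive_index must be >= 1")

    def channel(self, name: str) -> np.ndarray:
        if name == "green":
            return self.green
        if name == "red":
            return self.red
        raise DomainError(f"unknown channel {name!r}")


@dataclass
class AxialProfile:
    z_positions: np.ndarray  # um, strictly increasing
    mean_intensity: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if self.z_positions.shape != self.mean_intensity.shape:
            raise DomainError("z and intensity lengths differ")
        if np.any(np.diff(self.z_positions) <= 0):
            raise DomainError("z positions must be strictly increasing")


@dataclass(frozen=True)
class ThicknessResult:
    h: float  # um
    z_bottom: float
    z_top: float
    channel: str
    smoothing_window: int


@dataclass
class SurfaceMap:
    """Per-(y, x) surface elevation in um; mask marks detected columns."""

    z: np.ndarray  # (y, x) um
    mask: np.ndarray  # (y, x) bool
    z_step: float  # um
    xy_pixel_size: float  # um


@dataclass(frozen=True)
class IndentationDepthResult:
    delta: float  # um
    baseline_z: float
    min_z: float
    center_yx: tuple[int, int]


@dataclass(frozen=True)
class StackConfig:
    """Processing knobs for the profiler."""

    smoothing_window: int = 3
    apply_ri_correction: bool = False  # multiply nominal z-steps by the RI
    periphery_fraction: float = 0.2
    thickness_channel: str = "green"
    surface_channel: str = "red"
    min_surface_coverage: float = 0.05
    noise_floor_factor: float = 3.0


def axial_scale(
    z_index, z_step_nominal: float, refractive_index: float = 1.33,
    apply_correction: bool = False,
) -> np.ndarray | float:
    """Voxel z-index -> physical z position (um).

    By default the exported step size is trusted as already index-corrected;
    ``apply_correction`` multiplies nominal steps by the refractive index for
    instruments that export raw stage steps.
    """
    scale = refractive_index if apply_correction else 1.0
    return np.asarray(z_index, dtype=float) * z_step_nominal * scale


def axial_profile(
    stack: ZStack, channel: str, config: StackConfig = StackConfig()
) -> AxialProfile:
    """Mean intensity over (y, x) per slice, with scaled z positions."""
    vol = stack.channel(channel)
    if vol.size == 0:
        raise DomainError("empty stack")
    z = axial_scale(
        np.arange(vol.shape[0]),
        stack.z_step_nominal,
        stack.refractive_index,
        config.apply_ri_correction,
    )
    return AxialProfile(z_positions=z, mean_intensity=vol.mean(axis=(1, 2)), channel=channel)


def _edge_position(d: np.ndarray, z_mid: np.ndarray, idx: int, sign: float) -> float:
    """Derivative-weighted centroid of the half-max support around the peak.

    Smoothing spreads a step edge over ``window`` equal derivative samples;
    the centroid of that support recovers the edge centre exactly on clean
    data and averages out which-tie-wins jitter on noisy data.  ``idx`` is
    the first extremal sample from the bottom (argmax/argmin).
    """
    vals = sign * d
    half = 0.5 * vals[idx]
    lo = idx
    while lo - 1 >= 0 and vals[lo - 1] >= half:
        lo -= 1
    hi = idx
    while hi + 1 < vals.size and vals[hi + 1] >= half:
        hi += 1
    return float(np.average(z_mid[lo : hi + 1], weights=vals[lo : hi + 1]))


def thickness_from_profile(
    profile: AxialProfile,
    smoothing_window: int = 3,
    noise_floor_factor: float = 3.0,
) -> ThicknessResult:
    """Gel thickness from the extremal first differences of the smoothed profile.

    z_bottom = position of the maximum positive derivative, z_top = position
    of the most negative one (each reported at the midpoint between the two
    slices of the difference; ties resolved to the first slice from the
    bottom).  Raises :class:`FlatProfileError` when no edge rises above the
    noise floor and :class:`InvertedBoundaryError` when top <= bottom.
    """
    y = profile.mean_intensity
    if y.size < 5:
        raise DomainError("profile too short (need >= 5 slices)")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise DomainError("smoothing_window must be odd and >= 1")
    if smoothing_window > 1:
        # edge-padded so constant profiles stay exactly constant
        y = ndimage.uniform_filter1d(y, size=smoothing_window, mode="nearest")
    d = np.diff(y)
    z_mid = 0.5 * (profile.z_positions[:-1] + profile.z_positions[1:])
    abs_d = np.abs(d)
    max_abs = abs_d.max()
    noise_floor = noise_floor_factor * np.median(abs_d)
    if max_abs == 0 or max_abs < noise_floor:
        raise FlatProfileError(
            f"max |derivative| {max_abs:.4g} below noise floor {noise_floor:.4g}"
        )
    z_bottom = _edge_position(d, z_mid, int(np.argmax(d)), +1.0)
    z_top = _edge_position(d, z_mid, int(np.argmin(d)), -1.0)
    if z_top <= z_bottom:
        raise InvertedBoundaryError(
            f"detected top ({z_top:.3g} um) precedes bottom ({z_bottom:.3g} um)"
        )
    return ThicknessResult(
        h=z_top - z_bottom,
        z_bottom=z_bottom,
        z_top=z_top,
        channel=profile.channel,
        smoothing_window=smoothing_window,
    )


def surface_map(
    stack: ZStack, channel: str = "red", config: StackConfig = StackConfig()
) -> SurfaceMap:
    """Per-column surface elevation from the bead channel.

    For each (y, x) column the brightest contiguous axial blob above a
    half-maximum threshold is located and its intensity-weighted centroid
    taken as the surface z.  Columns whose peak does not clear the global
    detection threshold are masked out.
    """
    vol = stack.channel(channel)
    nz, ny, nx = vol.shape
    z = axial_scale(
        np.arange(nz), stack.z_step_nominal, stack.refractive_index,
        config.apply_ri_correction,
    )
    background = float(np.median(vol))
    mad = float(np.median(np.abs(vol - background)))
    noise = 1.4826 * mad
    global_max = float(vol.max())
    detection_thr = max(background + 10.0 * noise, background + 0.1 * (global_max - background))

    col_max = vol.max(axis=0)
    detected = col_max > detection_thr
    if detected.sum() < config.min_surface_coverage * ny * nx:
        raise EmptySurfaceError(
            f"surface detected in {int(detected.sum())}/{ny * nx} columns "
            f"(< {config.min_surface_coverage:.0%})"
        )

    elevation = np.zeros((ny, nx))
    yy, xx = np.nonzero(detected)
    for i, j in zip(yy, xx):
        col = vol[:, i, j]
        thr = background + 0.5 * (col.max() - background)
        above = col > thr
        # contiguous runs of above-threshold voxels
        edges = np.flatnonzero(np.diff(above.astype(np.int8)))
        starts = np.r_[0, edges + 1]
        stops = np.r_[edges + 1, above.size]
        best_sum, best = -np.inf, None
        for s, e in zip(starts, stops):
            if not above[s]:
                continue
            run_sum = col[s:e].sum()
            if run_sum > best_sum:
                best_sum, best = run_sum, (s, e)
        s, e = best
        weights = col[s:e] - background
        elevation[i, j] = float(np.average(z[s:e], weights=weights))
    return SurfaceMap(
        z=elevation,
        mask=detected,
        z_step=stack.z_step_nominal
        * (stack.refractive_index if config.apply_ri_correction else 1.0),
        xy_pixel_size=stack.xy_pixel_size,
    )


def _border_distance(ny: int, nx: int) -> np.ndarray:
    """Normalized distance of each pixel to the nearest field edge (0 at edge)."""
    iy = np.arange(ny)[:, None] / max(ny - 1, 1)
    ix = np.arange(nx)[None, :] / max(nx - 1, 1)
    return np.minimum.reduce([
        np.broadcast_to(iy, (ny, nx)),
        np.broadcast_to(1 - iy, (ny, nx)),
        np.broadcast_to(ix, (ny, nx)),
        np.broadcast_to(1 - ix, (ny, nx)),
    ])


def indentation_depth(
    smap: SurfaceMap, periphery_fraction: float = 0.2
) -> IndentationDepthResult:
    """Depression depth = periphery median elevation - smoothed interior minimum.

    The baseline is the median surface elevation over the outer annulus
    (band of normalized half-width ``periphery_fraction / 2`` on each side).
    Raises :class:`EdgeDepressionError` when the minimum sits on the field
    border (off-centre indenter).
    """
    ny, nx = smap.z.shape
    if not smap.mask.any():
        raise EmptySurfaceError("surface map has no detected columns")
    dist = _border_distance(ny, nx)
    periphery = (dist < periphery_fraction / 2.0) & smap.mask
    if not periphery.any():
        raise EmptySurfaceError("no detected columns in the periphery annulus")
    baseline = float(np.median(smap.z[periphery]))

    filled = np.where(smap.mask, smap.z, baseline)
    smoothed = ndimage.uniform_filter(filled, size=3, mode="nearest")
    interior = (dist >= periphery_fraction / 2.0) & smap.mask
    if not interior.any():
        raise EmptySurfaceError("no detected columns in the interior")
    candidate = np.where(interior, smoothed, np.inf)
    flat_idx = int(np.argmin(candidate))
    ci, cj = np.unravel_index(flat_idx, candidate.shape)
    min_z = float(candidate[ci, cj])
    # a material depression whose minimum sits on the interior boundary means
    # the indenter is off-centre and the true minimum may lie outside the field
    interior_dist = dist[interior].min()
    on_border = dist[ci, cj] <= interior_dist + 1e-12
    if on_border and (baseline - min_z) > smap.z_step:
        raise EdgeDepressionError(
            f"depression minimum at interior boundary (y={ci}, x={cj}); "
            "indenter not centred"
        )
    return IndentationDepthResult(
        delta=baseline - min_z,
        baseline_z=baseline,
        min_z=min_z,
        center_yx=(int(ci), int(cj)),
    )


def cross_section(stack: ZStack, channel: str, axis: str, index: int) -> np.ndarray:
    """XZ (axis='y') or YZ (axis='x') cross-section for visual inspection."""
    vol = stack.channel(channel)
    if axis == "y":
        return vol[:, index, :]
    if axis == "x":
        return vol[:, :, index]
    raise DomainError(f"axis must be 'x' or 'y', got {axis!r}")


def measure_stack(
    stack: ZStack, config: StackConfig = StackConfig()
) -> tuple[ThicknessResult, IndentationDepthResult]:
    """Thickness from the gel-channel profile, depth from the bead surface map."""
    profile = axial_profile(stack, config.thickness_channel, config)
    thickness = thickness_from_profile(
        profile, config.smoothing_window, config.noise_floor_factor
    )
    smap = surface_map(stack, config.surface_channel, config)
    depth = indentation_depth(smap, config.periphery_fraction)
    return thickness, depth
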