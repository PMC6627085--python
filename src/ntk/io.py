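"""Readers/writers for the toolkit's file formats.

Plates travel as CSV (long ``well,read_index,fluorescence`` or ``block5x5``
with one grid row per line), plate maps as CSV or TOML, stacks as
OME-TIFF (channels first), titrations as ``kx_mM,dff0`` CSV, and reports as
JSON with config/seed/digest provenance.
"""

from __future__ import annotations

import hashlib
import json
import re
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import (
    ChannelCountError,
    ConfigError,
    MissingMetadataError,
    PlateSchemaError,
)
from .flipr import READS_PER_WELL, PlateRead, TitrationSeries, WellRecord
from .stacks import ZStack

__all__ = [
    "read_plate_csv",
    "write_plate_csv",
    "read_plate_map",
    "read_titration_csv",
    "write_titration_csv",
    "read_stack",
    "write_stack",
    "write_report",
    "load_run_config",
]


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------

def write_plate_csv(path: str | Path, plate: PlateRead, dialect: str = "long") -> None:
    path = Path(path)
    rows = []
    if dialect == "long":
        for well_id in sorted(plate.wells):
            for idx, value in enumerate(plate.wells[well_id].reads):
                rows.append({"well": well_id, "read_index": idx, "fluorescence": value})
        pd.DataFrame(rows).to_csv(path, index=False)
    elif dialect == "block5x5":
        for well_id in sorted(plate.wells):
            grid = plate.wells[well_id].reads.reshape(5, 5)
            for r in range(5):
                rows.append(
                    {"well": well_id, "row": r}
                    | {f"c{c + 1}": grid[r, c] for c in range(5)}
                )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise PlateSchemaError(f"unknown dialect {dialect!r}")


def read_plate_csv(
    path: str | Path,
    dialect: str = "long",
    plate_map: dict[str, dict] | None = None,
    plate_id: str | None = None,
) -> PlateRead:
    """Read raw plate fluorescence; annotations come from ``plate_map``.

    Wells with a read count other than 25 are rejected with a diagnostic
    naming the well.
    """
    path = Path(path)
    df = pd.read_csv(path)
    reads_by_well: dict[str, np.ndarray] = {}
    if dialect == "long":
        required = {"well", "read_index", "fluorescence"}
        if not required.issubset(df.columns):
            raise PlateSchemaError(
                f"{path.name}: long dialect needs columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        for well_id, sub in df.groupby("well", sort=True):
            sub = sub.sort_values("read_index")
            if len(sub) != READS_PER_WELL:
                raise PlateSchemaError(
                    f"{path.name}: well {well_id} has {len(sub)} reads, "
                    f"expected {READS_PER_WELL} (rows {sub.index.min() + 2}.."
                    f"{sub.index.max() + 2})"
                )
            reads_by_well[str(well_id)] = sub["fluorescence"].to_numpy(dtype=float)
    elif dialect == "block5x5":
        required = {"well", "row", "c1", "c2", "c3", "c4", "c5"}
        if not required.issubset(df.columns):
            raise PlateSchemaError(
                f"{path.name}: block5x5 dialect needs columns {sorted(required)}"
            )
        for well_id, sub in df.groupby("well", sort=True):
            if len(sub) != 5:
                raise PlateSchemaError(
                    f"{path.name}: well {well_id} has {len(sub)} grid rows, expected 5"
                )
            grid = sub.sort_values("row")[["c1", "c2", "c3", "c4", "c5"]].to_numpy(
                dtype=float
            )
            reads_by_well[str(well_id)] = grid.reshape(-1)
    else:
        raise PlateSchemaError(f"unknown dialect {dialect!r}")

    wells: dict[str, WellRecord] = {}
    for well_id, reads in reads_by_well.items():
        meta = (plate_map or {}).get(well_id, {})
        wells[well_id] = WellRecord(
            reads=reads,
            role=meta.get("role", "sample"),
            group=meta.get("group", ""),
            condition=meta.get("condition", "rest"),
            density=meta.get("density"),
        )
    return PlateRead(plate_id=plate_id or path.stem, wells=wells)


def read_plate_map(path: str | Path) -> dict[str, dict]:
    """Plate map: well -> {role, group, condition, density}; CSV or TOML."""
    path = Path(path)
    entries: dict[str, dict] = {}
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        records = doc.get("wells", [])
        if not isinstance(records, list):
            raise ConfigError(f"{path.name}: [[wells]] array of tables expected")
    else:
        df = pd.read_csv(path)
        if "well" not in df.columns:
            raise PlateSchemaError(f"{path.name}: plate map needs a 'well' column")
        records = df.to_dict(orient="records")
    for rec in records:
        well = str(rec.get("well", "")).strip()
        if not well:
            raise PlateSchemaError(f"{path.name}: plate-map entry missing well id")
        density = rec.get("density")
        if density is not None and (isinstance(density, float) and np.isnan(density)):
            density = None
        entries[well] = {
            "role": str(rec.get("role", "sample")),
            "group": "" if pd.isna(rec.get("group", "")) else str(rec.get("group", "")),
            "condition": str(rec.get("condition", "rest")),
            "density": None if density is None else float(density),
        }
    return entries


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

def write_titration_csv(path: str | Path, series: TitrationSeries) -> None:
    rows = [
        {"kx_mM": kx, "dff0": value}
        for kx, values in series.points
        for value in values
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_titration_csv(path: str | Path, kr_mM: float = 5.4) -> TitrationSeries:
    df = pd.read_csv(path)
    if not {"kx_mM", "dff0"}.issubset(df.columns):
        raise PlateSchemaError(f"{Path(path).name}: need columns kx_mM, dff0")
    points = [
        (float(kx), sub["dff0"].to_numpy(dtype=float))
        for kx, sub in df.groupby("kx_mM", sort=True)
    ]
    return TitrationSeries(points=points, reference_K=kr_mM)


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def write_stack(path: str | Path, stack: ZStack) -> None:
    """Write the two channels as an OME-TIFF (CZYX) with physical voxel sizes."""
    data = np.stack([stack.green, stack.red]).astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.xy_pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.xy_pixel_size,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step_nominal,
            "PhysicalSizeZUnit": "µm",
        },
    )


def _ome_physical_sizes(ome_xml: str | None) -> dict[str, float]:
    sizes = {}
    if not ome_xml:
        return sizes
    for axis in ("X", "Y", "Z"):
        m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', ome_xml)
        if m:
            sizes[axis] = float(m.group(1))
    return sizes


def read_stack(
    path: str | Path,
    green_index: int = 0,
    red_index: int = 1,
    xy_pixel_size: float | None = None,
    z_step: float | None = None,
    refractive_index: float = 1.33,
) -> ZStack:
    """Read a two-channel TIFF/OME-TIFF stack.

    Metadata (pixel size, z-step, in um) comes from the OME header; explicit
    overrides win.  Missing metadata without an override raises
    :class:`MissingMetadataError` — never a silent default.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        sizes = _ome_physical_sizes(tif.ome_metadata)
    if data.ndim == 4 and data.shape[0] <= 8:  # CZYX
        channels = data
    elif data.ndim == 4:  # ZCYX
        channels = np.moveaxis(data, 1, 0)
    else:
        raise ChannelCountError(
            f"{path.name}: expected a 4-D two-channel stack, got shape {data.shape}"
        )
    n_channels = channels.shape[0]
    if max(green_index, red_index) >= n_channels:
        raise ChannelCountError(
            f"{path.name}: channel map needs index "
            f"{max(green_index, red_index)} but file has {n_channels} channel(s)"
        )
    xy = xy_pixel_size if xy_pixel_size is not None else sizes.get("X")
    dz = z_step if z_step is not None else sizes.get("Z")
    if xy is None:
        raise MissingMetadataError(f"{path.name}: xy pixel size absent; pass an override")
    if dz is None:
        raise MissingMetadataError(f"{path.name}: z step absent; pass an override")
    return ZStack(
        green=channels[green_index].astype(float),
        red=channels[red_index].astype(float),
        xy_pixel_size=float(xy),
        z_step_nominal=float(dz),
        refractive_index=refractive_index,
    )


# ---------------------------------------------------------------------------
# reports & config
# ---------------------------------------------------------------------------

def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(
    path: str | Path,
    payload: dict,
    *,
    config: dict | None = None,
    seed: int | None = None,
    inputs: list[str | Path] | None = None,
) -> None:
    """JSON report embedding toolkit version, config, seed, and input digests."""
    doc = {
        "ntk_version": __version__,
        "config": config or {},
        "seed": seed,
        "input_digests": {str(p): _digest(p) for p in (inputs or [])},
        "result": payload,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


_KNOWN_SECTIONS = {"elasticity", "ephys", "stack", "plan", "seed", "verbosity"}


def load_run_config(path: str | Path) -> dict:
    """Parse the run-configuration TOML, rejecting unknown top-level keys."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    unknown = set(doc) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return doc
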