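"""Stack and table I/O, and the geometry conventions shared by every stage.

Conventions (fixed package-wide):

* Spatial axis order is ``(z, y, x)``; the channel axis is the leading axis
  of a stack, kept separate from the spatial axes.
* Voxel indices are 0-based; the centre of voxel ``(i, j, k)`` sits at the
  physical position ``(i*dz, j*dy, k*dx)`` in micrometres. Centroids,
  distances and radii are always expressed in micrometres.
* Stacks round-trip losslessly through multi-page TIFF (integer data), cell
  tables through CSV written with full-precision decimal text. A JSON
  sidecar carries provenance (scene parameters, seed, software version).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ChannelRoleError, ConfigurationError

__all__ = ["ImageStack", "CellTable", "read_stack", "write_stack",
           "read_cell_table", "write_cell_table"]

#: default confocal sampling (z, y, x) in micrometres, used by the
#: synthetic generator; real data must carry its own voxel size.
DEFAULT_VOXEL_SIZE = (1.0, 0.31, 0.31)


@dataclass
class ImageStack:
    """A multi-channel 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (C, Z, Y, X)
        Non-negative per-channel intensity grids sharing one spatial shape.
    voxel_size : tuple of float
        Physical voxel edge lengths ``(dz, dy, dx)`` in micrometres.
    channel_names : list of str
        One name per channel, in axis order.
    source : str
        Origin of the data (a file path, or ``"synthetic"``).
    roles : dict
        Optional mapping of downstream role (``"nuclear"``, ``"hub"``, ...)
        to a channel name.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str]
    source: str = "synthetic"
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be (C, Z, Y, X), got ndim={self.voxels.ndim}")
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("one channel name per channel axis entry required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (um)")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape (Z, Y, X)."""
        return self.voxels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 3D array, resolving roles first."""
        name = self.roles.get(name, name)
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ChannelRoleError(
                f"channel {name!r} not present; have {self.channel_names}"
            ) from None
        return self.voxels[idx]

    def has_channel(self, name: str) -> bool:
        return self.roles.get(name, name) in self.channel_names

    def with_roles(self, roles: dict[str, str]) -> "ImageStack":
        for role, name in roles.items():
            if name not in self.channel_names:
                raise ChannelRoleError(
                    f"role {role!r} maps to missing channel {name!r}; "
                    f"have {self.channel_names}")
        return replace(self, roles=dict(roles))


@dataclass
class CellTable:
    """Per-nucleus measurements for one stack (one biological replicate).

    ``df`` holds one row per detected cell; columns are stable across
    versions: ``cell_id``, ``z_um``, ``y_um``, ``x_um``, ``volume_um3``,
    ``mean_<channel>`` per measured channel, then the phenotyping columns
    (``<marker>_pos`` flags, ``hub_distance_um``, ``cell_class``) once those
    stages have run.
    """

    df: pd.DataFrame
    genotype: str | None = None
    source: str = "unknown"

    def __post_init__(self) -> None:
        if "cell_id" in self.df.columns and self.df["cell_id"].duplicated().any():
            raise ValueError("cell ids must be unique within a stack")

    def __len__(self) -> int:
        return len(self.df)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF (pages = channel-major z-slices).

    Channel names and voxel size are embedded as JSON in the TIFF
    description tag, so a written stack re-reads without a sidecar.
    """
    path = Path(path)
    meta = {
        "axes": "CZYX",
        "channel_names": list(stack.channel_names),
        "voxel_size_um": list(stack.voxel_size),
    }
    tifffile.imwrite(path, stack.voxels, description=json.dumps(meta),
                     photometric="minisblack")
    return path


def read_stack(
    path: str | Path,
    channel_map: dict[str, str] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a multi-page TIFF stack written by :func:`write_stack`.

    Parameters
    ----------
    channel_map : dict, optional
        Mapping of downstream role to channel name. Every role named here
        must resolve to a channel or a :class:`ChannelRoleError` is raised.
    voxel_size : tuple, optional
        Explicit (dz, dy, dx) in micrometres. Precedence: this argument >
        embedded metadata > error — never a silent default on real data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if data.ndim == 3:
        data = data[np.newaxis]
    if data.ndim != 4:
        raise ConfigurationError(
            f"expected a (C, Z, Y, X) or (Z, Y, X) TIFF, got shape {data.shape}")
    names = meta.get("channel_names") or [f"ch{i}" for i in range(data.shape[0])]
    if voxel_size is None:
        if "voxel_size_um" in meta:
            voxel_size = tuple(meta["voxel_size_um"])
        else:
            raise ConfigurationError(
                f"{path}: no voxel size in metadata and none given explicitly")
    stack = ImageStack(data, voxel_size, list(names), source=str(path))
    if channel_map:
        missing = [r for r, n in channel_map.items() if n not in names]
        if missing:
            raise ChannelRoleError(
                f"{path}: channel roles {missing} name channels absent from "
                f"the file (channels: {names})")
        stack = stack.with_roles(channel_map)
    return stack


def write_cell_table(table: CellTable, path: str | Path) -> Path:
    """Write a cell table as CSV, one row per cell, with full precision.

    ``genotype`` and ``source`` are stored as ordinary columns so the file
    is self-contained.
    """
    path = Path(path)
    df = table.df.copy()
    df["genotype"] = table.genotype if table.genotype is not None else ""
    df["source"] = table.source
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_cell_table(path: str | Path) -> CellTable:
    """Re-read a CSV written by :func:`write_cell_table`, field-for-field."""
    df = pd.read_csv(path)
    genotype = None
    source = "unknown"
    if "genotype" in df.columns:
        if len(df) and str(df["genotype"].iloc[0]) not in ("", "nan"):
            genotype = str(df["genotype"].iloc[0])
        df = df.drop(columns=["genotype"])
    if "source" in df.columns:
        if len(df):
            source = str(df["source"].iloc[0])
        df = df.drop(columns=["source"])
    return CellTable(df, genotype=genotype, source=source)


def write_sidecar(path: str | Path, payload: dict) -> Path:
    """Write a JSON provenance sidecar next to an output file."""
    side = Path(str(path) + ".json")
    side.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return side
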