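"""Image-stack container and file I/O.

The in-memory convention throughout the package is a single axis order,
``(channel, z, y, x)``, with physical voxel sizes in nanometres per spatial
axis ``(z, y, x)``.  Physical coordinates follow the voxel-centre convention:
the centre of voxel ``i`` along an axis with voxel size ``v`` lies at
``i * v`` nm.

On disk, stacks are OME-TIFF with channel names and physical pixel sizes
embedded; tabular results are plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile


class StackError(ValueError):
    """Raised for malformed stacks or unreadable/underspecified image files."""


@dataclass
class ImageStack:
    """A multi-channel 3-D intensity stack with physical voxel sizes.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, nz, ny, nx)`` with finite, non-negative
        intensities.
    voxel_size
        Physical size of one voxel in nm, ordered ``(z, y, x)``.
    channel_names
        One name per channel, e.g. ``["nuclei", "mark", "spots"]``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise StackError(
                f"stack data must be (channel, z, y, x); got ndim={self.data.ndim}"
            )
        if not np.issubdtype(self.data.dtype, np.number):
            raise StackError(f"non-numeric stack dtype {self.data.dtype}")
        if not np.all(np.isfinite(self.data)):
            raise StackError("stack intensities must be finite")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise StackError(f"voxel sizes must be 3 positive nm values, got {self.voxel_size}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise StackError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape (z, y, x)."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's (z, y, x) volume by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise StackError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` to OME-TIFF.

    Channel names and physical voxel sizes (in nm) are embedded in the OME
    metadata so that :func:`read_stack` round-trips them.
    """
    path = Path(path)
    vz, vy, vx = stack.voxel_size
    tifffile.imwrite(
        path,
        stack.data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": vx,
            "PhysicalSizeXUnit": "nm",
            "PhysicalSizeY": vy,
            "PhysicalSizeYUnit": "nm",
            "PhysicalSizeZ": vz,
            "PhysicalSizeZUnit": "nm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


_UNIT_TO_NM = {"nm": 1.0, "µm": 1000.0, "um": 1000.0, "micron": 1000.0, "mm": 1e6}


def _pixel_sizes_from_ome(xml: str) -> tuple[float, float, float] | None:
    """Extract (z, y, x) voxel sizes in nm from OME-XML, or None if absent."""
    import xml.etree.ElementTree as ET

    root = ET.fromstring(xml)
    ns = root.tag.split("}")[0] + "}" if root.tag.startswith("{") else ""
    pixels = root.find(f".//{ns}Pixels")
    if pixels is None:
        return None
    out = []
    for axis in ("Z", "Y", "X"):
        raw = pixels.get(f"PhysicalSize{axis}")
        if raw is None:
            return None
        unit = pixels.get(f"PhysicalSize{axis}Unit", "µm")
        if unit not in _UNIT_TO_NM:
            raise StackError(f"unsupported pixel-size unit {unit!r}")
        out.append(float(raw) * _UNIT_TO_NM[unit])
    return tuple(out)  # type: ignore[return-value]


def _channel_names_from_ome(xml: str, n: int) -> list[str] | None:
    import xml.etree.ElementTree as ET

    root = ET.fromstring(xml)
    ns = root.tag.split("}")[0] + "}" if root.tag.startswith("{") else ""
    names = [c.get("Name") for c in root.iter(f"{ns}Channel")]
    if len(names) == n and all(names):
        return list(names)  # type: ignore[arg-type]
    return None


def read_stack(
    path: str | Path,
    voxel_size_override: Sequence[float] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    Voxel sizes come from the OME metadata; ``voxel_size_override`` (nm,
    ``(z, y, x)``) replaces or supplies them.  A plain TIFF without pixel-size
    metadata and without an override is an error: downstream quantities
    (radii, correlation shift distances) are physical lengths.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            ome = tf.ome_metadata
    except (OSError, tifffile.TiffFileError) as exc:
        raise StackError(f"cannot read {path}: {exc}") from exc

    data = np.asarray(data)
    if data.ndim == 2:  # single plane, single channel
        data = data[None, None]
    elif data.ndim == 3:  # assume (z, y, x), single channel
        data = data[None]
    elif data.ndim != 4:
        raise StackError(f"cannot interpret TIFF with ndim={data.ndim} as (c, z, y, x)")

    voxel_size = None
    channel_names: list[str] | None = None
    if ome:
        voxel_size = _pixel_sizes_from_ome(ome)
        channel_names = _channel_names_from_ome(ome, data.shape[0])
    if voxel_size_override is not None:
        voxel_size = tuple(float(v) for v in voxel_size_override)
    if voxel_size is None:
        raise StackError(
            f"{path} carries no physical pixel-size metadata; pass voxel_size_override=(z, y, x) nm"
        )
    return ImageStack(data=data, voxel_size=voxel_size, channel_names=channel_names or [])


def write_table(records: pd.DataFrame | Sequence[dict], path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write records to CSV with a header row.

    An empty record list still produces a header-only CSV (``columns`` must
    then be given unless ``records`` is already a DataFrame).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records), columns=columns)
    df.to_csv(path, index=False)


def read_table(path: str | Path, required_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a CSV table; optionally enforce a schema.

    Raises
    ------
    StackError
        If the file is not parseable CSV or required columns are missing.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise StackError(f"cannot read table {path}: {exc}") from exc
    if required_columns is not None:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise StackError(f"table {path} missing columns {missing}")
    return df
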