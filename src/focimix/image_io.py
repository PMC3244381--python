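"""Reading and writing of image stacks and result tables.

All stacks are held in a fixed internal axis order — ``(Z, Y, X, channel)``
for single time points and ``(T, Z, Y, X, channel)`` for time lapses — with
physical voxel dimensions in micrometres carried alongside the array.  The
axial (Z) pitch of confocal stacks generally differs from the lateral pitch,
so axis order is never inferred from array shape alone.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "RESULT_COLUMNS",
    "read_stack",
    "write_stack",
    "write_results",
    "read_results",
]

#: Fixed result-table column order: identity, condition, then the metric
#: columns in the order volume / percentages / Pearson / Mander / occupancy,
#: followed by provenance fields.
RESULT_COLUMNS = [
    "id",
    "condition",
    "region",
    "vol_coloc_um3",
    "pct_coloc",
    "pct_green",
    "pct_red",
    "pearson",
    "m_green",
    "m_red",
    "pct_occupied",
    "pct_occupied_union",
    "coloc_voxels",
    "filter",
    "threshold_rule",
    "t_green",
    "t_red",
    "mander_denominator",
]

_MAX_CHANNELS = 4


@dataclasses.dataclass
class ImageStack:
    """A multi-channel intensity stack with physical voxel dimensions.

    Parameters
    ----------
    data
        Non-negative intensities, shape ``(Z, Y, X, C)`` or ``(T, Z, Y, X, C)``.
    voxel_size_um
        Physical voxel pitch ``(z, y, x)`` in micrometres.
    channel_names
        One name per channel, e.g. ``("green", "red")``.
    bit_depth
        Declared dynamic range; intensities must fit in ``[0, 2**bit_depth - 1]``.
    frame_interval_min
        Time between frames in minutes, for 5-D (time-lapse) stacks only.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel_names: tuple[str, ...] = ("green", "red")
    bit_depth: int = 8
    frame_interval_min: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (4, 5):
            raise ValueError(
                f"expected (Z,Y,X,C) or (T,Z,Y,X,C) data, got ndim={self.data.ndim}"
            )
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"invalid voxel size {self.voxel_size_um}")
        n_ch = self.data.shape[-1]
        if n_ch > _MAX_CHANNELS:
            raise ValueError(f"{n_ch} channels exceeds the supported maximum of 4")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != n_ch:
            raise ValueError("channel_names length does not match channel axis")
        if self.data.size and self.data.min() < 0:
            raise ValueError("negative intensities")
        if self.data.size and self.data.max() > 2**self.bit_depth - 1:
            raise ValueError("intensities exceed the declared bit depth")

    @property
    def is_timelapse(self) -> bool:
        return self.data.ndim == 5

    @property
    def n_frames(self) -> int:
        return self.data.shape[0] if self.is_timelapse else 1

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel in µm³ (product of the three pitches)."""
        return float(np.prod(self.voxel_size_um))

    def channel(self, name: str, frame: int | None = None) -> np.ndarray:
        """Return one channel as a 3-D ``(Z, Y, X)`` array."""
        idx = self.channel_names.index(name)
        if self.is_timelapse:
            if frame is None:
                raise ValueError("frame index required for a time-lapse stack")
            return self.data[frame, ..., idx]
        return self.data[..., idx]


def _dtype_for_bit_depth(bit_depth: int) -> np.dtype:
    if bit_depth <= 8:
        return np.dtype(np.uint8)
    if bit_depth <= 16:
        return np.dtype(np.uint16)
    raise ValueError(f"unsupported bit depth {bit_depth}")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack to an ImageJ-compatible multi-page TIFF.

    Voxel size is recorded in the ImageJ metadata (``spacing`` for Z, the
    TIFF resolution tags for X/Y) so that a round trip through
    :func:`read_stack` preserves the physical dimensions exactly.
    """
    path = Path(path)
    dtype = _dtype_for_bit_depth(stack.bit_depth)
    pz, py, px = stack.voxel_size_um
    # internal (T)ZYXC -> ImageJ (T)ZCYX
    if stack.is_timelapse:
        arr = np.moveaxis(stack.data, -1, 2)
        axes = "TZCYX"
    else:
        arr = np.moveaxis(stack.data, -1, 1)
        axes = "ZCYX"
    metadata = {
        "axes": axes,
        "spacing": pz,
        "unit": "um",
        "focimix_channels": ",".join(stack.channel_names),
        "focimix_bit_depth": stack.bit_depth,
    }
    if stack.frame_interval_min is not None:
        metadata["finterval"] = stack.frame_interval_min * 60.0  # ImageJ uses seconds
    tifffile.imwrite(
        path,
        arr.astype(dtype),
        imagej=True,
        resolution=(1.0 / px, 1.0 / py),
        metadata=metadata,
    )


def read_stack(
    path: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> ImageStack:
    """Read a multi-channel TIFF stack.

    Parameters
    ----------
    path
        TIFF file with 1-4 channels.
    voxel_size_um
        Explicit ``(z, y, x)`` pitch in µm, overriding file metadata.  A file
        without voxel-size metadata and without an override is an error —
        volumes must never be computed from silently assumed pitches.
    channel_names
        Override for channel names when the file records none.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes
        ij = tif.imagej_metadata or {}
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")

    # normalise axes to (T)ZYXC ("Q"/"I" are tifffile's unknown page axes)
    axes = axes.replace("S", "C")
    if "Z" not in axes:
        for unknown in ("Q", "I"):
            if unknown in axes:
                axes = axes.replace(unknown, "Z", 1)
                break
    if "C" not in axes:
        arr = arr[..., np.newaxis]
        axes += "C"
    if "Z" not in axes:
        raise ValueError(f"{path}: not a Z stack (axes {axes!r})")
    order = [a for a in "TZYXC" if a in axes]
    arr = np.transpose(arr, [axes.index(a) for a in order])
    if arr.ndim not in (4, 5):
        raise ValueError(f"{path}: unsupported axis layout {axes!r}")
    if arr.shape[-1] > _MAX_CHANNELS:
        raise ValueError(f"{path}: {arr.shape[-1]} channels (max 4 supported)")

    if voxel_size_um is None:
        pz = ij.get("spacing")
        px = py = None
        if xres is not None and xres.value[0]:
            px = xres.value[1] / xres.value[0]
        if yres is not None and yres.value[0]:
            py = yres.value[1] / yres.value[0]
        if pz is None or px is None or py is None:
            raise ValueError(
                f"{path}: no voxel-size metadata; pass voxel_size_um explicitly"
            )
        voxel_size_um = (float(pz), float(py), float(px))

    if channel_names is None:
        recorded = ij.get("focimix_channels")
        if recorded:
            channel_names = tuple(recorded.split(","))
        else:
            channel_names = tuple(f"ch{i}" for i in range(arr.shape[-1]))

    bit_depth = int(ij.get("focimix_bit_depth", 8 * arr.dtype.itemsize))
    interval = ij.get("finterval")
    return ImageStack(
        data=arr,
        voxel_size_um=voxel_size_um,
        channel_names=channel_names,
        bit_depth=bit_depth,
        frame_interval_min=None if interval is None else float(interval) / 60.0,
    )


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV in the fixed column order.

    Missing provenance columns are added empty; unknown extra columns are
    appended after the standard ones so no information is dropped.
    """
    table = table.copy()
    for col in RESULT_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    extra = [c for c in table.columns if c not in RESULT_COLUMNS]
    if extra:
        warnings.warn(f"non-standard result columns appended: {extra}")
    table = table[RESULT_COLUMNS + extra]
    table.to_csv(Path(path), index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
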