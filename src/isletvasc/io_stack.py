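"""Reading and writing calibrated image stacks, masks and small tables.

Canonical on-disk dialect is OME-TIFF with physical voxel spacing in
micrometres.  Plain TIFF is accepted read-only, but only with an explicit
spacing override: a stack without calibration is an error, never a silent
1 µm default.  Axis order is z, y, x throughout; the physical coordinate of
voxel index ``i`` along an axis is ``i * spacing`` (0-based voxel centres).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "SegmentationMask",
    "CalibrationError",
    "read_stack",
    "write_stack",
    "write_stacks",
    "read_mask",
    "write_mask",
    "load_measurements",
]

_MICRON_ALIASES = {"µm", "um", "micron", "microns", "micrometer", "micrometre", "µm", "μm"}


class CalibrationError(ValueError):
    """Raised when voxel spacing cannot be determined and none was supplied."""


def _as_spacing(spacing_um) -> tuple[float, float, float]:
    s = tuple(float(v) for v in spacing_um)
    if len(s) != 3:
        raise ValueError(f"spacing_um must have 3 entries (z, y, x), got {spacing_um!r}")
    if any(not np.isfinite(v) or v <= 0 for v in s):
        raise ValueError(f"spacing_um must be strictly positive and finite, got {s}")
    return s


@dataclass
class ImageStack:
    """A single-channel 3D intensity volume with physical calibration.

    Attributes
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Non-negative intensities, integer or floating point.
    spacing_um : (float, float, float)
        Voxel spacing along z, y, x in micrometres; strictly positive.
    channel_name : str
        Free-text channel label (e.g. ``"vessel"`` for the EGFP channel,
        ``"cell"`` for the mCherry β-cell channel).
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got shape {self.voxels.shape}")
        self.spacing_um = _as_spacing(self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the volume along z, y, x (µm)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_um))

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))


@dataclass
class SegmentationMask:
    """A binary volume aligned to an :class:`ImageStack`; True = structure."""

    voxels: np.ndarray
    spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D (z, y, x), got shape {self.voxels.shape}")
        self.spacing_um = _as_spacing(self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))

    @property
    def foreground_fraction(self) -> float:
        return float(self.voxels.mean()) if self.voxels.size else 0.0

    def volume_um3(self) -> float:
        return float(self.voxels.sum()) * self.voxel_volume_um3


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def write_stacks(stacks: list[ImageStack], path) -> None:
    """Write one or more co-registered channels as a single OME-TIFF (CZYX)."""
    if not stacks:
        raise ValueError("need at least one channel to write")
    spacing = stacks[0].spacing_um
    shape = stacks[0].shape
    for s in stacks[1:]:
        if s.shape != shape or s.spacing_um != spacing:
            raise ValueError("all channels must share shape and spacing")
    data = np.stack([np.asarray(s.voxels) for s in stacks], axis=0)
    sz, sy, sx = spacing
    metadata = {
        "axes": "CZYX",
        "PhysicalSizeZ": sz,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeY": sy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeX": sx,
        "PhysicalSizeXUnit": "µm",
        "Channel": {"Name": [s.channel_name or f"channel{i}" for i, s in enumerate(stacks)]},
    }
    tifffile.imwrite(str(path), data, ome=True, photometric="minisblack", metadata=metadata)


def write_stack(stack: ImageStack, path) -> None:
    """Write a single-channel stack as OME-TIFF, preserving dtype and spacing."""
    write_stacks([stack], path)


def _spacing_from_ome(xml: str):
    d = tifffile.xml2dict(xml)
    try:
        images = d["OME"]["Image"]
        if isinstance(images, list):
            images = images[0]
        px = images["Pixels"]
    except (KeyError, TypeError):
        return None, []
    spacing = []
    for axis in ("Z", "Y", "X"):
        v = px.get(f"PhysicalSize{axis}")
        if v is None:
            return None, _channel_names(px)
        unit = str(px.get(f"PhysicalSize{axis}Unit", "µm")).lower()
        v = float(v)
        if unit == "nm":
            v *= 1e-3
        elif unit == "mm":
            v *= 1e3
        elif unit not in {a.lower() for a in _MICRON_ALIASES}:
            raise CalibrationError(f"unsupported spacing unit {unit!r}")
        spacing.append(v)
    return tuple(spacing), _channel_names(px)


def _channel_names(px) -> list[str]:
    ch = px.get("Channel", [])
    if isinstance(ch, dict):
        ch = [ch]
    return [str(c.get("Name", "")) for c in ch if isinstance(c, dict)]


def read_stack(path, channel=None, spacing_um=None) -> ImageStack:
    """Read a (single- or multi-channel) TIFF/OME-TIFF volume.

    Parameters
    ----------
    path : path-like
    channel : str or int, optional
        Channel to extract from a multi-channel file, by OME channel name or
        0-based index.  Required when the file holds more than one channel.
    spacing_um : 3 floats, optional
        Explicit (z, y, x) spacing override.  Mandatory for files that carry
        no calibration metadata.

    Raises
    ------
    CalibrationError
        If no spacing can be found in the metadata and no override is given.
    KeyError
        If the requested channel does not exist.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        names: list[str] = []
        meta_spacing = None
        if tf.ome_metadata:
            meta_spacing, names = _spacing_from_ome(tf.ome_metadata)
        elif tf.imagej_metadata is not None:
            zsp = tf.imagej_metadata.get("spacing")
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            if zsp and xres and yres and xres.value[0]:
                meta_spacing = (
                    float(zsp),
                    yres.value[1] / yres.value[0],
                    xres.value[1] / xres.value[0],
                )

    if spacing_um is not None:
        spacing = _as_spacing(spacing_um)
    elif meta_spacing is not None:
        spacing = _as_spacing(meta_spacing)
    else:
        raise CalibrationError(
            f"{path.name}: no voxel spacing in metadata; pass spacing_um=(z, y, x) explicitly"
        )

    # Normalize to (C?)ZYX
    if axes.endswith("YX"):
        pass
    else:
        raise ValueError(f"unsupported axis layout {axes!r}")
    if data.ndim == 2:
        data = data[np.newaxis]
        axes = "Z" + axes[-2:]
    if "C" in axes and data.ndim == 4:
        cax = axes.index("C")
        if channel is None:
            if data.shape[cax] == 1:
                idx = 0
            else:
                raise KeyError(
                    f"{path.name} has {data.shape[cax]} channels {names or ''}; pass channel="
                )
        elif isinstance(channel, str):
            if channel not in names:
                raise KeyError(f"channel {channel!r} not in {names}")
            idx = names.index(channel)
        else:
            idx = int(channel)
            if not 0 <= idx < data.shape[cax]:
                raise KeyError(f"channel index {idx} out of range for {data.shape[cax]} channels")
        data = np.take(data, idx, axis=cax)
        name = names[idx] if idx < len(names) else str(channel)
    else:
        if channel is not None and isinstance(channel, str) and names and channel not in names:
            raise KeyError(f"channel {channel!r} not in {names}")
        name = names[0] if names else ""
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume after channel selection, got shape {data.shape}")
    return ImageStack(voxels=data, spacing_um=spacing, channel_name=name)


def write_mask(mask: SegmentationMask, path) -> None:
    """Write a binary mask as an 8-bit 0/255 OME-TIFF."""
    stack = ImageStack(
        voxels=(mask.voxels.astype(np.uint8) * 255),
        spacing_um=mask.spacing_um,
        channel_name="mask",
    )
    write_stack(stack, path)


def read_mask(path, spacing_um=None) -> SegmentationMask:
    stack = read_stack(path, spacing_um=spacing_um)
    return SegmentationMask(voxels=stack.voxels > 0, spacing_um=stack.spacing_um)


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = ("subject_id", "group", "variable", "value")


def load_measurements(path) -> pd.DataFrame:
    """Load a per-subject measurement table.

    CSV with header ``subject_id,group,variable,value``.  Values must be
    finite; each (variable) comparison must involve exactly two group levels,
    which is validated downstream at comparison time.
    """
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns {missing}")
    df = df.loc[:, list(MEASUREMENT_COLUMNS)].copy()
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
        raise ValueError("measurement values must be finite")
    return df
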