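"""Containers and on-disk formats.

The central in-memory object is :class:`ImageStack`, a multi-channel 3D
volume with physical voxel sizes in micrometres (z, y, x order throughout).
Stacks round-trip through OME-TIFF with the channel axis explicit and the
voxel size recorded in the OME pixel metadata; boolean masks are stored as
single-channel 8-bit TIFFs and scalar ground truth as JSON sidecars.
"""
from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "write_ome_tiff", "read_ome_tiff", "write_mask", "read_mask"]


@dataclass
class ImageStack:
    """A (channel, z, y, x) intensity volume with physical calibration.

    Parameters
    ----------
    voxels
        Float array of shape ``(C, Z, Y, X)``; intensities must be finite.
    channel_names
        One name per channel, e.g. ``["DAPI", "GFP", "pH3"]``.
    voxel_size_um
        Physical voxel edge lengths ``(z, y, x)`` in micrometres, all > 0.
    """

    voxels: np.ndarray
    channel_names: list[str]
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 4:
            raise ValueError(f"expected (C, Z, Y, X) array, got shape {self.voxels.shape}")
        if self.voxels.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length does not match the channel axis")
        if self.voxels.shape[0] < 1:
            raise ValueError("at least one channel is required")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be three positive reals (z, y, x)")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    def channel(self, name: str) -> np.ndarray:
        """Return the (Z, Y, X) volume of the named channel."""
        if name not in self.channel_names:
            raise KeyError(
                f"unknown channel {name!r}; available channels: {self.channel_names}"
            )
        return self.voxels[self.channel_names.index(name)]


def write_ome_tiff(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF with channel names and voxel size in metadata."""
    path = Path(path)
    dz, dy, dx = stack.voxel_size_um
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": list(stack.channel_names)},
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
        },
    )
    return path


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_ome_tiff(path: str | Path) -> ImageStack:
    """Read an OME-TIFF written by :func:`write_ome_tiff` back into an ImageStack."""
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        ome_xml = tif.ome_metadata
    if axes == "ZYX":  # single channel collapsed
        data = data[None]
        axes = "CZYX"
    if axes != "CZYX":
        # reorder whatever axes tifffile reports into CZYX
        order = [axes.index(a) for a in "CZYX"]
        data = np.transpose(data, order)
    names: list[str] = []
    voxel = [1.0, 1.0, 1.0]
    if ome_xml:
        root = ET.fromstring(ome_xml)
        for el in root.iter():
            tag = _strip_ns(el.tag)
            if tag == "Pixels":
                voxel = [
                    float(el.get("PhysicalSizeZ", 1.0)),
                    float(el.get("PhysicalSizeY", 1.0)),
                    float(el.get("PhysicalSizeX", 1.0)),
                ]
            elif tag == "Channel" and el.get("Name"):
                names.append(el.get("Name"))
    if len(names) != data.shape[0]:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return ImageStack(data.astype(np.float32), names, tuple(voxel))


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean or small-integer label volume as an 8-bit TIFF."""
    path = Path(path)
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    tifffile.imwrite(path, arr)
    return path


def read_mask(path: str | Path, as_bool: bool = True) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr.astype(bool) if as_bool else arr


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))
    return path
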