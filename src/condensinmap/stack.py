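"""Voxel-grid image container with physical metadata and OME-TIFF I/O.

Conventions used throughout the package: arrays are indexed ``(z, y, x)``
(a leading channel axis where multi-channel), voxel indices are 0-based,
and physical positions are in nanometres at voxel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A 2-4D fluorescence image with voxel-size metadata.

    ``data`` is ``(z, y, x)`` for a single channel or ``(c, z, y, x)``
    with ``channels`` naming the leading axis.  ``voxel_size_nm`` is
    ``(z, y, x)`` in nanometres.
    """

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float]
    channels: tuple[str, ...] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.channels is not None and self.data.ndim != 4:
            raise ValueError("channel names given but data has no channel axis")
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        vz, vy, vx = self.voxel_size_nm
        return vz * vy * vx * 1e-9  # nm^3 -> um^3

    def channel(self, name: str) -> "ImageStack":
        if self.channels is None:
            raise KeyError("stack has no named channels")
        idx = self.channels.index(name)
        return ImageStack(self.data[idx], self.voxel_size_nm, meta=dict(self.meta))

    def voxel_centers_nm(self, indices: np.ndarray) -> np.ndarray:
        """Physical (z, y, x) positions in nm of 0-based voxel indices."""
        return np.asarray(indices, dtype=float) * np.asarray(self.voxel_size_nm)

    def write_ome_tiff(self, path) -> None:
        vz, vy, vx = self.voxel_size_nm
        data = self.data
        axes = "CZYX" if data.ndim == 4 else "ZYX"
        metadata = {
            "axes": axes,
            "PhysicalSizeX": vx / 1000.0,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": vy / 1000.0,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": vz / 1000.0,
            "PhysicalSizeZUnit": "µm",
        }
        if self.channels is not None:
            metadata["Channel"] = {"Name": list(self.channels)}
        tifffile.imwrite(path, data.astype(np.float32), ome=True, metadata=metadata)


def read_ome_tiff(path) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ome = tif.ome_metadata
    voxel = _voxel_size_from_ome(ome)
    if voxel is None:
        raise ValueError(f"{path}: missing voxel-size metadata")
    channels = None
    if data.ndim == 4:
        channels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return ImageStack(data, voxel, channels=channels)


def _voxel_size_from_ome(ome: str | None) -> tuple[float, float, float] | None:
    if not ome:
        return None
    import re

    def grab(axis: str) -> float | None:
        m = re.search(rf'PhysicalSize{axis}="([\d.eE+-]+)"', ome)
        return float(m.group(1)) * 1000.0 if m else None  # µm -> nm

    sizes = tuple(grab(a) for a in "ZYX")
    if any(s is None for s in sizes):
        return None
    return sizes  # type: ignore[return-value]
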