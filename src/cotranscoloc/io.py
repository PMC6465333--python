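"""TIFF and CSV I/O helpers.

Stacks are written as ImageJ-compatible multi-page TIFF in ZYX order;
label masks as 16-bit single-page TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .datatypes import VolumetricImage


def write_stack(path, image: VolumetricImage) -> None:
    dtype = np.uint8 if image.bit_depth <= 8 else np.uint16
    tifffile.imwrite(
        Path(path),
        image.data.astype(dtype),
        imagej=True,
        metadata={"axes": "ZYX"},
        resolution=(1e7 / image.voxel_xy_nm, 1e7 / image.voxel_xy_nm),  # px per cm
    )


def read_stack(
    path, voxel_xy_nm: float = 70.0, voxel_z_nm: float = 300.0, bit_depth: int | None = None
) -> VolumetricImage:
    data = tifffile.imread(Path(path))
    if data.ndim == 2:
        data = data[None]
    if bit_depth is None:
        bit_depth = 8 if data.dtype.itemsize == 1 else 16
    return VolumetricImage(
        data=np.asarray(data), voxel_xy_nm=voxel_xy_nm, voxel_z_nm=voxel_z_nm,
        bit_depth=bit_depth,
    )


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(labels).astype(np.uint16))


def read_labels(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path))).astype(np.int32)
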