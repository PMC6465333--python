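"""Shared in-memory containers for the imaging pipeline.

Conventions used throughout the package:

* image arrays are ``(z, y, x)``, 0-based voxel indices;
* physical spot coordinates are nanometres, with the centre of voxel
  ``i`` at ``i * voxel_size`` along each axis;
* masks are 2D label images (0 = background) applied to 3D spots by
  ``(y, x)`` containment only, mirroring manual 2D outlines combined
  with 3D detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPOT_COLUMNS = ["channel", "x_nm", "y_nm", "z_nm", "intensity", "quality", "flags"]


@dataclass
class VolumetricImage:
    """A single-channel 3D intensity grid with physical voxel sizes.

    Parameters
    ----------
    data : ndarray, shape (z, y, x)
        Intensity grid.
    voxel_xy_nm : float
        Lateral pixel size in nanometres (default 70 nm).
    voxel_z_nm : float
        Axial spacing in nanometres (default 300 nm).
    bit_depth : int
        Nominal camera bit depth (values live in ``[0, 2**bit_depth - 1]``).
    """

    data: np.ndarray
    voxel_xy_nm: float = 70.0
    voxel_z_nm: float = 300.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a (z, y, x) array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.voxel_xy_nm <= 0 or self.voxel_z_nm <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_extent_nm(self) -> tuple[float, float, float]:
        """Physical (z, y, x) extent in nm spanned by voxel centres."""
        nz, ny, nx = self.data.shape
        return (
            (nz - 1) * self.voxel_z_nm,
            (ny - 1) * self.voxel_xy_nm,
            (nx - 1) * self.voxel_xy_nm,
        )


@dataclass
class SpotSet:
    """Sub-voxel 3D spot coordinates with intensities for one channel.

    ``table`` is a DataFrame with columns ``channel, x_nm, y_nm, z_nm,
    intensity, quality, flags`` — the same schema written to spot CSVs by the
    detector and the simulator. ``settings`` records the detection settings
    verbatim; identical settings must be used when conditions are compared.
    """

    table: pd.DataFrame
    channel: str = "ch1"
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"spot table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_coords(
        cls,
        coords_nm: np.ndarray,
        channel: str = "ch1",
        intensity: np.ndarray | float = 1.0,
        quality: np.ndarray | float = 1.0,
        flags: str = "",
        settings: dict | None = None,
    ) -> "SpotSet":
        """Build a SpotSet from an ``(n, 3)`` array of (z, y, x) nm coordinates."""
        coords_nm = np.atleast_2d(np.asarray(coords_nm, dtype=float))
        if coords_nm.size == 0:
            coords_nm = coords_nm.reshape(0, 3)
        if coords_nm.shape[1] != 3:
            raise ValueError("coords_nm must be (n, 3) as (z, y, x)")
        n = len(coords_nm)
        table = pd.DataFrame(
            {
                "channel": channel,
                "x_nm": coords_nm[:, 2],
                "y_nm": coords_nm[:, 1],
                "z_nm": coords_nm[:, 0],
                "intensity": np.broadcast_to(np.asarray(intensity, dtype=float), n).copy(),
                "quality": np.broadcast_to(np.asarray(quality, dtype=float), n).copy(),
                "flags": flags,
            }
        )
        return cls(table=table, channel=channel, settings=settings or {})

    def coords_nm(self) -> np.ndarray:
        """Return spot coordinates as an ``(n, 3)`` array of (z, y, x) in nm."""
        return self.table[["z_nm", "y_nm", "x_nm"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, channel: str | None = None) -> "SpotSet":
        table = pd.read_csv(path, keep_default_na=False, na_values=[])
        if "flags" not in table.columns:
            table["flags"] = ""
        table["flags"] = table["flags"].astype(str)
        if channel is not None:
            table = table[table["channel"] == channel]
        name = channel
        if name is None:
            uniq = table["channel"].unique()
            name = str(uniq[0]) if len(uniq) else "ch1"
        return cls(table=table.reset_index(drop=True), channel=str(name))


class GeometryError(ValueError):
    """Raised when cell/nucleus masks violate the geometry contract."""


@dataclass
class CellGeometry:
    """2D cell and nucleus label masks with per-cell cytoplasm.

    Invariants enforced at construction: masks share a shape, every nucleus
    label has a matching cell label, each nucleus lies inside its cell, and
    labels are positive integers. Cells whose cytoplasm (cell minus nucleus)
    is empty are kept but flagged non-analysable.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    diagnostics: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cell_labels = np.asarray(self.cell_labels)
        self.nucleus_labels = np.asarray(self.nucleus_labels)
        if self.cell_labels.shape != self.nucleus_labels.shape:
            raise GeometryError("cell and nucleus masks differ in shape")
        if self.cell_labels.ndim != 2:
            raise GeometryError("masks must be 2D")
        if (self.cell_labels < 0).any() or (self.nucleus_labels < 0).any():
            raise GeometryError("labels must be non-negative integers")
        nuc_ids = set(np.unique(self.nucleus_labels)) - {0}
        cell_ids = set(np.unique(self.cell_labels)) - {0}
        orphans = nuc_ids - cell_ids
        if orphans:
            raise GeometryError(f"nucleus labels without matching cell: {sorted(orphans)}")
        for lab in sorted(nuc_ids):
            inside = self.cell_labels[self.nucleus_labels == lab]
            if not (inside == lab).all():
                raise GeometryError(f"nucleus {lab} extends outside cell {lab}")

    @property
    def cell_ids(self) -> list[int]:
        if not hasattr(self, "_cell_ids"):
            self._cell_ids = sorted(int(v) for v in np.unique(self.cell_labels) if v != 0)
        return self._cell_ids

    def cell_mask(self, cell_id: int) -> np.ndarray:
        self._check_id(cell_id)
        return self.cell_labels == cell_id

    def nucleus_mask(self, cell_id: int) -> np.ndarray:
        self._check_id(cell_id)
        return self.nucleus_labels == cell_id

    def cytoplasm_mask(self, cell_id: int) -> np.ndarray:
        """Cytoplasm of a cell: the cell footprint minus its nucleus."""
        if not hasattr(self, "_cyto_cache"):
            self._cyto_cache: dict[int, np.ndarray] = {}
        if cell_id not in self._cyto_cache:
            self._cyto_cache[cell_id] = self.cell_mask(cell_id) & ~self.nucleus_mask(cell_id)
        return self._cyto_cache[cell_id]

    def analysable_cells(self) -> list[int]:
        """Cells with a non-empty cytoplasm."""
        return [cid for cid in self.cell_ids if self.cytoplasm_mask(cid).any()]

    def _check_id(self, cell_id: int) -> None:
        if cell_id not in self.cell_ids:
            raise KeyError(f"unknown cell_id {cell_id}; valid labels: {self.cell_ids}")


@dataclass
class MatchSet:
    """Gated optimal pairing between two spot sets.

    ``pairs`` holds ``(index_a, index_b, distance_nm)`` rows; all distances
    are <= ``d_max_nm`` and each index appears in at most one pair.
    """

    pairs: pd.DataFrame  # columns: index_a, index_b, distance_nm
    unmatched_a: np.ndarray
    unmatched_b: np.ndarray
    d_max_nm: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if len(self.pairs) + len(self.unmatched_a) != self.n_a:
            raise ValueError("matched + unmatched counts must equal cloud A size")
        if len(self.pairs) + len(self.unmatched_b) != self.n_b:
            raise ValueError("matched + unmatched counts must equal cloud B size")
        if len(self.pairs) and (self.pairs["distance_nm"] > self.d_max_nm + 1e-9).any():
            raise ValueError("pair distance exceeds gating radius d_max")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def total_cost_nm(self) -> float:
        return float(self.pairs["distance_nm"].sum()) if len(self.pairs) else 0.0


def warn(message: str) -> None:
    warnings.warn(message, stacklevel=3)
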