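"""3D scalar volumes with a voxel-to-world affine."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VolumeGrid:
    """A 3D scalar map plus a 4x4 voxel-index -> world-mm affine.

    ``data`` may carry effect sizes, t-statistics, tissue probabilities
    or correlations depending on the role of the volume; missing values
    are encoded as NaN.
    """

    data: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm along each array axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return self.affine[:3, :3] @ ijk + self.affine[:3, 3]

    def world_to_voxel(self, xyz) -> np.ndarray:
        """Continuous voxel coordinates of a world-mm point."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return inv[:3, :3] @ xyz + inv[:3, 3]

    def nearest_voxel(self, xyz) -> tuple[int, int, int]:
        """Snap a world-mm coordinate to the nearest voxel index.

        Ties (.5 fractions) round half away from zero. Raises
        ``ValueError`` naming the coordinate if it falls outside the
        grid.
        """
        cont = self.world_to_voxel(xyz)
        idx = np.trunc(cont + np.copysign(0.5, cont)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise ValueError(
                f"coordinate {tuple(np.asarray(xyz, dtype=float))} maps to voxel "
                f"{tuple(idx)} outside grid of shape {self.shape}"
            )
        return tuple(int(i) for i in idx)

    def copy_with(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid with the same affine and new data."""
        return VolumeGrid(np.asarray(data, dtype=float), self.affine.copy())


def check_same_geometry(grids, what: str = "volumes") -> None:
    """Raise ValueError unless all grids share shape and affine."""
    first = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if g.shape != first.shape:
            raise ValueError(
                f"{what}: shape mismatch at index {i}: "
                f"{g.shape} vs {first.shape}"
            )
        if not np.allclose(g.affine, first.affine, atol=1e-6):
            raise ValueError(f"{what}: affine mismatch at index {i}")
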