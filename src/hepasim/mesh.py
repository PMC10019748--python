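"""Cartesian voxel mesh for the tissue microenvironment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelMesh", "OutsideDomainError"]


class OutsideDomainError(ValueError):
    """A queried position lies outside the simulation domain."""


@dataclass(frozen=True)
class VoxelMesh:
    """Uniform cubic-voxel Cartesian mesh.

    Lengths are in micrometres.  ``origin`` is the corner of voxel
    ``(0, 0, 0)``; voxel centres sit at ``origin + (i + 0.5) * dx``.
    """

    nx: int
    ny: int
    nz: int
    dx: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel counts must be >= 1")
        if self.dx <= 0:
            raise ValueError("voxel edge length must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def voxel_volume(self) -> float:
        """Volume of one cubic voxel (µm³)."""
        return self.dx**3

    @property
    def extent(self) -> np.ndarray:
        """Physical side lengths of the domain (µm)."""
        return np.array([self.nx, self.ny, self.nz]) * self.dx

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.origin) + 0.5 * self.extent

    def voxel_of(self, positions: np.ndarray) -> np.ndarray:
        """Map positions (shape (..., 3), µm) to integer voxel indices.

        Raises
        ------
        OutsideDomainError
            Naming the first violated axis if any position leaves the domain.
        """
        p = np.atleast_2d(np.asarray(positions, dtype=float))
        rel = (p - np.asarray(self.origin)) / self.dx
        idx = np.floor(rel).astype(np.int64)
        shape = np.array(self.shape)
        for ax, name in enumerate("xyz"):
            lo = idx[:, ax] < 0
            hi = idx[:, ax] >= shape[ax]
            # positions exactly on the upper face belong to the last voxel
            on_face = hi & np.isclose(rel[:, ax], shape[ax])
            idx[on_face, ax] = shape[ax] - 1
            hi &= ~on_face
            if np.any(lo | hi):
                bad = int(np.argmax(lo | hi))
                raise OutsideDomainError(
                    f"position {p[bad]} outside domain along axis {name!r}"
                )
        if np.asarray(positions).ndim == 1:
            return idx[0]
        return idx

    def voxel_center(self, ijk) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return np.asarray(self.origin) + (ijk + 0.5) * self.dx

    def centers(self) -> np.ndarray:
        """Array of all voxel centres, shape (nx, ny, nz, 3)."""
        ax = [
            np.asarray(self.origin)[a] + (np.arange(self.shape[a]) + 0.5) * self.dx
            for a in range(3)
        ]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def contains(self, positions: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(positions, dtype=float))
        lo = np.asarray(self.origin)
        hi = lo + self.extent
        ok = np.all((p >= lo) & (p <= hi), axis=1)
        return ok if np.asarray(positions).ndim > 1 else bool(ok[0])
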