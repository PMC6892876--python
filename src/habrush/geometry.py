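"""Voxel geometry and the in-memory image-stack container.

All physical lengths inside the package are nanometres; reports convert to
micrometres.  Voxel indices are 0-based with half-open extents, and the
physical coordinate of voxel ``i`` along an axis is ``i * pitch`` (the centre
of voxel 0 sits at the origin).  Arrays are ordered ``(C, Z, Y, X)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = ["VoxelGeometry", "ImageStack"]


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel pitch of a confocal stack, in nm.

    Defaults match a high-NA confocal acquisition of brushes on microspheres:
    50 nm lateral pixels with a 470 nm axial step.  Planar-brush stacks are
    typically acquired with a finer 100 nm axial step; pass ``dz=100`` there.
    """

    dx: float = 50.0
    dy: float = 50.0
    dz: float = 470.0
    origin: str = "voxel-center"  # coordinate of voxel index 0 along each axis

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            if not getattr(self, name) > 0:
                raise DomainError(f"voxel pitch {name} must be > 0")

    @property
    def anisotropy(self) -> float:
        """Axial-to-lateral pitch ratio dz/dx."""
        return self.dz / self.dx

    @property
    def spacing_zyx_nm(self) -> np.ndarray:
        return np.array([self.dz, self.dy, self.dx], dtype=float)

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz * 1e-9

    def extent_nm(self, shape_zyx: tuple[int, int, int]) -> np.ndarray:
        """Physical coordinate of the last voxel centre along each axis."""
        return (np.asarray(shape_zyx, dtype=float) - 1) * self.spacing_zyx_nm


@dataclass
class ImageStack:
    """A multichannel 3-D fluorescence stack with its voxel geometry.

    ``data`` has shape ``(C, Z, Y, X)``; ``channels`` names each channel
    (e.g. ``("brush", "surface", "particles")``).
    """

    data: np.ndarray
    geom: VoxelGeometry
    channels: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise DomainError("ImageStack data must be (C, Z, Y, X)")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise DomainError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} channels"
            )

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:])  # type: ignore[return-value]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channels}"
            ) from None
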