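"""Multi-channel 3D image stacks with physical voxel geometry.

Axis order is (z, y, x) throughout; all physical quantities are in
micrometres (um) and cubic micrometres (um^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A named collection of co-registered 3D intensity volumes.

    Parameters
    ----------
    channels
        Mapping from channel (marker) name to a 3D ``(z, y, x)`` array of
        non-negative, finite intensities. All channels must share one shape.
    voxel_size_zyx
        Physical voxel size in um per axis, e.g. ``(0.3, 0.18, 0.18)`` for
        a confocal stack sampled at 0.18 um laterally and 0.3 um axially.
    stack_id, case_id
        Provenance identifiers carried into every derived table.
    """

    channels: dict[str, np.ndarray]
    voxel_size_zyx: tuple[float, float, float] = (0.3, 0.18, 0.18)
    stack_id: str = ""
    case_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack requires at least one channel")
        self.voxel_size_zyx = tuple(float(v) for v in self.voxel_size_zyx)
        if len(self.voxel_size_zyx) != 3 or any(v <= 0 for v in self.voxel_size_zyx):
            raise ValueError(f"voxel sizes must be three positive values, got {self.voxel_size_zyx}")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 3 for s in shapes.values()):
            raise ValueError(f"channels must be 3D (z, y, x); got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"all channels must share one shape; got {shapes}")
        for name, arr in self.channels.items():
            a = np.asarray(arr)
            if not np.issubdtype(a.dtype, np.number):
                raise ValueError(f"channel {name!r} is not numeric")
            if np.issubdtype(a.dtype, np.floating) and not np.isfinite(a).all():
                raise ValueError(f"channel {name!r} contains non-finite intensities")
            if a.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_um3(self) -> float:
        vz, vy, vx = self.voxel_size_zyx
        return vz * vy * vx

    @property
    def volume_um3(self) -> float:
        """Physical volume of the whole stack."""
        return float(np.prod(self.shape)) * self.voxel_volume_um3

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            ) from None
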