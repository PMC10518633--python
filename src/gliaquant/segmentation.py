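"""Adaptive local-mean thresholding and 3D connected-component extraction.

Each channel is binarised slice by slice with an adaptive mean threshold
(a voxel is foreground when its intensity exceeds the local window mean
minus a constant offset), then objects are assembled as 3D connected
components across slices. This mirrors the classic auto-local-threshold
segmentation used for immunofluorescence burden quantification, where
fixed window/offset presets are applied identically to every image so the
resulting burdens are comparable across cases.

Shipped presets (window size in pixels, offset in native intensity counts):

====== ====== ======
marker window offset
====== ====== ======
CD68   70     0.2
Syn1   10     1.0
GFAP   70     0.15
====== ====== ======

Synaptophysin (``SyO``) reuses the synapsin preset; MAP2 and P2Y12 reuse
the GFAP preset (filamentous morphologies segmented with the same
wide-window setting). The offset is applied on the image's native count
scale and acts as a strictness margin: a voxel must exceed the local mean
by more than ``c_offset`` to be foreground, so flat or pure-background
windows produce no foreground at any positive offset, while a negative
offset relaxes the rule below the local mean (flat input then segments
entirely as one stack-spanning object).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stack import ImageStack

__all__ = [
    "SegmentationParams",
    "SegmentedObject",
    "ObjectSet",
    "PRESETS",
    "local_mean_threshold",
    "label_components",
    "segment_stack",
]

_STRUCTURES = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class SegmentationParams:
    """Adaptive-threshold settings for one channel.

    window_size
        Side of the square in-plane averaging window, in pixels. Even
        windows span ``floor((w-1)/2)`` pixels before and ``ceil((w-1)/2)``
        after the centre pixel. Edges are handled by replicate padding.
    c_offset
        Margin added to the local mean, in the image's native intensity
        units. Foreground is strictly ``intensity > mean + c``.
    method
        Only ``"mean"`` is supported.
    min_size
        Optional minimum object size in voxels; ``None`` keeps everything.
    """

    window_size: int = 70
    c_offset: float = 0.2
    method: str = "mean"
    min_size: int | None = None

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError(f"window_size must be >= 1, got {self.window_size}")
        if self.method != "mean":
            raise ValueError(f"unsupported threshold method {self.method!r}")
        if self.min_size is not None and self.min_size < 1:
            raise ValueError("min_size must be a positive voxel count or None")


#: Fixed per-marker presets applied identically to every stack.
PRESETS: dict[str, SegmentationParams] = {
    "CD68": SegmentationParams(window_size=70, c_offset=0.2),
    "Syn1": SegmentationParams(window_size=10, c_offset=1.0),
    "GFAP": SegmentationParams(window_size=70, c_offset=0.15),
    "SyO": SegmentationParams(window_size=10, c_offset=1.0),
    "MAP2": SegmentationParams(window_size=70, c_offset=0.15),
    "P2Y12": SegmentationParams(window_size=70, c_offset=0.15),
    "ThioS": SegmentationParams(window_size=70, c_offset=0.2),
}


@dataclass
class SegmentedObject:
    """One 3D connected component of a binarised channel."""

    object_id: int
    channel: str
    voxel_count: int
    volume_um3: float
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # (lo, hi) per axis
    centroid_zyx: tuple[float, float, float]


@dataclass
class ObjectSet:
    """All objects of one channel, backed by an integer label volume.

    ``labels`` is 0 for background and ``object_id`` elsewhere; per-object
    voxel coordinate lists are recovered on demand from the label volume.
    """

    labels: np.ndarray
    objects: list[SegmentedObject]
    channel: str
    voxel_size_zyx: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.objects)

    @property
    def voxel_counts(self) -> dict[int, int]:
        return {o.object_id: o.voxel_count for o in self.objects}

    def coords(self, object_id: int) -> np.ndarray:
        """(n, 3) array of (z, y, x) voxel coordinates of one object."""
        obj = next((o for o in self.objects if o.object_id == object_id), None)
        if obj is None:
            raise KeyError(f"no object with id {object_id}")
        (z0, z1), (y0, y1), (x0, x1) = obj.bbox
        sub = self.labels[z0:z1, y0:y1, x0:x1]
        local = np.argwhere(sub == object_id)
        return local + np.array([z0, y0, x0])

    @property
    def total_voxels(self) -> int:
        return int(sum(o.voxel_count for o in self.objects))

    @property
    def total_volume_um3(self) -> float:
        return float(sum(o.volume_um3 for o in self.objects))

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "channel": o.channel,
                "object_id": o.object_id,
                "voxel_count": o.voxel_count,
                "volume_um3": o.volume_um3,
                "z0": o.bbox[0][0], "z1": o.bbox[0][1],
                "y0": o.bbox[1][0], "y1": o.bbox[1][1],
                "x0": o.bbox[2][0], "x1": o.bbox[2][1],
                "centroid_z": o.centroid_zyx[0],
                "centroid_y": o.centroid_zyx[1],
                "centroid_x": o.centroid_zyx[2],
            }
            for o in self.objects
        ]
        return pd.DataFrame(
            rows,
            columns=["channel", "object_id", "voxel_count", "volume_um3",
                     "z0", "z1", "y0", "y1", "x0", "x1",
                     "centroid_z", "centroid_y", "centroid_x"],
        )


def local_mean_threshold(channel: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Binarise a 3D volume with a per-slice adaptive mean threshold.

    For every voxel the mean intensity of the ``window_size`` x
    ``window_size`` in-plane neighbourhood (replicate-padded at slice
    edges) is computed on its own z-slice, and the voxel is foreground iff
    its intensity is strictly greater than that mean plus ``c_offset``.
    """
    vol = np.asarray(channel)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D (z, y, x) volume, got shape {vol.shape}")
    if np.issubdtype(vol.dtype, np.floating) and not np.isfinite(vol).all():
        raise ValueError("volume contains non-finite intensities")
    w = int(params.window_size)
    out = np.empty(vol.shape, dtype=bool)
    f = vol.astype(np.float64, copy=False)
    origin = -1 if w % 2 == 0 else 0  # even windows: floor((w-1)/2) before
    for z in range(vol.shape[0]):
        local_mean = ndi.uniform_filter(f[z], size=w, mode="nearest",
                                        origin=origin)
        out[z] = f[z] > local_mean + params.c_offset
    return out


def label_components(
    mask: np.ndarray,
    connectivity: int = 26,
    voxel_size_zyx: tuple[float, float, float] = (0.3, 0.18, 0.18),
    channel: str = "",
    min_size: int | None = None,
) -> ObjectSet:
    """Extract maximal 3D connected components of a binary mask.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (faces+edges+
    corners). Components smaller than ``min_size`` voxels are dropped from
    both the object list and the label volume.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError(f"expected a 3D mask, got shape {mask.shape}")
    labels, n = ndi.label(mask, structure=_STRUCTURES[connectivity])
    voxel_vol = float(np.prod(voxel_size_zyx))
    if n == 0:
        return ObjectSet(labels=labels, objects=[], channel=channel,
                         voxel_size_zyx=tuple(voxel_size_zyx))
    counts = np.bincount(labels.ravel())[1:]  # per object id 1..n
    keep = np.ones(n, dtype=bool)
    if min_size is not None:
        keep = counts >= min_size
    slices = ndi.find_objects(labels)
    centroids = ndi.center_of_mass(mask, labels, np.arange(1, n + 1))
    objects: list[SegmentedObject] = []
    for oid in range(1, n + 1):
        if not keep[oid - 1]:
            labels[slices[oid - 1]][labels[slices[oid - 1]] == oid] = 0
            continue
        sl = slices[oid - 1]
        objects.append(
            SegmentedObject(
                object_id=oid,
                channel=channel,
                voxel_count=int(counts[oid - 1]),
                volume_um3=float(counts[oid - 1]) * voxel_vol,
                bbox=tuple((s.start, s.stop) for s in sl),
                centroid_zyx=tuple(float(c) for c in centroids[oid - 1]),
            )
        )
    return ObjectSet(labels=labels, objects=objects, channel=channel,
                     voxel_size_zyx=tuple(voxel_size_zyx))


def segment_stack(
    stack: ImageStack,
    presets: dict[str, SegmentationParams] | None = None,
    channels: list[str] | None = None,
    connectivity: int = 26,
) -> dict[str, ObjectSet]:
    """Threshold and label the requested channels of a stack.

    ``presets`` defaults to the shipped per-marker table; every requested
    channel must have either an entry there or in the shipped table.
    """
    names = channels if channels is not None else list(stack.channels)
    table = dict(PRESETS)
    if presets:
        table.update(presets)
    out: dict[str, ObjectSet] = {}
    for name in names:
        vol = stack.channel(name)  # raises KeyError naming the channel
        if name not in table:
            raise KeyError(f"no segmentation preset for channel {name!r}")
        p = table[name]
        mask = local_mean_threshold(vol, p)
        out[name] = label_components(
            mask, connectivity=connectivity, voxel_size_zyx=stack.voxel_size_zyx,
            channel=name, min_size=p.min_size,
        )
    return out


def params_with(base: SegmentationParams, **kw) -> SegmentationParams:
    """Convenience: a copy of ``base`` with fields replaced."""
    return replace(base, **kw)
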