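"""Object-based colocalization and engulfment burden metrics.

Two segmented objects are called colocalized when they share at least a
minimum fraction (default 25%) of a reference volume. Because a synaptic
punctum is orders of magnitude smaller than the glial arbor that may
contain it, the default reference is the smaller object of the pair,
which also makes the verdict symmetric; the anchoring object is
configurable. Triple colocalization (synaptic marker and neurite marker
inside glia) is computed at the voxel level as the intersection volume of
the three masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segmentation import ObjectSet
from .stack import ImageStack

__all__ = [
    "ColocalizationParams",
    "ColocalizationRecord",
    "CaseMetadata",
    "StackMetrics",
    "colocalize_pair",
    "colocalized_volume",
    "triple_colocalized_volume",
    "compute_stack_metrics",
    "plaque_stratify",
]

COHORTS = ("midlife control", "aged control", "AD")
REGIONS = ("BA17", "BA20/21", "synthetic")


@dataclass(frozen=True)
class ColocalizationParams:
    """Overlap rule configuration.

    min_overlap_fraction
        Minimum shared fraction of the reference object's volume for a
        pair to count as colocalized (default 0.25).
    denominator_rule
        Which object anchors the fraction: ``min_object`` (smaller of the
        pair; default), ``object_a`` or ``object_b``.
    plaque_distance_um
        Surface distance below which an object counts as "near" a plaque.
    """

    min_overlap_fraction: float = 0.25
    denominator_rule: str = "min_object"
    plaque_distance_um: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.min_overlap_fraction <= 1.0):
            raise ValueError("min_overlap_fraction must be in (0, 1]")
        if self.denominator_rule not in ("min_object", "object_a", "object_b"):
            raise ValueError(f"unknown denominator_rule {self.denominator_rule!r}")
        if self.plaque_distance_um < 0:
            raise ValueError("plaque_distance_um must be >= 0")


@dataclass
class ColocalizationRecord:
    """Overlap bookkeeping for one object pair with nonzero intersection."""

    object_a_id: int
    object_b_id: int
    overlap_voxels: int
    overlap_volume_um3: float
    fraction_of_a: float
    fraction_of_b: float
    colocalized: bool


@dataclass
class CaseMetadata:
    """Case-level covariates attached to every stack of a donor/case."""

    case_id: str
    cohort: str = "AD"
    region: str = "synthetic"
    apoe4: bool = False
    sex: str = "F"
    age: float = 0.0
    plaque_present: bool = False
    group: str = ""

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if not self.group:
            self.group = self.cohort


@dataclass
class StackMetrics:
    """Per-stack burden and colocalization summary.

    ``pair_metrics`` maps ``(target, host)`` marker pairs to dicts with the
    colocalized volume (sum of overlap volumes over colocalized object
    pairs, um^3), the same normalized to stack volume, and normalized to
    the host (glial) stained volume. The host-normalized entry is ``None``
    (flagged missing) when the host channel segmented to zero volume.
    """

    stack_id: str
    case_id: str
    stack_volume_um3: float
    channel_volume_um3: dict[str, float] = field(default_factory=dict)
    channel_volume_fraction: dict[str, float] = field(default_factory=dict)
    pair_metrics: dict[tuple[str, str], dict] = field(default_factory=dict)
    triple_volume_um3: float | None = None
    plaque_free: bool | None = None
    near_far_volumes: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "stack_id": self.stack_id,
            "case_id": self.case_id,
            "stack_volume_um3": self.stack_volume_um3,
        }
        for ch, v in self.channel_volume_um3.items():
            row[f"vol_{ch}_um3"] = v
            row[f"frac_{ch}"] = self.channel_volume_fraction[ch]
        for (a, b), m in self.pair_metrics.items():
            key = f"coloc_{a}_in_{b}"
            row[f"{key}_um3"] = m["volume_um3"]
            row[f"{key}_per_stack"] = m["per_stack_volume"]
            row[f"{key}_per_host"] = m["per_host_volume"]
        if self.triple_volume_um3 is not None:
            row["triple_coloc_um3"] = self.triple_volume_um3
        if self.plaque_free is not None:
            row["plaque_free"] = self.plaque_free
        for (a, b), d in self.near_far_volumes.items():
            row[f"coloc_{a}_in_{b}_near_um3"] = d["near"]
            row[f"coloc_{a}_in_{b}_far_um3"] = d["far"]
        return row


def _check_same_shape(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"masks must share one shape, got {sorted(shapes)}")


def colocalize_pair(
    objects_a: ObjectSet,
    objects_b: ObjectSet,
    params: ColocalizationParams | None = None,
) -> list[ColocalizationRecord]:
    """Evaluate the overlap rule for every intersecting object pair.

    Returns one record per (a, b) object pair with at least one shared
    voxel; ``colocalized`` is True when the shared voxel count reaches
    ``min_overlap_fraction`` of the reference object's voxel count.
    """
    params = params or ColocalizationParams()
    la, lb = objects_a.labels, objects_b.labels
    _check_same_shape(la, lb)
    both = (la > 0) & (lb > 0)
    if not both.any():
        return []
    pa = la[both].astype(np.int64)
    pb = lb[both].astype(np.int64)
    # joint histogram of overlapping label pairs
    key = pa * (lb.max() + 1) + pb
    uniq, counts = np.unique(key, return_counts=True)
    ids_a = uniq // (lb.max() + 1)
    ids_b = uniq % (lb.max() + 1)
    vol_a = objects_a.voxel_counts
    vol_b = objects_b.voxel_counts
    voxel_vol = float(np.prod(objects_a.voxel_size_zyx))
    records = []
    for ia, ib, c in zip(ids_a, ids_b, counts):
        na, nb = vol_a[int(ia)], vol_b[int(ib)]
        if params.denominator_rule == "min_object":
            denom = min(na, nb)
        elif params.denominator_rule == "object_a":
            denom = na
        else:
            denom = nb
        records.append(
            ColocalizationRecord(
                object_a_id=int(ia),
                object_b_id=int(ib),
                overlap_voxels=int(c),
                overlap_volume_um3=float(c) * voxel_vol,
                fraction_of_a=float(c) / na,
                fraction_of_b=float(c) / nb,
                colocalized=bool(c >= params.min_overlap_fraction * denom),
            )
        )
    return records


def records_to_frame(records: list[ColocalizationRecord]) -> pd.DataFrame:
    cols = ["object_a_id", "object_b_id", "overlap_voxels", "overlap_volume_um3",
            "fraction_of_a", "fraction_of_b", "colocalized"]
    return pd.DataFrame([vars(r) for r in records], columns=cols)


def colocalized_volume(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    voxel_size_zyx: tuple[float, float, float],
) -> float:
    """Physical volume (um^3) of the voxel-level intersection of two masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    _check_same_shape(a, b)
    return float(np.count_nonzero(a & b)) * float(np.prod(voxel_size_zyx))


def triple_colocalized_volume(
    mask_syn: np.ndarray,
    mask_neurite: np.ndarray,
    mask_glia: np.ndarray,
    voxel_size_zyx: tuple[float, float, float],
) -> float:
    """Volume (um^3) of voxels present in all three masks."""
    s = np.asarray(mask_syn, dtype=bool)
    n = np.asarray(mask_neurite, dtype=bool)
    g = np.asarray(mask_glia, dtype=bool)
    _check_same_shape(s, n, g)
    return float(np.count_nonzero(s & n & g)) * float(np.prod(voxel_size_zyx))


def colocalized_record_volume(records: list[ColocalizationRecord]) -> float:
    """Total overlap volume over pairs flagged colocalized."""
    return float(sum(r.overlap_volume_um3 for r in records if r.colocalized))


def compute_stack_metrics(
    stack: ImageStack,
    objects: dict[str, ObjectSet],
    records: dict[tuple[str, str], list[ColocalizationRecord]],
    plaque_mask: np.ndarray | None = None,
    params: ColocalizationParams | None = None,
    triple_channels: tuple[str, str, str] | None = None,
) -> StackMetrics:
    """Assemble raw and normalized burden metrics for one stack.

    ``records`` is keyed by ``(target, host)`` channel pairs, target being
    the engulfed marker (e.g. a synaptic stain) and host the engulfing
    glial stain whose volume anchors the glial normalization. When the
    host volume is zero the host-normalized metric is flagged missing
    (``None``) while all other fields remain valid.
    """
    params = params or ColocalizationParams()
    m = StackMetrics(
        stack_id=stack.stack_id,
        case_id=stack.case_id,
        stack_volume_um3=stack.volume_um3,
    )
    for ch, objset in objects.items():
        m.channel_volume_um3[ch] = objset.total_volume_um3
        m.channel_volume_fraction[ch] = objset.total_volume_um3 / stack.volume_um3
    for (target, host), recs in records.items():
        vol = colocalized_record_volume(recs)
        host_vol = objects[host].total_volume_um3 if host in objects else 0.0
        m.pair_metrics[(target, host)] = {
            "volume_um3": vol,
            "per_stack_volume": vol / stack.volume_um3,
            "per_host_volume": (vol / host_vol) if host_vol > 0 else None,
        }
    if triple_channels is not None:
        syn, neurite, glia = triple_channels
        m.triple_volume_um3 = triple_colocalized_volume(
            objects[syn].mask, objects[neurite].mask, objects[glia].mask,
            stack.voxel_size_zyx,
        )
    if plaque_mask is not None:
        plaque_mask = np.asarray(plaque_mask, dtype=bool)
        _check_same_shape(plaque_mask, next(iter(objects.values())).labels)
        m.plaque_free = not plaque_mask.any()
        if not m.plaque_free:
            for (target, host), recs in records.items():
                strata, _ = plaque_stratify(
                    objects[target], plaque_mask, params.plaque_distance_um,
                )
                near = far = 0.0
                for r in recs:
                    if not r.colocalized:
                        continue
                    if strata.get(r.object_a_id) == "near":
                        near += r.overlap_volume_um3
                    else:
                        far += r.overlap_volume_um3
                m.near_far_volumes[(target, host)] = {"near": near, "far": far}
    return m


def plaque_stratify(
    objects: ObjectSet,
    plaque_mask: np.ndarray,
    distance_um: float = 10.0,
) -> tuple[dict[int, str], bool]:
    """Label objects as near/far from the nearest plaque surface.

    Distances are Euclidean in physical units (anisotropic voxels
    respected via the sampling argument of the distance transform). An
    object is "near" when any of its voxels lies within ``distance_um`` of
    a plaque voxel. Returns ``(labels, plaque_free)``; with an empty
    plaque mask no objects are labeled and the stack is flagged
    plaque-free, to be excluded from near/far contrasts.
    """
    plaque_mask = np.asarray(plaque_mask, dtype=bool)
    _check_same_shape(plaque_mask, objects.labels)
    if not plaque_mask.any():
        return {}, True
    dist = ndi.distance_transform_edt(~plaque_mask, sampling=objects.voxel_size_zyx)
    out: dict[int, str] = {}
    if objects.objects:
        min_dist = ndi.labeled_comprehension(
            dist, objects.labels, [o.object_id for o in objects.objects],
            np.min, float, np.inf,
        )
        for o, d in zip(objects.objects, min_dist):
            out[o.object_id] = "near" if d <= distance_um else "far"
    return out, False
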