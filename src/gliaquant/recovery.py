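"""Planted-truth recovery experiments on the packaged cohort presets.

Each function generates a preset cohort, runs the real segmentation and
colocalization pipeline on the rendered images (never on the ground
truth), and summarises the recovered effect size the same way the
human-tissue analyses are summarised: case-level means first, then group
means, then their ratio. Used to validate that the pipeline recovers the
effect sizes the presets plant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .colocalization import (
    ColocalizationParams,
    colocalize_pair,
    colocalized_record_volume,
    triple_colocalized_volume,
)
from .segmentation import segment_stack
from .simulate import generate_cohort, get_cohort_preset

__all__ = [
    "overlap_decision_boundary",
    "pair_colocalization_ratio",
    "burden_ratio",
    "triple_ratio",
]


def overlap_decision_boundary(
    volume_a: int = 100,
    volume_b: int = 40,
    fractions=None,
) -> float:
    """Smallest overlap fraction (in %) at which a pair is colocalized.

    Builds voxel-object pairs (``volume_a`` and ``volume_b`` voxels) with
    the overlap swept across fractions of the smaller object's volume and
    runs pair colocalization with default parameters on each.
    """
    from .segmentation import label_components

    if fractions is None:
        fractions = np.arange(0.05, 0.5001, 0.025)
    small = min(volume_a, volume_b)
    hits = []
    for f in fractions:
        k = int(round(f * small))
        n = volume_a + volume_b - k
        base = np.zeros((1, 1, n + 2), dtype=bool)
        mask_a = base.copy()
        mask_a[0, 0, :volume_a] = True
        mask_b = base.copy()
        mask_b[0, 0, volume_a - k:volume_a - k + volume_b] = True
        objs_a = label_components(mask_a, channel="a")
        objs_b = label_components(mask_b, channel="b")
        recs = colocalize_pair(objs_a, objs_b, ColocalizationParams())
        flagged = any(r.colocalized for r in recs)
        hits.append((f, flagged))
    for f, flagged in hits:
        if flagged:
            return 100.0 * f
    return float("nan")


def _case_group_ratio(per_stack: pd.DataFrame, value: str,
                      group_a: str, group_b: str) -> float:
    case_means = per_stack.groupby(["group", "case_id"])[value].mean()
    group_means = case_means.groupby("group").mean()
    return float(group_means[group_a] / group_means[group_b])


def pair_colocalization_ratio(preset_name: str, seed: int) -> tuple[float, int]:
    """Recovered group-mean ratio of target-in-glia colocalized volume.

    Segments the synaptic and glial channels of every stack with the
    shipped presets, applies the object-overlap rule, sums the overlap
    volume of colocalized pairs per stack, and returns the ratio of group
    means of case-level mean colocalized volume (first group over second)
    together with the number of stacks analysed.
    """
    design = get_cohort_preset(preset_name)
    target = design.base.synaptic_marker
    host = design.base.resolved_glial_marker
    rows = []
    for stack, _truth, meta in generate_cohort(design, seed):
        objs = segment_stack(stack, channels=[target, host])
        recs = colocalize_pair(objs[target], objs[host])
        rows.append({
            "group": meta.group, "case_id": meta.case_id,
            "coloc_um3": colocalized_record_volume(recs),
        })
    df = pd.DataFrame(rows)
    ga, gb = design.groups[0][0], design.groups[1][0]
    return _case_group_ratio(df, "coloc_um3", ga, gb), len(df)


def burden_ratio(preset_name: str, seed: int) -> tuple[float, int]:
    """Recovered group-mean ratio of glial stained volume fraction."""
    design = get_cohort_preset(preset_name)
    host = design.base.resolved_glial_marker
    rows = []
    for stack, _truth, meta in generate_cohort(design, seed):
        objs = segment_stack(stack, channels=[host])
        frac = objs[host].total_voxels / float(np.prod(stack.shape))
        rows.append({"group": meta.group, "case_id": meta.case_id,
                     "burden": frac})
    df = pd.DataFrame(rows)
    ga, gb = design.groups[0][0], design.groups[1][0]
    return _case_group_ratio(df, "burden", ga, gb), len(df)


def triple_ratio(preset_name: str, seed: int) -> tuple[float, int]:
    """Recovered ratio of pairwise to triple colocalized volume.

    Pairwise volume follows the object-overlap rule (synaptic marker in
    glia); triple volume is the voxel-level intersection of the synaptic,
    neurite and glial masks. Both are averaged to case level and then
    over cases before the ratio is taken.
    """
    design = get_cohort_preset(preset_name)
    target = design.base.synaptic_marker
    neurite = design.base.neurite_marker
    host = design.base.resolved_glial_marker
    rows = []
    for stack, _truth, meta in generate_cohort(design, seed):
        objs = segment_stack(stack, channels=[target, neurite, host])
        recs = colocalize_pair(objs[target], objs[host])
        rows.append({
            "group": meta.group, "case_id": meta.case_id,
            "pair_um3": colocalized_record_volume(recs),
            "triple_um3": triple_colocalized_volume(
                objs[target].mask, objs[neurite].mask, objs[host].mask,
                stack.voxel_size_zyx),
        })
    df = pd.DataFrame(rows)
    case = df.groupby("case_id")[["pair_um3", "triple_um3"]].mean().mean(axis=0)
    return float(case["pair_um3"] / case["triple_um3"]), len(df)
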