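"""End-to-end orchestration: simulate -> segment -> colocalize -> stats.

``run_pipeline`` drives the full imaging branch and/or the phagocytosis
branch from a validated YAML config, writes every output table as CSV
with provenance columns (config hash and seed), and drops a JSON run
record next to them. Re-running the same config reproduces all tables
bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .colocalization import (
    ColocalizationParams,
    colocalized_record_volume,
    compute_stack_metrics,
)
from .phagocytosis import (
    curve_auc,
    curves_to_frame,
    normalize_to_final_control,
    series_to_curve,
)
from .segmentation import PRESETS, SegmentationParams, segment_stack
from .simulate import (
    CohortDesign,
    KineticsDesign,
    StackSimParams,
    generate_cohort,
    generate_timeseries,
    get_cohort_preset,
    get_kinetics_preset,
)
from .stats import fit_group_model, pairwise_contrasts

__all__ = ["run_pipeline"]

log = logging.getLogger("gliaquant")


def _setup_logging(level: str) -> None:
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(h)
    log.setLevel(getattr(logging, level.upper(), logging.INFO))


def _design_from_config(sim: dict) -> CohortDesign:
    if "preset" in sim:
        design = get_cohort_preset(sim["preset"])
        overrides = {k: v for k, v in sim.items() if k != "preset"}
        if "base" in overrides:
            design = dataclasses.replace(
                design, base=dataclasses.replace(design.base, **overrides.pop("base")))
        if overrides:
            design = dataclasses.replace(design, **_tupleize(overrides))
        return design
    base = StackSimParams(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in sim.get("base", {}).items()})
    kw = {k: v for k, v in sim.items() if k not in ("base", "groups")}
    return CohortDesign(groups=_tupleize({"groups": sim["groups"]})["groups"],
                        base=base, **kw)


def _tupleize(d: dict) -> dict:
    out = dict(d)
    if "groups" in out:
        out["groups"] = tuple(
            (g[0], float(g[1]), float(g[2])) for g in out["groups"])
    return out


def _seg_presets(seg_cfg: dict) -> dict[str, SegmentationParams]:
    out: dict[str, SegmentationParams] = {}
    for ch, p in (seg_cfg.get("presets") or {}).items():
        out[ch] = SegmentationParams(**p)
    return out


def run_pipeline(config, output_dir=None) -> dict:
    """Execute the configured stages; returns the output tables.

    Stage failures abort with a diagnostic naming the stage. Outputs:
    ``metrics`` (one row per stack), ``objects`` (one row per segmented
    object), ``stats_*`` (model fit tables), ``curves``/``auc`` for the
    phagocytosis branch, and ``run_record.json``.
    """
    cfg = gio.load_config(config)
    _setup_logging(cfg.get("log_level", "INFO"))
    outdir = Path(output_dir or cfg.get("output_dir", "gliaquant-out"))
    outdir.mkdir(parents=True, exist_ok=True)
    chash = gio.config_hash(cfg)
    seed = int(cfg.get("seed", 0))
    results: dict[str, pd.DataFrame] = {}
    record = {"config_hash": chash, "seed": seed, "stages": []}

    def _finish(df: pd.DataFrame, name: str) -> pd.DataFrame:
        df = df.copy()
        df["config_hash"] = chash
        df["seed"] = seed
        df.to_csv(outdir / f"{name}.csv", index=False)
        results[name] = df
        record["stages"].append(name)
        return df

    # ---- imaging branch
    if "simulate" in cfg or "inputs" in cfg:
        seg_cfg = cfg.get("segmentation", {}) or {}
        coloc_cfg = cfg.get("colocalization", {}) or {}
        presets = dict(PRESETS)
        presets.update(_seg_presets(seg_cfg))
        connectivity = int(seg_cfg.get("connectivity", 26))
        cparams = ColocalizationParams(
            min_overlap_fraction=float(coloc_cfg.get("min_overlap_fraction", 0.25)),
            denominator_rule=coloc_cfg.get("denominator_rule", "min_object"),
            plaque_distance_um=float(coloc_cfg.get("plaque_distance_um", 10.0)),
        )
        pairs = [tuple(p) for p in coloc_cfg.get("pairs", [])]
        triple = coloc_cfg.get("triple")
        plaque_channel = coloc_cfg.get("plaque_channel")
        metric_rows, object_rows = [], []

        def _stacks():
            if "simulate" in cfg:
                design = _design_from_config(cfg["simulate"])
                log.info("simulating cohort (%d groups x %d cases x %d stacks)",
                         len(design.groups), design.n_cases_per_group,
                         design.n_stacks_per_case)
                yield from generate_cohort(design, seed)
            for path in cfg.get("inputs", []):
                stack = gio.read_stack(path)
                yield stack, None, None

        try:
            for stack, truth, meta in _stacks():
                channels = seg_cfg.get("channels") or list(stack.channels)
                objs = segment_stack(stack, presets=presets, channels=channels,
                                     connectivity=connectivity)
                records = {}
                for target, host in pairs:
                    from .colocalization import colocalize_pair
                    records[(target, host)] = colocalize_pair(
                        objs[target], objs[host], cparams)
                plaque_mask = None
                if plaque_channel and plaque_channel in objs:
                    plaque_mask = objs[plaque_channel].mask
                m = compute_stack_metrics(
                    stack, objs, records, plaque_mask=plaque_mask,
                    params=cparams,
                    triple_channels=tuple(triple) if triple else None,
                )
                row = m.to_row()
                if meta is not None:
                    row.update({"group": meta.group, "cohort": meta.cohort,
                                "apoe4": meta.apoe4, "sex": meta.sex,
                                "age": meta.age, "region": meta.region})
                if truth is not None:
                    row["truth_engulfed_volume_um3"] = truth.engulfed_volume_um3
                    row["truth_glial_volume_um3"] = truth.glial_volume_um3
                metric_rows.append(row)
                for ch, o in objs.items():
                    df = o.to_frame()
                    df.insert(0, "stack_id", stack.stack_id)
                    df.insert(1, "case_id", stack.case_id)
                    object_rows.append(df)
                if cfg.get("write_stacks"):
                    gio.write_stack(stack, outdir / f"{stack.stack_id}.ome.tif")
        except Exception as e:
            raise RuntimeError(f"stage 'segment/colocalize' failed: {e}") from e
        metrics = _finish(pd.DataFrame(metric_rows), "metrics")
        if object_rows:
            _finish(pd.concat(object_rows, ignore_index=True), "objects")

        st = cfg.get("stats")
        if st:
            try:
                outcome = st["outcome"]
                fixed = st.get("fixed", ["group"])
                random_group = st.get("random", "case_id")
                fit = fit_group_model(
                    metrics, outcome, fixed, random_group,
                    transform=bool(st.get("tukey_transform", True)))
                _finish(fit.anova.assign(outcome=outcome), "stats_anova")
                _finish(fit.params.assign(outcome=outcome), "stats_params")
                factor = st.get("contrast_factor", fixed[0] if fixed else None)
                if factor and metrics[factor].nunique() > 1:
                    _finish(pairwise_contrasts(fit, factor).assign(outcome=outcome),
                            "stats_contrasts")
                record["transform"] = (
                    {"lambda": fit.transform.lambda_, "shift": fit.transform.shift}
                    if fit.transform else None)
            except Exception as e:
                raise RuntimeError(f"stage 'stats' failed: {e}") from e

    # ---- phagocytosis branch
    if "kinetics" in cfg:
        kin = cfg["kinetics"]
        try:
            if "preset" in kin:
                design = get_kinetics_preset(kin["preset"])
            else:
                design = KineticsDesign(
                    conditions=tuple(tuple(c) for c in kin["conditions"]),
                    timepoints_h=tuple(kin["timepoints_h"]),
                    **{k: v for k, v in kin.items()
                       if k not in ("conditions", "timepoints_h",
                                    "preset", "control_condition")},
                )
            series = generate_timeseries(design, seed)
            curves = [series_to_curve(s) for s in series]
            curves = normalize_to_final_control(
                curves, control_condition=kin.get("control_condition", "control"))
            _finish(curves_to_frame(curves), "curves")
            auc_rows = [{
                "well_id": c.well_id, "replicate": c.replicate,
                "condition": c.condition, "treatment": c.treatment,
                "auc_pct_h": curve_auc(c),
                "auc_t0_h": c.meta["auc_range_h"][0],
                "auc_t1_h": c.meta["auc_range_h"][1],
            } for c in curves]
            _finish(pd.DataFrame(auc_rows), "auc")
        except Exception as e:
            raise RuntimeError(f"stage 'phagocytosis' failed: {e}") from e

    (outdir / "run_record.json").write_text(json.dumps(record, indent=1))
    log.info("pipeline complete: %s", ", ".join(record["stages"]))
    return results
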