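"""OME-TIFF stack IO, ground-truth sidecars and YAML pipeline configs.

Stacks travel as multi-channel OME-TIFF (CZYX planes, channel names and
physical voxel sizes in the OME metadata); ground truth as a companion
integer-label OME-TIFF plus a JSON sidecar holding the punctum table and
the planted parameters; configuration as YAML with an explicit seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import GroundTruth, StackSimParams
from .stack import ImageStack

__all__ = [
    "read_stack",
    "write_stack",
    "write_ground_truth",
    "read_ground_truth",
    "load_config",
    "config_hash",
    "ConfigError",
]


class ConfigError(ValueError):
    """A pipeline configuration failed validation."""


def write_stack(stack: ImageStack, path) -> None:
    """Write all channels as one OME-TIFF with voxel-size metadata."""
    path = Path(path)
    names = list(stack.channels)
    data = np.stack([np.asarray(stack.channels[n]) for n in names])
    vz, vy, vx = stack.voxel_size_zyx
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": names},
            "PhysicalSizeZ": vz, "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": vy, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": vx, "PhysicalSizeXUnit": "µm",
        },
    )


def _parse_ome(xml_text: str):
    root = ET.fromstring(xml_text)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    voxel = None
    names: list[str] = []
    if pixels is not None:
        try:
            voxel = (
                float(pixels.attrib["PhysicalSizeZ"]),
                float(pixels.attrib["PhysicalSizeY"]),
                float(pixels.attrib["PhysicalSizeX"]),
            )
        except KeyError:
            voxel = None
        for ch in pixels.findall("ome:Channel", ns):
            names.append(ch.attrib.get("Name", ""))
    return voxel, names


def read_stack(
    path,
    voxel_size_zyx: tuple[float, float, float] | None = None,
    channel_names: list[str] | None = None,
    require_channels: list[str] | None = None,
) -> ImageStack:
    """Read an OME-TIFF written by :func:`write_stack` (or compatible).

    Voxel size is taken from the OME metadata; ``voxel_size_zyx`` acts as
    an override (and is required when the file carries none). A missing
    required channel raises a ``KeyError`` naming it.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        meta_voxel, meta_names = (None, [])
        if tf.ome_metadata:
            meta_voxel, meta_names = _parse_ome(tf.ome_metadata)
    if axes == "ZYX" or data.ndim == 3:
        data = data[None]
    elif axes == "CZYX":
        pass
    elif axes == "ZCYX":
        data = np.moveaxis(data, 1, 0)
    else:
        raise ValueError(f"unsupported axis layout {axes!r} in {path}")
    voxel = voxel_size_zyx or meta_voxel
    if voxel is None:
        raise ValueError(
            f"{path} carries no voxel size metadata and no override was given"
        )
    names = channel_names or [n for n in meta_names if n]
    if len(names) != data.shape[0]:
        names = [f"ch{i}" for i in range(data.shape[0])]
    channels = {n: data[i] for i, n in enumerate(names)}
    stack = ImageStack(channels=channels, voxel_size_zyx=tuple(voxel),
                       stack_id=path.stem)
    if require_channels:
        for ch in require_channels:
            stack.channel(ch)
    return stack


def write_ground_truth(truth: GroundTruth, tiff_path, json_path) -> None:
    """Companion label TIFF + JSON sidecar (punctum table, parameters)."""
    names = list(truth.label_volumes)
    data = np.stack([truth.label_volumes[n].astype(np.int32) for n in names])
    vz, vy, vx = truth.params.voxel_size_zyx
    tifffile.imwrite(
        Path(tiff_path), data, ome=True,
        metadata={"axes": "CZYX", "Channel": {"Name": names},
                  "PhysicalSizeZ": vz, "PhysicalSizeY": vy, "PhysicalSizeX": vx},
    )
    payload = {
        "seed": truth.seed,
        "params": dataclasses.asdict(truth.params),
        "label_channels": names,
        "puncta": truth.puncta.to_dict(orient="list"),
    }
    Path(json_path).write_text(json.dumps(payload, indent=1, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def read_ground_truth(tiff_path, json_path) -> GroundTruth:
    payload = json.loads(Path(json_path).read_text())
    with tifffile.TiffFile(Path(tiff_path)) as tf:
        data = tf.series[0].asarray()
    if data.ndim == 3:
        data = data[None]
    names = payload["label_channels"]
    params = StackSimParams(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in payload["params"].items()
    })
    label_volumes = {n: data[i] for i, n in enumerate(names)}
    puncta = pd.DataFrame(payload["puncta"])
    return GroundTruth(label_volumes=label_volumes, puncta=puncta,
                       params=params, seed=payload["seed"])


# --------------------------------------------------------------------------
# configuration


_KNOWN_TOP = {"seed", "output_dir", "log_level", "simulate", "kinetics",
              "segmentation", "colocalization", "stats", "inputs",
              "write_stacks"}


def load_config(path_or_dict) -> dict:
    """Load and validate a pipeline config; raises ConfigError on problems.

    Validation is structural (known keys, types, required fields, presets
    that exist) so failures surface before any compute starts.
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - _KNOWN_TOP
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    sim = cfg.get("simulate")
    kin = cfg.get("kinetics")
    if (sim or kin) and "seed" not in cfg:
        raise ConfigError("simulation requested but no seed given")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    if sim is not None:
        if not isinstance(sim, dict):
            raise ConfigError("simulate section must be a mapping")
        if "preset" in sim:
            from .simulate import COHORT_PRESETS
            if sim["preset"] not in COHORT_PRESETS:
                raise ConfigError(
                    f"unknown cohort preset {sim['preset']!r}; "
                    f"available: {sorted(COHORT_PRESETS)}")
        elif "groups" not in sim:
            raise ConfigError("simulate needs a 'preset' or explicit 'groups'")
    if kin is not None and isinstance(kin, dict) and "preset" in kin:
        from .simulate import KINETICS_PRESETS
        if kin["preset"] not in KINETICS_PRESETS:
            raise ConfigError(f"unknown kinetics preset {kin['preset']!r}")
    seg = cfg.get("segmentation")
    if seg is not None:
        for ch, p in (seg.get("presets") or {}).items():
            if not isinstance(p, dict) or "window_size" not in p:
                raise ConfigError(
                    f"segmentation preset for {ch!r} needs window_size/c_offset")
    coloc = cfg.get("colocalization")
    if coloc is not None:
        for pair in coloc.get("pairs", []):
            if len(pair) != 2:
                raise ConfigError(f"colocalization pair {pair!r} must have 2 channels")
    st = cfg.get("stats")
    if st is not None and "outcome" not in st:
        raise ConfigError("stats section needs an 'outcome' column name")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of the canonicalised config, for provenance."""
    canon = json.dumps(cfg, sort_keys=True, default=_jsonify)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
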