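"""Synthetic confocal-style stacks, cohorts and phagocytosis time series.

The generator renders multi-channel 3D stacks that emulate immunostained
cortical tissue at confocal resolution (0.18 x 0.18 x 0.3 um voxels):
filamentous (GFAP/P2Y12-like) or blobby (CD68-like) glial signal,
diffraction-limited synaptic puncta of which a planted fraction sits
inside the glial ground-truth volume, optional dense neurite (MAP2-like)
tubes with ingested neurite fragments co-located with a planted fraction
of the engulfed puncta, and optional amyloid-plaque blobs. Every stack is
emitted together with its :class:`GroundTruth` (label volumes and a
punctum table), the oracle for all recovery tests.

The forward optics model is signal -> Gaussian PSF blur -> Poisson shot
noise -> additive Gaussian read noise -> clip and quantize. Defaults put
the images in a high-signal-to-noise regime so that the fixed adaptive
mean-threshold presets operate in their quantitative range; see the
methods note for the calibration rationale.

Cohort presets named ``fig1-astro-ad``, ``fig1-astro-aging``,
``fig2-cd68-burden``, ``fig3-astro-triple`` and ``fig3-microglia-triple``
plant the group effect sizes reported for human tissue (2.1x and 2.7x
astrocytic engulfment, 1.9x CD68 burden, 10x and 44x pair:triple volume
ratios) so the full segmentation+colocalization pipeline can be validated
against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .colocalization import CaseMetadata
from .phagocytosis import PhagocytosisTimeSeries
from .stack import ImageStack

__all__ = [
    "StackSimParams",
    "GroundTruth",
    "CohortDesign",
    "KineticsDesign",
    "generate_stack",
    "generate_cohort",
    "cohort_plan",
    "generate_timeseries",
    "COHORT_PRESETS",
    "KINETICS_PRESETS",
    "get_cohort_preset",
    "get_kinetics_preset",
]

TREATMENTS = ("none", "CytD", "antiMFGE8", "IgG1", "anti_a5b5", "K777")


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class StackSimParams:
    """Geometry, density and optics settings for one simulated stack.

    Densities are per um^3, radii and sizes in um, amplitudes in detector
    counts on the quantized output scale. ``punctum_radius`` is the
    Gaussian sigma of a punctum's intensity profile; its ground-truth
    support is the ellipsoid within 1.5 sigma. ``engulfed_fraction`` of
    the puncta are centred at voxels drawn uniformly from the glial
    ground-truth volume; the remainder are planted in neuropil with
    ``clearance_um`` of free space to the glial surface.
    ``neurite_engulfed_volume_ratio`` is the planted ratio of triple
    (synapse+neurite inside glia) to pair (synapse inside glia) volume,
    realised by co-locating a neurite fragment with that fraction of the
    engulfed puncta.
    """

    shape_zyx: tuple[int, int, int] = (32, 128, 128)
    voxel_size_zyx: tuple[float, float, float] = (0.3, 0.18, 0.18)
    glial_morphology: str = "filamentous"
    n_glial_cells: int = 3
    glial_volume_fraction: float = 0.15
    punctum_density: float = 0.06
    punctum_radius: float = 0.12
    engulfed_fraction: float = 0.15
    neurite_density: float = 0.0
    neurite_engulfed_volume_ratio: float = 0.0
    plaque_count: int = 0
    psf_sigma_zyx: tuple[float, float, float] = (1.2, 0.55, 0.55)
    background_level: float = 30.0
    read_noise_sd: float = 0.05
    photon_scale: float = 10000.0
    bit_depth: int = 8
    # morphology details
    process_radius_um: float = 0.7
    blob_semiaxes_um: tuple[float, float, float] = (2.2, 1.3, 1.3)
    clearance_um: float = 0.5
    neurite_radius_um: float = 0.3
    neurite_glia_clearance_um: float = 1.0
    fragment_sigma_scale: float = 1.5
    # rendering amplitudes (counts)
    glial_amplitude: float = 80.0
    punctum_amplitude: float = 45.0
    neurite_amplitude: float = 70.0
    plaque_amplitude: float = 90.0
    # channel naming
    glial_marker: str = ""
    synaptic_marker: str = "Syn1"
    neurite_marker: str = "MAP2"
    plaque_marker: str = "ThioS"

    def __post_init__(self) -> None:
        if len(self.shape_zyx) != 3 or any(s < 8 for s in self.shape_zyx):
            raise ValueError(f"shape must have >= 8 voxels per axis, got {self.shape_zyx}")
        if any(v <= 0 for v in self.voxel_size_zyx):
            raise ValueError("voxel sizes must be positive")
        if self.glial_morphology not in ("filamentous", "blobby"):
            raise ValueError(f"unknown glial morphology {self.glial_morphology!r}")
        for name in ("glial_volume_fraction", "engulfed_fraction",
                     "neurite_engulfed_volume_ratio"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.punctum_density < 0 or self.neurite_density < 0:
            raise ValueError("densities must be >= 0")
        if self.punctum_radius <= 0:
            raise ValueError("punctum_radius must be positive")
        if self.n_glial_cells < 1 or self.plaque_count < 0:
            raise ValueError("counts must be non-negative (>= 1 glial cell)")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")

    @property
    def resolved_glial_marker(self) -> str:
        if self.glial_marker:
            return self.glial_marker
        return "GFAP" if self.glial_morphology == "filamentous" else "CD68"

    @property
    def stack_volume_um3(self) -> float:
        return float(np.prod(self.shape_zyx)) * float(np.prod(self.voxel_size_zyx))


@dataclass
class GroundTruth:
    """Planted object masks and the punctum table for one stack.

    ``label_volumes`` maps ``glia`` / ``synapse`` / ``neurite`` / ``plaque``
    to integer object-id volumes of the stack's shape. ``puncta`` has one
    row per planted punctum: id, centre (voxel coordinates), truth volume,
    engulfed flag, host glial cell id (-1 when free) and whether a neurite
    fragment was co-ingested (``covered``).
    """

    label_volumes: dict[str, np.ndarray]
    puncta: pd.DataFrame
    params: StackSimParams
    seed: int

    def mask(self, name: str) -> np.ndarray:
        return self.label_volumes[name] > 0

    @property
    def glial_volume_um3(self) -> float:
        vv = float(np.prod(self.params.voxel_size_zyx))
        return float(np.count_nonzero(self.label_volumes["glia"])) * vv

    @property
    def engulfed_volume_um3(self) -> float:
        p = self.puncta
        return float(p.loc[p.engulfed, "volume_um3"].sum())

    @property
    def n_engulfed(self) -> int:
        return int(self.puncta.engulfed.sum())


@dataclass(frozen=True)
class CohortDesign:
    """A multi-group, multi-case imaging study plan.

    ``groups`` lists ``(name, engulfed_multiplier, glial_multiplier)``
    applied to the base engulfed fraction and glial volume fraction; the
    group name doubles as the cohort label. Each case carries a lognormal
    random multiplier with coefficient of variation ``case_cv`` (unit
    mean), shared by the case's stacks. With ``paired_case_noise`` the
    same case-multiplier draws are reused across groups (matched-pairs
    design), which plants the group-mean ratio exactly while keeping each
    group's case-level CV at ``case_cv``.
    """

    groups: tuple[tuple[str, float, float], ...]
    n_cases_per_group: int = 12
    n_stacks_per_case: int = 4
    case_cv: float = 0.2
    base: StackSimParams = field(default_factory=StackSimParams)
    preset_name: str = ""
    paired_case_noise: bool = True

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        for name, me, mg in self.groups:
            if me <= 0 or mg <= 0:
                raise ValueError(f"group {name!r} multipliers must be > 0")
        if self.n_cases_per_group < 1 or self.n_stacks_per_case < 1:
            raise ValueError("counts must be >= 1")
        if self.case_cv < 0:
            raise ValueError("case_cv must be >= 0")


@dataclass(frozen=True)
class KineticsDesign:
    """Design of a live-imaging uptake experiment.

    Each condition is ``(label, plateau, rate_per_h, half_time_h,
    treatment)``; the noiseless uptake index follows the logistic
    ``plateau / (1 + exp(-rate * (t - half_time)))``. Cytochalasin D
    abolishes phagocytosis, so a CytD condition's plateau is forced to 0.
    After an optional wash at ``wash_time_h`` the signal decays
    exponentially at ``decay_rate_post_wash`` per hour — except under the
    cathepsin inhibitor K777, which blocks degradation (no decay).
    """

    conditions: tuple[tuple[str, float, float, float, str], ...]
    timepoints_h: tuple[float, ...]
    wells_per_condition: int = 3
    n_replicates: int = 1
    well_noise_cv: float = 0.0
    mode: str = "cell_count"
    wash_time_h: float | None = None
    decay_rate_post_wash: float = 0.2

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("at least one condition required")
        t = np.asarray(self.timepoints_h, dtype=float)
        if t.size == 0:
            raise ValueError("timepoints_h must be non-empty")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")
        for label, plateau, rate, half, treatment in self.conditions:
            if plateau < 0:
                raise ValueError(f"condition {label!r}: plateau must be >= 0")
            if treatment not in TREATMENTS:
                raise ValueError(f"condition {label!r}: unknown treatment {treatment!r}")
        if self.mode not in ("cell_count", "red_area"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.well_noise_cv < 0:
            raise ValueError("well_noise_cv must be >= 0")


# --------------------------------------------------------------------------
# geometry helpers


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


def _persistent_walk(
    rng: np.random.Generator,
    start_um: np.ndarray,
    n_steps: int,
    bounds_um: np.ndarray,
    step_um: float,
    wiggle: float,
) -> np.ndarray:
    """Random walk with directional persistence, reflected at the borders."""
    pos = start_um.astype(float).copy()
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    out = np.empty((n_steps, 3))
    for i in range(n_steps):
        d = d + wiggle * rng.normal(size=3)
        d /= np.linalg.norm(d)
        pos = pos + step_um * d
        for ax in range(3):
            if pos[ax] < 0:
                pos[ax] = -pos[ax]
                d[ax] = -d[ax]
            elif pos[ax] > bounds_um[ax]:
                pos[ax] = 2 * bounds_um[ax] - pos[ax]
                d[ax] = -d[ax]
        out[i] = pos
    return out


def _points_to_seed_volume(
    points_um: np.ndarray, ids: np.ndarray, shape: tuple, voxel: np.ndarray
) -> np.ndarray:
    seed = np.zeros(shape, dtype=np.int32)
    idx = np.minimum(
        np.maximum((points_um / voxel).astype(int), 0),
        np.array(shape) - 1,
    )
    seed[idx[:, 0], idx[:, 1], idx[:, 2]] = ids
    return seed


def _tube_mask_from_points(
    points_um: np.ndarray,
    ids: np.ndarray,
    shape: tuple,
    voxel: np.ndarray,
    radius_um: float,
    with_labels: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Union of tubes of ``radius_um`` around polyline sample points.

    Uses an anisotropy-aware distance transform so tube cross-sections are
    spherical in physical space despite the coarser z sampling.
    """
    seed = _points_to_seed_volume(points_um, ids, shape, voxel)
    if with_labels:
        dist, (iz, iy, ix) = ndi.distance_transform_edt(
            seed == 0, sampling=voxel, return_indices=True
        )
        mask = dist <= radius_um
        labels = np.zeros(shape, dtype=np.int32)
        labels[mask] = seed[iz[mask], iy[mask], ix[mask]]
        return mask, labels
    dist = ndi.distance_transform_edt(seed == 0, sampling=voxel)
    return dist <= radius_um, None


def _paint_ellipsoid(vol: np.ndarray, center: np.ndarray, semi_vox: np.ndarray,
                     value: int) -> int:
    """Label an ellipsoid in-place; returns the number of voxels painted."""
    lo = np.maximum(np.floor(center - semi_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center + semi_vox).astype(int) + 1,
                    np.array(vol.shape))
    if np.any(lo >= hi):
        return 0
    zz, yy, xx = np.meshgrid(
        *(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij"
    )
    r2 = (((zz - center[0]) / semi_vox[0]) ** 2
          + ((yy - center[1]) / semi_vox[1]) ** 2
          + ((xx - center[2]) / semi_vox[2]) ** 2)
    sel = r2 <= 1.0
    sub = vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    painted = int(np.count_nonzero(sel & (sub == 0)))
    sub[sel] = value
    return painted


def _make_filamentous_glia(params: StackSimParams, rng: np.random.Generator):
    shape = tuple(params.shape_zyx)
    voxel = np.asarray(params.voxel_size_zyx)
    bounds = voxel * np.array(shape)
    r = params.process_radius_um
    target_vox = params.glial_volume_fraction * np.prod(shape)
    step = 0.25
    # initial length estimate from tube volume, then measure-and-top-up
    vol_per_step = math.pi * r * r * step
    target_v_um3 = params.glial_volume_fraction * params.stack_volume_um3
    n_steps0 = max(int(0.9 * target_v_um3 / vol_per_step / params.n_glial_cells), 20)
    points, ids = [], []
    starts = rng.uniform(0.15, 0.85, size=(params.n_glial_cells, 3)) * bounds
    for c in range(params.n_glial_cells):
        pts = _persistent_walk(rng, starts[c], n_steps0, bounds, step, wiggle=0.3)
        points.append(pts)
        ids.append(np.full(len(pts), c + 1))
    for _ in range(4):
        pts_all = np.concatenate(points)
        ids_all = np.concatenate(ids)
        mask, _ = _tube_mask_from_points(pts_all, ids_all, shape, voxel, r)
        got = mask.sum()
        if got >= 0.98 * target_vox:
            break
        yield_per_step = max(got / len(pts_all), 1.0)
        extra = int((target_vox - got) / yield_per_step) + 10
        per_cell = max(extra // params.n_glial_cells, 5)
        for c in range(params.n_glial_cells):
            anchor = points[c][rng.integers(len(points[c]))]
            pts = _persistent_walk(rng, anchor, per_cell, bounds, step, wiggle=0.3)
            points.append(pts)
            ids.append(np.full(len(pts), c + 1))
    pts_all = np.concatenate(points)
    ids_all = np.concatenate(ids)
    _, labels = _tube_mask_from_points(pts_all, ids_all, shape, voxel, r,
                                       with_labels=True)
    return labels


def _make_blobby_glia(params: StackSimParams, rng: np.random.Generator):
    shape = tuple(params.shape_zyx)
    voxel = np.asarray(params.voxel_size_zyx)
    labels = np.zeros(shape, dtype=np.int32)
    target_vox = params.glial_volume_fraction * np.prod(shape)
    semi_um = np.asarray(params.blob_semiaxes_um)
    painted = 0
    blob_i = 0
    while painted < target_vox and blob_i < 100000:
        blob_i += 1
        center = rng.uniform(0.0, 1.0, size=3) * (np.array(shape) - 1)
        jitter = rng.uniform(0.75, 1.25, size=3)
        semi_vox = semi_um * jitter / voxel
        blob_vox = 4.0 / 3.0 * math.pi * np.prod(semi_vox)
        remaining = target_vox - painted
        if blob_vox > remaining:
            # shrink the last blob to land on the target fraction
            semi_vox = semi_vox * (remaining / blob_vox) ** (1.0 / 3.0)
        cell = (blob_i - 1) % params.n_glial_cells + 1
        painted += _paint_ellipsoid(labels, center, semi_vox, cell)
    return labels


_GAUSS_TRUNC = 2.5  # intensity stamp support, in sigmas
_TRUTH_TRUNC = 1.5  # ground-truth support, in sigmas


def _ellipsoid_offsets(semi_vox: np.ndarray) -> np.ndarray:
    rad = np.ceil(semi_vox).astype(int)
    zz, yy, xx = np.meshgrid(
        *(np.arange(-r, r + 1) for r in rad), indexing="ij"
    )
    r2 = ((zz / semi_vox[0]) ** 2 + (yy / semi_vox[1]) ** 2
          + (xx / semi_vox[2]) ** 2)
    sel = r2 <= 1.0
    return np.stack([zz[sel], yy[sel], xx[sel]], axis=1)


def _gauss_stamp(sigma_vox: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(offsets, weights) of a truncated Gaussian intensity stamp."""
    rad = np.ceil(_GAUSS_TRUNC * sigma_vox).astype(int)
    zz, yy, xx = np.meshgrid(
        *(np.arange(-r, r + 1) for r in rad), indexing="ij"
    )
    r2 = ((zz / sigma_vox[0]) ** 2 + (yy / sigma_vox[1]) ** 2
          + (xx / sigma_vox[2]) ** 2)
    sel = r2 <= _GAUSS_TRUNC ** 2
    w = np.exp(-0.5 * r2[sel])
    off = np.stack([zz[sel], yy[sel], xx[sel]], axis=1)
    return off, w


def _stamp_add(img: np.ndarray, centers: np.ndarray, offsets: np.ndarray,
               weights: np.ndarray, amplitude: float) -> None:
    shape = np.array(img.shape)
    for c in centers:
        pos = c[None, :] + offsets
        ok = np.all((pos >= 0) & (pos < shape[None, :]), axis=1)
        p = pos[ok]
        np.add.at(img, (p[:, 0], p[:, 1], p[:, 2]), amplitude * weights[ok])


def _paint_labels(vol: np.ndarray, centers: np.ndarray, offsets: np.ndarray,
                  values: np.ndarray) -> np.ndarray:
    """Paint fixed-shape supports; returns per-centre painted voxel counts."""
    shape = np.array(vol.shape)
    counts = np.empty(len(centers), dtype=int)
    for i, c in enumerate(centers):
        pos = c[None, :] + offsets
        ok = np.all((pos >= 0) & (pos < shape[None, :]), axis=1)
        p = pos[ok]
        vol[p[:, 0], p[:, 1], p[:, 2]] = values[i]
        counts[i] = int(ok.sum())
    return counts


# --------------------------------------------------------------------------
# stack generation


def generate_stack(params: StackSimParams, seed: int) -> tuple[ImageStack, GroundTruth]:
    """Render one multi-channel stack and its ground truth.

    The same ``(params, seed)`` pair always yields bit-identical output.
    Independent random streams drive glial geometry, punctum placement,
    neurites, plaques and detector noise, so that e.g. raising
    ``engulfed_fraction`` at a fixed seed re-labels puncta without
    re-rolling the glial morphology (engulfed volume is then monotone in
    the fraction).
    """
    shape = tuple(params.shape_zyx)
    voxel = np.asarray(params.voxel_size_zyx)
    voxvol = float(np.prod(voxel))

    # --- glial ground truth
    rng_glia = _rng(seed, 0)
    if params.glial_morphology == "filamentous":
        glia_labels = _make_filamentous_glia(params, rng_glia)
    else:
        glia_labels = _make_blobby_glia(params, rng_glia)
    glia_mask = glia_labels > 0

    # --- puncta
    rng_count = _rng(seed, 1)
    rng_flags = _rng(seed, 2)
    rng_in = _rng(seed, 3)
    rng_out = _rng(seed, 4)
    n_puncta = int(rng_count.poisson(params.punctum_density * params.stack_volume_um3))
    sigma_vox = params.punctum_radius / voxel
    truth_off = _ellipsoid_offsets(_TRUTH_TRUNC * sigma_vox)
    dist_out = ndi.distance_transform_edt(~glia_mask, sampling=voxel)
    inside_idx = np.argwhere(glia_mask)
    outside_idx = np.argwhere(dist_out > params.clearance_um)
    if outside_idx.size == 0:
        outside_idx = np.argwhere(~glia_mask)
    syn_labels = np.zeros(shape, dtype=np.int32)
    if n_puncta > 0 and inside_idx.size > 0:
        engulfed = rng_flags.random(n_puncta) < params.engulfed_fraction
        cand_in = inside_idx[rng_in.integers(0, len(inside_idx), n_puncta)]
        cand_out = outside_idx[rng_out.integers(0, len(outside_idx), n_puncta)]
        centers = np.where(engulfed[:, None], cand_in, cand_out)
        hosts = np.where(
            engulfed,
            glia_labels[cand_in[:, 0], cand_in[:, 1], cand_in[:, 2]],
            -1,
        )
        ids = np.arange(1, n_puncta + 1)
        counts = _paint_labels(syn_labels, centers, truth_off, ids)
        puncta = pd.DataFrame({
            "punctum_id": ids,
            "z": centers[:, 0], "y": centers[:, 1], "x": centers[:, 2],
            "volume_um3": counts * voxvol,
            "engulfed": engulfed,
            "host_glia_id": hosts,
            "covered": np.zeros(n_puncta, dtype=bool),
        })
    else:
        n_puncta = 0
        centers = np.empty((0, 3), dtype=int)
        puncta = pd.DataFrame({
            "punctum_id": pd.Series(dtype=int),
            "z": pd.Series(dtype=int), "y": pd.Series(dtype=int),
            "x": pd.Series(dtype=int),
            "volume_um3": pd.Series(dtype=float),
            "engulfed": pd.Series(dtype=bool),
            "host_glia_id": pd.Series(dtype=int),
            "covered": pd.Series(dtype=bool),
        })

    # --- neurites: background tubes clear of glia + ingested fragments
    rng_neur = _rng(seed, 5)
    neurite_labels = None
    frag_centers = np.empty((0, 3), dtype=int)
    if params.neurite_density > 0:
        bounds = voxel * np.array(shape)
        n_tubes = int(round(params.neurite_density))
        pts, ids_t = [], []
        for t in range(n_tubes):
            start = rng_neur.uniform(0.05, 0.95, size=3) * bounds
            length_steps = int(rng_neur.uniform(25.0, 45.0) / 0.25)
            pts.append(_persistent_walk(rng_neur, start, length_steps, bounds,
                                        0.25, wiggle=0.08))
            ids_t.append(np.full(len(pts[-1]), t + 1))
        mask_n, _ = _tube_mask_from_points(
            np.concatenate(pts), np.concatenate(ids_t), shape, voxel,
            params.neurite_radius_um,
        )
        # dendrites are displaced by glial processes: keep tubes clear of
        # glia so that only planted fragments contribute triple volume
        mask_n &= dist_out > params.neurite_glia_clearance_um
        neurite_labels, _ = ndi.label(mask_n)
        neurite_labels = neurite_labels.astype(np.int32)
        if params.neurite_engulfed_volume_ratio > 0 and n_puncta > 0:
            eng_rows = np.flatnonzero(puncta.engulfed.to_numpy())
            n_cov = int(rng_neur.binomial(
                len(eng_rows), params.neurite_engulfed_volume_ratio))
            if n_cov > 0:
                chosen = rng_neur.choice(eng_rows, size=n_cov, replace=False)
                covered = puncta["covered"].to_numpy()
                covered[chosen] = True
                puncta["covered"] = covered
                frag_centers = centers[chosen]
                frag_off = _ellipsoid_offsets(
                    _TRUTH_TRUNC * params.fragment_sigma_scale * sigma_vox)
                frag_ids = np.arange(
                    neurite_labels.max() + 1,
                    neurite_labels.max() + 1 + n_cov, dtype=np.int32)
                _paint_labels(neurite_labels, frag_centers, frag_off, frag_ids)

    # --- plaques
    rng_plq = _rng(seed, 6)
    plaque_labels = None
    if params.plaque_count > 0:
        plaque_labels = np.zeros(shape, dtype=np.int32)
        for p in range(params.plaque_count):
            c = rng_plq.uniform(0.2, 0.8, size=3) * (np.array(shape) - 1)
            for _ in range(3):  # irregular union of ellipsoids
                cc = c + rng_plq.normal(0, 1.0, size=3) * np.array([2, 6, 6])
                semi = rng_plq.uniform(2.0, 4.0, size=3) / voxel
                _paint_ellipsoid(plaque_labels, cc, semi, p + 1)

    # --- rendering + forward optics
    rng_noise = _rng(seed, 7)
    cell_amp = params.glial_amplitude * rng_glia.uniform(
        0.85, 1.15, size=max(int(glia_labels.max()), 1) + 1)
    cell_amp[0] = 0.0
    channels: dict[str, np.ndarray] = {}
    glia_img = cell_amp[glia_labels]
    channels[params.resolved_glial_marker] = glia_img
    syn_img = np.zeros(shape, dtype=np.float64)
    if n_puncta > 0:
        off_g, w_g = _gauss_stamp(sigma_vox)
        _stamp_add(syn_img, centers, off_g, w_g, params.punctum_amplitude)
    channels[params.synaptic_marker] = syn_img
    if neurite_labels is not None:
        neur_img = np.where(neurite_labels > 0, params.neurite_amplitude, 0.0)
        if len(frag_centers):
            off_f, w_f = _gauss_stamp(params.fragment_sigma_scale * sigma_vox)
            _stamp_add(neur_img, frag_centers, off_f, w_f,
                       1.6 * params.neurite_amplitude)
        channels[params.neurite_marker] = neur_img
    if plaque_labels is not None:
        channels[params.plaque_marker] = np.where(
            plaque_labels > 0, params.plaque_amplitude, 0.0)

    maxval = 2 ** params.bit_depth - 1
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    for name, img in channels.items():
        blurred = ndi.gaussian_filter(img, sigma=params.psf_sigma_zyx, truncate=3.0)
        lam = (blurred + params.background_level) * params.photon_scale
        detected = rng_noise.poisson(lam).astype(np.float64) / params.photon_scale
        detected += rng_noise.normal(0.0, params.read_noise_sd, size=detected.shape)
        channels[name] = np.clip(np.rint(detected), 0, maxval).astype(dtype)

    label_volumes = {"glia": glia_labels, "synapse": syn_labels}
    if neurite_labels is not None:
        label_volumes["neurite"] = neurite_labels
    if plaque_labels is not None:
        label_volumes["plaque"] = plaque_labels
    stack = ImageStack(channels=channels, voxel_size_zyx=tuple(voxel),
                       stack_id=f"sim-{seed}", meta={"seed": int(seed)})
    truth = GroundTruth(label_volumes=label_volumes, puncta=puncta,
                        params=params, seed=int(seed))
    return stack, truth


# --------------------------------------------------------------------------
# cohorts


def _case_multipliers(design: CohortDesign, seed: int) -> np.ndarray:
    """(n_groups, n_cases, 2) lognormal multipliers (engulfment, glia)."""
    cv = design.case_cv
    n_g, n_c = len(design.groups), design.n_cases_per_group
    if cv == 0:
        return np.ones((n_g, n_c, 2))
    s2 = math.log(1.0 + cv * cv)
    rng = _rng(seed, 100)
    draws = rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=(n_g, n_c, 2))
    if design.paired_case_noise:
        draws = np.broadcast_to(draws[:1], draws.shape).copy()
    return draws


_COHORT_AGES = {"midlife control": 48.0, "aged control": 80.0, "AD": 79.0}
_APOE4_RATES = {"midlife control": 0.25, "aged control": 0.25, "AD": 0.6}


def cohort_plan(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Deterministic per-stack plan (the cohort metadata table).

    One row per stack: group, case id, stack id, per-stack seed, the
    effective engulfed/glial fractions after group and case multipliers,
    and case-level covariates (APOE4 status, sex, age).
    """
    mult = _case_multipliers(design, seed)
    rng_meta = _rng(seed, 101)
    rows = []
    stack_counter = 0
    for gi, (gname, m_eng, m_glia) in enumerate(design.groups):
        cohort = gname if gname in _COHORT_AGES else "AD"
        for ci in range(design.n_cases_per_group):
            case_id = f"{gname.replace(' ', '_')}_c{ci + 1:02d}"
            ef = min(design.base.engulfed_fraction * m_eng * mult[gi, ci, 0], 0.95)
            gvf = min(design.base.glial_volume_fraction * m_glia * mult[gi, ci, 1], 0.6)
            apoe4 = bool(rng_meta.random() < _APOE4_RATES.get(cohort, 0.3))
            sex = "F" if rng_meta.random() < 0.5 else "M"
            age = float(rng_meta.normal(_COHORT_AGES.get(cohort, 70.0), 5.0))
            for si in range(design.n_stacks_per_case):
                rows.append({
                    "group": gname,
                    "cohort": cohort,
                    "case_id": case_id,
                    "stack_id": f"{case_id}_s{si + 1:02d}",
                    "stack_seed": int((seed * 100003 + stack_counter) % (2 ** 31)),
                    "engulfed_fraction": ef,
                    "glial_volume_fraction": gvf,
                    "apoe4": apoe4,
                    "sex": sex,
                    "age": round(age, 1),
                })
                stack_counter += 1
    return pd.DataFrame(rows)


def generate_cohort(design: CohortDesign, seed: int):
    """Yield ``(ImageStack, GroundTruth, CaseMetadata)`` per planned stack.

    Lazily generated (a full cohort does not fit comfortably in memory);
    wrap in ``list`` for small designs. ``cohort_plan`` gives the metadata
    table without rendering any images.
    """
    plan = cohort_plan(design, seed)
    for row in plan.itertuples(index=False):
        params = replace(
            design.base,
            engulfed_fraction=row.engulfed_fraction,
            glial_volume_fraction=row.glial_volume_fraction,
        )
        stack, truth = generate_stack(params, row.stack_seed)
        stack.stack_id = row.stack_id
        stack.case_id = row.case_id
        meta = CaseMetadata(
            case_id=row.case_id, cohort=row.cohort, region="synthetic",
            apoe4=row.apoe4, sex=row.sex, age=row.age,
            plaque_present=design.base.plaque_count > 0, group=row.group,
        )
        yield stack, truth, meta


# --------------------------------------------------------------------------
# presets encoding the reported human-tissue effect sizes


def _astro_base(**kw) -> StackSimParams:
    return StackSimParams(**{
        "glial_morphology": "filamentous",
        "glial_volume_fraction": 0.15,
        "punctum_density": 0.06,
        **kw,
    })


COHORT_PRESETS: dict[str, CohortDesign] = {
    # astrocytic engulfment, AD vs aged control: planted ratio 2.1
    "fig1-astro-ad": CohortDesign(
        groups=(("AD", 2.1, 1.0), ("aged control", 1.0, 1.0)),
        base=_astro_base(engulfed_fraction=0.15),
        preset_name="fig1-astro-ad",
    ),
    # astrocytic engulfment, aged vs midlife control: planted ratio 2.7
    "fig1-astro-aging": CohortDesign(
        groups=(("aged control", 2.7, 1.0), ("midlife control", 1.0, 1.0)),
        base=_astro_base(engulfed_fraction=0.10),
        preset_name="fig1-astro-aging",
    ),
    # CD68 (microglial lysosome) burden, AD vs aged control: planted ratio 1.9
    "fig2-cd68-burden": CohortDesign(
        groups=(("AD", 1.0, 1.9), ("aged control", 1.0, 1.0)),
        case_cv=0.1,
        base=StackSimParams(
            shape_zyx=(32, 192, 192),
            glial_morphology="blobby",
            n_glial_cells=6,
            glial_volume_fraction=0.012,
            punctum_density=0.0,
            engulfed_fraction=0.0,
        ),
        preset_name="fig2-cd68-burden",
    ),
    # synaptophysin-in-astrocyte pair vs +MAP2 triple volume: ratio 10
    "fig3-astro-triple": CohortDesign(
        groups=(("AD", 1.0, 1.0),),
        base=_astro_base(
            engulfed_fraction=0.30,
            synaptic_marker="SyO",
            neurite_density=40.0,
            neurite_engulfed_volume_ratio=0.1,
        ),
        preset_name="fig3-astro-triple",
    ),
    # synaptophysin-in-microglia pair vs +MAP2 triple volume: ratio 44
    "fig3-microglia-triple": CohortDesign(
        groups=(("AD", 1.0, 1.0),),
        base=_astro_base(
            engulfed_fraction=0.30,
            punctum_density=0.12,  # elevated to stabilise the small triple volume
            glial_marker="P2Y12",
            synaptic_marker="SyO",
            neurite_density=40.0,
            neurite_engulfed_volume_ratio=1.0 / 44.0,
        ),
        preset_name="fig3-microglia-triple",
    ),
}


def get_cohort_preset(name: str) -> CohortDesign:
    try:
        return COHORT_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown cohort preset {name!r}; available: {sorted(COHORT_PRESETS)}"
        ) from None


# --------------------------------------------------------------------------
# phagocytosis kinetics


def _logistic(t: np.ndarray, plateau: float, rate: float, half: float) -> np.ndarray:
    return plateau / (1.0 + np.exp(-rate * (t - half)))


def noiseless_curve(
    t: np.ndarray, plateau: float, rate: float, half_time_h: float,
    treatment: str = "none", wash_time_h: float | None = None,
    decay_rate_post_wash: float = 0.0,
) -> np.ndarray:
    """Closed-form uptake index: logistic rise, exponential post-wash decay."""
    t = np.asarray(t, dtype=float)
    if treatment == "CytD":
        plateau = 0.0
    y = _logistic(t, plateau, rate, half_time_h)
    if wash_time_h is not None:
        post = t > wash_time_h
        y_wash = float(_logistic(np.array([wash_time_h]), plateau, rate, half_time_h)[0])
        decay = 0.0 if treatment == "K777" else decay_rate_post_wash
        y = np.where(post, y_wash * np.exp(-decay * (t - wash_time_h)), y)
    return y


def generate_timeseries(design: KineticsDesign, seed: int) -> list[PhagocytosisTimeSeries]:
    """One measurement series per well of the designed experiment.

    In ``cell_count`` mode the logistic index is the expected fraction of
    cells with internalised cargo among a nominal 200 cells per well; in
    ``red_area`` mode it is the expected red-signal area per unit phase
    confluency at t = 0. With ``well_noise_cv`` = 0 the recorded indices
    equal the closed form exactly (counts are instrument-averaged and may
    be fractional).
    """
    rng = _rng(seed, 200)
    t = np.asarray(design.timepoints_h, dtype=float)
    cv = design.well_noise_cv
    s2 = math.log(1.0 + cv * cv) if cv > 0 else 0.0
    out: list[PhagocytosisTimeSeries] = []
    for rep in range(1, design.n_replicates + 1):
        for label, plateau, rate, half, treatment in design.conditions:
            for w in range(1, design.wells_per_condition + 1):
                y = noiseless_curve(
                    t, plateau, rate, half, treatment,
                    design.wash_time_h, design.decay_rate_post_wash,
                )
                if cv > 0:
                    well_f = rng.lognormal(-s2 / 2.0, math.sqrt(s2))
                    point_f = rng.lognormal(-s2 / 2.0, math.sqrt(s2), size=t.shape)
                    y = y * well_f * point_f
                well_id = f"R{rep}_{label}_{treatment}_w{w}"
                if design.mode == "cell_count":
                    total = np.full(t.shape, 200.0)
                    out.append(PhagocytosisTimeSeries(
                        well_id=well_id, replicate=f"R{rep}", condition=label,
                        treatment=treatment, mode="cell_count", timepoints_h=t.copy(),
                        cells_total=total,
                        cells_phagocytosing=np.minimum(np.clip(y, 0.0, 1.0) * total, total),
                        wash_time_h=design.wash_time_h,
                    ))
                else:
                    confluency = float(rng.normal(30.0, 2.0)) if cv > 0 else 30.0
                    out.append(PhagocytosisTimeSeries(
                        well_id=well_id, replicate=f"R{rep}", condition=label,
                        treatment=treatment, mode="red_area", timepoints_h=t.copy(),
                        red_area=y * confluency,
                        phase_confluency_t0=confluency,
                        wash_time_h=design.wash_time_h,
                    ))
    return out


_BV2_T = tuple(np.round(np.arange(0.0, 3.01, 1.0 / 6.0), 4))  # every 10 min, 3 h
_INCU_T = tuple(float(x) for x in np.arange(0.0, 48.1, 2.0))  # every 2 h, 48 h

KINETICS_PRESETS: dict[str, KineticsDesign] = {
    # BV2 microglia fed pHrodo synaptoneurosomes; CytD negative control
    "bv2-validation": KineticsDesign(
        conditions=(
            ("control", 0.6, 2.5, 1.2, "none"),
            ("control", 0.0, 2.5, 1.2, "CytD"),
        ),
        timepoints_h=_BV2_T,
        wells_per_condition=4,
        n_replicates=3,
        well_noise_cv=0.08,
        mode="cell_count",
    ),
    # astrocytes fed AD vs control synaptoneurosomes (long IncuCyte run)
    "astro-ad-uptake": KineticsDesign(
        conditions=(
            ("control", 1.0, 0.25, 16.0, "none"),
            ("AD", 2.0, 0.25, 16.0, "none"),
            ("control", 0.0, 0.25, 16.0, "CytD"),
        ),
        timepoints_h=_INCU_T,
        wells_per_condition=4,
        n_replicates=3,
        well_noise_cv=0.1,
        mode="red_area",
    ),
    # MFG-E8 pathway blocking on astrocytes
    "astro-blocking": KineticsDesign(
        conditions=(
            ("AD", 2.0, 0.25, 16.0, "none"),
            ("AD", 2.0, 0.25, 16.0, "IgG1"),
            ("AD", 1.0, 0.25, 16.0, "antiMFGE8"),
            ("AD", 1.1, 0.25, 16.0, "anti_a5b5"),
        ),
        timepoints_h=_INCU_T,
        wells_per_condition=4,
        n_replicates=3,
        well_noise_cv=0.1,
        mode="red_area",
    ),
    # wash + degradation; K777 blocks lysosomal degradation
    "degradation": KineticsDesign(
        conditions=(
            ("control", 1.5, 2.0, 1.0, "none"),
            ("control", 1.5, 2.0, 1.0, "K777"),
        ),
        timepoints_h=tuple(float(x) for x in np.concatenate([
            np.arange(0.0, 2.01, 0.25), np.arange(4.0, 48.1, 2.0)])),
        wells_per_condition=4,
        n_replicates=3,
        well_noise_cv=0.08,
        mode="red_area",
        wash_time_h=2.0,
        decay_rate_post_wash=0.15,
    ),
}


def get_kinetics_preset(name: str) -> KineticsDesign:
    try:
        return KINETICS_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown kinetics preset {name!r}; available: {sorted(KINETICS_PRESETS)}"
        ) from None
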