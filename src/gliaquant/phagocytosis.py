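"""Live-imaging phagocytosis assay quantification.

Converts per-well uptake measurements (fraction of cells with
internalised pHrodo cargo, or pHrodo-red area per starting confluency)
into index curves, normalizes them to the within-experiment control at
the final timepoint, integrates the area under the curve, and summarises
post-wash degradation. The module consumes measurement tables, not raw
movies; instrument-side cell detection is upstream of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhagocytosisTimeSeries",
    "PhagocytosisCurve",
    "index_cell_fraction",
    "index_area",
    "series_to_curve",
    "normalize_to_final_control",
    "curve_auc",
    "degradation_metrics",
    "curves_to_frame",
]


@dataclass
class PhagocytosisTimeSeries:
    """Raw per-well measurements over time.

    ``cell_count`` mode carries total and phagocytosing cell counts per
    timepoint; ``red_area`` mode carries the red-signal area per timepoint
    and the well's phase confluency at t = 0.
    """

    well_id: str
    replicate: str
    condition: str
    treatment: str
    mode: str
    timepoints_h: np.ndarray
    cells_total: np.ndarray | None = None
    cells_phagocytosing: np.ndarray | None = None
    red_area: np.ndarray | None = None
    phase_confluency_t0: float | None = None
    wash_time_h: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")
        self.timepoints_h = t
        if self.mode not in ("cell_count", "red_area"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "cell_count":
            if self.cells_total is None or self.cells_phagocytosing is None:
                raise ValueError("cell_count mode requires both cell count arrays")
            self.cells_total = np.asarray(self.cells_total, dtype=float)
            self.cells_phagocytosing = np.asarray(self.cells_phagocytosing, dtype=float)
            if np.any(self.cells_phagocytosing > self.cells_total + 1e-9):
                raise ValueError("cells_phagocytosing cannot exceed cells_total")
            if np.any(self.cells_total < 0) or np.any(self.cells_phagocytosing < 0):
                raise ValueError("cell counts must be >= 0")
        else:
            if self.red_area is None or self.phase_confluency_t0 is None:
                raise ValueError("red_area mode requires red_area and confluency")
            self.red_area = np.asarray(self.red_area, dtype=float)
            if np.any(self.red_area < 0):
                raise ValueError("red_area must be >= 0")


@dataclass
class PhagocytosisCurve:
    """A well's uptake index over time, optionally control-normalized."""

    well_id: str
    replicate: str
    condition: str
    treatment: str
    timepoints_h: np.ndarray
    index: np.ndarray
    normalized_pct: np.ndarray | None = None
    wash_time_h: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        """Normalized values when available, else the raw index."""
        return self.normalized_pct if self.normalized_pct is not None else self.index


def index_cell_fraction(cells_phagocytosing, cells_total):
    """Percentage of cells with internalised cargo (phagocytosis index)."""
    phago = np.asarray(cells_phagocytosing, dtype=float)
    total = np.asarray(cells_total, dtype=float)
    if np.any(total <= 0):
        raise ValueError("cells_total must be > 0")
    return 100.0 * phago / total


def index_area(red_area, phase_confluency_t0):
    """pHrodo-red area normalized to the well's confluency at t = 0."""
    area = np.asarray(red_area, dtype=float)
    conf = float(phase_confluency_t0)
    if conf <= 0:
        raise ValueError("phase_confluency_t0 must be > 0")
    return area / conf


def series_to_curve(series: PhagocytosisTimeSeries) -> PhagocytosisCurve:
    """Compute the raw index curve of one well."""
    if series.mode == "cell_count":
        idx = index_cell_fraction(series.cells_phagocytosing, series.cells_total)
    else:
        idx = index_area(series.red_area, series.phase_confluency_t0)
    return PhagocytosisCurve(
        well_id=series.well_id, replicate=series.replicate,
        condition=series.condition, treatment=series.treatment,
        timepoints_h=series.timepoints_h.copy(), index=np.asarray(idx, dtype=float),
        wash_time_h=series.wash_time_h,
    )


def normalize_to_final_control(
    curves: list[PhagocytosisCurve],
    control_condition: str = "control",
    control_treatment: str = "none",
) -> list[PhagocytosisCurve]:
    """Express every curve as % of the control's final-timepoint mean.

    "Within experiment" is the replicate grouping: inside each replicate
    the mean index of the control-condition wells at the last timepoint
    maps to 100%, and every well of that replicate is scaled accordingly.
    """
    by_rep: dict[str, list[PhagocytosisCurve]] = {}
    for c in curves:
        by_rep.setdefault(c.replicate, []).append(c)
    out: list[PhagocytosisCurve] = []
    for rep, group in by_rep.items():
        finals = [
            c.index[-1] for c in group
            if c.condition == control_condition and c.treatment == control_treatment
        ]
        if not finals:
            raise ValueError(
                f"replicate {rep!r} has no "
                f"{control_condition}/{control_treatment} control well"
            )
        denom = float(np.mean(finals))
        if denom <= 0:
            raise ValueError(f"replicate {rep!r}: control final-timepoint mean is 0")
        for c in group:
            out.append(PhagocytosisCurve(
                well_id=c.well_id, replicate=c.replicate, condition=c.condition,
                treatment=c.treatment, timepoints_h=c.timepoints_h.copy(),
                index=c.index.copy(),
                normalized_pct=100.0 * c.index / denom,
                wash_time_h=c.wash_time_h,
                meta={**c.meta, "control_final_mean": denom},
            ))
    return out


def curve_auc(curve: PhagocytosisCurve, use_normalized: bool = True) -> float:
    """Trapezoidal area under the curve over the hour axis (%*h).

    Missing (NaN) interior points are linearly interpolated; leading or
    trailing gaps truncate the integration range, which is recorded in
    ``curve.meta['auc_range_h']``.
    """
    t = np.asarray(curve.timepoints_h, dtype=float)
    y = np.asarray(curve.values if use_normalized else curve.index, dtype=float)
    if t.size < 2:
        raise ValueError("AUC requires at least two timepoints")
    ok = np.isfinite(y)
    if not ok.any() or ok.sum() < 2:
        raise ValueError("AUC requires at least two finite values")
    first, last = np.flatnonzero(ok)[[0, -1]]
    t_win, y_win = t[first:last + 1], y[first:last + 1]
    inner = np.isfinite(y_win)
    if not inner.all():
        y_win = np.interp(t_win, t_win[inner], y_win[inner])
    curve.meta["auc_range_h"] = (float(t_win[0]), float(t_win[-1]))
    return float(np.trapezoid(y_win, t_win))


def degradation_metrics(
    curve: PhagocytosisCurve, wash_time_h: float, use_normalized: bool = False
) -> tuple[float, float, float]:
    """(peak before wash, final value, fraction remaining) of a wash assay."""
    t = np.asarray(curve.timepoints_h, dtype=float)
    y = np.asarray(curve.values if use_normalized else curve.index, dtype=float)
    if not (t[0] <= wash_time_h <= t[-1]):
        raise ValueError("wash_time_h outside the recorded time range")
    pre = y[t <= wash_time_h]
    peak = float(np.nanmax(pre))
    if peak <= 0:
        raise ValueError("peak uptake before wash is 0; fraction undefined")
    final = float(y[-1])
    return peak, final, final / peak


def curves_to_frame(curves: list[PhagocytosisCurve]) -> pd.DataFrame:
    """Long-format table: one row per well and timepoint."""
    rows = []
    for c in curves:
        for i, t in enumerate(c.timepoints_h):
            rows.append({
                "well_id": c.well_id,
                "replicate": c.replicate,
                "condition": c.condition,
                "treatment": c.treatment,
                "time_h": float(t),
                "index": float(c.index[i]),
                "normalized_pct": (float(c.normalized_pct[i])
                                   if c.normalized_pct is not None else np.nan),
            })
    return pd.DataFrame(rows, columns=["well_id", "replicate", "condition",
                                       "treatment", "time_h", "index",
                                       "normalized_pct"])
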