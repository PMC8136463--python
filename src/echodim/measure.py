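"""Keypoint sets and guideline linear LV dimensions.

The parasternal long-axis (PLAX) convention measures three dimensions between
four named landmarks placed on the myocardial boundaries:

* ``ivs``  — interventricular septal thickness, anterior to posterior septal
  boundary (``sept_ant`` → ``sept_post``);
* ``lvid`` — LV internal diameter, posterior septal endocardium to
  posterior-wall endocardium (``sept_post`` → ``pw_endo``);
* ``pw``   — posterior wall thickness, endocardial to epicardial boundary
  (``pw_endo`` → ``pw_epi``).

Each dimension is the Euclidean distance between its two keypoints *after*
conversion to physical millimetres, so anisotropic pixel spacing is honoured.
A dimension is missing exactly when either of its keypoints is missing; no
plausibility clamping is applied — downstream agreement statistics must see
raw values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical keypoint order used everywhere (tables, loss weights, heatmaps).
KEYPOINT_NAMES: tuple[str, ...] = ("sept_ant", "sept_post", "pw_endo", "pw_epi")

#: Canonical dimension order.
DIMENSIONS: tuple[str, ...] = ("ivs", "lvid", "pw")

#: Dimension -> (start keypoint, end keypoint).  The direction start→end runs
#: anterior to posterior (septum towards posterior wall).
DIMENSION_ENDPOINTS: dict[str, tuple[str, str]] = {
    "ivs": ("sept_ant", "sept_post"),
    "lvid": ("sept_post", "pw_endo"),
    "pw": ("pw_endo", "pw_epi"),
}

#: The measurement line each keypoint is referred to when simulating and when
#: decomposing its placement error.  ``sept_post`` and ``pw_endo`` are the two
#: endpoints of the LV internal diameter and are analysed against that line.
KEYPOINT_LINE: dict[str, str] = {
    "sept_ant": "ivs",
    "sept_post": "lvid",
    "pw_endo": "lvid",
    "pw_epi": "pw",
}

Point = np.ndarray  # shape (2,), (x, y) order


def _as_point(p) -> Point | None:
    if p is None:
        return None
    arr = np.asarray(p, dtype=float)
    if arr.shape != (2,):
        raise ValueError(f"a point must have exactly 2 coordinates, got shape {arr.shape}")
    if np.isnan(arr).any():
        return None
    if not np.isfinite(arr).all():
        raise ValueError(f"point coordinates must be finite, got {arr}")
    return arr


@dataclass
class KeypointSet:
    """The four PLAX landmarks in pixel coordinates, each possibly missing.

    Coordinates are ``(x, y)`` = (column, row), 0-based, origin at the
    top-left pixel centre.  ``None`` marks a missing keypoint.
    """

    sept_ant: Point | None = None
    sept_post: Point | None = None
    pw_endo: Point | None = None
    pw_epi: Point | None = None

    def __post_init__(self) -> None:
        for name in KEYPOINT_NAMES:
            setattr(self, name, _as_point(getattr(self, name)))

    def __getitem__(self, name: str) -> Point | None:
        if name not in KEYPOINT_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self) -> dict[str, Point | None]:
        return {name: self[name] for name in KEYPOINT_NAMES}

    def present(self) -> list[str]:
        return [name for name in KEYPOINT_NAMES if self[name] is not None]

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "KeypointSet":
        return cls(**{name: d.get(name) for name in KEYPOINT_NAMES})


@dataclass
class MeasurementRecord:
    """Derived dimensions in mm for one annotation of one frame."""

    ivs_mm: float
    lvid_mm: float
    pw_mm: float
    frame_id: str | None = None
    rater_id: str | None = None
    reading_index: int | None = None
    phase: str | None = None

    def as_dict(self) -> dict[str, float]:
        return {"ivs": self.ivs_mm, "lvid": self.lvid_mm, "pw": self.pw_mm}


def _to_mm(p: Point, spacing_row_mm: float, spacing_col_mm: float) -> Point:
    return np.array([p[0] * spacing_col_mm, p[1] * spacing_row_mm])


def _check_spacings(spacing_row_mm: float, spacing_col_mm: float) -> None:
    if spacing_row_mm <= 0 or spacing_col_mm <= 0:
        raise ValueError(
            f"pixel spacings must be positive, got row={spacing_row_mm}, col={spacing_col_mm}"
        )


def compute_dimensions(
    keypoints: KeypointSet,
    spacing_row_mm: float,
    spacing_col_mm: float,
    *,
    frame_id: str | None = None,
    rater_id: str | None = None,
    reading_index: int | None = None,
    phase: str | None = None,
) -> MeasurementRecord:
    """Euclidean mm distances between the keypoint pairs of each dimension.

    Missing keypoints propagate: a dimension is ``nan`` iff either endpoint
    is missing.  Coincident endpoints give 0.0 mm.
    """
    _check_spacings(spacing_row_mm, spacing_col_mm)
    dims: dict[str, float] = {}
    for dim, (a, b) in DIMENSION_ENDPOINTS.items():
        pa, pb = keypoints[a], keypoints[b]
        if pa is None or pb is None:
            dims[dim] = float("nan")
        else:
            d = _to_mm(pb, spacing_row_mm, spacing_col_mm) - _to_mm(
                pa, spacing_row_mm, spacing_col_mm
            )
            dims[dim] = float(np.hypot(d[0], d[1]))
    return MeasurementRecord(
        ivs_mm=dims["ivs"],
        lvid_mm=dims["lvid"],
        pw_mm=dims["pw"],
        frame_id=frame_id,
        rater_id=rater_id,
        reading_index=reading_index,
        phase=phase,
    )


def keypoint_localization_error(
    point,
    reference_point,
    spacing_row_mm: float,
    spacing_col_mm: float,
) -> float:
    """Euclidean mm distance between an observed and a reference keypoint.

    Returns ``nan`` when either point is missing.
    """
    _check_spacings(spacing_row_mm, spacing_col_mm)
    p, q = _as_point(point), _as_point(reference_point)
    if p is None or q is None:
        return float("nan")
    d = _to_mm(p, spacing_row_mm, spacing_col_mm) - _to_mm(q, spacing_row_mm, spacing_col_mm)
    return float(np.hypot(d[0], d[1]))


# ---------------------------------------------------------------------------
# Table-level operations


def measurements_table(annotations: pd.DataFrame, frames: pd.DataFrame) -> pd.DataFrame:
    """Per-reading dimension measurements from a long annotation table.

    Parameters
    ----------
    annotations
        Long table with columns ``frame_id, rater_id, reading_index,
        keypoint_name, x_px, y_px, missing``.
    frames
        Frame metadata with ``frame_id, phase, pixel_spacing_row_mm,
        pixel_spacing_col_mm``.

    Returns
    -------
    DataFrame with one row per (frame_id, rater_id, reading_index) and columns
    ``phase, ivs_mm, lvid_mm, pw_mm`` (NaN = missing).
    """
    ann = annotations.copy()
    miss = ann["missing"].astype(bool)
    ann.loc[miss, ["x_px", "y_px"]] = np.nan
    wide = ann.pivot(
        index=["frame_id", "rater_id", "reading_index"],
        columns="keypoint_name",
        values=["x_px", "y_px"],
    )
    meta = frames.set_index("frame_id")[
        ["phase", "pixel_spacing_row_mm", "pixel_spacing_col_mm"]
    ]
    idx = wide.index.get_level_values("frame_id")
    row_sp = meta["pixel_spacing_row_mm"].reindex(idx).to_numpy(float)
    col_sp = meta["pixel_spacing_col_mm"].reindex(idx).to_numpy(float)
    if np.isnan(row_sp).any() or np.isnan(col_sp).any():
        orphans = sorted(set(idx) - set(meta.index))
        raise ValueError(f"annotations reference frames absent from metadata: {orphans}")

    out = pd.DataFrame(index=wide.index)
    out["phase"] = meta["phase"].reindex(idx).to_numpy()
    for dim, (a, b) in DIMENSION_ENDPOINTS.items():
        dx = (wide[("x_px", b)] - wide[("x_px", a)]).to_numpy(float) * col_sp
        dy = (wide[("y_px", b)] - wide[("y_px", a)]).to_numpy(float) * row_sp
        out[f"{dim}_mm"] = np.hypot(dx, dy)
    return out.reset_index()


def localization_error_table(
    annotations: pd.DataFrame,
    reference: pd.DataFrame,
    frames: pd.DataFrame,
) -> pd.DataFrame:
    """Per-keypoint mm localization error of each annotation vs a reference.

    ``reference`` is a long table ``frame_id, keypoint_name, x_px, y_px``
    (e.g. ground truth or consensus keypoints in pixel coordinates).
    """
    meta = frames.set_index("frame_id")[["pixel_spacing_row_mm", "pixel_spacing_col_mm"]]
    ann = annotations.copy()
    miss = ann["missing"].astype(bool)
    ann.loc[miss, ["x_px", "y_px"]] = np.nan
    merged = ann.merge(
        reference.rename(columns={"x_px": "x_ref", "y_px": "y_ref"}),
        on=["frame_id", "keypoint_name"],
        how="left",
    )
    row_sp = meta["pixel_spacing_row_mm"].reindex(merged["frame_id"]).to_numpy(float)
    col_sp = meta["pixel_spacing_col_mm"].reindex(merged["frame_id"]).to_numpy(float)
    dx = (merged["x_px"] - merged["x_ref"]).to_numpy(float) * col_sp
    dy = (merged["y_px"] - merged["y_ref"]).to_numpy(float) * row_sp
    merged["error_mm"] = np.hypot(dx, dy)
    return merged[["frame_id", "rater_id", "reading_index", "keypoint_name", "error_mm"]]
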