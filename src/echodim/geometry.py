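"""Decomposition of keypoint placement errors along the measurement line.

Each keypoint's deviation from the expert-consensus location is re-expressed
in the frame of the consensus measurement line of its own structure (the two
LV-diameter points against the LVID line, the anterior septal point against
the IVS line, the posterior-wall epicardial point against the PW line),
equivalent to rotating and rescaling the image so that the consensus line is
vertical with length 1 unit.  The component along the measurement direction
is termed *transverse* and the perpendicular component (along the myocardium)
*longitudinal*; both are signed fractions of the line length.  Sign
conventions: transverse is positive towards the line's end point (the
posterior direction), longitudinal positive towards the +90° side of the
line (visually counterclockwise from it, with image y pointing down).

All geometry is computed in physical mm so anisotropic pixel spacing cannot
distort angles.  The decomposition is invariant under any global similarity
transform (rotation, uniform scaling, translation) of the coordinates — that
invariance is exactly what the normalization is for.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .measure import DIMENSION_ENDPOINTS, KEYPOINT_LINE, KEYPOINT_NAMES
from .stats import DEFAULT_MIN_EXPERTS, f_test_sd


@dataclass(frozen=True)
class LineFrame:
    """Orthonormal frame attached to one consensus measurement line (mm)."""

    start_mm: np.ndarray
    end_mm: np.ndarray
    length_mm: float
    unit_along: np.ndarray
    unit_perp: np.ndarray


def line_frame(start_mm, end_mm) -> LineFrame:
    """Build the measurement-line frame from its two endpoints (mm)."""
    start = np.asarray(start_mm, dtype=float)
    end = np.asarray(end_mm, dtype=float)
    d = end - start
    length = float(np.hypot(d[0], d[1]))
    if length == 0:
        raise ValueError("coincident endpoints: measurement line has zero length")
    u = d / length
    return LineFrame(
        start_mm=start,
        end_mm=end,
        length_mm=length,
        unit_along=u,
        unit_perp=np.array([u[1], -u[0]]),
    )


def decompose_deviation(observed_mm, consensus_mm, frame: LineFrame) -> tuple[float, float]:
    """(transverse_frac, longitudinal_frac) of one keypoint deviation.

    ``observed_mm`` and ``consensus_mm`` are the observed and consensus
    locations of the same keypoint; components are projections of their
    difference on the line frame, divided by the line length.
    """
    obs = np.asarray(observed_mm, dtype=float)
    con = np.asarray(consensus_mm, dtype=float)
    if np.isnan(obs).any() or np.isnan(con).any():
        raise ValueError("decompose_deviation requires present points")
    d = obs - con
    return (
        float(d @ frame.unit_along / frame.length_mm),
        float(d @ frame.unit_perp / frame.length_mm),
    )


# ---------------------------------------------------------------------------
# Table-level pipeline


def _annotations_mm(annotations: pd.DataFrame, frames: pd.DataFrame) -> pd.DataFrame:
    meta = frames.set_index("frame_id")[
        ["phase", "pixel_spacing_row_mm", "pixel_spacing_col_mm"]
    ]
    ann = annotations.merge(meta, left_on="frame_id", right_index=True, how="left")
    if ann["pixel_spacing_row_mm"].isna().any():
        orphans = sorted(set(annotations["frame_id"]) - set(meta.index))
        raise ValueError(f"annotations reference frames absent from metadata: {orphans}")
    miss = ann["missing"].astype(bool) if "missing" in ann else ann["x_px"].isna()
    ann["x_mm"] = np.where(miss, np.nan, ann["x_px"] * ann["pixel_spacing_col_mm"])
    ann["y_mm"] = np.where(miss, np.nan, ann["y_px"] * ann["pixel_spacing_row_mm"])
    return ann


def consensus_keypoints_table(
    annotations: pd.DataFrame,
    frames: pd.DataFrame,
    expert_ids: Sequence[str],
    *,
    min_experts: int = DEFAULT_MIN_EXPERTS,
) -> pd.DataFrame:
    """Consensus keypoint locations per frame, in mm.

    Coordinate-wise median (x and y separately) across experts of each
    expert's coordinate-wise median position over their readings.  Keypoints
    with fewer than ``min_experts`` contributing experts are NaN.
    """
    ann = _annotations_mm(annotations[annotations["rater_id"].isin(expert_ids)], frames)
    per_expert = ann.groupby(["frame_id", "keypoint_name", "rater_id"], as_index=False)[
        ["x_mm", "y_mm"]
    ].median()
    g = per_expert.groupby(["frame_id", "keypoint_name"])
    cons = g[["x_mm", "y_mm"]].median()
    counts = g["x_mm"].apply(lambda s: int(s.notna().sum()))
    cons.loc[counts < min_experts, ["x_mm", "y_mm"]] = np.nan
    return cons.reset_index()


def _reference_lines(reference: pd.DataFrame) -> pd.DataFrame:
    """Per-frame line parameters (unit vectors, length) from reference keypoints."""
    wide = reference.pivot(index="frame_id", columns="keypoint_name", values=["x_mm", "y_mm"])
    rows = []
    for frame_id, row in wide.iterrows():
        for dim, (a, b) in DIMENSION_ENDPOINTS.items():
            sx, sy = row[("x_mm", a)], row[("y_mm", a)]
            ex, ey = row[("x_mm", b)], row[("y_mm", b)]
            if np.isnan([sx, sy, ex, ey]).any():
                continue
            dx, dy = ex - sx, ey - sy
            length = float(np.hypot(dx, dy))
            if length == 0:
                continue
            rows.append(
                {
                    "frame_id": frame_id,
                    "line": dim,
                    "length_mm": length,
                    "ux": dx / length,
                    "uy": dy / length,
                }
            )
    return pd.DataFrame(rows)


def decompose_table(
    annotations: pd.DataFrame,
    frames: pd.DataFrame,
    expert_ids: Sequence[str],
    ai_id: str = "AI",
    *,
    min_experts: int = DEFAULT_MIN_EXPERTS,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Transverse/longitudinal error fractions for every method and keypoint.

    ``reference`` overrides the consensus keypoints (long table ``frame_id,
    keypoint_name, x_px, y_px`` in pixels — e.g. synthetic ground truth);
    by default the expert consensus is used, as in the validation analysis.
    Every individual reading contributes a row (each expert's two blinded
    readings separately; the AI its single reading).  Rows with a missing
    observed or reference point, or a missing reference line, are dropped.
    """
    if reference is None:
        ref = consensus_keypoints_table(
            annotations, frames, expert_ids, min_experts=min_experts
        )
    else:
        ref = _annotations_mm(reference.assign(rater_id="ref", reading_index=0), frames)[
            ["frame_id", "keypoint_name", "x_mm", "y_mm"]
        ]
    lines = _reference_lines(ref)

    ann = _annotations_mm(annotations, frames)
    obs = ann[ann["rater_id"].isin(list(expert_ids) + [ai_id])][
        ["frame_id", "rater_id", "reading_index", "keypoint_name", "phase", "x_mm", "y_mm"]
    ].rename(columns={"rater_id": "method_id"})
    obs["line"] = obs["keypoint_name"].map(KEYPOINT_LINE)

    merged = obs.merge(
        ref.rename(columns={"x_mm": "cx_mm", "y_mm": "cy_mm"}),
        on=["frame_id", "keypoint_name"],
        how="left",
    ).merge(lines, on=["frame_id", "line"], how="left")
    merged = merged.dropna(subset=["x_mm", "y_mm", "cx_mm", "cy_mm", "length_mm"])

    dx = (merged["x_mm"] - merged["cx_mm"]).to_numpy()
    dy = (merged["y_mm"] - merged["cy_mm"]).to_numpy()
    ux, uy = merged["ux"].to_numpy(), merged["uy"].to_numpy()
    length = merged["length_mm"].to_numpy()
    merged["transverse_frac"] = (dx * ux + dy * uy) / length
    merged["longitudinal_frac"] = (dx * uy - dy * ux) / length
    merged["deviation_mm"] = np.hypot(dx, dy)
    cols = [
        "frame_id",
        "method_id",
        "reading_index",
        "keypoint_name",
        "line",
        "phase",
        "transverse_frac",
        "longitudinal_frac",
        "deviation_mm",
    ]
    return merged[cols].reset_index(drop=True)


def _component_sds(sub: pd.DataFrame) -> tuple[float, float]:
    return (
        float(sub["transverse_frac"].std(ddof=1)) * 100.0,
        float(sub["longitudinal_frac"].std(ddof=1)) * 100.0,
    )


def decomposition_summary(
    decomposition: pd.DataFrame,
    *,
    ai_id: str = "AI",
    expert_pool_id: str = "EXPERTS",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Component SDs (% of line length) and F-test comparisons per stratum.

    Summaries are produced per method (the AI, each expert, and all experts
    pooled under ``expert_pool_id``), per phase (ED, ES, pooled), per
    keypoint and per line (both keypoints of the line pooled).  Comparisons:
    longitudinal vs transverse SD within each line stratum, and posterior vs
    anterior point of the LVID line per component.
    """
    decomp = decomposition.copy()
    pooled = decomp[decomp["method_id"] != ai_id].assign(method_id=expert_pool_id)
    full = pd.concat([decomp, pooled], ignore_index=True)

    summaries, tests = [], []
    for method_id, msub in full.groupby("method_id", sort=True):
        for phase in ("ED", "ES", "pooled"):
            psub = msub if phase == "pooled" else msub[msub["phase"] == phase]
            if psub.empty:
                continue
            strata = [("keypoint_name", kp) for kp in KEYPOINT_NAMES] + [
                ("line", ln) for ln in DIMENSION_ENDPOINTS
            ]
            for col, name in strata:
                sub = psub[psub[col] == name]
                if len(sub) < 2:
                    continue
                t_sd, l_sd = _component_sds(sub)
                summaries.append(
                    {
                        "method_id": method_id,
                        "phase": phase,
                        "scope": col.removesuffix("_name"),
                        "name": name,
                        "n": len(sub),
                        "transverse_sd_pct": t_sd,
                        "longitudinal_sd_pct": l_sd,
                    }
                )
            for ln in DIMENSION_ENDPOINTS:
                sub = psub[psub["line"] == ln]
                if len(sub) < 2:
                    continue
                try:
                    f, p = f_test_sd(sub["longitudinal_frac"], sub["transverse_frac"])
                except ValueError:
                    continue
                tests.append(
                    {
                        "method_id": method_id,
                        "phase": phase,
                        "comparison": f"longitudinal_vs_transverse[{ln}]",
                        "F": f,
                        "p": p,
                        "significant": bool(p < alpha),
                    }
                )
            post = psub[psub["keypoint_name"] == "pw_endo"]
            ant = psub[psub["keypoint_name"] == "sept_post"]
            if len(post) >= 2 and len(ant) >= 2:
                for comp in ("longitudinal_frac", "transverse_frac"):
                    try:
                        f, p = f_test_sd(post[comp], ant[comp])
                    except ValueError:
                        continue
                    tests.append(
                        {
                            "method_id": method_id,
                            "phase": phase,
                            "comparison": f"posterior_vs_anterior[{comp.removesuffix('_frac')}]",
                            "F": f,
                            "p": p,
                            "significant": bool(p < alpha),
                        }
                    )
    return pd.DataFrame(summaries), pd.DataFrame(tests)
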