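"""Simulated expert and AI annotations of phantom frames.

Each reading displaces every ground-truth keypoint by independent Gaussian
noise expressed in the local frame of that keypoint's own measurement line
(septal anterior point → IVS line, the two LV-diameter points → LVID line,
posterior-wall epicardial point → PW line): SD ``transverse_sd_frac * L``
along the measurement direction, ``longitudinal_sd_frac * L`` perpendicular
to it (along the myocardium), with ``L`` the true line length in mm.  A
systematic bias lengthens the targeted dimension by exactly ``bias_mm``
(endpoints displaced by ∓b/2 along the line).  Noise is applied in physical
mm and converted back to pixels.  Readings and keypoint missingness are
mutually independent, mirroring blinded repeated reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RaterModel
from .measure import DIMENSION_ENDPOINTS, KEYPOINT_LINE, KEYPOINT_NAMES, KeypointSet
from .phantom import Frame


@dataclass
class AnnotationRecord:
    """One rater's one reading of one frame."""

    frame_id: str
    rater_id: str
    reading_index: int
    keypoints: KeypointSet


def _perp(u: np.ndarray) -> np.ndarray:
    """Unit vector rotated +90 deg from u (visually counterclockwise, y down)."""
    return np.array([u[1], -u[0]])


def _line_frames(truth_mm: dict[str, np.ndarray]) -> dict[str, tuple[np.ndarray, float]]:
    """Per-dimension (unit direction start→end, length mm) from truth points."""
    frames = {}
    for dim, (a, b) in DIMENSION_ENDPOINTS.items():
        d = truth_mm[b] - truth_mm[a]
        length = float(np.hypot(d[0], d[1]))
        if length == 0:
            raise ValueError(f"degenerate truth geometry: zero-length {dim} line")
        frames[dim] = (d / length, length)
    return frames


def _bias_displacements(
    rater: RaterModel, lines: dict[str, tuple[np.ndarray, float]]
) -> dict[str, np.ndarray]:
    """Keypoint displacements (mm) lengthening each dimension by its bias.

    Anchored at the LVID midline: the two LVID endpoints move by ∓b_lvid/2
    along the LVID direction, and the outer wall points follow their shared
    endpoint plus the full IVS/PW bias along their own line, so each
    dimension changes by exactly its own bias and no other.
    """
    u_ivs, _ = lines["ivs"]
    u_lvid, _ = lines["lvid"]
    u_pw, _ = lines["pw"]
    b_ivs, b_lvid, b_pw = (rater.bias_for(d) for d in ("ivs", "lvid", "pw"))
    d_sept_post = -0.5 * b_lvid * u_lvid
    d_pw_endo = +0.5 * b_lvid * u_lvid
    return {
        "sept_ant": d_sept_post - b_ivs * u_ivs,
        "sept_post": d_sept_post,
        "pw_endo": d_pw_endo,
        "pw_epi": d_pw_endo + b_pw * u_pw,
    }


def simulate_rater_annotations(
    frame: Frame,
    rater: RaterModel,
    n_readings: int = 2,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[AnnotationRecord]:
    """Simulate ``n_readings`` independent blinded readings of one frame."""
    if frame.truth is None or len(frame.truth.present()) < len(KEYPOINT_NAMES):
        raise ValueError("frame must carry complete ground-truth keypoints")
    if n_readings < 1:
        raise ValueError("n_readings must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    row_sp, col_sp = frame.pixel_spacing_row_mm, frame.pixel_spacing_col_mm
    truth_mm = {
        name: np.array([p[0] * col_sp, p[1] * row_sp])
        for name, p in frame.truth.as_dict().items()
    }
    lines = _line_frames(truth_mm)
    bias = _bias_displacements(rater, lines)
    w, h = None, None
    if frame.image is not None:
        h, w = frame.image.shape

    records = []
    for reading in range(n_readings):
        pts: dict[str, np.ndarray | None] = {}
        for name in KEYPOINT_NAMES:
            if rng.random() < rater.miss_prob:
                pts[name] = None
                continue
            u, length = lines[KEYPOINT_LINE[name]]
            noise = (
                rng.normal(0.0, rater.transverse_sd_frac * length) * u
                + rng.normal(0.0, rater.longitudinal_sd_frac * length) * _perp(u)
            )
            p_mm = truth_mm[name] + bias[name] + noise
            p_px = np.array([p_mm[0] / col_sp, p_mm[1] / row_sp])
            if w is not None:
                p_px = np.clip(p_px, [0.0, 0.0], [w - 1.0, h - 1.0])
            pts[name] = p_px
        records.append(
            AnnotationRecord(
                frame_id=frame.frame_id,
                rater_id=rater.rater_id,
                reading_index=reading,
                keypoints=KeypointSet.from_dict(pts),
            )
        )
    return records


def simulate_ai_annotations(
    frame: Frame,
    ai_model: RaterModel,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AnnotationRecord:
    """One automated reading per frame (the AI reads each image once)."""
    return simulate_rater_annotations(frame, ai_model, n_readings=1, seed=seed, rng=rng)[0]
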