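"""Rendering of PLAX-like phantom frames with known ground-truth keypoints.

The phantom is deliberately simple: two bright wall bands (septum and
posterior wall) flanking a dark cavity band, oriented along a sampled
measurement axis, plus additive Gaussian speckle.  It exists to give every
downstream stage — heatmap codec, augmentation, measurement, consensus and
decomposition — a fully known geometry, not to model ultrasound physics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PhantomConfig
from .measure import KeypointSet

#: Rendered intensities (arbitrary units in [0, 1]).
_BACKGROUND = 0.30
_WALL = 0.85
_CAVITY = 0.08


class PhantomGeometryError(ValueError):
    """The requested dimensions do not fit inside the image."""


@dataclass(frozen=True)
class StudyDimensions:
    """True dimensions (mm) drawn for one study; shared by its ED/ES pair."""

    lvid_d_mm: float
    lvid_s_mm: float
    ivs_mm: float
    pw_mm: float

    def lvid_for(self, phase: str) -> float:
        return self.lvid_d_mm if phase == "ED" else self.lvid_s_mm


@dataclass
class Frame:
    """One phantom frame: image, spacing metadata and ground-truth keypoints."""

    frame_id: str
    study_id: str
    video_id: str
    phase: str
    image: np.ndarray | None
    pixel_spacing_row_mm: float
    pixel_spacing_col_mm: float
    truth: KeypointSet


def _truncated_positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw resampled until strictly positive."""
    if sd == 0:
        if mean <= 0:
            raise ValueError("zero-SD dimension with nonpositive mean cannot be positive")
        return float(mean)
    while True:
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)


def sample_study_dimensions(config: PhantomConfig, rng: np.random.Generator) -> StudyDimensions:
    """Draw one study's true dimensions; LVIDs is resampled until < LVIDd."""
    lvid_d = _truncated_positive_normal(rng, config.lvid_d_mean_mm, config.lvid_d_sd_mm)
    while True:
        lvid_s = _truncated_positive_normal(rng, config.lvid_s_mean_mm, config.lvid_s_sd_mm)
        if lvid_s < lvid_d:
            break
        if config.lvid_s_sd_mm == 0:
            raise ValueError("lvid_s_mean_mm >= lvid_d draw with zero SD cannot satisfy LVIDs < LVIDd")
    ivs = _truncated_positive_normal(rng, config.ivsd_mean_mm, config.ivsd_sd_mm)
    pw = _truncated_positive_normal(rng, config.pwd_mean_mm, config.pwd_sd_mm)
    return StudyDimensions(lvid_d_mm=lvid_d, lvid_s_mm=lvid_s, ivs_mm=ivs, pw_mm=pw)


def generate_phantom_frame(
    config: PhantomConfig,
    dims: StudyDimensions,
    phase: str,
    *,
    study_id: str = "S000",
    axis_angle_deg: float = 90.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    render: bool = True,
) -> Frame:
    """Render one frame and place its ground-truth keypoints.

    The four landmarks sit on the band boundaries along the measurement axis
    (angle from the image x-axis, y pointing down), centred in the image:
    ``sept_ant``, ``sept_post`` delimit the bright septal band, the dark
    cavity spans the LVID, and ``pw_endo``, ``pw_epi`` delimit the bright
    posterior-wall band.  By construction the mm distance between the truth
    LVID keypoints equals the requested LVID exactly.

    With ``render=False`` only metadata and truth are produced (``image`` is
    ``None``) — used when only geometry is needed.
    """
    if phase not in ("ED", "ES"):
        raise ValueError(f"phase must be 'ED' or 'ES', got {phase!r}")
    if rng is None:
        rng = np.random.default_rng(seed)

    h, w = config.image_height_px, config.image_width_px
    row_sp, col_sp = config.pixel_spacing_row_mm, config.pixel_spacing_col_mm
    theta = np.deg2rad(axis_angle_deg)
    u = np.array([np.cos(theta), np.sin(theta)])  # (x, y) unit vector, mm space

    lvid = dims.lvid_for(phase)
    total = dims.ivs_mm + lvid + dims.pw_mm
    center = np.array([(w - 1) / 2 * col_sp, (h - 1) / 2 * row_sp])
    s0 = -total / 2
    offsets = {
        "sept_ant": s0,
        "sept_post": s0 + dims.ivs_mm,
        "pw_endo": s0 + dims.ivs_mm + lvid,
        "pw_epi": s0 + total,
    }
    kp_dim = {"sept_ant": "ivs", "sept_post": "lvid", "pw_endo": "lvid", "pw_epi": "pw"}
    margin_mm = 2.0 * max(row_sp, col_sp)
    pts_px: dict[str, np.ndarray] = {}
    for name, s in offsets.items():
        p_mm = center + s * u
        x_px, y_px = p_mm[0] / col_sp, p_mm[1] / row_sp
        if not (
            margin_mm / col_sp <= x_px <= (w - 1) - margin_mm / col_sp
            and margin_mm / row_sp <= y_px <= (h - 1) - margin_mm / row_sp
        ):
            raise PhantomGeometryError(
                f"rendered ventricle exceeds image bounds at keypoint {name} "
                f"(dimension '{kp_dim[name]}'): requested ivs={dims.ivs_mm:.1f} mm, "
                f"lvid={lvid:.1f} mm, pw={dims.pw_mm:.1f} mm in a "
                f"{h}x{w} px image at {row_sp}x{col_sp} mm/px"
            )
        pts_px[name] = np.array([x_px, y_px])

    image = None
    if render:
        cols = np.arange(w) * col_sp
        rows = np.arange(h) * row_sp
        X, Y = np.meshgrid(cols, rows)
        s = (X - center[0]) * u[0] + (Y - center[1]) * u[1]
        image = np.full((h, w), _BACKGROUND)
        image[(s >= offsets["sept_ant"]) & (s <= offsets["sept_post"])] = _WALL
        image[(s > offsets["sept_post"]) & (s < offsets["pw_endo"])] = _CAVITY
        image[(s >= offsets["pw_endo"]) & (s <= offsets["pw_epi"])] = _WALL
        if config.speckle_noise_sd > 0:
            image = image + rng.normal(0.0, config.speckle_noise_sd, size=image.shape)
        image = np.clip(image, 0.0, 1.0)

    return Frame(
        frame_id=f"{study_id}_{phase}",
        study_id=study_id,
        video_id=study_id,
        phase=phase,
        image=image,
        pixel_spacing_row_mm=row_sp,
        pixel_spacing_col_mm=col_sp,
        truth=KeypointSet.from_dict(pts_px),
    )
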