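"""Configuration objects for the synthetic validation study.

Defaults reproduce the structure of the multi-centre PLAX validation design:
100 studies contributing one end-diastolic (ED) and one end-systolic (ES)
frame each, 13 accredited experts reading every frame twice while mutually
blinded, plus a single automated ("AI") reading per frame.  Dimension
population parameters are the validation cohort values (LVIDd 47.0 ± 6.4 mm,
LVIDs 37.7 ± 7.3 mm, IVSd 11.7 ± 2.4 mm, PWd 11.0 ± 1.6 mm).

Rater noise is expressed as fractions of the length of the measurement line a
keypoint belongs to, split into a *transverse* component (along the
measurement direction) and a *longitudinal* component (perpendicular, i.e.
along the myocardium).  Observed reader behaviour is strongly anisotropic:
longitudinal scatter far exceeds transverse scatter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .measure import DIMENSIONS


@dataclass
class PhantomConfig:
    """Geometry and population parameters of the rendered PLAX phantom."""

    image_height_px: int = 256
    image_width_px: int = 256
    pixel_spacing_row_mm: float = 0.5
    pixel_spacing_col_mm: float = 0.5
    lvid_d_mean_mm: float = 47.0
    lvid_d_sd_mm: float = 6.4
    lvid_s_mean_mm: float = 37.7
    lvid_s_sd_mm: float = 7.3
    ivsd_mean_mm: float = 11.7
    ivsd_sd_mm: float = 2.4
    pwd_mean_mm: float = 11.0
    pwd_sd_mm: float = 1.6
    axis_angle_deg_range: tuple[float, float] = (60.0, 120.0)
    speckle_noise_sd: float = 0.05
    n_studies: int = 100

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_spacing_row_mm <= 0 or self.pixel_spacing_col_mm <= 0:
            raise ValueError("pixel spacings must be positive")
        for name in ("lvid_d_sd_mm", "lvid_s_sd_mm", "ivsd_sd_mm", "pwd_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.speckle_noise_sd < 0:
            raise ValueError("speckle_noise_sd must be nonnegative")
        if self.n_studies <= 0:
            raise ValueError("n_studies must be positive")
        lo, hi = self.axis_angle_deg_range
        if hi < lo:
            raise ValueError("axis_angle_deg_range must be an interval (lo <= hi)")


@dataclass
class RaterModel:
    """Stochastic annotation model for one reader (human or AI).

    ``transverse_sd_frac`` is the SD of the error along the measurement
    direction and ``longitudinal_sd_frac`` along the myocardium
    (perpendicular), both as fractions of the true length of the keypoint's
    own measurement line.  ``bias_mm`` is a systematic lengthening applied
    along the measurement direction; a scalar applies to all three dimensions,
    a mapping (e.g. ``{"lvid": 2.0}``) targets specific ones.  Each keypoint
    of each reading is independently flagged missing with ``miss_prob``.
    """

    rater_id: str
    longitudinal_sd_frac: float = 0.0
    transverse_sd_frac: float = 0.0
    bias_mm: float | Mapping[str, float] = 0.0
    miss_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.longitudinal_sd_frac < 0 or self.transverse_sd_frac < 0:
            raise ValueError("noise SD fractions must be nonnegative")
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must lie in [0, 1]")

    def bias_for(self, dimension: str) -> float:
        if isinstance(self.bias_mm, Mapping):
            return float(self.bias_mm.get(dimension, 0.0))
        return float(self.bias_mm)


@dataclass
class StudyConfig:
    """Full synthetic validation study: phantom frames plus simulated raters.

    Expert noise presets are the pooled observed per-point component SDs for
    the LV-diameter keypoints (longitudinal ≈ 23 %, transverse ≈ 11.5 % of
    line length); the AI preset uses the corresponding automated-reader
    magnitudes (15 % / 7 %).  ``expert_sd_scale_range`` spreads individual
    experts multiplicatively around the preset so that per-expert summaries
    differ, as they do between real readers.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_experts: int = 13
    n_readings: int = 2
    expert_longitudinal_sd_frac: float = 0.23
    expert_transverse_sd_frac: float = 0.115
    expert_sd_scale_range: tuple[float, float] = (0.7, 1.3)
    expert_miss_prob: float = 0.01
    ai_longitudinal_sd_frac: float = 0.15
    ai_transverse_sd_frac: float = 0.07
    ai_bias_mm: float = 0.0
    ai_miss_prob: float = 0.0
    ai_id: str = "AI"
    render_images: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.phantom, dict):
            self.phantom = PhantomConfig(**self.phantom)
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        if self.n_readings < 1:
            raise ValueError("n_readings must be >= 1")

    def expert_ids(self) -> list[str]:
        return [f"E{i + 1:02d}" for i in range(self.n_experts)]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def study_config_to_dict(config: StudyConfig) -> dict:
    return _to_plain(config)


def study_config_from_dict(d: Mapping) -> StudyConfig:
    d = dict(d)
    if "phantom" in d and isinstance(d["phantom"], Mapping):
        ph = dict(d["phantom"])
        if "axis_angle_deg_range" in ph:
            ph["axis_angle_deg_range"] = tuple(ph["axis_angle_deg_range"])
        d["phantom"] = PhantomConfig(**ph)
    for key in ("expert_sd_scale_range",):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return StudyConfig(**d)


def save_study_config(config: StudyConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(study_config_to_dict(config), sort_keys=True))


def load_study_config(path: str | Path) -> StudyConfig:
    return study_config_from_dict(yaml.safe_load(Path(path).read_text()) or {})
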