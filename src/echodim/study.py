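"""Assembly and serialization of a full synthetic validation study.

A study comprises ``n_studies`` echocardiograms, each contributing one ED and
one ES frame (both from the same notional video), annotated twice by each of
``n_experts`` blinded experts plus once by the AI.  On disk the study is a
directory of 8-bit grayscale PNG frames plus three CSV tables:

* ``frames.csv``      — frame_id, study_id, video_id, phase, pixel spacings;
* ``truth.csv``       — long table of ground-truth keypoints (pixel coords);
* ``annotations.csv`` — long table frame_id, rater_id, reading_index,
  keypoint_name, x_px, y_px, missing (0/1; empty coords when missing).

Coordinates are x = column, y = row, 0-based, origin at the top-left pixel
centre.  Identical seed and config reproduce the dataset byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import RaterModel, StudyConfig, save_study_config
from .measure import KEYPOINT_NAMES
from .phantom import Frame, generate_phantom_frame, sample_study_dimensions
from .raters import AnnotationRecord, simulate_ai_annotations, simulate_rater_annotations

_CSV_FLOAT_FORMAT = "%.6f"


@dataclass
class StudyTables:
    """In-memory representation of a generated study."""

    frames: pd.DataFrame
    truth: pd.DataFrame
    annotations: pd.DataFrame
    images: dict[str, np.ndarray] | None = None


def build_rater_models(config: StudyConfig, rng: np.random.Generator) -> tuple[list[RaterModel], RaterModel]:
    """Expert models (preset SDs jittered per expert) and the AI model."""
    lo, hi = config.expert_sd_scale_range
    experts = []
    for rid in config.expert_ids():
        scale = rng.uniform(lo, hi) if hi > lo else lo
        experts.append(
            RaterModel(
                rater_id=rid,
                longitudinal_sd_frac=config.expert_longitudinal_sd_frac * scale,
                transverse_sd_frac=config.expert_transverse_sd_frac * scale,
                miss_prob=config.expert_miss_prob,
            )
        )
    ai = RaterModel(
        rater_id=config.ai_id,
        longitudinal_sd_frac=config.ai_longitudinal_sd_frac,
        transverse_sd_frac=config.ai_transverse_sd_frac,
        bias_mm=config.ai_bias_mm,
        miss_prob=config.ai_miss_prob,
    )
    return experts, ai


def _annotation_rows(rec: AnnotationRecord) -> list[dict]:
    rows = []
    for name in KEYPOINT_NAMES:
        p = rec.keypoints[name]
        rows.append(
            {
                "frame_id": rec.frame_id,
                "rater_id": rec.rater_id,
                "reading_index": rec.reading_index,
                "keypoint_name": name,
                "x_px": np.nan if p is None else p[0],
                "y_px": np.nan if p is None else p[1],
                "missing": int(p is None),
            }
        )
    return rows


def generate_study_tables(
    config: StudyConfig,
    seed: int,
    *,
    render_images: bool | None = None,
) -> StudyTables:
    """Generate the full study in memory.

    One sequential RNG drives every draw, so a given (config, seed) pair
    always yields the identical study.
    """
    rng = np.random.default_rng(seed)
    render = config.render_images if render_images is None else render_images
    experts, ai = build_rater_models(config, rng)

    frame_rows, truth_rows, ann_rows = [], [], []
    images: dict[str, np.ndarray] = {}
    lo, hi = config.phantom.axis_angle_deg_range
    for i in range(config.phantom.n_studies):
        study_id = f"S{i + 1:03d}"
        dims = sample_study_dimensions(config.phantom, rng)
        angle = rng.uniform(lo, hi) if hi > lo else lo
        for phase in ("ED", "ES"):
            frame = generate_phantom_frame(
                config.phantom,
                dims,
                phase,
                study_id=study_id,
                axis_angle_deg=angle,
                rng=rng,
                render=render,
            )
            frame_rows.append(
                {
                    "frame_id": frame.frame_id,
                    "study_id": frame.study_id,
                    "video_id": frame.video_id,
                    "phase": frame.phase,
                    "pixel_spacing_row_mm": frame.pixel_spacing_row_mm,
                    "pixel_spacing_col_mm": frame.pixel_spacing_col_mm,
                }
            )
            for name in KEYPOINT_NAMES:
                p = frame.truth[name]
                truth_rows.append(
                    {
                        "frame_id": frame.frame_id,
                        "keypoint_name": name,
                        "x_px": p[0],
                        "y_px": p[1],
                        "missing": 0,
                    }
                )
            if render:
                images[frame.frame_id] = frame.image
            for expert in experts:
                for rec in simulate_rater_annotations(
                    frame, expert, n_readings=config.n_readings, rng=rng
                ):
                    ann_rows.extend(_annotation_rows(rec))
            ann_rows.extend(_annotation_rows(simulate_ai_annotations(frame, ai, rng=rng)))

    return StudyTables(
        frames=pd.DataFrame(frame_rows),
        truth=pd.DataFrame(truth_rows),
        annotations=pd.DataFrame(ann_rows),
        images=images if render else None,
    )


def write_study(tables: StudyTables, out_dir: str | Path, *, write_images: bool = True) -> None:
    """Serialize a study to ``out_dir`` (created if absent)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables.frames.to_csv(out / "frames.csv", index=False, float_format=_CSV_FLOAT_FORMAT)
    tables.truth.to_csv(out / "truth.csv", index=False, float_format=_CSV_FLOAT_FORMAT)
    tables.annotations.to_csv(
        out / "annotations.csv", index=False, float_format=_CSV_FLOAT_FORMAT
    )
    if write_images and tables.images is not None:
        frames_dir = out / "frames"
        frames_dir.mkdir(exist_ok=True)
        for frame_id, img in tables.images.items():
            iio.imwrite(
                frames_dir / f"{frame_id}.png",
                np.round(img * 255).astype(np.uint8),
            )


def generate_validation_study(
    config: StudyConfig,
    out_dir: str | Path,
    seed: int,
    *,
    write_images: bool = True,
) -> StudyTables:
    """Generate a study and write it to disk, recording config and seed."""
    tables = generate_study_tables(config, seed, render_images=write_images)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_study(tables, out, write_images=write_images)
    save_study_config(config, out / "study_config.yaml")
    manifest = {
        "seed": seed,
        "n_frames": int(len(tables.frames)),
        "n_annotation_rows": int(len(tables.annotations)),
        "n_experts": config.n_experts,
        "n_readings": config.n_readings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return tables


def load_study(study_dir: str | Path) -> StudyTables:
    """Load the CSV tables of a previously written study (images stay on disk)."""
    d = Path(study_dir)
    truth_path = d / "truth.csv"
    return StudyTables(
        frames=pd.read_csv(d / "frames.csv"),
        truth=pd.read_csv(truth_path) if truth_path.exists() else None,
        annotations=pd.read_csv(d / "annotations.csv"),
    )


def grouped_train_split(
    frames: pd.DataFrame,
    train_frac: float = 0.8,
    seed: int | None = None,
) -> tuple[list[str], list[str]]:
    """Split frames into train / progress-monitoring partitions by video.

    Frames from one video never straddle the two partitions.  Videos are
    shuffled and assigned greedily to the training partition while it fits
    within ``floor(train_frac * n_frames)`` frames; the rest go to progress
    monitoring.  Returns the two lists of frame ids.
    """
    if not {"frame_id", "video_id"}.issubset(frames.columns):
        raise ValueError("frames table must have 'frame_id' and 'video_id' columns")
    if frames["video_id"].isna().any():
        raise ValueError("every frame must have a video id")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    videos = frames.groupby("video_id")["frame_id"].apply(list)
    if len(videos) < 2:
        raise ValueError("need at least 2 videos to form two partitions")
    capacity = int(np.floor(train_frac * len(frames)))
    order = np.random.default_rng(seed).permutation(videos.index.to_numpy())
    train, progress = [], []
    used = 0
    for vid in order:
        ids = videos[vid]
        if used + len(ids) <= capacity:
            train.extend(ids)
            used += len(ids)
        else:
            progress.extend(ids)
    return train, progress
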