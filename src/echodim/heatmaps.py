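"""Gaussian heatmap codec, crop/augmentation operators and unit conversion.

A keypoint regression target is an image with intensity 1 at the point of
interest, decaying to 0 in all directions as a Gaussian with SD ``sigma_px``
(default 4 px — readers cannot re-select the same pixel consistently, so a
broad target is used).  Decoding takes the coordinates of the heatmap peak;
no sub-pixel refinement is applied.  A missing keypoint encodes to an
all-zero map and an all-zero map decodes to missing; its loss weight is 0 so
it contributes nothing to training.

Inference images are centre-cropped to 640x640 with zero padding as needed;
``CropSpec`` carries the exact coordinate mapping both ways.  Training-time
augmentation applies a random affine (identically to image and keypoints),
a gamma change on [0, 1] intensities, and rectangular erasure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

DEFAULT_SIGMA_PX = 4.0
DEFAULT_CROP_PX = 640


def encode_heatmap(
    point,
    shape: tuple[int, int],
    sigma_px: float = DEFAULT_SIGMA_PX,
) -> np.ndarray:
    """Gaussian target map for one keypoint.

    ``point`` is (x, y) pixel coordinates or ``None`` (missing → all zeros).
    Value at pixel q is exp(-||q - p||^2 / (2 sigma^2)); the peak is exactly 1
    at the encoded pixel and the map is *not* renormalized after boundary
    truncation.
    """
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("heatmap shape must be positive")
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    if point is None:
        return np.zeros((h, w))
    x, y = float(point[0]), float(point[1])
    if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
        raise ValueError(f"keypoint ({x}, {y}) lies outside a {h}x{w} image")
    cols = np.arange(w) - x
    rows = np.arange(h) - y
    sq = rows[:, None] ** 2 + cols[None, :] ** 2
    return np.exp(-sq / (2.0 * sigma_px**2))


def decode_heatmap(heatmap: np.ndarray) -> np.ndarray | None:
    """Peak coordinates (x, y) of a heatmap; ``None`` for an all-zero map.

    Ties are broken at the smallest row-major index (numpy argmax order).
    """
    h = np.asarray(heatmap)
    if h.size == 0:
        raise ValueError("heatmap is empty")
    if not h.any():
        return None
    r, c = np.unravel_index(int(np.argmax(h)), h.shape)
    return np.array([float(c), float(r)])


@dataclass(frozen=True)
class CropSpec:
    """Coordinate bookkeeping for a centre crop/pad.

    ``cropped = original + offset`` per axis (offset = leading pad − leading
    crop); the extra pixel of an odd crop or pad goes to the trailing side.
    """

    target_size_px: int
    row_offset: int
    col_offset: int
    pad_top: int
    pad_bottom: int
    pad_left: int
    pad_right: int

    def to_cropped(self, point) -> np.ndarray:
        x, y = float(point[0]), float(point[1])
        return np.array([x + self.col_offset, y + self.row_offset])

    def to_original(self, point) -> np.ndarray:
        x, y = float(point[0]), float(point[1])
        return np.array([x - self.col_offset, y - self.row_offset])

    def contains_original(self, point) -> bool:
        x, y = self.to_cropped(point)
        return 0 <= x <= self.target_size_px - 1 and 0 <= y <= self.target_size_px - 1


def _axis_split(size: int, target: int) -> tuple[int, int, int]:
    """(leading crop, leading pad, trailing pad) for one axis."""
    diff = size - target
    if diff >= 0:
        return diff // 2, 0, 0
    pad = -diff
    return 0, pad // 2, pad - pad // 2


def center_crop(image: np.ndarray, target: int = DEFAULT_CROP_PX) -> tuple[np.ndarray, CropSpec]:
    """Centre crop (or zero-pad) an image to ``target`` x ``target`` pixels."""
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    if target <= 0:
        raise ValueError("target size must be positive")
    h, w = img.shape
    crop_r, pad_t, pad_b = _axis_split(h, target)
    crop_c, pad_l, pad_r = _axis_split(w, target)
    out = img[crop_r : crop_r + min(h, target), crop_c : crop_c + min(w, target)]
    if pad_t or pad_b or pad_l or pad_r:
        out = np.pad(out, ((pad_t, pad_b), (pad_l, pad_r)), constant_values=0)
    spec = CropSpec(
        target_size_px=target,
        row_offset=pad_t - crop_r,
        col_offset=pad_l - crop_c,
        pad_top=pad_t,
        pad_bottom=pad_b,
        pad_left=pad_l,
        pad_right=pad_r,
    )
    return out, spec


def loss_weights(keypoints) -> np.ndarray:
    """Per-keypoint loss weights: 0 where missing, 1 where present.

    Accepts a :class:`~echodim.measure.KeypointSet` or an
    :class:`~echodim.raters.AnnotationRecord`.  Order follows
    :data:`~echodim.measure.KEYPOINT_NAMES`.
    """
    from .measure import KEYPOINT_NAMES

    kps = getattr(keypoints, "keypoints", keypoints)
    return np.array([0.0 if kps[name] is None else 1.0 for name in KEYPOINT_NAMES])


@dataclass
class AugmentConfig:
    """Ranges for the random training-time augmentations.

    Ranges are package choices: rotation ±15°, scale 0.9–1.1, translation ±5 %
    of the image side, gamma 0.7–1.4, erased rectangle up to 10 % of the
    image area.
    """

    rotation_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_frac: float = 0.05
    gamma_range: tuple[float, float] = (0.7, 1.4)
    erase_area_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.scale_range[0] <= 0:
            raise ValueError("affine scale must be positive")
        if self.gamma_range[0] <= 0:
            raise ValueError("gamma must be positive")
        if not 0 <= self.erase_area_frac <= 1:
            raise ValueError("erase_area_frac must lie in [0, 1]")


IDENTITY_AUGMENT = AugmentConfig(
    rotation_deg=0.0,
    scale_range=(1.0, 1.0),
    translate_frac=0.0,
    gamma_range=(1.0, 1.0),
    erase_area_frac=0.0,
)


def _rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def augment_frame(
    image: np.ndarray,
    keypoints: dict[str, np.ndarray | None],
    aug: AugmentConfig | None = None,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    params: dict | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray | None], dict[str, bool]]:
    """Apply one random affine + gamma + erasure draw.

    The affine (rotation, isotropic scale about the image centre, then
    translation) is applied identically to the image and the keypoint
    coordinates; gamma maps intensities I → I**gamma; erasure zeroes a random
    rectangle.  Keypoints mapped outside the image are flagged invalid (their
    loss weight should be 0 downstream); erasure never invalidates a
    keypoint.  Returns (image, keypoints, validity flags).

    ``params`` bypasses sampling with explicit values (keys ``rotation_deg,
    scale, translate_px, gamma, erase``; ``erase`` is (row0, col0, height,
    width) or None) — useful for reproducing a specific transform.
    """
    if aug is None:
        aug = AugmentConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    h, w = img.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)

    if params is not None:
        theta = np.deg2rad(params.get("rotation_deg", 0.0))
        scale = params.get("scale", 1.0)
        t = np.asarray(params.get("translate_px", (0.0, 0.0)), dtype=float)
        gamma = params.get("gamma", 1.0)
        erase = params.get("erase")
        if scale <= 0 or gamma <= 0:
            raise ValueError("scale and gamma must be positive")
    else:
        theta = np.deg2rad(rng.uniform(-aug.rotation_deg, aug.rotation_deg))
        scale = rng.uniform(*aug.scale_range)
        t = np.array(
            [
                rng.uniform(-aug.translate_frac, aug.translate_frac) * w,
                rng.uniform(-aug.translate_frac, aug.translate_frac) * h,
            ]
        )
        gamma = rng.uniform(*aug.gamma_range)

    A = scale * _rotation(theta)  # forward map p' = A (p - c) + c + t, (x, y)
    A_inv = _rotation(-theta) / scale
    swap = np.array([[0.0, 1.0], [1.0, 0.0]])
    matrix_rc = swap @ A_inv @ swap  # same map in (row, col) ordering
    c_rc = center[::-1]
    offset = c_rc - matrix_rc @ (c_rc + t[::-1])
    warped = ndimage.affine_transform(
        img, matrix_rc, offset=offset, order=1, mode="constant", cval=0.0
    )

    warped = np.clip(warped, 0.0, 1.0) ** gamma

    if params is not None:
        if erase is not None:
            r0, c0, eh, ew = erase
            warped[r0 : r0 + eh, c0 : c0 + ew] = 0.0
    elif aug.erase_area_frac > 0:
        area = rng.uniform(0.0, aug.erase_area_frac) * h * w
        aspect = rng.uniform(0.5, 2.0)
        eh = min(h, max(1, int(round(np.sqrt(area * aspect)))))
        ew = min(w, max(1, int(round(np.sqrt(area / aspect)))))
        r0 = rng.integers(0, h - eh + 1)
        c0 = rng.integers(0, w - ew + 1)
        warped[r0 : r0 + eh, c0 : c0 + ew] = 0.0

    out_kps: dict[str, np.ndarray | None] = {}
    valid: dict[str, bool] = {}
    for name, p in keypoints.items():
        if p is None:
            out_kps[name] = None
            valid[name] = False
            continue
        q = A @ (np.asarray(p, dtype=float) - center) + center + t
        out_kps[name] = q
        valid[name] = bool(0 <= q[0] <= w - 1 and 0 <= q[1] <= h - 1)
    return warped, out_kps, valid


def pixels_to_mm(point, spacing_row_mm: float, spacing_col_mm: float) -> np.ndarray:
    """(x_px, y_px) → (x_mm, y_mm) using row/column pixel spacing."""
    if spacing_row_mm <= 0 or spacing_col_mm <= 0:
        raise ValueError("pixel spacings must be positive")
    x, y = float(point[0]), float(point[1])
    return np.array([x * spacing_col_mm, y * spacing_row_mm])


def mm_to_pixels(point, spacing_row_mm: float, spacing_col_mm: float) -> np.ndarray:
    """Inverse of :func:`pixels_to_mm`."""
    if spacing_row_mm <= 0 or spacing_col_mm <= 0:
        raise ValueError("pixel spacings must be positive")
    x, y = float(point[0]), float(point[1])
    return np.array([x / spacing_col_mm, y / spacing_row_mm])
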