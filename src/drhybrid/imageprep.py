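"""Fundus image preparation: black-border cropping, per-model resizing and
training-time augmentation.

The border crop binarizes the grayscale image (channel mean) at a small
intensity threshold and keeps the tight bounding box of pixels above it; the
threshold default of 10 tolerates JPEG noise in nominally black borders.
Augmentation applies rotation, width/height shift, shear, zoom and optional
flips, with out-of-frame regions filled black.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import AffineTransform, resize, warp

__all__ = [
    "GradedImage",
    "CropResult",
    "AugmentConfig",
    "EmptyFundusError",
    "crop_black_border",
    "resize_for_model",
    "augment_image",
    "read_manifest",
    "write_manifest",
    "load_image",
    "save_image",
]

DEFAULT_THRESHOLD = 10


class EmptyFundusError(ValueError):
    """Raised when no pixel exceeds the binarization threshold (all-black image)."""


@dataclass
class GradedImage:
    """An RGB pixel array with its severity grade (0-4)."""

    pixels: np.ndarray
    grade: int
    source_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be non-empty")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.grade not in (0, 1, 2, 3, 4):
            raise ValueError(f"grade must be an integer 0-4, got {self.grade}")


@dataclass(frozen=True)
class CropResult:
    """Cropped pixels and the source bounding box (half-open, 0-based)."""

    pixels: np.ndarray
    bbox: tuple[int, int, int, int]  # (row_min, row_max_ex, col_min, col_max_ex)


@dataclass(frozen=True)
class AugmentConfig:
    rotation_degrees: float = 15.0
    width_shift_frac: float = 0.1
    height_shift_frac: float = 0.1
    shear_degrees: float = 10.0
    zoom_frac: float = 0.1
    horizontal_flip: bool = True
    vertical_flip: bool = True
    flip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("rotation_degrees", "shear_degrees"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("width_shift_frac", "height_shift_frac", "zoom_frac"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must lie in [0, 1]")


def crop_black_border(image: GradedImage, intensity_threshold: int = DEFAULT_THRESHOLD) -> CropResult:
    """Tight bounding box of pixels whose channel-mean intensity exceeds the threshold."""
    if not 0 <= intensity_threshold < 255:
        raise ValueError("intensity_threshold must lie in [0, 255)")
    gray = image.pixels.mean(axis=2)
    mask = gray > intensity_threshold
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyFundusError(
            f"image {image.source_id or '<unnamed>'}: no pixel exceeds threshold "
            f"{intensity_threshold}; rejecting empty fundus"
        )
    bbox = (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
    pixels = image.pixels[bbox[0]:bbox[1], bbox[2]:bbox[3]]
    return CropResult(pixels=pixels, bbox=bbox)


def resize_for_model(pixels: np.ndarray, model_name: str) -> np.ndarray:
    """Resize to the registered square input size of ``model_name`` (bilinear)."""
    from . import backbones  # deferred: backbones imports AugmentConfig from here

    spec = backbones.get_backbone_spec(model_name)
    size = spec.input_size
    pixels = np.asarray(pixels)
    if pixels.shape[:2] == (size, size):
        return pixels.copy()
    out = resize(pixels, (size, size, 3), order=1, preserve_range=True,
                 anti_aliasing=pixels.shape[0] > size)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _affine_params(cfg: AugmentConfig, rng: np.random.Generator) -> dict:
    """Draw one set of transform parameters; draw order is part of the contract."""
    return {
        "rotation": rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees),
        "tx": rng.uniform(-cfg.width_shift_frac, cfg.width_shift_frac),
        "ty": rng.uniform(-cfg.height_shift_frac, cfg.height_shift_frac),
        "shear": rng.uniform(-cfg.shear_degrees, cfg.shear_degrees),
        "zoom": rng.uniform(1.0 - cfg.zoom_frac, 1.0 + cfg.zoom_frac),
        "hflip": bool(cfg.horizontal_flip and rng.random() < cfg.flip_prob),
        "vflip": bool(cfg.vertical_flip and rng.random() < cfg.flip_prob),
    }


def augment_image(pixels: np.ndarray, config: AugmentConfig,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Random affine + flips; preserves shape and dtype, black border fill."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("expected an HxWx3 array")
    p = _affine_params(config, rng)
    out = pixels
    if p["hflip"]:
        out = out[:, ::-1, :]
    if p["vflip"]:
        out = out[::-1, :, :]
    if (p["rotation"], p["shear"], p["tx"], p["ty"]) == (0.0, 0.0, 0.0, 0.0) and p["zoom"] == 1.0:
        return out.copy()

    h, w = pixels.shape[:2]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    core = AffineTransform(
        rotation=np.deg2rad(p["rotation"]),
        shear=np.deg2rad(p["shear"]),
        scale=(p["zoom"], p["zoom"]),
    )
    to_center = AffineTransform(translation=-center)
    back = AffineTransform(translation=center + np.array([p["tx"] * w, p["ty"] * h]))
    tform = to_center + core + back
    warped = warp(out.astype(float), tform.inverse, order=1, cval=0.0,
                  preserve_range=True, mode="constant")
    return np.clip(np.rint(warped), 0, 255).astype(pixels.dtype)


# ---------------------------------------------------------------------------
# manifest and image file I/O

def read_manifest(path: str | Path) -> pd.DataFrame:
    """Delimited manifest with header ``image_path,grade``; grades validated."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = {"image_path", "grade"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    if not df["grade"].isin(range(5)).all():
        bad = sorted(set(df["grade"]) - set(range(5)))
        raise ValueError(f"manifest {path} has grades outside 0-4: {bad}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_image(path: str | Path, grade: int = 0) -> GradedImage:
    with Image.open(path) as img:
        pixels = np.asarray(img.convert("RGB"))
    return GradedImage(pixels=pixels, grade=int(grade), source_id=str(path))


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)
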