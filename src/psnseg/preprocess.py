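"""Intensity and spatial preprocessing, plus training-time augmentation.

Pipeline order: HU clipping -> resampling to the target grid -> (training
only) augmentation.  Evaluation never augments.  Rotations are axis-aligned
90-degree multiples so masks stay exactly binary with no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = ["PreprocessConfig", "clip_hu", "resample", "normalize_intensity", "augment"]


@dataclass
class PreprocessConfig:
    """Preprocessing constants.

    ``intensity_shift_offset`` is a fraction of the clipped window width: with
    the default (-350, 350) HU window an offset of 0.1 allows shifts of up to
    +/- 70 HU, drawn uniformly, applied with probability
    ``intensity_shift_prob`` to the image only.
    """

    hu_window: tuple[float, float] = (-350.0, 350.0)
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    crop_size: tuple[int, int, int] = (96, 96, 96)
    flip_prob: float = 0.1
    rot_prob: float = 0.1
    intensity_shift_prob: float = 0.5
    intensity_shift_offset: float = 0.1
    max_crop_retries: int = 10
    background_crop_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.hu_window
        if low >= high:
            raise ValueError(f"hu_window low must be < high, got {self.hu_window}")
        for p in (self.flip_prob, self.rot_prob, self.intensity_shift_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        self.crop_size = tuple(int(c) for c in self.crop_size)

    @property
    def window_width(self) -> float:
        return self.hu_window[1] - self.hu_window[0]


def clip_hu(vol: Volume, window: tuple[float, float]) -> Volume:
    """Clip intensities to the HU window (idempotent)."""
    low, high = window
    if low >= high:
        raise ValueError(f"window low must be < high, got {window}")
    return Volume(np.clip(vol.values, low, high), vol.spacing_mm, vol.origin_mm)


def normalize_intensity(vol: Volume, window: tuple[float, float]) -> Volume:
    """Map the clipped HU window linearly onto [0, 1] for model input."""
    low, high = window
    vals = (np.clip(vol.values, low, high) - low) / (high - low)
    return Volume(vals.astype(np.float32), vol.spacing_mm, vol.origin_mm)


def resample(
    vol: Volume, target_spacing_mm: tuple[float, float, float], is_mask: bool = False
) -> Volume:
    """Resample to a target spacing; nearest-neighbour for masks, linear else.

    Identical source and target spacings return the values unchanged
    (bit-equal).  Physical extent is preserved to within one voxel.
    """
    target = tuple(float(s) for s in target_spacing_mm)
    if any(s <= 0 for s in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if target == vol.spacing_mm:
        return Volume(vol.values.copy(), vol.spacing_mm, vol.origin_mm)
    factors = [s / t for s, t in zip(vol.spacing_mm, target)]
    out_shape = tuple(int(round(n * f)) for n, f in zip(vol.shape, factors))
    if any(n == 0 for n in out_shape):
        raise ValueError(
            f"resampling {vol.shape} at {vol.spacing_mm} mm to {target} mm "
            "yields a zero-size grid"
        )
    order = 0 if is_mask else 1
    out = ndimage.zoom(vol.values, factors, order=order, grid_mode=True, mode="nearest")
    if is_mask:
        out = out.astype(np.uint8)
    return Volume(out, target, vol.origin_mm)


def _crop_slices(start: np.ndarray, size: tuple[int, int, int]) -> tuple[slice, ...]:
    return tuple(slice(int(s), int(s) + c) for s, c in zip(start, size))


def augment(
    image: Volume,
    mask: np.ndarray,
    config: PreprocessConfig,
    rng: np.random.Generator,
) -> tuple[Volume, np.ndarray]:
    """Seeded spatial + intensity augmentation of an aligned image/mask pair.

    The identical spatial transform (per-axis flips, per-axis 90-degree
    rotations, random crop) is applied to both grids; the intensity shift is
    applied to the image only.  With probability
    ``1 - background_crop_prob`` the crop is re-drawn a bounded number of
    times until it contains foreground (falling back to centring on the
    mask), so a nonempty reference yields a nonempty training target;
    otherwise the crop is unconstrained, exposing the model to the
    pure-background patches it will meet at whole-volume inference.
    """
    mask = np.asarray(mask)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    crop = config.crop_size
    if any(c > n for c, n in zip(crop, image.shape)):
        raise ValueError(f"crop {crop} larger than grid {image.shape}")

    img = image.values
    msk = mask

    # Per-axis flips.
    for ax in range(3):
        if rng.random() < config.flip_prob:
            img = np.flip(img, axis=ax)
            msk = np.flip(msk, axis=ax)

    # Per-axis rotations by random multiples of 90 degrees (exact on masks).
    axis_planes = {0: (1, 2), 1: (0, 2), 2: (0, 1)}
    for ax in range(3):
        if rng.random() < config.rot_prob:
            k = int(rng.integers(1, 4))
            img = np.rot90(img, k=k, axes=axis_planes[ax])
            msk = np.rot90(msk, k=k, axes=axis_planes[ax])

    # Random crop, guaranteed to contain foreground when any exists.
    shape = img.shape
    max_start = np.array([n - c for n, c in zip(shape, crop)])
    unconstrained = rng.random() < config.background_crop_prob
    start = None
    for _ in range(max(1, config.max_crop_retries)):
        cand = np.array([rng.integers(0, m + 1) for m in max_start])
        if unconstrained or msk[_crop_slices(cand, crop)].any() or not msk.any():
            start = cand
            break
    if start is None:
        centroid = np.array(np.nonzero(msk)).mean(axis=1)
        start = np.clip(
            np.round(centroid - np.array(crop) / 2).astype(int), 0, max_start
        )
    sl = _crop_slices(start, crop)
    img = np.ascontiguousarray(img[sl])
    msk = np.ascontiguousarray(msk[sl])

    # Intensity shift on the image only.
    if rng.random() < config.intensity_shift_prob:
        shift = rng.uniform(-1.0, 1.0) * config.intensity_shift_offset * config.window_width
        img = img + shift

    return Volume(img, image.spacing_mm, image.origin_mm), msk
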