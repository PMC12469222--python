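"""Paired image/mask augmentation and minority-class balancing.

Eight techniques are supported: the three flips, rotation within ±10°,
horizontal flip + rotation, translation by up to 1% of the frame, center
zoom within ±10%, and a photometric brightness (±20%) / contrast (±10%)
adjustment.  Geometric techniques are applied identically to image and
mask; the photometric one touches the image only.  Small geometric ranges
are deliberate: large rotations or shifts would change the apparent disc
and cup extents and thereby distort the vCDR the labels are based on.

Masks are always resampled with nearest-neighbor so labels stay in
{0, 1, 2}; images use bilinear interpolation.  Areas transformed in from
outside the frame are filled with background (label 0 / black) — inventing
anatomy at the border is never acceptable.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from skimage import transform

from .synthetic import FundusSample
from .vcdr import classify_vcdr, vertical_extent

TECHNIQUES = (
    "hflip",
    "vflip",
    "hvflip",
    "rotate",
    "hflip_rotate",
    "translate",
    "scale",
    "brightness_contrast",
)

ROTATE_MAX_DEG = 10.0
TRANSLATE_MAX_FRAC = 0.01
SCALE_MAX_FRAC = 0.10
BRIGHTNESS_MAX = 0.20
CONTRAST_MAX = 0.10


def _warp_pair(image, mask, tform):
    warped_img = transform.warp(image.astype(float), tform, order=1,
                                mode="constant", cval=0.0, preserve_range=True)
    warped_mask = transform.warp(mask, tform, order=0,
                                 mode="constant", cval=0, preserve_range=True)
    return np.clip(warped_img, 0, 255).astype(np.uint8), warped_mask.astype(np.uint8)


def _rotate_pair(image, mask, angle_deg):
    img = transform.rotate(image.astype(float), angle_deg, order=1,
                           mode="constant", cval=0.0, preserve_range=True)
    msk = transform.rotate(mask, angle_deg, order=0,
                           mode="constant", cval=0, preserve_range=True)
    return np.clip(img, 0, 255).astype(np.uint8), msk.astype(np.uint8)


def _with_geometry(sample: FundusSample, image, mask, suffix: str) -> FundusSample:
    """Rebuild a sample after a geometric transform, refreshing the vCDR
    ground truth from the transformed mask so the label invariant holds."""
    disc_rows = vertical_extent(mask > 0)
    cup_rows = vertical_extent(mask == 2)
    vcdr = cup_rows / disc_rows if disc_rows else 0.0
    return FundusSample(
        image=image,
        mask=mask,
        glaucoma=classify_vcdr(vcdr) == "glaucoma",
        true_vcdr=vcdr,
        name=f"{sample.name}_{suffix}" if sample.name else suffix,
    )


def apply_technique(sample: FundusSample, technique: str,
                    rng_seed: int = 0) -> FundusSample:
    """Apply one named augmentation (probability fixed at 1) to a sample.

    Random parameters (angle, shift, zoom, brightness/contrast) are drawn
    deterministically from ``rng_seed``.
    """
    if technique not in TECHNIQUES:
        raise ValueError(f"unknown augmentation technique: {technique!r}")
    rng = np.random.default_rng(rng_seed)
    image, mask = sample.image, sample.mask

    if technique == "hflip":
        return _with_geometry(sample, image[:, ::-1].copy(), mask[:, ::-1].copy(),
                              technique)
    if technique == "vflip":
        return _with_geometry(sample, image[::-1].copy(), mask[::-1].copy(),
                              technique)
    if technique == "hvflip":
        return _with_geometry(sample, image[::-1, ::-1].copy(),
                              mask[::-1, ::-1].copy(), technique)
    if technique == "rotate":
        angle = rng.uniform(-ROTATE_MAX_DEG, ROTATE_MAX_DEG)
        return _with_geometry(sample, *_rotate_pair(image, mask, angle), technique)
    if technique == "hflip_rotate":
        angle = rng.uniform(-ROTATE_MAX_DEG, ROTATE_MAX_DEG)
        img, msk = _rotate_pair(image[:, ::-1].copy(), mask[:, ::-1].copy(), angle)
        return _with_geometry(sample, img, msk, technique)
    if technique == "translate":
        h, w = mask.shape
        tx = rng.uniform(-TRANSLATE_MAX_FRAC, TRANSLATE_MAX_FRAC) * w
        ty = rng.uniform(-TRANSLATE_MAX_FRAC, TRANSLATE_MAX_FRAC) * h
        # inverse map: warp applies the inverse of the given transform's inverse
        tform = transform.AffineTransform(translation=(-tx, -ty))
        return _with_geometry(sample, *_warp_pair(image, mask, tform), technique)
    if technique == "scale":
        h, w = mask.shape
        factor = 1.0 + rng.uniform(-SCALE_MAX_FRAC, SCALE_MAX_FRAC)
        # zoom about the frame center, output kept at the original size;
        # inverse map (output -> input): p_in = (p_out - c)/factor + c
        cx, cy = w / 2, h / 2
        inv = np.array([
            [1 / factor, 0, cx * (1 - 1 / factor)],
            [0, 1 / factor, cy * (1 - 1 / factor)],
            [0, 0, 1],
        ])
        tform = transform.AffineTransform(matrix=inv)
        return _with_geometry(sample, *_warp_pair(image, mask, tform), technique)
    # brightness_contrast — image only, mask and vCDR untouched
    b = rng.uniform(-BRIGHTNESS_MAX, BRIGHTNESS_MAX)
    c = rng.uniform(-CONTRAST_MAX, CONTRAST_MAX)
    # fixed affine form: contrast scales around mid-gray, brightness shifts
    adjusted = (image.astype(float) - 127.5) * (1.0 + c) + 127.5 + 255.0 * b
    adjusted = np.clip(adjusted, 0, 255).astype(np.uint8)
    return replace(
        FundusSample(adjusted, mask.copy(), sample.glaucoma, sample.true_vcdr),
        name=f"{sample.name}_{technique}" if sample.name else technique,
    )


def balance_minority(samples: list[FundusSample],
                     rng_seed: int = 0) -> list[FundusSample]:
    """Balance the two classes by augmenting every minority sample 8 ways.

    Each of the eight techniques is applied exactly once per minority
    sample, growing the minority from m to 9m while the majority is left
    untouched.  With the clinical 1:9 imbalance (m majority = 9m) the
    output is exactly balanced.  Output order: all originals in input
    order, then augmented samples grouped by source sample.
    """
    n_glaucoma = sum(1 for s in samples if s.glaucoma)
    n_normal = len(samples) - n_glaucoma
    if n_glaucoma == 0 or n_normal == 0:
        raise ValueError("both classes must be present to balance")
    if n_glaucoma == n_normal:
        return list(samples)
    minority_is_glaucoma = n_glaucoma < n_normal

    out = list(samples)
    aug_index = 0
    for sample in samples:
        if sample.glaucoma != minority_is_glaucoma:
            continue
        for technique in TECHNIQUES:
            out.append(apply_technique(
                sample, technique,
                rng_seed=(rng_seed * 131 + aug_index) % (2**31)))
            aug_index += 1
    return out
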