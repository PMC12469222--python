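"""Synthetic fundus-like images with pixel-perfect disc/cup ground truth.

Real fundus photographs show the optic disc as a bright yellow-orange
ellipse on a dark reddish retina, with the still-brighter optic cup inside
it and dark vessels crossing the frame.  The generator reproduces exactly
those features — nothing more — so that every downstream stage (detection,
cropping, segmentation, ellipse refit, vCDR) can be exercised and verified
against exact ground truth without downloading clinical data.

The glaucoma label of each synthetic eye is derived from the rendered
mask's true vertical cup-to-disc ratio with the same strict > 0.5 rule the
screening pipeline applies, so generator and pipeline agree by
construction.  Normal eyes draw the vertical cup ratio uniformly from
[0.30, 0.45], glaucomatous eyes from [0.55, 0.80]; both ranges sit clear of
the 0.5 decision boundary so rasterization cannot flip a label.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .vcdr import CUP, DISC, classify_vcdr, vertical_extent

# Intensity model (8-bit RGB): dark red retina, bright disc, brighter cup.
BACKGROUND_COLOR = np.array([120.0, 45.0, 30.0])
DISC_COLOR = np.array([235.0, 180.0, 95.0])
CUP_COLOR = np.array([252.0, 228.0, 160.0])
VESSEL_COLOR = np.array([80.0, 22.0, 18.0])

NORMAL_VCDR_RANGE = (0.30, 0.45)
GLAUCOMA_VCDR_RANGE = (0.55, 0.80)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic fundus image."""

    image_size: int = 640
    disc_center: tuple[float, float] = (320.0, 320.0)  # (x, y) pixels
    disc_axes: tuple[float, float] = (70.0, 80.0)  # (semi-horizontal, semi-vertical)
    cup_ratio_v: float = 0.4
    cup_ratio_h: float = 0.4
    cup_jitter: tuple[float, float] = (0.0, 0.0)  # cup-center offset, pixels
    vessel_count: int = 4
    noise_sd: float = 8.0
    brightness_gradient: bool = True
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0 < self.cup_ratio_v < 1 and 0 < self.cup_ratio_h < 1):
            raise ValueError("cup ratios must lie in (0, 1)")
        ax, ay = self.disc_axes
        cx, cy = self.disc_center
        s = self.image_size
        if not (ax <= cx <= s - ax and ay <= cy <= s - ay):
            raise ValueError("disc ellipse must lie fully inside the image frame")
        jx, jy = self.cup_jitter
        # containment: cup semi-axis + |jitter| must stay inside the disc axis
        if abs(jx) > (1 - self.cup_ratio_h) * ax or abs(jy) > (1 - self.cup_ratio_v) * ay:
            raise ValueError("cup jitter breaks cup-inside-disc containment")


@dataclass
class FundusSample:
    image: np.ndarray  # uint8 H x W x 3
    mask: np.ndarray  # uint8 H x W, values in {0, 1, 2}
    glaucoma: bool
    true_vcdr: float
    name: str | None = None


def sample_spec(population: str, rng_seed: int,
                image_size: int = 640) -> SyntheticSpec:
    """Draw a random image specification for one of the two populations.

    ``normal`` draws the vertical cup ratio uniformly in [0.30, 0.45],
    ``glaucoma`` in [0.55, 0.80].  The disc is placed uniformly at random
    subject to fitting fully inside the frame.  Deterministic per seed.
    """
    if population not in ("normal", "glaucoma"):
        raise ValueError(f"population must be 'normal' or 'glaucoma', got {population!r}")
    rng = np.random.default_rng(rng_seed)
    lo, hi = NORMAL_VCDR_RANGE if population == "normal" else GLAUCOMA_VCDR_RANGE
    cup_ratio_v = float(rng.uniform(lo, hi))
    cup_ratio_h = float(np.clip(cup_ratio_v + rng.uniform(-0.05, 0.05), 0.2, 0.9))
    # disc semi-axes ~ 9-13% of the frame, slightly taller than wide
    ax = float(rng.uniform(0.09, 0.12) * image_size)
    ay = float(ax * rng.uniform(1.05, 1.2))
    pad = 10.0
    cx = float(rng.uniform(ax + pad, image_size - ax - pad))
    cy = float(rng.uniform(ay + pad, image_size - ay - pad))
    # small cup-center jitter, <= 10% of the free axis difference
    jx = float(rng.uniform(-0.1, 0.1) * (1 - cup_ratio_h) * ax)
    jy = float(rng.uniform(-0.1, 0.1) * (1 - cup_ratio_v) * ay)
    return SyntheticSpec(
        image_size=image_size,
        disc_center=(cx, cy),
        disc_axes=(ax, ay),
        cup_ratio_v=cup_ratio_v,
        cup_ratio_h=cup_ratio_h,
        cup_jitter=(jx, jy),
        rng_seed=rng_seed,
    )


def _ellipse_interior(shape, center, axes):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((xx - center[0]) / axes[0]) ** 2 + ((yy - center[1]) / axes[1]) ** 2 <= 1.0


def _draw_vessels(image: np.ndarray, rng: np.random.Generator, count: int) -> None:
    """Paint dark quadratic-Bezier curves of varying thickness in place."""
    h, w = image.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(count):
        p0 = rng.uniform(0, [w, h])
        p2 = rng.uniform(0, [w, h])
        p1 = (p0 + p2) / 2 + rng.uniform(-0.3, 0.3, 2) * [w, h]
        thickness = rng.uniform(2.0, 5.0)
        t = np.linspace(0, 1, 160)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
        for px, py in pts:
            x0, x1 = int(max(px - thickness - 1, 0)), int(min(px + thickness + 2, w))
            y0, y1 = int(max(py - thickness - 1, 0)), int(min(py + thickness + 2, h))
            if x0 >= x1 or y0 >= y1:
                continue
            patch = (xx[y0:y1, x0:x1] - px) ** 2 + (yy[y0:y1, x0:x1] - py) ** 2
            inside = patch <= thickness**2
            image[y0:y1, x0:x1][inside] = VESSEL_COLOR


def render_fundus(spec: SyntheticSpec) -> FundusSample:
    """Rasterize a specification into an image + noise-free label mask.

    The mask is exact (ellipse-interior tests at pixel centers) and never
    receives noise; photometric effects (vessels, brightness gradient,
    Gaussian noise) touch the image only.  ``true_vcdr`` is measured from
    the rendered mask by row extents, so downstream vCDR recovery is
    compared like with like.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    s = spec.image_size
    ax, ay = spec.disc_axes
    cup_center = (spec.disc_center[0] + spec.cup_jitter[0],
                  spec.disc_center[1] + spec.cup_jitter[1])
    cup_axes = (spec.cup_ratio_h * ax, spec.cup_ratio_v * ay)

    disc = _ellipse_interior((s, s), spec.disc_center, spec.disc_axes)
    cup = _ellipse_interior((s, s), cup_center, cup_axes)
    cup &= disc  # containment is guaranteed by validate(); clip for safety

    mask = np.zeros((s, s), dtype=np.uint8)
    mask[disc] = DISC
    mask[cup] = CUP

    image = np.empty((s, s, 3), dtype=float)
    image[:] = BACKGROUND_COLOR
    # mild background texture so thresholding is not trivially exact
    image += rng.normal(0.0, 3.0, (s, s, 1))
    _draw_vessels(image, rng, spec.vessel_count)
    image[disc] = DISC_COLOR
    image[cup] = CUP_COLOR
    if spec.brightness_gradient:
        gy = np.linspace(-1.0, 1.0, s)[:, None, None]
        image = image * (1.0 + 0.05 * gy)
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)

    disc_vd = vertical_extent(disc)
    cup_vd = vertical_extent(cup)
    true_vcdr = cup_vd / disc_vd
    return FundusSample(
        image=image,
        mask=mask,
        glaucoma=classify_vcdr(true_vcdr) == "glaucoma",
        true_vcdr=true_vcdr,
    )


def per_sample_seed(master_seed: int, index: int) -> int:
    """Derived per-sample seed: fixed affine increments, kept below 2**31."""
    return (master_seed * 1_000_003 + 7919 * index) % (2**31)


def generate_samples(n_normal: int, n_glaucoma: int, rng_seed: int,
                     image_size: int = 640, noise_sd: float | None = None,
                     ) -> list[FundusSample]:
    """Generate labelled samples in memory (normals first, deterministic)."""
    samples = []
    populations = ["normal"] * n_normal + ["glaucoma"] * n_glaucoma
    for i, pop in enumerate(populations):
        spec = sample_spec(pop, per_sample_seed(rng_seed, i), image_size)
        if noise_sd is not None:
            spec = replace(spec, noise_sd=noise_sd)
        sample = render_fundus(spec)
        sample.name = f"{pop}_{i:04d}"
        samples.append(sample)
    return samples


def generate_dataset(n_normal: int, n_glaucoma: int, rng_seed: int,
                     out_dir: str | os.PathLike, image_size: int = 640,
                     noise_sd: float | None = None) -> pd.DataFrame:
    """Write a synthetic dataset (PNG images + masks + CSV manifest) to disk.

    Layout: ``images/<name>.png`` (8-bit RGB), ``masks/<name>.png``
    (single-channel, raw labels {0,1,2}), ``manifest.csv`` with columns
    filename, split, label, true_vcdr.  Reproducible under the seed.
    """
    if n_normal < 0 or n_glaucoma < 0:
        raise ValueError("sample counts must be non-negative")
    out = Path(out_dir)
    samples = generate_samples(n_normal, n_glaucoma, rng_seed, image_size, noise_sd)
    records = []
    if samples:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
    else:
        out.mkdir(parents=True, exist_ok=True)
    for sample in samples:
        fname = f"{sample.name}.png"
        iio.imwrite(out / "images" / fname, sample.image)
        iio.imwrite(out / "masks" / fname, sample.mask)
        records.append({
            "filename": fname,
            "split": "",
            "label": "glaucoma" if sample.glaucoma else "normal",
            "true_vcdr": sample.true_vcdr,
        })
    manifest = pd.DataFrame(records,
                            columns=["filename", "split", "label", "true_vcdr"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_sample(dataset_dir: str | os.PathLike, filename: str) -> FundusSample:
    """Load one image/mask pair written by :func:`generate_dataset`."""
    root = Path(dataset_dir)
    image = iio.imread(root / "images" / filename)
    mask = iio.imread(root / "masks" / filename)
    disc_rows = vertical_extent(mask > 0)
    cup_rows = vertical_extent(mask == CUP)
    vcdr = cup_rows / disc_rows if disc_rows else 0.0
    return FundusSample(image=image, mask=mask,
                        glaucoma=classify_vcdr(vcdr) == "glaucoma",
                        true_vcdr=vcdr, name=Path(filename).stem)
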