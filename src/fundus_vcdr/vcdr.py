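"""Cup-to-disc ratio computation and ellipse-based mask refinement.

The vertical cup-to-disc ratio (vCDR) is the vertical diameter of the optic
cup divided by the vertical diameter of the optic disc.  An enlarged cup
relative to the disc is the classic structural sign of glaucomatous damage,
and a vCDR above 0.5 is treated as glaucoma-suspect throughout this package.

Masks follow a fixed 3-class convention: 0 = background, 1 = optic disc rim
(disc excluding cup), 2 = optic cup.  The anatomical disc region is therefore
the union of labels 1 and 2.

Vertical diameters are measured as the number of raster rows touched by a
region (inclusive row extent).  This is integer-exact, orientation-locked to
the image y-axis, and — for axis-aligned elliptical regions — coincides with
the ellipse's vertical axis length to within one pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

BACKGROUND, DISC, CUP = 0, 1, 2

#: vCDR strictly above this value is classified as glaucoma.
VCDR_THRESHOLD = 0.5


class MissingDiscError(ValueError):
    """Raised when a mask contains no disc pixels, so the vCDR is undefined."""


class DegenerateRegionError(ValueError):
    """Raised when a region is too small or malformed for an ellipse fit."""


@dataclass(frozen=True)
class EllipseParams:
    """A fitted ellipse: ``center`` is (x, y) in pixels, ``semi_axes`` is
    (major, minor) with major >= minor, ``angle_deg`` is the major-axis
    orientation in degrees within [0, 180)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_deg: float

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a > 0 and b > 0):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")


@dataclass(frozen=True)
class VCDRResult:
    disc_vdiam: int
    cup_vdiam: int
    vcdr: float
    label: str  # "glaucoma" | "normal"
    degenerate: bool = False


@dataclass(frozen=True)
class RefitResult:
    """Output of :func:`refit_mask_ellipses`."""

    mask: np.ndarray
    disc_ellipse: EllipseParams | None
    cup_ellipse: EllipseParams | None
    disc_degenerate: bool
    cup_degenerate: bool


def _class_region(mask: np.ndarray, class_label: int) -> np.ndarray:
    if class_label == DISC:
        # The cup sits inside the disc anatomically; label 1 alone is only
        # the neuroretinal rim.
        return (mask == DISC) | (mask == CUP)
    if class_label == CUP:
        return mask == CUP
    raise ValueError(f"class_label must be 1 (disc) or 2 (cup), got {class_label}")


def largest_component(mask: np.ndarray, class_label: int) -> np.ndarray:
    """Largest 8-connected component of the given class region.

    For the disc (class 1) the region is the union of labels 1 and 2.
    Ties in size are broken by the component whose top-left pixel comes
    first in row-major order.  Returns an all-False raster if the class
    is absent.
    """
    region = _class_region(np.asarray(mask), class_label)
    if not region.any():
        return np.zeros_like(region, dtype=bool)
    labeled, n = measure.label(region, connectivity=2, return_num=True)
    if n == 1:
        return labeled == 1
    flat = labeled.ravel()
    sizes = np.bincount(flat)[1:]  # skip background 0
    best = None
    best_key = None
    first_idx = _first_indices(flat, n)
    for lab in range(1, n + 1):
        key = (-sizes[lab - 1], first_idx[lab - 1])
        if best_key is None or key < best_key:
            best_key, best = key, lab
    return labeled == best


def _first_indices(flat_labels: np.ndarray, n: int) -> np.ndarray:
    first = np.full(n, flat_labels.size, dtype=np.int64)
    idx = np.flatnonzero(flat_labels)
    np.minimum.at(first, flat_labels[idx] - 1, idx)
    return first


def _boundary_points(region: np.ndarray) -> np.ndarray:
    """Sub-pixel boundary of a binary region as (x, y) points."""
    contours = measure.find_contours(region.astype(float), 0.5)
    if not contours:
        return np.empty((0, 2))
    contour = max(contours, key=len)  # outer boundary dominates
    return contour[:, ::-1]  # (row, col) -> (x, y)


def fit_ellipse_to_class(mask: np.ndarray, class_label: int) -> EllipseParams:
    """Least-squares ellipse fit to the boundary of the largest component.

    Raises
    ------
    DegenerateRegionError
        If the component has fewer than 5 boundary points or the fit fails.
    """
    region = largest_component(mask, class_label)
    return fit_ellipse_to_region(region)


def fit_ellipse_to_region(region: np.ndarray) -> EllipseParams:
    # an ellipse has 5 degrees of freedom: demand at least 5 boundary pixels
    n_boundary = int((region & ~ndimage.binary_erosion(region)).sum())
    if n_boundary < 5:
        raise DegenerateRegionError(
            f"need >= 5 boundary pixels for an ellipse fit, got {n_boundary}"
        )
    pts = _boundary_points(region)
    if len(pts) < 5:
        raise DegenerateRegionError(
            f"need >= 5 boundary points for an ellipse fit, got {len(pts)}"
        )
    model = measure.EllipseModel.from_estimate(pts)
    if not model:
        raise DegenerateRegionError("ellipse fit did not converge")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not (np.isfinite([xc, yc, a, b, theta]).all() and a > 0 and b > 0):
        raise DegenerateRegionError("ellipse fit produced invalid parameters")
    angle = np.degrees(theta)
    if b > a:  # canonicalise: first axis is the major one
        a, b = b, a
        angle += 90.0
    return EllipseParams((float(xc), float(yc)), (float(a), float(b)),
                         float(angle % 180.0))


def rasterize_ellipse(params: EllipseParams, shape: tuple[int, int]) -> np.ndarray:
    """Boolean interior raster of an ellipse, evaluated at pixel centers."""
    xc, yc = params.center
    a, b = params.semi_axes
    theta = np.radians(params.angle_deg)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = xx - xc
    dy = yy - yc
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def refit_mask_ellipses(mask: np.ndarray) -> RefitResult:
    """Replace the disc and cup regions by their least-squares ellipses.

    Segmentation networks produce masks with ragged boundaries; refitting
    each region with the ellipse of its boundary points smooths
    irregularities before the vCDR is measured.  The cup is clipped to the
    disc interior so the output always satisfies cup ⊆ disc.  A region whose
    fit is degenerate is passed through unchanged; a mask with no disc
    pixels yields an all-background mask with the degenerate flag set.
    """
    mask = np.asarray(mask)
    disc_region = largest_component(mask, DISC)
    if not disc_region.any():
        return RefitResult(np.zeros_like(mask), None, None, True, True)

    disc_ellipse: EllipseParams | None = None
    disc_degenerate = False
    try:
        disc_ellipse = fit_ellipse_to_region(disc_region)
        disc_fill = rasterize_ellipse(disc_ellipse, mask.shape)
        if not disc_fill.any():  # pathological fit
            raise DegenerateRegionError("disc ellipse rasterised to nothing")
    except DegenerateRegionError:
        disc_degenerate = True
        disc_fill = disc_region

    cup_region = largest_component(mask, CUP)
    cup_ellipse: EllipseParams | None = None
    cup_degenerate = False
    if cup_region.any():
        try:
            cup_ellipse = fit_ellipse_to_region(cup_region)
            cup_fill = rasterize_ellipse(cup_ellipse, mask.shape)
        except DegenerateRegionError:
            cup_degenerate = True
            cup_fill = cup_region
    else:
        cup_degenerate = True
        cup_fill = np.zeros_like(disc_fill)

    cup_fill = cup_fill & disc_fill  # clipping contract
    out = np.zeros_like(mask)
    out[disc_fill] = DISC
    out[cup_fill] = CUP
    return RefitResult(out, disc_ellipse, cup_ellipse, disc_degenerate, cup_degenerate)


def vertical_extent(region: np.ndarray) -> int:
    """Number of raster rows touched by a binary region."""
    rows = np.flatnonzero(region.any(axis=1))
    return int(rows.size)


def compute_vcdr(mask: np.ndarray, threshold: float = VCDR_THRESHOLD) -> VCDRResult:
    """Vertical cup-to-disc ratio of a 3-class mask.

    ``disc_vdiam`` counts rows containing any disc-region pixel (labels 1
    or 2), ``cup_vdiam`` counts rows containing label 2.  A mask without a
    cup yields vcdr = 0 with the degenerate flag set; a mask without a
    disc raises :class:`MissingDiscError` (0/0 is never silently reported).
    """
    mask = np.asarray(mask)
    disc_vdiam = vertical_extent((mask == DISC) | (mask == CUP))
    cup_vdiam = vertical_extent(mask == CUP)
    if disc_vdiam == 0:
        raise MissingDiscError("mask contains no disc pixels; vCDR undefined")
    vcdr = cup_vdiam / disc_vdiam
    return VCDRResult(
        disc_vdiam=disc_vdiam,
        cup_vdiam=cup_vdiam,
        vcdr=vcdr,
        label=classify_vcdr(vcdr, threshold),
        degenerate=cup_vdiam == 0,
    )


def classify_vcdr(vcdr: float, threshold: float = VCDR_THRESHOLD) -> str:
    """Binary screening rule: glaucoma iff vcdr is strictly above threshold.

    A value of exactly 0.5 is classified as normal (the rule is strict).
    """
    if vcdr < 0:
        raise ValueError(f"vcdr must be non-negative, got {vcdr}")
    return "glaucoma" if vcdr > threshold else "normal"


def mean_vcdr_error(pairs: list[tuple[float, float]]) -> float:
    """Mean absolute difference between predicted and true vCDR values."""
    if not pairs:
        raise ValueError("mean_vcdr_error of an empty list is undefined")
    arr = np.asarray(pairs, dtype=float)
    return float(np.abs(arr[:, 0] - arr[:, 1]).mean())
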