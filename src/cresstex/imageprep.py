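"""Plate-image preparation: grey conversion, normalisation, annular ROIs.

Crystallisation plates are scanned at 256 grey levels with equal RGB
weighting.  Analysis regions are concentric annuli ("circular segments") of
the crystallised disc, specified by inner/outer radius percentages of the
90 mm disc (set to 100 %).  The standard segments are 0-50, 50-70, 70-90 and
90-100 %, plus the entire disc 0-100 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

__all__ = [
    "GreyImage",
    "ROISpec",
    "STANDARD_ROIS",
    "to_grey",
    "gaussian_normalize",
    "detect_centre",
    "roi_mask",
    "read_image",
    "write_mask_png",
]


@dataclass
class GreyImage:
    """8-bit grey plate raster with plate geometry.

    ``plate_diameter_px`` is the pixel length of the crystallised disc
    (the 90 mm area, excluding the acrylic ring), not the glass plate.
    """

    pixels: np.ndarray
    centre: tuple[float, float] | None = None
    plate_diameter_px: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("GreyImage requires a 2-D array")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)
        if self.centre is not None:
            r, c = self.centre
            if not (0 <= r < px.shape[0] and 0 <= c < px.shape[1]):
                raise ValueError("centre must lie inside the image")


@dataclass(frozen=True)
class ROISpec:
    """Annulus of the crystallised disc by radius percentages."""

    inner_pct: float
    outer_pct: float

    def __post_init__(self) -> None:
        if not (0 <= self.inner_pct < self.outer_pct <= 100):
            raise ValueError(
                f"need 0 <= inner < outer <= 100, got {self.inner_pct}-{self.outer_pct}"
            )

    @property
    def label(self) -> str:
        return f"{self.inner_pct:g}-{self.outer_pct:g}%"


STANDARD_ROIS = (
    ROISpec(0, 50),
    ROISpec(50, 70),
    ROISpec(70, 90),
    ROISpec(90, 100),
    ROISpec(0, 100),
)


def to_grey(image: np.ndarray) -> np.ndarray:
    """Convert RGB to grey with equal channel weights (rounded mean).

    Grey input passes through unchanged.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 3:
        return np.round(arr.astype(float).mean(axis=2)).astype(np.uint8)
    raise ValueError(f"unsupported channel layout with shape {arr.shape}")


def gaussian_normalize(
    img: GreyImage,
    mask: np.ndarray,
    target_mean: float = 127.5,
    target_sd: float = 32.0,
    method: str = "linear",
) -> GreyImage:
    """Normalise within-ROI intensities to a target mean and SD.

    ``linear`` (default) maps intensities affinely so the within-mask sample
    mean/SD equal the targets, then clips to [0, 255] and re-quantizes.
    ``histogram`` rank-maps the masked intensities onto Gaussian quantiles
    with the same target moments (an alternative reading of "Gaussian
    normalisation"); ties share their mean normal score so the map stays a
    function of grey value.  Pixels outside the mask are untouched.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    px = img.pixels.astype(float)
    vals = px[mask]
    out = px.copy()
    if method == "linear":
        m, s = vals.mean(), vals.std()
        if s == 0:
            out[mask] = target_mean
        else:
            out[mask] = (vals - m) / s * target_sd + target_mean
    elif method == "histogram":
        # average normal score per distinct grey value
        ranks = stats.rankdata(vals, method="average")
        z = stats.norm.ppf(ranks / (len(vals) + 1.0))
        out[mask] = z * target_sd + target_mean
    else:
        raise ValueError(f"unknown method {method!r}")
    out = np.clip(np.round(out), 0, 255)
    return GreyImage(out.astype(np.uint8), img.centre, img.plate_diameter_px)


def detect_centre(img: GreyImage, threshold: float | None = None) -> tuple[float, float]:
    """Centroid of the plate-disc foreground mask.

    Falls back to the metadata centre when present.  A blank image (no
    foreground above threshold) raises.
    """
    if img.centre is not None:
        return img.centre
    px = img.pixels
    if threshold is None:
        if px.min() == px.max():
            raise ValueError("blank image: no foreground")
        threshold = threshold_otsu(px)
    fg = px > threshold
    if not fg.any():
        raise ValueError("no foreground above threshold")
    r, c = ndimage.center_of_mass(fg)
    return float(r), float(c)


def roi_mask(img: GreyImage, spec: ROISpec) -> np.ndarray:
    """Boolean annulus mask: inner_pct/100*R <= r < outer_pct/100*R.

    R is half the plate diameter; the annulus is half-open (inner inclusive)
    so the four standard segments partition the disc pixel-exactly.  The
    outer boundary of the full disc (outer_pct == 100) is closed so no disc
    pixel is orphaned by rounding.
    """
    if img.plate_diameter_px is None:
        raise ValueError("plate_diameter_px is required for ROI masks")
    cy, cx = detect_centre(img)
    R = img.plate_diameter_px / 2.0
    yy, xx = np.ogrid[: img.pixels.shape[0], : img.pixels.shape[1]]
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    lo, hi = spec.inner_pct / 100.0 * R, spec.outer_pct / 100.0 * R
    if spec.outer_pct >= 100:
        return (r >= lo) & (r <= hi)
    return (r >= lo) & (r < hi)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit PNG or TIFF as an 8-bit grey/RGB array."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)  # 65535 -> 255
    return arr


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Export a boolean mask as a black/white PNG for visual audit."""
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)
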