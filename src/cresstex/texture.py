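"""Masked grey-level co-occurrence matrices and second-order texture variables.

A GLCM is the joint probability of the grey values of pixel pairs at a fixed
displacement.  Here pairs are accumulated over the four standard directions
(0, 45, 90, 135 degrees) and both orientations (symmetric matrix), and a
pair contributes only if *both* endpoints lie inside the region-of-interest
mask — this is what makes annular-segment analysis exact at the segment
boundaries.

Fifteen second-order variables characterise each matrix.  With p(i, j) the
pair probabilities, p_x the marginal, mu/sigma its moments, and p_{x+y},
p_{x-y} the sum- and absolute-difference distributions:

- energy            = sum p^2
- entropy           = -sum p ln p
- inertia           = sum (i-j)^2 p           (a.k.a. contrast)
- inverse_different_moment = sum p / (1 + (i-j)^2)
- maximum_probability      = max p
- correlation       = sum (i-mu_x)(j-mu_y) p / (sigma_x sigma_y)
- cluster_shade     = sum (i+j-mu_x-mu_y)^3 p
- cluster_prominence= sum (i+j-mu_x-mu_y)^4 p
- sum_energy / sum_entropy / sum_variance        on p_{x+y}
- difference_energy / difference_entropy         on p_{|x-y|}
- kappa             = (P0 - Pe) / (1 - Pe), the chance-corrected diagonal
                      agreement (P0 = trace, Pe = sum p_x p_y)
- diagonal_moment   = sum sqrt(|i-j|) (i+j-mu_x-mu_y) p, an odd-moment
                      asymmetry statistic that co-varies with cluster_shade

0 * log 0 is 0 throughout; natural logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imageprep import GreyImage, ROISpec, roi_mask

__all__ = [
    "CoocParams",
    "CoocMatrix",
    "FEATURE_NAMES",
    "compute_glcm",
    "compute_features",
    "features_for_rois",
]

DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))

FEATURE_NAMES = (
    "cluster_prominence",
    "cluster_shade",
    "correlation",
    "diagonal_moment",
    "difference_energy",
    "difference_entropy",
    "energy",
    "entropy",
    "inertia",
    "inverse_different_moment",
    "kappa",
    "maximum_probability",
    "sum_energy",
    "sum_entropy",
    "sum_variance",
)


@dataclass(frozen=True)
class CoocParams:
    """GLCM accumulation parameters.

    ``displacement`` is the texture scale in pixels (the assay uses scale 1;
    larger displacements are accepted but unvalidated).  ``levels`` < 256
    rebins grey values by uniform bin width with floor assignment.
    """

    displacement: int = 1
    directions: tuple[tuple[int, int], ...] = DIRECTIONS
    levels: int = 256

    def __post_init__(self) -> None:
        if self.displacement < 1:
            raise ValueError("displacement must be >= 1")
        if not (2 <= self.levels <= 256):
            raise ValueError("levels must be in [2, 256]")


@dataclass
class CoocMatrix:
    """Normalised symmetric co-occurrence probability matrix."""

    p: np.ndarray
    n_pairs: int
    levels: int
    i: np.ndarray = field(init=False, repr=False)
    j: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        idx = np.arange(self.levels, dtype=float)
        self.i, self.j = np.meshgrid(idx, idx, indexing="ij")

    @property
    def p_x(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def p_y(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @property
    def p_sum(self) -> np.ndarray:
        """Distribution of i+j over 0..2(levels-1)."""
        k = (self.i + self.j).astype(int).ravel()
        return np.bincount(k, weights=self.p.ravel(), minlength=2 * self.levels - 1)

    @property
    def p_diff(self) -> np.ndarray:
        """Distribution of |i-j| over 0..levels-1."""
        k = np.abs(self.i - self.j).astype(int).ravel()
        return np.bincount(k, weights=self.p.ravel(), minlength=self.levels)


def _rebin(pixels: np.ndarray, levels: int) -> np.ndarray:
    if levels == 256:
        return pixels.astype(np.int64)
    return (pixels.astype(np.int64) * levels) // 256


def compute_glcm(
    img: GreyImage | np.ndarray,
    mask: np.ndarray,
    params: CoocParams = CoocParams(),
    roi_label: str | None = None,
) -> CoocMatrix:
    """Accumulate the masked symmetric GLCM.

    A pixel pair contributes iff both endpoints lie in the mask; counts are
    accumulated over all directions and both orientations in integer
    arithmetic, then normalised by the total pair count.
    """
    pixels = img.pixels if isinstance(img, GreyImage) else np.asarray(img)
    mask = np.asarray(mask, bool)
    if mask.shape != pixels.shape:
        raise ValueError("mask shape must match image shape")
    g = _rebin(pixels, params.levels)
    L = params.levels
    d = params.displacement
    counts = np.zeros(L * L, dtype=np.int64)
    h, w = g.shape
    for dr, dc in params.directions:
        dr, dc = dr * d, dc * d
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = g[r0:r1, c0:c1]
        b = g[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        m = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if not m.any():
            continue
        counts += np.bincount(a[m] * L + b[m], minlength=L * L)
    counts = counts.reshape(L, L)
    counts = counts + counts.T  # symmetric closure: both orientations
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        where = f" in ROI {roi_label}" if roi_label else ""
        raise ValueError(f"no valid pixel pairs{where}")
    return CoocMatrix(p=counts / n_pairs, n_pairs=n_pairs, levels=L)


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def compute_features(m: CoocMatrix) -> dict[str, float]:
    """The 15 second-order texture variables of a co-occurrence matrix."""
    p, i, j = m.p, m.i, m.j
    p_x, p_y = m.p_x, m.p_y
    mu_x = float((np.arange(m.levels) * p_x).sum())
    mu_y = float((np.arange(m.levels) * p_y).sum())
    var_x = float(((np.arange(m.levels) - mu_x) ** 2 * p_x).sum())
    var_y = float(((np.arange(m.levels) - mu_y) ** 2 * p_y).sum())
    sd = np.sqrt(var_x * var_y)

    dev = i + j - mu_x - mu_y
    diff = i - j

    p_sum = m.p_sum
    ks = np.arange(p_sum.size, dtype=float)
    mu_sum = float((ks * p_sum).sum())
    p_diff = m.p_diff

    p0 = float(np.trace(p))
    pe = float((p_x * p_y).sum())
    kappa = 1.0 if pe == 1.0 else (p0 - pe) / (1.0 - pe)

    if sd == 0:
        correlation = 0.0
    else:
        correlation = float(((i - mu_x) * (j - mu_y) * p).sum() / sd)

    return {
        "cluster_prominence": float((dev**4 * p).sum()),
        "cluster_shade": float((dev**3 * p).sum()),
        "correlation": correlation,
        "diagonal_moment": float((np.sqrt(np.abs(diff)) * dev * p).sum()),
        "difference_energy": float((p_diff**2).sum()),
        "difference_entropy": _entropy(p_diff),
        "energy": float((p**2).sum()),
        "entropy": _entropy(p),
        "inertia": float((diff**2 * p).sum()),
        "inverse_different_moment": float((p / (1.0 + diff**2)).sum()),
        "kappa": float(kappa),
        "maximum_probability": float(p.max()),
        "sum_energy": float((p_sum**2).sum()),
        "sum_entropy": _entropy(p_sum),
        "sum_variance": float(((ks - mu_sum) ** 2 * p_sum).sum()),
    }


def features_for_rois(
    img: GreyImage,
    specs: tuple[ROISpec, ...],
    params: CoocParams = CoocParams(),
) -> pd.DataFrame:
    """Texture variables per annular ROI: one row per ROI.

    A per-ROI failure (no valid pairs) yields NaN features for that row and
    does not abort the other ROIs; ``n_pairs`` records the pair count for
    quality control (0 for failed ROIs).
    """
    rows = []
    for spec in specs:
        mask = roi_mask(img, spec)
        row: dict[str, object] = {"roi": spec.label}
        try:
            m = compute_glcm(img, mask, params, roi_label=spec.label)
            row.update(compute_features(m))
            row["n_pairs"] = m.n_pairs
        except ValueError:
            row.update({name: np.nan for name in FEATURE_NAMES})
            row["n_pairs"] = 0
        rows.append(row)
    return pd.DataFrame(rows)
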