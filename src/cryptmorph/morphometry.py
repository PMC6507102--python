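"""Per-crypt shape features and per-image summaries.

Feature suite computed for every segmented crypt, matching the standard
morphometric definitions used for gland shape:

area
    pixel count converted to um^2;
circularity
    ``4 * pi * A / P^2`` — 1 for a perfect circle, lower for elongated or
    serrated shapes.  The perimeter P uses the Crofton estimator, which
    is unbiased enough on rasterized disks to keep circularity near 1;
eccentricity
    ``sqrt(1 - (b/a)^2)`` of the ellipse with the same normalized second
    central moments as the pixel set (semi-axes a >= b);
nearest neighbor
    minimum centroid-to-centroid distance to any other crypt in the
    image (undefined, not zero, for an isolated crypt);
centroid distance function (CDF)
    distances from the centroid to every boundary pixel, summarized as
    average / minimum / maximum.

All features are computed in pixel units and converted by the pixel
pitch at the module boundary.  Coordinates are 0-based with x = column
and y = row.  Undefined values are represented as NaN and excluded
pairwise from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.measure import perimeter_crofton, regionprops

FEATURE_COLUMNS = [
    "area_um2",
    "circularity",
    "eccentricity",
    "nn_um",
    "cdf_avg_um",
    "cdf_min_um",
    "cdf_max_um",
]


@dataclass
class CryptObject:
    """One segmented crypt and its raw pixel-level measurements."""

    label: int
    pixel_set: np.ndarray  # (n, 2) of (x, y) px
    centroid: tuple[float, float]  # (x_c, y_c) px, area centroid
    boundary: np.ndarray  # (m, 2) of (x_b, y_b) px
    area_px: int
    perimeter_px: float
    ellipse: tuple[float, float, float]  # (a, b, orientation), semi-axes px

    @property
    def a(self) -> float:
        return self.ellipse[0]

    @property
    def b(self) -> float:
        return self.ellipse[1]


def _fit_ellipse(coords_rc: np.ndarray) -> tuple[float, float, float]:
    """Ellipse (a, b, orientation) from normalized second central moments.

    Treats each pixel as a unit square (adds 1/12 to the diagonal of the
    covariance), so even a straight line of pixels has b > 0.  Semi-axes
    follow the moment-matched solid ellipse: a = 2*sqrt(lambda_max).
    """
    rc = coords_rc.astype(float)
    mu = rc.mean(axis=0)
    d = rc - mu
    cov = d.T @ d / len(rc) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_min, lam_max = evals
    a = 2.0 * np.sqrt(lam_max)
    b = 2.0 * np.sqrt(max(lam_min, 0.0))
    vec = evecs[:, 1]  # (row, col) direction of the major axis
    orientation = float(np.arctan2(vec[0], vec[1]))  # angle from +x toward +y
    return float(a), float(b), orientation


def extract_crypts(labels: np.ndarray) -> list[CryptObject]:
    """Build :class:`CryptObject` measurements for every label.

    Boundary pixels are foreground pixels with at least one background
    4-neighbor.  The perimeter is the Crofton estimate on the object's
    own binary mask; the ellipse comes from the pixel-set second moments.
    """
    labels = np.asarray(labels)
    crypts: list[CryptObject] = []
    for prop in regionprops(labels):
        mask = prop.image  # within bbox
        r0, c0, _, _ = prop.bbox
        interior = ndi.binary_erosion(
            mask, structure=ndi.generate_binary_structure(2, 1), border_value=0
        )
        bound = np.argwhere(mask & ~interior)  # (row, col) within bbox
        coords = prop.coords  # (row, col), absolute
        cy, cx = prop.centroid
        a, b, orient = _fit_ellipse(coords)
        crypts.append(
            CryptObject(
                label=int(prop.label),
                pixel_set=coords[:, ::-1].copy(),  # (x, y)
                centroid=(float(cx), float(cy)),
                boundary=(bound[:, ::-1] + [c0, r0]).astype(float),
                area_px=int(prop.area),
                perimeter_px=float(perimeter_crofton(mask, directions=4)),
                ellipse=(a, b, orient),
            )
        )
    return crypts


def circularity(crypt: CryptObject) -> float:
    """``4 pi A / P^2``; NaN for degenerate (single-pixel) objects."""
    if crypt.area_px < 2 or crypt.perimeter_px <= 0:
        return float("nan")
    return 4.0 * np.pi * crypt.area_px / crypt.perimeter_px**2


def eccentricity(crypt: CryptObject) -> float:
    """``sqrt(1 - (b/a)^2)`` of the fitted ellipse; NaN if a == 0."""
    a, b, _ = crypt.ellipse
    if a <= 0:
        return float("nan")
    return float(np.sqrt(max(0.0, 1.0 - (b / a) ** 2)))


def nearest_neighbor_distances(
    crypts: Sequence[CryptObject] | np.ndarray, pitch_um: float = 1.0
) -> np.ndarray:
    """Nearest-neighbor centroid distance for each crypt, in um.

    Accepts a crypt list or an (n, 2) centroid array.  A crypt with no
    neighbor (n < 2) gets NaN — imputing zero or the field diagonal
    would bias cohort means.
    """
    if len(crypts) and isinstance(crypts[0], CryptObject):
        pts = np.array([c.centroid for c in crypts], dtype=float)
    else:
        pts = np.asarray(crypts, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 2:
        return np.full(n, np.nan)
    dist, _ = cKDTree(pts).query(pts, k=2)
    return dist[:, 1] * pitch_um


def centroid_distance_function(
    crypt: CryptObject, pitch_um: float = 1.0
) -> tuple[float, float, float]:
    """(average, minimum, maximum) centroid-to-boundary distance, um."""
    if len(crypt.boundary) == 0:
        raise ValueError(f"crypt {crypt.label} has no boundary pixels")
    d = np.hypot(
        crypt.boundary[:, 0] - crypt.centroid[0],
        crypt.boundary[:, 1] - crypt.centroid[1],
    )
    return (
        float(d.mean()) * pitch_um,
        float(d.min()) * pitch_um,
        float(d.max()) * pitch_um,
    )


def compute_features(
    crypts: Sequence[CryptObject], pitch_um: float
) -> pd.DataFrame:
    """Feature table: one row per crypt, columns :data:`FEATURE_COLUMNS`."""
    nn = nearest_neighbor_distances(crypts, pitch_um)
    rows = []
    for crypt, nn_i in zip(crypts, nn):
        cdf_avg, cdf_min, cdf_max = centroid_distance_function(crypt, pitch_um)
        rows.append(
            dict(
                label=crypt.label,
                area_um2=crypt.area_px * pitch_um**2,
                circularity=circularity(crypt),
                eccentricity=eccentricity(crypt),
                nn_um=nn_i,
                cdf_avg_um=cdf_avg,
                cdf_min_um=cdf_min,
                cdf_max_um=cdf_max,
            )
        )
    return pd.DataFrame(rows, columns=["label", *FEATURE_COLUMNS])


def summarize_image(features: pd.DataFrame, metadata: dict | None = None) -> pd.Series:
    """Per-image mean and sample SD of every feature.

    The SD (the "variance" of the image, heterogeneity of crypts within
    the field) uses the n-1 denominator and needs at least two defined
    values; the mean needs one.  NaN features are excluded pairwise.
    A zero-crypt image yields crypt_count 0 and all statistics NaN.
    """
    out: dict = dict(metadata or {})
    out["crypt_count"] = len(features)
    for col in FEATURE_COLUMNS:
        vals = features[col].dropna() if len(features) else pd.Series(dtype=float)
        out[f"{col}_mean"] = float(vals.mean()) if len(vals) >= 1 else float("nan")
        out[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) >= 2 else float("nan")
    return pd.Series(out)
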