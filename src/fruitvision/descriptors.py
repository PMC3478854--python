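"""The 79-dimensional hybrid descriptor: color, texture, and shape.

Layout (fixed across a fitted pipeline):

* features 0-63  — normalized 4x4x4 quantized-RGB histogram of the object,
* features 64-70 — the seven Unser sum/difference-histogram texture
  indexes (mean, contrast, homogeneity, energy, variance, correlation,
  entropy) computed on the 64-level grayscale of the object,
* features 71-78 — eight mathematical-morphology shape measures (area,
  perimeter, Euler number, convex area, solidity, minor/major ellipse axis
  lengths, eccentricity).

Unser's sum and difference histograms tally ``s = I(k,l) + I(k+d1,l+d2)``
and ``d = I(k,l) - I(k+d1,l+d2)`` over every pixel pair at displacement
``(d1, d2)`` whose members both lie inside the object mask; they are a fast
surrogate for the gray-level co-occurrence matrix.  Both histograms are
normalized to probability masses before the indexes are evaluated, so
energy and homogeneity live in (0, 1] and entropy (natural log) is >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class DescriptorError(ValueError):
    """Raised on degenerate descriptor input (empty mask, no pixel pairs)."""


# ---------------------------------------------------------------------------
# color histogram


@dataclass
class ColorHistogram:
    counts: np.ndarray       # integer counts, one per quantized RGB cell
    normalized: np.ndarray   # fractions summing to 1
    bins_per_channel: int


def color_histogram(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    bins_per_channel: int = 4,
) -> ColorHistogram:
    """Quantized-RGB histogram of the masked pixels.

    Each channel value in [0, 255] maps to bin ``floor(v / (256/bins))``;
    the cell index is ``bR*bins^2 + bG*bins + bB``.  With the default four
    bins per channel the histogram has 4*4*4 = 64 cells.
    """
    if bins_per_channel < 1 or 256 % bins_per_channel != 0:
        raise ValueError("bins_per_channel must divide 256")
    image = np.asarray(image)
    pixels = image.reshape(-1, 3) if mask is None else image[np.asarray(mask, bool)]
    if pixels.size == 0:
        raise DescriptorError("empty mask: no pixels to count")
    width = 256 // bins_per_channel
    q = pixels.astype(np.int64) // width
    idx = (q[:, 0] * bins_per_channel + q[:, 1]) * bins_per_channel + q[:, 2]
    counts = np.bincount(idx, minlength=bins_per_channel**3)
    return ColorHistogram(
        counts=counts,
        normalized=counts / counts.sum(),
        bins_per_channel=bins_per_channel,
    )


# ---------------------------------------------------------------------------
# Unser texture


def quantize_gray(gray: np.ndarray, levels: int = 64) -> np.ndarray:
    """Requantize a [0, 255] gray image to ``levels`` gray levels."""
    if 256 % levels != 0:
        raise ValueError("levels must divide 256")
    return np.asarray(gray).astype(np.int64) // (256 // levels)


@dataclass
class SumDiffHistograms:
    """Counts of pixel-pair sums and differences at one displacement.

    ``h_s[i]`` counts pairs with sum ``i`` for i in [0, 2(G-1)];
    ``h_d[j + G - 1]`` counts pairs with difference ``j`` for
    j in [-(G-1), G-1].  Both sum to the number of valid pairs.
    """

    h_s: np.ndarray
    h_d: np.ndarray
    displacement: tuple[int, int]
    levels: int

    @property
    def n_pairs(self) -> int:
        return int(self.h_s.sum())

    @property
    def sum_values(self) -> np.ndarray:
        return np.arange(2 * self.levels - 1)

    @property
    def diff_values(self) -> np.ndarray:
        return np.arange(-(self.levels - 1), self.levels)


def sum_diff_histograms(
    gray: np.ndarray,
    displacement: tuple[int, int] = (1, 1),
    mask: np.ndarray | None = None,
    levels: int = 64,
) -> SumDiffHistograms:
    """Tally sum/difference histograms over all valid displaced pairs.

    A pair is valid when both pixels are inside the image and (if a mask
    is given) inside the mask.  ``gray`` must already hold quantized
    levels in ``[0, levels-1]``.
    """
    gray = np.asarray(gray, dtype=np.int64)
    if gray.min() < 0 or gray.max() > levels - 1:
        raise ValueError(f"gray values must lie in [0, {levels - 1}]")
    d1, d2 = displacement
    h, w = gray.shape

    r0, r1 = max(0, -d1), min(h, h - d1)
    c0, c1 = max(0, -d2), min(w, w - d2)
    if r0 >= r1 or c0 >= c1:
        raise DescriptorError("displacement larger than image: no pairs")
    a = gray[r0:r1, c0:c1]
    b = gray[r0 + d1 : r1 + d1, c0 + d2 : c1 + d2]
    if mask is not None:
        mask = np.asarray(mask, bool)
        valid = mask[r0:r1, c0:c1] & mask[r0 + d1 : r1 + d1, c0 + d2 : c1 + d2]
    else:
        valid = np.ones(a.shape, bool)
    if not valid.any():
        raise DescriptorError("no valid pixel pairs under the mask")
    s = (a + b)[valid]
    d = (a - b)[valid]
    h_s = np.bincount(s, minlength=2 * levels - 1)
    h_d = np.bincount(d + levels - 1, minlength=2 * levels - 1)
    return SumDiffHistograms(h_s=h_s, h_d=h_d, displacement=(d1, d2), levels=levels)


@dataclass
class UnserFeatures:
    """The seven sum/difference-histogram texture indexes."""

    mean: float
    contrast: float
    homogeneity: float
    energy: float
    variance: float
    correlation: float
    entropy: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.mean,
                self.contrast,
                self.homogeneity,
                self.energy,
                self.variance,
                self.correlation,
                self.entropy,
            ]
        )


def unser_indexes(hists: SumDiffHistograms) -> UnserFeatures:
    """Evaluate the seven texture indexes from normalized histograms.

    With P_s, P_d the probability-normalized sum/difference histograms and
    i, j their support values:

    * mean        mu   = 1/2 sum_i i P_s(i)
    * contrast    C    = sum_j j^2 P_d(j)
    * homogeneity H    = sum_j P_d(j) / (1 + j^2)
    * energy      E    = (sum_i P_s(i)^2) (sum_j P_d(j)^2)
    * variance    s2   = 1/2 (sum_i (i - 2 mu)^2 P_s(i) + sum_j j^2 P_d(j))
    * correlation Cr   = 1/2 (sum_i (i - 2 mu)^2 P_s(i) - sum_j j^2 P_d(j))
    * entropy     Hn   = -sum_i P_s ln P_s - sum_j P_d ln P_d

    so that s2 = Cr + C holds identically.
    """
    n = hists.n_pairs
    if n == 0:
        raise DescriptorError("empty histograms")
    ps = hists.h_s / n
    pd = hists.h_d / n
    i = hists.sum_values
    j = hists.diff_values
    mu = 0.5 * float(np.sum(i * ps))
    contrast = float(np.sum(j**2 * pd))
    homogeneity = float(np.sum(pd / (1.0 + j**2)))
    energy = float(np.sum(ps**2) * np.sum(pd**2))
    s_spread = float(np.sum((i - 2 * mu) ** 2 * ps))
    variance = 0.5 * (s_spread + contrast)
    correlation = 0.5 * (s_spread - contrast)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_s = -np.sum(np.where(ps > 0, ps * np.log(ps), 0.0))
        ent_d = -np.sum(np.where(pd > 0, pd * np.log(pd), 0.0))
    return UnserFeatures(
        mean=mu,
        contrast=contrast,
        homogeneity=homogeneity,
        energy=energy,
        variance=variance,
        correlation=correlation,
        entropy=float(ent_s + ent_d),
    )


def texture_features(
    gray: np.ndarray,
    mask: np.ndarray | None = None,
    displacement: tuple[int, int] = (1, 1),
    levels: int = 64,
) -> UnserFeatures:
    """Unser indexes of a [0, 255] gray image after 64-level quantization."""
    return unser_indexes(
        sum_diff_histograms(quantize_gray(gray, levels), displacement, mask, levels)
    )


# ---------------------------------------------------------------------------
# convex hull


def graham_scan(points: np.ndarray) -> np.ndarray:
    """Convex hull of 2-D points as a counterclockwise vertex array.

    Classic Graham scan: pivot at the lowest (then leftmost) point, sort
    the rest by polar angle, and keep only strict left turns, so collinear
    boundary points are excluded.  Every returned vertex is an input point.

    Raises
    ------
    ValueError
        For fewer than 3 distinct points or an all-collinear set.
    """
    pts = np.unique(np.asarray(points, dtype=np.float64), axis=0)
    if len(pts) < 3:
        raise ValueError("degenerate hull: need >= 3 distinct points")
    pivot_idx = np.lexsort((pts[:, 0], pts[:, 1]))[0]
    pivot = pts[pivot_idx]
    rest = np.delete(pts, pivot_idx, axis=0)
    vec = rest - pivot
    angles = np.arctan2(vec[:, 1], vec[:, 0])
    dist2 = np.einsum("ij,ij->i", vec, vec)
    rest = rest[np.lexsort((dist2, angles))]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    hull = [pivot]
    for p in rest:
        while len(hull) >= 2 and cross(hull[-2], hull[-1], p) <= 0:
            hull.pop()
        hull.append(p)
    if len(hull) < 3:
        raise ValueError("degenerate hull: all points collinear")
    return np.array(hull)


# ---------------------------------------------------------------------------
# shape features


@dataclass
class ShapeFeatures:
    """Morphology measures of a binary object mask.

    Conventions: perimeter counts unit crack edges between foreground and
    background (the frame border counts as background); the Euler number
    uses 8-connected foreground components and 4-connected holes; the
    convex hull is built from pixel-corner points and the convex area
    counts pixel centers inside or on it; ellipse axes come from the
    central second moments with a 1/12 per-pixel variance correction and
    the 4*sqrt(eigenvalue) axis-length convention.
    """

    area: float
    perimeter: float
    euler: float
    convex_area: float
    solidity: float
    minor_length: float
    major_length: float
    eccentricity: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.area,
                self.perimeter,
                self.euler,
                self.convex_area,
                self.solidity,
                self.minor_length,
                self.major_length,
                self.eccentricity,
            ]
        )


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _euler_number(mask: np.ndarray) -> int:
    """Connected components (8-conn) minus holes (4-conn, border open)."""
    n_comp = ndimage.label(mask, structure=np.ones((3, 3), bool))[1]
    bg, n_bg = ndimage.label(~mask, structure=_CROSS)
    border = np.unique(
        np.concatenate([bg[0, :], bg[-1, :], bg[:, 0], bg[:, -1]])
    )
    n_holes = n_bg - np.count_nonzero(border)
    return n_comp - n_holes


def _convex_area(mask: np.ndarray) -> float:
    """Pixel centers inside or on the hull of the boundary pixel corners.

    Works in doubled integer coordinates (corners of pixel (r, c) sit at
    integer points, centers at half-integers) so the inside test is exact.
    """
    # boundary pixels suffice for the hull
    padded = np.pad(mask, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    br, bc = np.nonzero(mask & ~interior)
    corners = np.concatenate(
        [
            np.stack([bc, br], axis=1),
            np.stack([bc + 1, br], axis=1),
            np.stack([bc, br + 1], axis=1),
            np.stack([bc + 1, br + 1], axis=1),
        ]
    )
    try:
        hull = graham_scan(corners)
    except ValueError:  # cannot happen for a non-empty pixel set, but be safe
        return float(mask.sum())
    hull2 = np.rint(hull * 2).astype(np.int64)  # doubled, exact ints
    # doubled pixel centers are the odd lattice points; test the hull bbox
    xmin, ymin = hull2.min(axis=0)
    xmax, ymax = hull2.max(axis=0)
    gx, gy = np.meshgrid(
        np.arange(xmin | 1, xmax + 1, 2), np.arange(ymin | 1, ymax + 1, 2)
    )
    gx, gy = gx.ravel(), gy.ravel()
    inside = np.ones(gx.shape, bool)
    for k in range(len(hull2)):
        x1, y1 = hull2[k]
        x2, y2 = hull2[(k + 1) % len(hull2)]
        inside &= (x2 - x1) * (gy - y1) - (y2 - y1) * (gx - x1) >= 0
    return float(inside.sum())


def shape_features(mask: np.ndarray) -> ShapeFeatures:
    """Compute the eight morphology measures of a binary mask."""
    mask = np.asarray(mask, bool)
    area = int(mask.sum())
    if area == 0:
        raise DescriptorError("empty mask: no object")

    padded = np.pad(mask, 1).astype(np.int64)
    n_adj = (
        (padded[1:-1, 1:-1] & padded[:-2, 1:-1]).sum()
        + (padded[1:-1, 1:-1] & padded[2:, 1:-1]).sum()
        + (padded[1:-1, 1:-1] & padded[1:-1, :-2]).sum()
        + (padded[1:-1, 1:-1] & padded[1:-1, 2:]).sum()
    )
    perimeter = 4 * area - int(n_adj)

    euler = _euler_number(mask)
    convex_area = _convex_area(mask)
    solidity = area / convex_area

    rows, cols = np.nonzero(mask)
    x = cols - cols.mean()
    y = rows - rows.mean()
    mu20 = float(np.mean(x**2)) + 1.0 / 12.0
    mu02 = float(np.mean(y**2)) + 1.0 / 12.0
    mu11 = float(np.mean(x * y))
    common = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    major = 4.0 * np.sqrt(lam1)
    minor = 4.0 * np.sqrt(max(lam2, 0.0))
    eccentricity = float(np.sqrt(max(1.0 - lam2 / lam1, 0.0)))

    return ShapeFeatures(
        area=float(area),
        perimeter=float(perimeter),
        euler=float(euler),
        convex_area=convex_area,
        solidity=float(solidity),
        minor_length=float(minor),
        major_length=float(major),
        eccentricity=eccentricity,
    )


# ---------------------------------------------------------------------------
# assembly


TEXTURE_NAMES = [
    "texture_mean",
    "texture_contrast",
    "texture_homogeneity",
    "texture_energy",
    "texture_variance",
    "texture_correlation",
    "texture_entropy",
]
SHAPE_NAMES = [
    "shape_area",
    "shape_perimeter",
    "shape_euler",
    "shape_convex_area",
    "shape_solidity",
    "shape_minor_length",
    "shape_major_length",
    "shape_eccentricity",
]
FEATURE_NAMES: list[str] = (
    [f"color_{i:02d}" for i in range(64)] + TEXTURE_NAMES + SHAPE_NAMES
)
N_FEATURES = len(FEATURE_NAMES)  # 64 + 7 + 8 = 79


def assemble_feature_vector(
    color: ColorHistogram, texture: UnserFeatures, shape: ShapeFeatures
) -> np.ndarray:
    """Concatenate the three descriptor families in the fixed 79-dim layout."""
    vec = np.concatenate([color.normalized, texture.as_array(), shape.as_array()])
    if vec.shape[0] != N_FEATURES:
        raise ValueError(
            f"descriptor layout mismatch: got {vec.shape[0]} features"
        )
    return vec


@dataclass
class DescriptorConfig:
    bins_per_channel: int = 4
    displacement: tuple[int, int] = (1, 1)
    texture_levels: int = 64
    masked: bool = True  # compute color/texture on foreground pixels only


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    config: DescriptorConfig | None = None,
) -> np.ndarray:
    """Full 79-dimensional descriptor of one segmented image."""
    from fruitvision.segmentation import to_gray

    cfg = config or DescriptorConfig()
    used_mask = np.asarray(mask, bool) if cfg.masked else None
    color = color_histogram(image, used_mask, cfg.bins_per_channel)
    gray = to_gray(image)
    texture = texture_features(
        gray, used_mask, cfg.displacement, cfg.texture_levels
    )
    shape = shape_features(mask)
    return assemble_feature_vector(color, texture, shape)
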