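"""Quadtree split-and-merge segmentation with an Otsu-threshold baseline.

The segmenter assumes one object of interest roughly centered in the frame
on a background whose gray level may drift smoothly (non-uniform lighting).
A global threshold fails on such scenes because the background's gray range
overlaps the object's; split-and-merge instead quadrisects inhomogeneous
blocks until each block is nearly flat, merges adjacent blocks of similar
mean into connected regions, and declares the dominant border-touching
region group to be background.

Conventions: 0-based row-major coordinates; a block is the half-open
rectangle ``[top, top+height) x [left, left+width)``; grayscale conversion
is the broadcast luma ``round(0.299 R + 0.587 G + 0.114 B)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image


class SegmentationError(ValueError):
    """Raised when an image cannot be segmented (e.g. no foreground)."""


# ---------------------------------------------------------------------------
# raster I/O and grayscale conversion


def read_rgb(path) -> np.ndarray:
    """Read a PNG/JPEG raster as an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_mask(path, foreground: np.ndarray) -> None:
    """Write a boolean foreground mask as a single-channel PNG (0/255)."""
    Image.fromarray(np.where(foreground, 255, 0).astype(np.uint8), mode="L").save(path)


def read_mask(path) -> np.ndarray:
    """Read a single-channel mask PNG back to a boolean array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127


def to_gray(image: np.ndarray) -> np.ndarray:
    """Luma grayscale of an H x W x 3 image in [0, 255]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {image.shape}")
    luma = image[..., 0] * 0.299 + image[..., 1] * 0.587 + image[..., 2] * 0.114
    return np.rint(luma).astype(np.uint8)


# ---------------------------------------------------------------------------
# Otsu baseline


def otsu_threshold(gray: np.ndarray, levels: int = 256) -> int:
    """Gray level t in [0, levels-2] maximizing between-class variance.

    Pixels <= t form one class, pixels > t the other.  The smallest
    maximizing level is returned so the result is deterministic.

    Raises
    ------
    SegmentationError
        If the image is constant (no two-class split exists).
    """
    gray = np.asarray(gray)
    hist = np.bincount(gray.ravel(), minlength=levels).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise SegmentationError("constant image: no threshold exists")
    total = hist.sum()
    p = hist / total
    omega = np.cumsum(p)                      # class-0 mass at threshold t
    mu = np.cumsum(p * np.arange(levels))     # class-0 first moment
    mu_t = mu[-1]
    t = np.arange(levels - 1)
    w0, w1 = omega[t], 1.0 - omega[t]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = np.where(
            (w0 > 0) & (w1 > 0),
            (mu_t * w0 - mu[t]) ** 2 / (w0 * w1),
            -np.inf,
        )
    return int(np.argmax(sigma_b))


def otsu_foreground(gray: np.ndarray, levels: int = 256) -> np.ndarray:
    """Baseline object mask from a global Otsu threshold.

    Of the two threshold classes, the one occupying less of the image
    border is taken as the object.
    """
    t = otsu_threshold(gray, levels)
    above = np.asarray(gray) > t
    border = np.zeros_like(above)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    # object = class with the smaller share of the border ring
    if above[border].mean() <= (~above)[border].mean():
        return above
    return ~above


# ---------------------------------------------------------------------------
# split


@dataclass(frozen=True)
class QuadBlock:
    """A rectangular tile of the image (half-open, 0-based)."""

    top: int
    left: int
    height: int
    width: int

    @property
    def area(self) -> int:
        return self.height * self.width


def quadtree_split(
    gray: np.ndarray, split_tolerance: float = 20.0, min_size: int = 4
) -> list[QuadBlock]:
    """Recursively quadrisect inhomogeneous blocks.

    A block is homogeneous iff ``max - min <= split_tolerance``.  Blocks
    whose height and width are both <= ``min_size`` are never split.
    Uneven sides split as floor/ceil halves; the returned blocks tile the
    image exactly.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    gray = np.asarray(gray)
    h, w = gray.shape
    out: list[QuadBlock] = []
    stack = [QuadBlock(0, 0, h, w)]
    while stack:
        b = stack.pop()
        tile = gray[b.top : b.top + b.height, b.left : b.left + b.width]
        if int(tile.max()) - int(tile.min()) <= split_tolerance:
            out.append(b)
            continue
        if b.height <= min_size and b.width <= min_size:
            out.append(b)
            continue
        # floor/ceil quadrant split; a side of length 1 simply is not cut
        rsplit = [b.height // 2, b.height - b.height // 2] if b.height > 1 else [b.height]
        csplit = [b.width // 2, b.width - b.width // 2] if b.width > 1 else [b.width]
        top = b.top
        for rh in rsplit:
            left = b.left
            for cw in csplit:
                stack.append(QuadBlock(top, left, rh, cw))
                left += cw
            top += rh
    return out


# ---------------------------------------------------------------------------
# merge


@dataclass
class RegionMask:
    """Labeled segmentation: region ids 1..R plus an optional object mask."""

    labels: np.ndarray
    foreground: np.ndarray | None = None
    region_means: dict[int, float] = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # anchor to the smaller root for determinism
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def merge_regions(
    blocks: list[QuadBlock],
    gray: np.ndarray,
    merge_tolerance: float = 10.0,
    connectivity: int = 4,
    mixed_threshold: float | None = 20.0,
) -> RegionMask:
    """Merge adjacent blocks of similar mean gray into labeled regions.

    Two adjacent homogeneous blocks join the same region when their mean
    gray values differ by at most ``merge_tolerance``; merging is
    transitive through the block adjacency graph.  Blocks that are still
    inhomogeneous at the minimum size (gray range > ``mixed_threshold``)
    straddle region boundaries: their intermediate means would otherwise
    chain unrelated regions together, so they are excluded from merging
    and afterwards each one joins the adjacent region with the nearest
    mean.  Labels are assigned 1..R in raster order of each region's
    first block (by top-left corner).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    order = sorted(range(len(blocks)), key=lambda i: (blocks[i].top, blocks[i].left))
    n = len(blocks)
    ids = np.empty((h, w), dtype=np.int64)
    means = np.empty(n)
    mixed = np.zeros(n, dtype=bool)
    for rank, i in enumerate(order):
        b = blocks[i]
        tile = gray[b.top : b.top + b.height, b.left : b.left + b.width]
        ids[b.top : b.top + b.height, b.left : b.left + b.width] = rank
        means[rank] = tile.mean()
        if mixed_threshold is not None:
            mixed[rank] = float(tile.max()) - float(tile.min()) > mixed_threshold

    pairs = [
        np.stack([ids[:, :-1].ravel(), ids[:, 1:].ravel()], axis=1),
        np.stack([ids[:-1, :].ravel(), ids[1:, :].ravel()], axis=1),
    ]
    if connectivity == 8:
        pairs.append(np.stack([ids[:-1, :-1].ravel(), ids[1:, 1:].ravel()], axis=1))
        pairs.append(np.stack([ids[:-1, 1:].ravel(), ids[1:, :-1].ravel()], axis=1))
    edges = np.concatenate(pairs)
    edges = np.unique(edges[edges[:, 0] != edges[:, 1]], axis=0)
    edges = np.concatenate([edges, edges[:, ::-1]])  # symmetric adjacency

    uf = _UnionFind(n)
    for a, b_ in edges:
        if mixed[a] or mixed[b_]:
            continue
        if abs(means[a] - means[b_]) <= merge_tolerance:
            uf.union(int(a), int(b_))

    roots = np.array([uf.find(i) for i in range(n)])
    # relabel clean blocks 1..R in order of first appearance
    label_of_root: dict[int, int] = {}
    block_label = np.zeros(n, dtype=np.int64)
    for i in range(n):
        if mixed[i]:
            continue
        r = roots[i]
        if r not in label_of_root:
            label_of_root[r] = len(label_of_root) + 1
        block_label[i] = label_of_root[r]

    region_means: dict[int, float] = {}
    for lab in range(1, len(label_of_root) + 1):
        sel = block_label == lab
        areas = np.array([blocks[order[i]].area for i in np.nonzero(sel)[0]])
        region_means[lab] = float(np.average(means[sel], weights=areas))

    labels = block_label[ids]

    # Mixed blocks straddle region boundaries or belong to heavily
    # textured areas.  They merge transitively among themselves first;
    # then each pixel of a mixed group joins the adjacent clean region
    # whose mean matches its own gray value within merge_tolerance (a
    # sharp edge dissolves cleanly into its two sides), and whatever
    # remains — e.g. a textured object whose blocks are all
    # inhomogeneous — becomes a region of its own.
    if mixed.any():
        uf2 = _UnionFind(n)
        neighbors: dict[int, set[int]] = {}
        for a, b_ in edges:
            neighbors.setdefault(int(a), set()).add(int(b_))
            if mixed[a] and mixed[b_] and abs(means[a] - means[b_]) <= merge_tolerance:
                uf2.union(int(a), int(b_))
        groups: dict[int, list[int]] = {}
        for i in range(n):
            if mixed[i]:
                groups.setdefault(uf2.find(i), []).append(i)
        for root in sorted(groups, key=lambda r: min(groups[r])):
            members = groups[root]
            cand = sorted(
                {
                    int(block_label[j])
                    for i in members
                    for j in neighbors.get(i, set())
                    if block_label[j] > 0
                }
            )
            rows = np.concatenate([
                np.repeat(
                    np.arange(blocks[order[i]].top,
                              blocks[order[i]].top + blocks[order[i]].height),
                    blocks[order[i]].width,
                )
                for i in members
            ])
            cols = np.concatenate([
                np.tile(
                    np.arange(blocks[order[i]].left,
                              blocks[order[i]].left + blocks[order[i]].width),
                    blocks[order[i]].height,
                )
                for i in members
            ])
            vals = gray[rows, cols]
            if cand:
                cmeans = np.array([region_means[c] for c in cand])
                dist = np.abs(vals[:, None] - cmeans[None, :])
                nearest = np.argmin(dist, axis=1)
                matched = dist[np.arange(len(vals)), nearest] <= merge_tolerance
                for ci, c in enumerate(cand):
                    sel = matched & (nearest == ci)
                    labels[rows[sel], cols[sel]] = c
            else:
                matched = np.zeros(len(vals), bool)
            rest = ~matched
            if rest.any():
                lab = len(region_means) + 1
                region_means[lab] = float(vals[rest].mean())
                labels[rows[rest], cols[rest]] = lab
                for i in members:  # so later groups can attach to this one
                    if block_label[i] == 0:
                        block_label[i] = lab

    return RegionMask(labels=labels, region_means=region_means)


# ---------------------------------------------------------------------------
# foreground extraction


def extract_foreground(
    mask: RegionMask, gray: np.ndarray, group_tolerance: float = 10.0
) -> RegionMask:
    """Identify the object as everything outside the dominant border group.

    Regions touching the image border are clustered by mean-gray
    similarity (single linkage, gap <= ``group_tolerance``); the cluster
    with the largest total area is background.  All remaining regions —
    including border-touching clusters of other gray levels — form the
    foreground.
    """
    labels = mask.labels
    h, w = labels.shape
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    if mask.region_means:
        means = mask.region_means
    else:  # reconstruct from the raster if merge metadata is absent
        g = np.asarray(gray, dtype=np.float64)
        means = {
            int(lab): float(g[labels == lab].mean()) for lab in np.unique(labels)
        }
    areas = np.bincount(labels.ravel())

    cand = sorted(border_labels, key=lambda lab: means[int(lab)])
    groups: list[list[int]] = [[int(cand[0])]]
    for lab in cand[1:]:
        if means[int(lab)] - means[groups[-1][-1]] <= group_tolerance:
            groups[-1].append(int(lab))
        else:
            groups.append([int(lab)])
    group_area = [sum(int(areas[lab]) for lab in g) for g in groups]
    background = groups[int(np.argmax(group_area))]

    all_labels = np.unique(labels)
    fg_labels = [int(lab) for lab in all_labels if int(lab) not in background]
    if not fg_labels:
        raise SegmentationError("no foreground found: every region is background")
    foreground = np.isin(labels, fg_labels)
    return RegionMask(labels=labels, foreground=foreground, region_means=means)


# ---------------------------------------------------------------------------
# end-to-end


@dataclass
class SegmentationConfig:
    """Tolerances of the split-and-merge segmenter (0-255 gray scale)."""

    split_tolerance: float = 20.0
    merge_tolerance: float = 10.0
    min_size: int = 4
    connectivity: int = 4


def split_and_merge(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> RegionMask:
    """Segment an RGB image and extract its foreground object.

    Composition: grayscale -> quadtree split -> region merge -> border-rule
    foreground extraction.  Deterministic for a fixed configuration.
    """
    cfg = config or SegmentationConfig()
    gray = to_gray(image)
    blocks = quadtree_split(gray, cfg.split_tolerance, cfg.min_size)
    merged = merge_regions(
        blocks, gray, cfg.merge_tolerance, cfg.connectivity,
        mixed_threshold=cfg.split_tolerance,
    )
    return extract_foreground(merged, gray, cfg.merge_tolerance)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Pixelwise Jaccard overlap of two boolean masks."""
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
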