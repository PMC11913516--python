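"""Color information feature (CIF) extraction.

The CIF descriptor summarizes the color content of an image in two small
probability histograms.  The image is tiled into blocks; each block is
reduced to its channelwise minimum color ``s_min(u, v)`` and maximum
color ``s_max(u, v)`` (the "min and max quantizers").  The collections of
block minima and maxima are each reduced to a small palette with a
balanced color tree (octree) quantizer, and the relative frequency with
which blocks land on each palette entry gives the CIF_min / CIF_max
histograms.

A small convolutional micro-block (pointwise 1x1 convolution, channel
shuffle, 3x3 depthwise convolution, channel reorder) is also provided; it
operates on any NHWC feature map, e.g. the stacked quantizer maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CifContractError(ValueError):
    """Raised when CIF inputs violate an operation contract."""


# ---------------------------------------------------------------------------
# block partition and min/max quantizers


@dataclass
class BlockGrid:
    """Tiling of an image into ``block_size`` chunks; trailing partial blocks kept."""

    image: np.ndarray
    block_size: int
    n_rows: int
    n_cols: int

    def block(self, u: int, v: int) -> np.ndarray:
        b = self.block_size
        return self.image[u * b : (u + 1) * b, v * b : (v + 1) * b]

    def __iter__(self):
        for u in range(self.n_rows):
            for v in range(self.n_cols):
                yield (u, v), self.block(u, v)

    @property
    def n_blocks(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class QuantizerMaps:
    """Per-block channelwise minimum and maximum colors, shape (U, V, C)."""

    s_min: np.ndarray
    s_max: np.ndarray


@dataclass
class Palette:
    """Reduced color palette; entries are distinct RGB triples, lexicographically sorted."""

    entries: np.ndarray  # (k, 3) float64

    @property
    def size(self) -> int:
        return len(self.entries)

    def assign(self, colors: np.ndarray) -> np.ndarray:
        """Nearest-entry index (Euclidean RGB) per color; ties -> lowest index."""
        colors = np.atleast_2d(np.asarray(colors, dtype=np.float64))
        d2 = ((colors[:, None, :] - self.entries[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


@dataclass
class CifFeature:
    """Normalized CIF histograms over the min/max palettes."""

    hist_min: np.ndarray
    hist_max: np.ndarray

    def fused(self) -> np.ndarray:
        return np.concatenate([self.hist_min, self.hist_max])


def partition_blocks(image: np.ndarray, block_size: int) -> BlockGrid:
    """Tile an image into ``ceil(H/b) * ceil(W/b)`` blocks covering every pixel once."""
    if block_size < 1:
        raise CifContractError("block_size must be >= 1")
    image = np.asarray(image)
    h, w = image.shape[:2]
    return BlockGrid(
        image=image,
        block_size=block_size,
        n_rows=-(-h // block_size),
        n_cols=-(-w // block_size),
    )


def minmax_quantize(grid: BlockGrid) -> QuantizerMaps:
    """Channelwise min and max color of every block."""
    if grid.n_blocks == 0:
        raise CifContractError("empty block grid")
    img = grid.image
    channels = 1 if img.ndim == 2 else img.shape[2]
    s_min = np.empty((grid.n_rows, grid.n_cols, channels), dtype=np.float64)
    s_max = np.empty_like(s_min)
    for (u, v), block in grid:
        flat = block.reshape(-1, channels)
        s_min[u, v] = flat.min(axis=0)
        s_max[u, v] = flat.max(axis=0)
    return QuantizerMaps(s_min=s_min, s_max=s_max)


# ---------------------------------------------------------------------------
# balanced-tree (octree) color reduction

_DEPTH = 8


class _OctreeNode:
    __slots__ = ("children", "count", "sums", "depth", "order")

    def __init__(self, depth: int, order: int) -> None:
        self.children: list[_OctreeNode | None] = [None] * 8
        self.count = 0
        self.sums = np.zeros(3, dtype=np.float64)
        self.depth = depth
        self.order = order

    @property
    def is_leaf(self) -> bool:
        return all(c is None for c in self.children)


def _branch_index(color: np.ndarray, depth: int) -> int:
    shift = _DEPTH - 1 - depth
    return (
        (((int(color[0]) >> shift) & 1) << 2)
        | (((int(color[1]) >> shift) & 1) << 1)
        | ((int(color[2]) >> shift) & 1)
    )


def reduce_colors(colors: np.ndarray, k: int) -> Palette:
    """Reduce a color list to at most ``k`` palette entries via octree merging.

    Colors are inserted into a depth-8 balanced color tree (one level per
    RGB bit); leaves are then merged bottom-up — deepest, least-populated
    parents first — until at most ``k`` leaves remain.  Each palette entry
    is the mean color of its merged leaf.  If the input has <= k distinct
    colors the palette is exactly those colors.
    """
    if k < 1:
        raise CifContractError("palette size k must be >= 1")
    colors = np.atleast_2d(np.asarray(colors, dtype=np.float64))
    if colors.size == 0:
        raise CifContractError("colors must be nonempty")
    quantized = np.clip(np.rint(colors), 0, 255).astype(np.int64)

    root = _OctreeNode(0, 0)
    counter = 1
    for color in quantized:
        node = root
        node.count += 1
        node.sums += color
        for depth in range(_DEPTH):
            idx = _branch_index(color, depth)
            if node.children[idx] is None:
                node.children[idx] = _OctreeNode(depth + 1, counter)
                counter += 1
            node = node.children[idx]
            node.count += 1
            node.sums += color

    def leaves(node: _OctreeNode) -> list[_OctreeNode]:
        if node.is_leaf:
            return [node]
        out: list[_OctreeNode] = []
        for c in node.children:
            if c is not None:
                out.extend(leaves(c))
        return out

    def collapsible(node: _OctreeNode) -> list[_OctreeNode]:
        """Internal nodes whose children are all leaves."""
        out = []
        if not node.is_leaf:
            if all(c is None or c.is_leaf for c in node.children):
                out.append(node)
            for c in node.children:
                if c is not None:
                    out.extend(collapsible(c))
        return out

    # merge deepest-first, least-populated-first, in scan batches; a collapsed
    # node already carries its subtree's count and color sum.  Single-child
    # chains collapse without changing the leaf count, so a few outer scans
    # (at most the tree depth) may be needed.
    while True:
        excess = len(leaves(root)) - k
        if excess <= 0:
            break
        cands = collapsible(root)
        cands.sort(key=lambda n: (-n.depth, n.count, n.order))
        for node in cands:
            m = sum(1 for c in node.children if c is not None)
            node.children = [None] * 8
            excess -= m - 1
            if excess <= 0:
                break

    means = np.array([leaf.sums / leaf.count for leaf in leaves(root)])
    means = np.unique(means, axis=0)  # lexicographic sort + dedupe
    return Palette(entries=means)


def cif_histograms(
    maps: QuantizerMaps, pal_min: Palette, pal_max: Palette
) -> CifFeature:
    """Relative-frequency histograms of block quantizers over their palettes.

    ``hist_min[c]`` is the fraction of blocks whose minimum color maps to
    palette entry ``c`` (nearest Euclidean neighbor); likewise ``hist_max``.
    Both histograms sum to one.
    """
    mins = maps.s_min.reshape(-1, maps.s_min.shape[-1])
    maxs = maps.s_max.reshape(-1, maps.s_max.shape[-1])
    if mins.size == 0:
        raise CifContractError("empty quantizer maps")
    hist_min = np.bincount(pal_min.assign(mins), minlength=pal_min.size).astype(float)
    hist_max = np.bincount(pal_max.assign(maxs), minlength=pal_max.size).astype(float)
    return CifFeature(hist_min=hist_min / len(mins), hist_max=hist_max / len(maxs))


def cif_feature(
    image: np.ndarray, block_size: int = 8, k_min: int = 16, k_max: int = 16
) -> np.ndarray:
    """Full CIF pipeline for one image -> fixed-length feature vector.

    The histograms are zero-padded to ``k_min``/``k_max`` entries so the
    feature length is constant even when the palette under-fills.
    """
    grid = partition_blocks(image, block_size)
    maps = minmax_quantize(grid)
    pal_min = reduce_colors(maps.s_min.reshape(-1, maps.s_min.shape[-1]), k_min)
    pal_max = reduce_colors(maps.s_max.reshape(-1, maps.s_max.shape[-1]), k_max)
    feat = cif_histograms(maps, pal_min, pal_max)
    out = np.zeros(k_min + k_max)
    out[: pal_min.size] = feat.hist_min
    out[k_min : k_min + pal_max.size] = feat.hist_max
    return out


# ---------------------------------------------------------------------------
# CIF convolutional micro-block


@dataclass
class CifConvSpec:
    """Configuration of the PWConv -> shuffle -> DWConv -> reorder micro-block.

    ``pw_weights`` has shape (C_in, pw_filters); ``dw_kernels`` has shape
    (pw_filters, 3, 3) — one 3x3 kernel per channel.  ``reorder`` defaults
    to the inverse of the shuffle permutation, restoring channel order.
    """

    pw_filters: int
    shuffle_groups: int
    pw_weights: np.ndarray | None = None
    dw_kernels: np.ndarray | None = None
    reorder: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.pw_filters % self.shuffle_groups != 0:
            raise CifContractError(
                f"shuffle_groups={self.shuffle_groups} must divide "
                f"pw_filters={self.pw_filters}"
            )


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """Channel-shuffle permutation: split into groups, interleave."""
    if channels % groups != 0:
        raise CifContractError("groups must divide channel count")
    return np.arange(channels).reshape(groups, channels // groups).T.reshape(-1)


def cif_conv_block(feature_map: np.ndarray, spec: CifConvSpec) -> np.ndarray:
    """Apply PWConv -> channel shuffle -> 3x3 DWConv (same padding) -> reorder.

    ``feature_map`` is NHWC.  Spatial dimensions are preserved; the
    depthwise stage is the standard cross-correlation of each channel with
    its own 3x3 kernel.
    """
    x = np.asarray(feature_map, dtype=np.float64)
    if x.ndim != 4:
        raise CifContractError("feature_map must be NHWC (4-D)")
    c_in = x.shape[3]
    pw = spec.pw_weights
    if pw is None:
        pw = np.eye(c_in)[:, : spec.pw_filters]
    if pw.shape != (c_in, spec.pw_filters):
        raise CifContractError("pw_weights must have shape (C_in, pw_filters)")
    x = x @ pw  # 1x1 pointwise convolution

    perm = shuffle_permutation(spec.pw_filters, spec.shuffle_groups)
    x = x[:, :, :, perm]

    dw = spec.dw_kernels
    if dw is None:
        dw = np.zeros((spec.pw_filters, 3, 3))
        dw[:, 1, 1] = 1.0
    if dw.shape != (spec.pw_filters, 3, 3):
        raise CifContractError("dw_kernels must have shape (pw_filters, 3, 3)")
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.zeros_like(x)
    for a in range(3):
        for b in range(3):
            out += dw[None, None, None, :, a, b] * xp[
                :, a : a + x.shape[1], b : b + x.shape[2], :
            ]

    reorder = spec.reorder if spec.reorder is not None else np.argsort(perm)
    return out[:, :, :, reorder]


def quantizer_feature_map(maps: QuantizerMaps) -> np.ndarray:
    """Stack s_min and s_max into a 1xUxVx6 NHWC map for the conv micro-block."""
    stacked = np.concatenate([maps.s_min, maps.s_max], axis=2)
    return stacked[None, ...]
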