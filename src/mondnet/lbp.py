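"""Local binary pattern (LBP) texture features.

An RGB image is first reduced to its interband average P = (R+G+B)/3.
Each interior pixel is then coded by thresholding its ``s`` neighbors on
a radius-``r`` ring against the center intensity::

    LBP_{s,r}(u, v) = sum_{alpha=1..s}  step(t_alpha - t_center) * 2^(alpha-1)

with step(x) = 1 if x >= 0 else 0; neighbors equal to the center count as
1.  Neighbors are taken clockwise starting from the top-left.  For the
canonical (s=8, r=1) configuration the neighbors are the eight pixels of
the 3x3 grid; any other configuration samples the circle of radius r with
bilinear interpolation.  Codes are pooled into a 2^s-bin occurrence
histogram, the texture descriptor.

Because only the sign of intensity differences matters, the codes are
invariant to adding a constant to, or scaling by a positive constant,
every pixel — the descriptor survives monotonic grayscale changes.

A local ternary pattern (LTP) variant is exposed through the same
interface: with a nonzero ``ternary_threshold`` t, differences in
(-t, t) are treated as "equal" and the upper/lower halves are coded as
two binary patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class LbpContractError(ValueError):
    """Raised when LBP inputs violate an operation contract."""


@dataclass(frozen=True)
class LbpParams:
    """LBP configuration: ``neighbors`` in {4, 8, 16}, ``radius`` >= 1."""

    neighbors: int = 8
    radius: int = 1
    ternary_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.neighbors not in (4, 8, 16):
            raise LbpContractError("neighbors must be one of {4, 8, 16}")
        if self.radius < 1:
            raise LbpContractError("radius must be >= 1")
        if self.ternary_threshold < 0:
            raise LbpContractError("ternary_threshold must be >= 0")

    @property
    def n_bins(self) -> int:
        return 2**self.neighbors


@dataclass
class LbpHistogram:
    """Occurrence histogram of LBP codes over the interior pixels."""

    bins: np.ndarray
    normalized: bool


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Interband average P(x, y) = (R + G + B) / 3, kept real-valued."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise LbpContractError("to_grayscale expects an (H, W, 3) image")
    return image.mean(axis=2)


def neighbor_offsets(params: LbpParams) -> np.ndarray:
    """(s, 2) array of (dy, dx) offsets, clockwise from the top-left.

    (8, 1) uses the integer 3x3 ring; other configurations sample the
    circle of radius r, starting at the top-left diagonal direction and
    proceeding clockwise (screen coordinates, y down).
    """
    s, r = params.neighbors, params.radius
    if s == 8 and r == 1:
        return np.array(
            [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)],
            dtype=np.float64,
        )
    theta0 = 5.0 * np.pi / 4.0  # top-left direction
    angles = theta0 + 2.0 * np.pi * np.arange(s) / s
    return np.stack([r * np.sin(angles), r * np.cos(angles)], axis=1)


def _sample(gray: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    """Bilinear sample of ``gray`` at real coordinates (vectorized)."""
    y0 = np.floor(yy).astype(int)
    x0 = np.floor(xx).astype(int)
    fy = yy - y0
    fx = xx - x0
    y1 = np.minimum(y0 + 1, gray.shape[0] - 1)
    x1 = np.minimum(x0 + 1, gray.shape[1] - 1)
    return (
        gray[y0, x0] * (1 - fy) * (1 - fx)
        + gray[y0, x1] * (1 - fy) * fx
        + gray[y1, x0] * fy * (1 - fx)
        + gray[y1, x1] * fy * fx
    )


def _margin(params: LbpParams) -> int:
    return int(np.ceil(params.radius))


def lbp_code(gray: np.ndarray, center: tuple[int, int], params: LbpParams) -> int:
    """LBP code of one pixel; the center must be >= r pixels from every border."""
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise LbpContractError("lbp_code expects a 2-D grayscale image")
    u, v = center
    m = _margin(params)
    h, w = gray.shape
    if not (m <= u < h - m and m <= v < w - m):
        raise LbpContractError(
            f"center {center} is within {m} pixels of the border of {gray.shape}"
        )
    t_c = gray[u, v]
    code = 0
    for alpha, (dy, dx) in enumerate(neighbor_offsets(params)):
        t_a = _sample(gray, np.array([u + dy]), np.array([v + dx]))[0]
        if t_a - t_c >= 0:
            code |= 1 << alpha
    return code


def lbp_code_map(gray: np.ndarray, params: LbpParams) -> np.ndarray:
    """LBP codes of all interior pixels, shape (H - 2m, W - 2m)."""
    gray = np.asarray(gray, dtype=np.float64)
    m = _margin(params)
    h, w = gray.shape
    if h < 2 * m + 1 or w < 2 * m + 1:
        raise LbpContractError(f"image {gray.shape} too small for radius {params.radius}")
    yy, xx = np.mgrid[m : h - m, m : w - m].astype(np.float64)
    center = gray[m : h - m, m : w - m]
    codes = np.zeros(center.shape, dtype=np.int64)
    for alpha, (dy, dx) in enumerate(neighbor_offsets(params)):
        t_a = _sample(gray, yy + dy, xx + dx)
        codes |= (t_a - center >= 0).astype(np.int64) << alpha
    return codes


def lbp_histogram(
    gray: np.ndarray, params: LbpParams, normalized: bool = True
) -> LbpHistogram:
    """Histogram of LBP codes over all interior pixels.

    Un-normalized bins sum to ``(H - 2m) * (W - 2m)``; the normalized
    variant divides by that count.
    """
    codes = lbp_code_map(gray, params)
    bins = np.bincount(codes.reshape(-1), minlength=params.n_bins).astype(np.float64)
    if normalized:
        bins = bins / codes.size
    return LbpHistogram(bins=bins, normalized=normalized)


def ltp_histograms(
    gray: np.ndarray, params: LbpParams, normalized: bool = True
) -> tuple[LbpHistogram, LbpHistogram]:
    """Local ternary pattern: upper/lower binary-pattern histograms.

    Upper bit: difference >= +t; lower bit: difference <= -t, with
    t = ``params.ternary_threshold``.  At t = 0 the upper histogram
    coincides with the plain LBP histogram.
    """
    gray = np.asarray(gray, dtype=np.float64)
    m = _margin(params)
    h, w = gray.shape
    if h < 2 * m + 1 or w < 2 * m + 1:
        raise LbpContractError(f"image {gray.shape} too small for radius {params.radius}")
    t = params.ternary_threshold
    yy, xx = np.mgrid[m : h - m, m : w - m].astype(np.float64)
    center = gray[m : h - m, m : w - m]
    upper = np.zeros(center.shape, dtype=np.int64)
    lower = np.zeros(center.shape, dtype=np.int64)
    for alpha, (dy, dx) in enumerate(neighbor_offsets(params)):
        diff = _sample(gray, yy + dy, xx + dx) - center
        upper |= (diff >= t).astype(np.int64) << alpha
        lower |= (diff <= -t).astype(np.int64) << alpha
    n = center.size
    up = np.bincount(upper.reshape(-1), minlength=params.n_bins).astype(np.float64)
    lo = np.bincount(lower.reshape(-1), minlength=params.n_bins).astype(np.float64)
    if normalized:
        up, lo = up / n, lo / n
    return LbpHistogram(up, normalized), LbpHistogram(lo, normalized)


def lbp_feature(image: np.ndarray, params: LbpParams | None = None) -> np.ndarray:
    """Normalized LBP histogram of an RGB (or grayscale) image as a vector."""
    params = params or LbpParams()
    gray = to_grayscale(image) if np.asarray(image).ndim == 3 else np.asarray(image, float)
    return lbp_histogram(gray, params, normalized=True).bins
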