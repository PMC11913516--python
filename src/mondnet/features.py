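"""Duple (color + texture) feature extraction and fusion.

One row per image: the CIF color histograms (k_min + k_max columns) and
the 2^s-bin LBP texture histogram, flattened and concatenated.  This is
the representation the classifier consumes.

The CIF palettes are shared across the image collection: block quantizer
colors from every image are pooled and reduced once, and each image is
histogrammed against that common codebook.  A shared palette is what
makes histogram bins comparable between images — a per-image palette
adapts to each image's own colors and normalizes away exactly the global
color shifts that distinguish the classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cif import (
    Palette,
    cif_feature,
    cif_histograms,
    minmax_quantize,
    partition_blocks,
    reduce_colors,
)
from .lbp import LbpParams, lbp_feature
from .synthetic import LabelledDataset


@dataclass(frozen=True)
class FeatureConfig:
    """Settings of the duple feature extractor."""

    block_size: int = 8
    k_min: int = 16
    k_max: int = 16
    lbp: LbpParams = LbpParams()

    @property
    def length(self) -> int:
        return self.k_min + self.k_max + self.lbp.n_bins

    def column_names(self) -> list[str]:
        return (
            [f"cif_min_{i}" for i in range(self.k_min)]
            + [f"cif_max_{i}" for i in range(self.k_max)]
            + [f"lbp_{i}" for i in range(self.lbp.n_bins)]
        )


def build_shared_palettes(
    data: LabelledDataset, config: FeatureConfig | None = None
) -> tuple[Palette, Palette]:
    """Pool block quantizer colors over the whole collection; reduce once."""
    config = config or FeatureConfig()
    mins, maxs = [], []
    for img in data.images:
        maps = minmax_quantize(partition_blocks(img, config.block_size))
        mins.append(maps.s_min.reshape(-1, maps.s_min.shape[-1]))
        maxs.append(maps.s_max.reshape(-1, maps.s_max.shape[-1]))
    return (
        reduce_colors(np.vstack(mins), config.k_min),
        reduce_colors(np.vstack(maxs), config.k_max),
    )


def extract_fused(
    image: np.ndarray,
    config: FeatureConfig | None = None,
    palettes: tuple[Palette, Palette] | None = None,
) -> np.ndarray:
    """Fused CIF + LBP feature vector of one image.

    With ``palettes`` the CIF histograms use that shared codebook
    (zero-padded to k_min/k_max columns); without, the palette is built
    from this image alone.
    """
    config = config or FeatureConfig()
    if palettes is None:
        cif = cif_feature(image, config.block_size, config.k_min, config.k_max)
    else:
        pal_min, pal_max = palettes
        maps = minmax_quantize(partition_blocks(image, config.block_size))
        feat = cif_histograms(maps, pal_min, pal_max)
        cif = np.zeros(config.k_min + config.k_max)
        cif[: pal_min.size] = feat.hist_min
        cif[config.k_min : config.k_min + pal_max.size] = feat.hist_max
    lbp = lbp_feature(image, config.lbp)
    return np.concatenate([cif, lbp])


def extract_features(
    data: LabelledDataset, config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Feature table for a dataset: path/label/provenance plus feature columns.

    The CIF palettes are built from the whole collection (unsupervised;
    no labels are consulted), then every image is histogrammed against
    them.
    """
    config = config or FeatureConfig()
    if len(data):
        palettes = build_shared_palettes(data, config)
        rows = np.stack([extract_fused(img, config, palettes) for img in data.images])
    else:
        rows = np.empty((0, config.length))
    frame = pd.DataFrame(rows, columns=config.column_names())
    frame.insert(0, "provenance", list(data.provenance))
    frame.insert(0, "label", list(data.labels))
    frame.insert(0, "path", [f"{lab}/{name}.png" for lab, name in zip(data.labels, data.names)])
    return frame
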