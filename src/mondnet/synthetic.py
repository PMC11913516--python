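"""Seeded synthetic tractography-style images for the screening pipeline.

Real directionally-encoded-color (DEC) tractography renders white-matter
fiber bundles with the conventional orientation colors: red for
left-right, green for anterior-posterior, blue for through-plane fibers.
This module emulates that appearance well enough to exercise every stage
of the pipeline — coherent striped bundles on a dark background, colored
by orientation — without simulating any diffusion physics.

"Abnormal" images carry a localized lesion: a smooth region in which
streamline intensity is suppressed and coherence is degraded, both scaled
by ``lesion_contrast``.  At ``lesion_contrast=0`` the two classes are
drawn from the same distribution, which gives the pipeline a null control.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical specs give
byte-identical datasets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image

NORMAL = "normal"
ABNORMAL = "abnormal"
CLASSES = (NORMAL, ABNORMAL)

ALL_TRANSFORMS = frozenset(
    {"rotation", "horizontal_flip", "vertical_flip", "brightness", "noise", "translation"}
)


class InvalidSpecError(ValueError):
    """Raised when a synthetic-data specification violates its invariants."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic two-class dataset.

    Defaults reproduce the reference composition of 78 normal and 52
    abnormal images at a desk-scale 64x64 raster.
    """

    n_normal: int = 78
    n_abnormal: int = 52
    height: int = 64
    width: int = 64
    seed: int = 0
    noise_sd: float = 8.0
    lesion_contrast: float = 0.5

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise InvalidSpecError("class counts must be nonnegative")
        if self.height < 32 or self.width < 32:
            raise InvalidSpecError("height and width must be >= 32")
        if not 0.0 <= self.lesion_contrast <= 1.0:
            raise InvalidSpecError("lesion_contrast must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class AugmentPolicy:
    """Augmentation policy: ``factor`` label/shape-preserving variants per original.

    The default enumerates 6 geometric ops (identity, three rotations, two
    flips) crossed with 4 photometric ops (brightness 0.8x, brightness
    1.2x, additive noise, brightness 1.1x + noise), i.e. 24 distinct
    non-identity variants — matching the x24 expansion of the reference
    dataset (78 -> 1872, 52 -> 1248).
    """

    factor: int = 24
    transforms: frozenset[str] = frozenset(
        {"rotation", "horizontal_flip", "vertical_flip", "brightness", "noise"}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise InvalidSpecError("augmentation factor must be >= 1")
        unknown = set(self.transforms) - ALL_TRANSFORMS
        if unknown:
            raise InvalidSpecError(f"unknown transforms: {sorted(unknown)}")
        if not self.transforms:
            raise InvalidSpecError("at least one transform must be enabled")


@dataclass
class LabelledDataset:
    """Aligned images, class labels and provenance tags."""

    images: list[np.ndarray] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.images)
        if not (len(self.labels) == n and len(self.provenance) == n):
            raise ValueError("images, labels and provenance must be equal length")
        if not self.names:
            self.names = [f"img_{i:04d}" for i in range(n)]
        elif len(self.names) != n:
            raise ValueError("names must match images length")

    def __len__(self) -> int:
        return len(self.images)

    def count(self, label: str) -> int:
        return sum(1 for lab in self.labels if lab == label)

    def extend(self, other: "LabelledDataset") -> None:
        self.images.extend(other.images)
        self.labels.extend(other.labels)
        self.provenance.extend(other.provenance)
        self.names.extend(other.names)

    # ---- disk round trip -------------------------------------------------

    def save(self, out_dir: str | Path, seed: int | None = None) -> Path:
        """Write PNGs into ``<out>/<label>/`` plus a manifest CSV; returns manifest path."""
        out = Path(out_dir)
        for label in CLASSES:
            (out / label).mkdir(parents=True, exist_ok=True)
        manifest = out / "manifest.csv"
        with open(manifest, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "label", "provenance", "seed"])
            for img, label, prov, name in zip(
                self.images, self.labels, self.provenance, self.names
            ):
                rel = f"{label}/{name}.png"
                Image.fromarray(np.asarray(img, dtype=np.uint8)).save(out / rel)
                writer.writerow([rel, label, prov, "" if seed is None else seed])
        return manifest

    @classmethod
    def load(cls, in_dir: str | Path) -> "LabelledDataset":
        in_dir = Path(in_dir)
        manifest = in_dir / "manifest.csv"
        if not manifest.exists():
            raise FileNotFoundError(f"no manifest at {manifest}")
        images, labels, prov, names = [], [], [], []
        with open(manifest, newline="") as fh:
            for row in csv.DictReader(fh):
                images.append(np.asarray(Image.open(in_dir / row["path"])))
                labels.append(row["label"])
                prov.append(row["provenance"])
                names.append(Path(row["path"]).stem)
        return cls(images, labels, prov, names)


# ---------------------------------------------------------------------------
# image rendering


def _bundle(
    yy: np.ndarray,
    xx: np.ndarray,
    axis: np.ndarray,
    center: float,
    half_width: float,
    wobble_amp: float,
    wobble_freq: float,
    wobble_phase: float,
    stripe_period: float,
    stripe_phase: float,
) -> np.ndarray:
    """Intensity field of one striped fiber bundle.

    ``axis`` is the across-bundle coordinate; ``xx``/``yy`` only feed the
    sinusoidal wobble along the bundle.  Stripes run along the bundle to
    mimic individual streamlines.
    """
    along = xx if axis is yy else yy
    span = max(along.max(), 1.0)
    offset = wobble_amp * np.sin(2 * np.pi * wobble_freq * along / span + wobble_phase)
    d = axis - center - offset
    envelope = np.exp(-(d**2) / (2.0 * half_width**2))
    stripes = 0.65 + 0.35 * np.sin(2 * np.pi * d / stripe_period + stripe_phase)
    return envelope * stripes


def _render_image(
    rng: np.random.Generator,
    height: int,
    width: int,
    noise_sd: float,
    lesion_contrast: float,
) -> np.ndarray:
    """Render one tractography-like RGB frame; lesion applied iff contrast > 0."""
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    img = np.zeros((height, width, 3), dtype=np.float64)

    # left-right bundle (red), anterior-posterior (green), through-plane (blue)
    colors = np.array(
        [[230.0, 40.0, 30.0], [35.0, 225.0, 45.0], [45.0, 55.0, 235.0]]
    )
    axes = [yy, xx, yy]
    centers = [
        rng.uniform(0.18, 0.38) * height,
        rng.uniform(0.30, 0.70) * width,
        rng.uniform(0.62, 0.85) * height,
    ]
    # degeneration affects one entire tract (as in motor-pathway disease),
    # strongest around a focal core; both effects scale with the contrast
    lesioned = rng.integers(0, 3)
    core_y = rng.uniform(0.3, 0.7) * height
    core_x = rng.uniform(0.3, 0.7) * width
    core_radius = rng.uniform(0.15, 0.25) * min(height, width)
    degradation_noise = rng.normal(0.0, 1.0, size=(height, width))

    for k, (color, axis, center) in enumerate(zip(colors, axes, centers)):
        intensity = _bundle(
            yy,
            xx,
            axis,
            center=center,
            half_width=rng.uniform(0.05, 0.09) * height,
            wobble_amp=rng.uniform(0.02, 0.06) * height,
            wobble_freq=rng.uniform(0.8, 1.8),
            wobble_phase=rng.uniform(0, 2 * np.pi),
            stripe_period=rng.uniform(2.2, 3.5),
            stripe_phase=rng.uniform(0, 2 * np.pi),
        )
        if lesion_contrast > 0.0 and k == lesioned:
            core = np.exp(
                -((yy - core_y) ** 2 + (xx - core_x) ** 2) / (2.0 * core_radius**2)
            )
            # tract-wide thinning plus a stronger focal core ...
            intensity *= 1.0 - lesion_contrast * (0.45 + 0.4 * core)
            # ... and loss of streamline coherence along the tract
            intensity += (
                lesion_contrast * 0.25 * intensity.max() * (intensity > 0.05)
                * degradation_noise
            )
            intensity = np.clip(intensity, 0.0, None)
        img += intensity[:, :, None] * color[None, None, :]

    # faint isotropic background tissue
    img += rng.uniform(8.0, 16.0)

    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_dataset(spec: SyntheticSpec) -> LabelledDataset:
    """Generate ``n_normal + n_abnormal`` labelled synthetic images.

    Normal images get coherent orientation-colored bundles; abnormal ones
    add a localized lesion whose strength is ``spec.lesion_contrast``.
    Identical specs yield byte-identical datasets.
    """
    total = spec.n_normal + spec.n_abnormal
    children = np.random.SeedSequence(spec.seed).spawn(total)
    images, labels, prov, names = [], [], [], []
    for i in range(total):
        rng = np.random.default_rng(children[i])
        is_abnormal = i >= spec.n_normal
        img = _render_image(
            rng,
            spec.height,
            spec.width,
            spec.noise_sd,
            spec.lesion_contrast if is_abnormal else 0.0,
        )
        images.append(img)
        labels.append(ABNORMAL if is_abnormal else NORMAL)
        prov.append("original")
        names.append(f"orig_{i:04d}")
    return LabelledDataset(images, labels, prov, names)


# ---------------------------------------------------------------------------
# augmentation


def _brightness(factor: float) -> Callable[[np.ndarray, np.random.Generator], np.ndarray]:
    def op(img: np.ndarray, _rng: np.random.Generator) -> np.ndarray:
        return np.clip(np.rint(img.astype(np.float64) * factor), 0, 255).astype(np.uint8)

    return op


def _additive_noise(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = img.astype(np.float64) + rng.normal(0.0, 6.0, size=img.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _translate(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    dy, dx = rng.integers(-3, 4, size=2)
    return np.roll(np.roll(img, int(dy), axis=0), int(dx), axis=1)


def _geometric_ops(policy: AugmentPolicy, square: bool) -> list[tuple[str, Callable]]:
    ops: list[tuple[str, Callable]] = [("id", lambda im, _r: im)]
    if "rotation" in policy.transforms:
        if square:
            ops.append(("rot90", lambda im, _r: np.rot90(im, 1).copy()))
            ops.append(("rot270", lambda im, _r: np.rot90(im, 3).copy()))
        ops.append(("rot180", lambda im, _r: np.rot90(im, 2).copy()))
    if "horizontal_flip" in policy.transforms:
        ops.append(("fliph", lambda im, _r: im[:, ::-1].copy()))
    if "vertical_flip" in policy.transforms:
        ops.append(("flipv", lambda im, _r: im[::-1, :].copy()))
    if "translation" in policy.transforms:
        ops.append(("shift", _translate))
    return ops


def _photometric_ops(policy: AugmentPolicy) -> list[tuple[str, Callable]]:
    ops: list[tuple[str, Callable]] = []
    if "brightness" in policy.transforms:
        ops.append(("bright-", _brightness(0.8)))
        ops.append(("bright+", _brightness(1.2)))
    if "noise" in policy.transforms:
        ops.append(("noise", _additive_noise))
        if "brightness" in policy.transforms:
            b11 = _brightness(1.1)
            ops.append(("bright~noise", lambda im, r: _additive_noise(b11(im, r), r)))
    return ops


def _variant_plan(policy: AugmentPolicy, square: bool) -> list[tuple[str, Callable, Callable | None]]:
    """Enumerate ``factor`` distinct (geometric, photometric) transform pairs."""
    geo = _geometric_ops(policy, square)
    photo = _photometric_ops(policy)
    plan: list[tuple[str, Callable, Callable | None]] = []
    if photo:
        for gname, gop in geo:
            for pname, pop in photo:
                plan.append((f"{gname}+{pname}", gop, pop))
    else:
        plan = [(gname, gop, None) for gname, gop in geo if gname != "id"]
    if not plan:
        raise InvalidSpecError("enabled transforms admit no non-identity variant")
    if len(plan) < policy.factor:
        if "noise" in policy.transforms:
            # extra seeded-noise variants keep every slot distinct
            base = list(plan)
            j = 0
            while len(plan) < policy.factor:
                name, gop, _ = base[j % len(base)]
                plan.append((f"{name}+noise{j}", gop, _additive_noise))
                j += 1
        else:
            plan = [plan[i % len(plan)] for i in range(policy.factor)]
    return plan[: policy.factor]


def augment_dataset(data: LabelledDataset, policy: AugmentPolicy) -> LabelledDataset:
    """Return originals plus exactly ``factor`` augmented variants per original.

    Every variant preserves the image shape and class label; the per-variant
    RNG is spawned from ``(policy.seed, original index, variant index)`` so
    reruns are byte-identical.
    """
    if len(data) == 0:
        return LabelledDataset([], [], [], [])
    combined = LabelledDataset(
        list(data.images), list(data.labels), list(data.provenance), list(data.names)
    )
    children = np.random.SeedSequence(policy.seed).spawn(len(data) * policy.factor)
    for idx, (img, label) in enumerate(zip(data.images, data.labels)):
        square = img.shape[0] == img.shape[1]
        plan = _variant_plan(policy, square)
        for v, (_vname, gop, pop) in enumerate(plan):
            rng = np.random.default_rng(children[idx * policy.factor + v])
            out = gop(np.asarray(img), rng)
            if pop is not None:
                out = pop(out, rng)
            if out.shape != img.shape:  # pragma: no cover - guarded by op choice
                raise RuntimeError("augmentation transform changed image shape")
            combined.images.append(out)
            combined.labels.append(label)
            combined.provenance.append("augmented")
            combined.names.append(f"aug_{idx:04d}_{v:02d}")
    return combined


def augmented_only(data: LabelledDataset) -> LabelledDataset:
    """Subset of a combined dataset carrying only augmented items."""
    keep = [i for i, p in enumerate(data.provenance) if p == "augmented"]
    return LabelledDataset(
        [data.images[i] for i in keep],
        [data.labels[i] for i in keep],
        [data.provenance[i] for i in keep],
        [data.names[i] for i in keep],
    )
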