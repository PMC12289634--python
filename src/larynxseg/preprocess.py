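"""Pre-processing: crop detection, paired augmentation, embedding checks, splits.

This is the first block of the pipeline. Raw screen recordings place the
laryngoscope view somewhere on a black canvas, so the content area is found
as the largest bright connected region. Augmentation applies one geometric
transform jointly to an image and its label mask (bilinear for pixels,
nearest-neighbour for labels, so no fractional class indices can appear).
A PCA / t-SNE projection of down-sampled pixels provides a quick visual
check that augmented images stay inside the original data distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure, transform
from skimage.color import rgb2gray
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .synthetic import Sample

LUMINANCE_THRESHOLD = 10.0 / 255.0


@dataclass(frozen=True)
class CropBox:
    """Half-open pixel box [row0, row0+height) x [col0, col0+width)."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("crop box must have positive size")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("crop box origin must be non-negative")


@dataclass(frozen=True)
class AugmentConfig:
    crop_scale_range: tuple[float, float] = (0.7, 1.0)   # fraction of area
    flip_probability: float = 0.5
    rotation_range_deg: float = 15.0                     # sampled in (-r, +r)
    output_size: tuple[int, int] | None = None           # None: keep input size

    def __post_init__(self):
        lo, hi = self.crop_scale_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError(f"crop_scale_range must satisfy 0 < lo <= hi <= 1, got {self.crop_scale_range}")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must be in [0,1]")
        if self.rotation_range_deg < 0:
            raise ValueError("rotation_range_deg must be >= 0")


@dataclass(frozen=True)
class SplitFractions:
    train: float = 0.7
    val: float = 0.2
    test: float = 0.1

    def __post_init__(self):
        if min(self.train, self.val, self.test) < 0:
            raise ValueError("split fractions must be non-negative")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.train + self.val + self.test}")


@dataclass
class DatasetSplit:
    train: list
    val: list
    test: list

    def __post_init__(self):
        groups = [set(self.train), set(self.val), set(self.test)]
        total = sum(len(g) for g in groups)
        if len(groups[0] | groups[1] | groups[2]) != total:
            raise ValueError("split groups must be pairwise disjoint")


def compute_crop_bounds(frame: np.ndarray,
                        threshold: float = LUMINANCE_THRESHOLD) -> CropBox:
    """Bounding box of the largest bright 8-connected region of a frame."""
    frame = np.asarray(frame, dtype=np.float32)
    if frame.size == 0:
        raise ValueError("frame is empty")
    lum = rgb2gray(frame) if frame.ndim == 3 else frame
    bright = lum > threshold
    if not bright.any():
        raise ValueError("no content region: no pixel exceeds the luminance threshold")
    labels = measure.label(bright, connectivity=2)
    regions = measure.regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    r0, c0, r1, c1 = largest.bbox
    return CropBox(row0=r0, col0=c0, height=r1 - r0, width=c1 - c0)


def crop(frame: np.ndarray, box: CropBox) -> np.ndarray:
    """Copy (never resample) the pixels inside ``box``."""
    h, w = frame.shape[:2]
    if box.row0 + box.height > h or box.col0 + box.width > w:
        raise ValueError(f"crop box {box} exceeds frame bounds {(h, w)}")
    return frame[box.row0:box.row0 + box.height, box.col0:box.col0 + box.width].copy()


def _resize_pair(image, mask, out_hw):
    if image.shape[:2] == tuple(out_hw):
        return image, mask
    image = transform.resize(image, out_hw, order=1, mode="edge",
                             anti_aliasing=False, preserve_range=True)
    mask = transform.resize(mask, out_hw, order=0, mode="edge",
                            anti_aliasing=False, preserve_range=True)
    return image, mask


def augment(sample: Sample, config: AugmentConfig, rng_seed: int) -> Sample:
    """Apply one random rotate / resized-crop / horizontal-flip jointly.

    The mask is transformed with nearest-neighbour resampling throughout, so
    its value set never grows; rotation padding is labelled background.
    """
    rng = np.random.default_rng(rng_seed)
    image = np.asarray(sample.image, dtype=np.float64)
    mask = np.asarray(sample.mask)
    h, w = mask.shape

    angle = float(rng.uniform(-config.rotation_range_deg, config.rotation_range_deg))
    if angle != 0.0:
        image = transform.rotate(image, angle, resize=False, order=1,
                                 mode="constant", cval=0.0, preserve_range=True)
        mask = transform.rotate(mask.astype(np.float64), angle, resize=False,
                                order=0, mode="constant", cval=0.0,
                                preserve_range=True)

    scale = float(rng.uniform(*config.crop_scale_range))
    ch = max(1, int(round(math.sqrt(scale) * h)))
    cw = max(1, int(round(math.sqrt(scale) * w)))
    if ch == 0 or cw == 0:
        raise ValueError("degenerate crop window")
    r0 = int(rng.integers(0, h - ch + 1))
    c0 = int(rng.integers(0, w - cw + 1))
    image = image[r0:r0 + ch, c0:c0 + cw]
    mask = mask[r0:r0 + ch, c0:c0 + cw]

    out_hw = config.output_size if config.output_size is not None else (h, w)
    image, mask = _resize_pair(image, mask, out_hw)

    if rng.uniform() < config.flip_probability:
        image = image[:, ::-1]
        mask = mask[:, ::-1]

    return Sample(image=np.clip(image, 0.0, 1.0).astype(np.float32),
                  mask=np.ascontiguousarray(mask).astype(np.uint8),
                  params=None)


def double_with_augmentation(samples: list[Sample], config: AugmentConfig,
                             seed: int) -> list[Sample]:
    """Emit the originals plus exactly one augmented copy of each."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(samples))
    return list(samples) + [augment(s, config, int(k)) for s, k in zip(samples, seeds)]


def _embedding_matrix(images: list[np.ndarray]) -> np.ndarray:
    """Flattened 32x32 grayscale pixel vectors, one row per image."""
    rows = []
    for im in images:
        g = rgb2gray(np.asarray(im, dtype=np.float64)) if np.asarray(im).ndim == 3 else np.asarray(im, dtype=np.float64)
        g = transform.resize(g, (32, 32), order=1, mode="edge",
                             anti_aliasing=False, preserve_range=True)
        rows.append(g.ravel())
    return np.asarray(rows)


def project_embeddings(images: list[np.ndarray], method: str = "pca",
                       rng_seed: int = 0) -> np.ndarray:
    """Project images to 2-d for an augmentation-distribution sanity check."""
    if len(images) < 3:
        raise ValueError(f"need at least 3 images, got {len(images)}")
    shapes = {np.asarray(im).shape for im in images}
    if len(shapes) > 1:
        raise ValueError("all images must have equal shape")
    X = _embedding_matrix(images)
    if method == "pca":
        return PCA(n_components=2, svd_solver="full", random_state=rng_seed).fit_transform(X)
    if method == "tsne":
        n = len(images)
        perplexity = min(30.0, max(0.5, (n - 1) / 3.0))
        return TSNE(n_components=2, random_state=rng_seed, init="pca",
                    perplexity=perplexity).fit_transform(X)
    raise ValueError(f"unknown method {method!r}; expected 'pca' or 'tsne'")


def split_dataset(ids: list, fractions: SplitFractions, seed: int) -> DatasetSplit:
    """Shuffle ids by seed, then partition.

    Sizes follow floor rounding on the validation and test fractions with the
    remainder assigned to training, so no identifier is ever dropped.
    """
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 ids, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    n_val = int(math.floor(fractions.val * n))
    n_test = int(math.floor(fractions.test * n))
    return DatasetSplit(
        val=shuffled[:n_val],
        test=shuffled[n_val:n_val + n_test],
        train=shuffled[n_val + n_test:],
    )
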