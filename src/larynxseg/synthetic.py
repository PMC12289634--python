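"""Seeded generator of laryngeal-like scenes with exact ground truth.

Endoscopic laryngeal frames show a dark airway opening (the trachea, seen
through the glottis) surrounded by an annular ring of reddish mucosa (the
supraglottis) on a tissue-toned background. Airway obstruction narrows the
opening. This module renders that geometry as two nested ellipses with
smooth shading, a global illumination scale and additive sensor noise, so
the full segmentation pipeline can be exercised and tested without patient
data. Class labels: 0 = background, 1 = trachea, 2 = supraglottis.

The renderer is a pure function of :class:`SceneParams`: identical
parameters always give bit-identical pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

# Obstruction shrinks the trachea minor axis linearly; the 0.95 cap keeps
# the airway class non-empty even at full obstruction so per-class metrics
# stay defined.
OBSTRUCTION_AXIS_SCALE = 0.95
DEFAULT_OBSTRUCTION_MIX = (0.0, 0.5, 0.9)

# Mean RGB of each region before shading/illumination, on [0,1].
_BACKGROUND_RGB = np.array([0.46, 0.40, 0.40], dtype=np.float32)
_SUPRAGLOTTIS_RGB = np.array([0.78, 0.38, 0.40], dtype=np.float32)
_TRACHEA_RGB = np.array([0.08, 0.05, 0.06], dtype=np.float32)


@dataclass(frozen=True)
class SceneParams:
    """Generative parameters of one synthetic laryngeal scene."""

    image_size: tuple[int, int]                 # (height, width) px
    trachea_center: tuple[float, float]         # (row, col) px
    trachea_axes: tuple[float, float]           # (semi-major, semi-minor) px
    trachea_angle: float                        # degrees
    supraglottis_outer_axes: tuple[float, float]
    obstruction: float                          # 0 open .. 1 near-closed
    illumination: float                         # (0, 1] brightness scale
    noise_sigma: float                          # Gaussian std on [0,1] scale
    seed: int

    def __post_init__(self):
        h, w = self.image_size
        if not 0.0 <= self.obstruction <= 1.0:
            raise ValueError(f"obstruction must be in [0,1], got {self.obstruction}")
        if not 0.0 < self.illumination <= 1.0:
            raise ValueError(f"illumination must be in (0,1], got {self.illumination}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        ta, tb = self.trachea_axes
        oa, ob = self.supraglottis_outer_axes
        if ta >= oa or tb >= ob:
            raise ValueError("trachea ellipse must lie strictly inside the supraglottis outer ellipse")
        cy, cx = self.trachea_center
        margin = max(oa, ob)
        if cy - margin < 0 or cy + margin > h - 1 or cx - margin < 0 or cx + margin > w - 1:
            raise ValueError("supraglottis outer ellipse must lie inside image bounds")


@dataclass
class Sample:
    """An image paired with its class-indexed label mask."""

    image: np.ndarray            # H x W x 3 float in [0,1]
    mask: np.ndarray             # H x W uint8 in {0,1,2}
    params: SceneParams | None = None

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(f"image {self.image.shape[:2]} and mask {self.mask.shape} sizes differ")
        bad = set(np.unique(self.mask)) - {0, 1, 2}
        if bad:
            raise ValueError(f"mask contains labels outside {{0,1,2}}: {sorted(bad)}")


def sample_scene_params(rng_seed: int, obstruction: float,
                        image_size: tuple[int, int] = (128, 128)) -> SceneParams:
    """Draw one random scene at the requested obstruction severity.

    All geometry scales with the shorter image side, so the same generator
    serves the 128x128 desk scale and the 400x500 full training shape.
    """
    if not 0.0 <= obstruction <= 1.0:
        raise ValueError(f"obstruction must be in [0,1], got {obstruction}")
    h, w = image_size
    if h < 32 or w < 32:
        raise ValueError(f"image_size must be at least 32x32, got {image_size}")
    rng = np.random.default_rng(rng_seed)
    s = min(h, w)
    cy = h / 2.0 + rng.uniform(-0.04, 0.04) * s
    cx = w / 2.0 + rng.uniform(-0.04, 0.04) * s
    outer_a = rng.uniform(0.26, 0.34) * s
    outer_b = rng.uniform(0.20, 0.28) * s
    # keep the rotated outer ellipse inside the frame
    limit = min(cy, h - 1 - cy, cx, w - 1 - cx) - 2.0
    scale = min(1.0, limit / max(outer_a, outer_b))
    outer_a *= scale
    outer_b *= scale
    tr_a = rng.uniform(0.45, 0.60) * outer_a
    tr_b_open = rng.uniform(0.45, 0.60) * outer_b
    tr_b = max(1.0, tr_b_open * (1.0 - OBSTRUCTION_AXIS_SCALE * obstruction))
    return SceneParams(
        image_size=(h, w),
        trachea_center=(cy, cx),
        trachea_axes=(tr_a, tr_b),
        trachea_angle=float(rng.uniform(-30.0, 30.0)),
        supraglottis_outer_axes=(outer_a, outer_b),
        obstruction=float(obstruction),
        illumination=float(rng.uniform(0.6, 1.0)),
        noise_sigma=float(rng.uniform(0.01, 0.05)),
        seed=int(rng_seed),
    )


def _ellipse_radius2(params: SceneParams, axes: tuple[float, float]) -> np.ndarray:
    """Normalized squared elliptical radius at every pixel (<=1 inside)."""
    h, w = params.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    cy, cx = params.trachea_center
    theta = np.deg2rad(params.trachea_angle)
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2


def render_sample(params: SceneParams) -> Sample:
    """Rasterize a scene into an image and its exact label mask."""
    r2_tr = _ellipse_radius2(params, params.trachea_axes)
    r2_out = _ellipse_radius2(params, params.supraglottis_outer_axes)
    trachea = r2_tr <= 1.0
    supra = (r2_out <= 1.0) & ~trachea
    mask = np.zeros(params.image_size, dtype=np.uint8)
    mask[trachea] = 1
    mask[supra] = 2

    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    # low-frequency mucosal texture: two seeded sinusoids
    fy, fx = rng.uniform(1.5, 3.5, size=2)
    py, px = rng.uniform(0, 2 * np.pi, size=2)
    texture = 0.04 * (np.sin(2 * np.pi * fy * yy / h + py)
                      + np.sin(2 * np.pi * fx * xx / w + px))

    image = np.empty((h, w, 3), dtype=np.float32)
    image[:] = _BACKGROUND_RGB
    # mucosa brightens toward the airway rim, a crude specular-lighting cue
    shade = np.clip(1.25 - 0.45 * np.sqrt(np.clip(r2_out, 0, None)), 0.6, 1.25)
    image[supra] = _SUPRAGLOTTIS_RGB * shade[supra, None]
    image[trachea] = _TRACHEA_RGB * np.clip(r2_tr[trachea, None] + 0.5, 0.5, 1.5)
    image += texture[:, :, None]
    image *= params.illumination
    if params.noise_sigma > 0:
        image += rng.normal(0.0, params.noise_sigma, size=image.shape).astype(np.float32)
    np.clip(image, 0.0, 1.0, out=image)
    return Sample(image=image.astype(np.float32), mask=mask, params=params)


def generate_dataset(n: int, seed: int,
                     obstruction_mix=DEFAULT_OBSTRUCTION_MIX,
                     image_size: tuple[int, int] = (128, 128)) -> list[Sample]:
    """Generate ``n`` scenes whose obstruction cycles through ``obstruction_mix``.

    The default three-level mix mirrors balanced frame selection across
    severity strata: open airway, mild obstruction, severe obstruction.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    mix = list(obstruction_mix)
    if not mix:
        raise ValueError("obstruction_mix must be non-empty")
    if any(not 0.0 <= o <= 1.0 for o in mix):
        raise ValueError("obstruction_mix values must be in [0,1]")
    children = np.random.SeedSequence(seed).spawn(n)
    samples = []
    for i in range(n):
        child_seed = int(children[i].generate_state(1)[0])
        params = sample_scene_params(child_seed, mix[i % len(mix)], image_size)
        samples.append(render_sample(params))
    return samples


# -- on-disk format --------------------------------------------------------

def save_dataset(samples: list[Sample], out_dir: str | Path, prefix: str = "scene") -> pd.DataFrame:
    """Write ``<stem>.png`` / ``<stem>_mask.png`` pairs plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        stem = f"{prefix}_{i:04d}"
        iio.imwrite(out_dir / f"{stem}.png", (s.image * 255).round().astype(np.uint8))
        iio.imwrite(out_dir / f"{stem}_mask.png", s.mask)
        rows.append({
            "stem": stem,
            "obstruction": s.params.obstruction if s.params else np.nan,
            "seed": s.params.seed if s.params else -1,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(in_dir: str | Path) -> list[Sample]:
    """Read back a dataset written by :func:`save_dataset`."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    samples = []
    for stem in manifest["stem"]:
        image = iio.imread(in_dir / f"{stem}.png").astype(np.float32) / 255.0
        mask = np.asarray(iio.imread(in_dir / f"{stem}_mask.png"), dtype=np.uint8)
        samples.append(Sample(image=image, mask=mask))
    return samples
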