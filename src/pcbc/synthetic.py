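"""Deterministic synthetic datasets: glyph classes and cluttered scenes.

Glyphs are procedural stroke/disc shapes rendered on a fixed canvas, so
no external dataset is required.  Each instance is perturbed by affine
jitter (translation, rotation, scale), a random linear illumination
gradient and additive Gaussian noise — the variation axes the model is
expected to tolerate.  Scenes plant glyph instances on a textured
background at known positions and scales, with full annotations.

All randomness flows from a single explicit seed through one
``numpy.random.Generator``; fixed seed means bit-identical output.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np
from scipy import ndimage
from skimage.transform import AffineTransform, warp

from pcbc.io import Annotation

__all__ = [
    "GlyphSpec", "SceneSpec", "GlyphDataset", "SceneDataset",
    "make_glyph_dataset", "make_scene_dataset", "make_target_crops",
]

# Canonical shapes as line segments (r1, c1, r2, c2) in unit coordinates.
# Class 6 is a filled disc instead.
_L, _R, _T, _B, _M = 0.2, 0.8, 0.2, 0.8, 0.5
_SEGMENTS = {
    0: [(_T, _L, _T, _R), (_B, _L, _B, _R), (_T, _L, _B, _L), (_T, _R, _B, _R)],  # square
    1: [(_T, _L, _B, _R), (_T, _R, _B, _L)],                                      # X
    2: [(_M, _L, _M, _R), (_T, _M, _B, _M)],                                      # plus
    3: [(_T, _L, _T, _R), (_T, _M, _B, _M)],                                      # T
    4: [(_T, _L, _B, _L), (_B, _L, _B, _R)],                                      # L
    5: [(_T, _M, _B, _L), (_T, _M, _B, _R), (_B, _L, _B, _R)],                    # triangle
    7: [(_T, _L, _B, _L), (_T, _R, _B, _R), (_M, _L, _M, _R)],                    # H
    8: [(_T, _L, _T, _R), (_T, _R, _B, _L), (_B, _L, _B, _R)],                    # Z
    9: [(_M, _L, _B, _L), (_M, _R, _B, _R), (_B, _L, _B, _R), (_M, _L, _T, _M)],  # u + accent
}
N_SHAPES = 10
_THICKNESS = 0.07
_DISC_RADIUS = 0.3


@dataclasses.dataclass
class GlyphSpec:
    """Parameters of a multi-class glyph dataset."""

    n_classes: int = 10
    image_size: int = 28
    jitter_px: float = 2.0
    jitter_deg: float = 8.0
    scale_range: tuple = (0.9, 1.1)
    noise_sigma: float = 0.03
    illum_range: tuple = (0.0, 0.25)
    seed: int = 0


@dataclasses.dataclass
class SceneSpec:
    """Parameters of a cluttered annotated scene dataset."""

    scene_size: int = 64
    n_objects: tuple = (0, 3)
    clutter: float = 0.08
    object_scale_range: tuple = (1.0, 1.0)
    object_size: int = 21
    target_class: int = 0
    max_overlap: float = 0.25
    seed: int = 0


@dataclasses.dataclass
class GlyphDataset:
    train_images: list
    train_labels: list
    test_images: list
    test_labels: list


@dataclasses.dataclass
class SceneDataset:
    images: list
    annotations: list   # list (per scene) of lists of Annotation
    negatives: list     # object-free scenes


@lru_cache(maxsize=None)
def _canonical(class_index: int, size: int) -> np.ndarray:
    """Render the canonical shape of one class on a ``size x size`` canvas."""
    coords = (np.arange(size) + 0.5) / size
    rr = coords[:, None]
    cc = coords[None, :]
    img = np.zeros((size, size))
    if class_index == 6:
        d = np.hypot(rr - _M, cc - _M)
        img = np.clip((_DISC_RADIUS - d) * size + 0.5, 0.0, 1.0)
    else:
        for r1, c1, r2, c2 in _SEGMENTS[class_index]:
            vr, vc = r2 - r1, c2 - c1
            length2 = vr * vr + vc * vc
            t = np.clip(((rr - r1) * vr + (cc - c1) * vc) / length2, 0.0, 1.0)
            d = np.hypot(rr - (r1 + t * vr), cc - (c1 + t * vc))
            img = np.maximum(img, np.clip((_THICKNESS - d) * size + 0.5,
                                          0.0, 1.0))
    img.setflags(write=False)
    return img


def _render_instance(class_index: int, spec: GlyphSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """One jittered, noisy, illumination-perturbed glyph instance."""
    size = spec.image_size
    base = np.array(_canonical(class_index, size))  # writable copy for warp
    scale = rng.uniform(*spec.scale_range)
    rot = np.deg2rad(rng.uniform(-spec.jitter_deg, spec.jitter_deg))
    dr, dc = rng.uniform(-spec.jitter_px, spec.jitter_px, size=2)
    centre = (size - 1) / 2.0
    # transform mapping output to input coords, rotation/scale about centre
    shift = AffineTransform(translation=(-centre, -centre))
    affine = AffineTransform(rotation=rot, scale=(scale, scale))
    unshift = AffineTransform(translation=(centre + dc, centre + dr))
    tform = shift + affine + unshift
    img = warp(base, tform.inverse, order=1, mode="constant", cval=0.0)
    amp = rng.uniform(*spec.illum_range)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    coords = (np.arange(size) - centre) / size
    ramp = amp * (np.cos(theta) * coords[None, :] +
                  np.sin(theta) * coords[:, None])
    img = img + ramp
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def _validate_glyph_spec(spec: GlyphSpec) -> None:
    if spec.n_classes < 2:
        raise ValueError("need at least 2 glyph classes")
    if spec.n_classes > N_SHAPES:
        raise ValueError(f"at most {N_SHAPES} distinct glyph classes exist")
    if spec.image_size < 8:
        raise ValueError("image_size too small")


def make_glyph_dataset(spec: GlyphSpec, n_train: int, n_test: int
                       ) -> GlyphDataset:
    """Balanced, disjoint train/test sets of perturbed glyph instances.

    ``n_train`` and ``n_test`` must be divisible by ``n_classes`` so class
    counts are exactly balanced.
    """
    _validate_glyph_spec(spec)
    if n_train % spec.n_classes or n_test % spec.n_classes:
        raise ValueError("n_train and n_test must be divisible by n_classes")
    rng = np.random.default_rng(spec.seed)
    sets = []
    for total in (n_train, n_test):
        images, labels = [], []
        per_class = total // spec.n_classes
        for c in range(spec.n_classes):
            for _ in range(per_class):
                images.append(_render_instance(c, spec, rng))
                labels.append(f"g{c}")
        sets.append((images, labels))
    return GlyphDataset(train_images=sets[0][0], train_labels=sets[0][1],
                        test_images=sets[1][0], test_labels=sets[1][1])


def make_target_crops(glyphs: GlyphSpec, crop_size: int, n_crops: int,
                      class_index: int = 0, seed: int | None = None) -> list:
    """Registered training crops of the target glyph, centred in an odd canvas."""
    if crop_size % 2 == 0:
        raise ValueError("crop_size must be odd (object centred on a pixel)")
    spec = dataclasses.replace(glyphs, image_size=crop_size)
    _validate_glyph_spec(spec)
    rng = np.random.default_rng(glyphs.seed if seed is None else seed)
    return [_render_instance(class_index, spec, rng) for _ in range(n_crops)]


def _background(size: int, clutter: float, rng: np.random.Generator
                ) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, (size, size))
    smooth = ndimage.gaussian_filter(noise, 2.0, mode="wrap")
    z = (smooth - smooth.mean()) / max(smooth.std(), 1e-12)
    return np.clip(0.35 + clutter * z, 0.0, 1.0)


def make_scene_dataset(spec: SceneSpec, glyphs: GlyphSpec, n_scenes: int,
                       n_negative: int = 0) -> SceneDataset:
    """Cluttered scenes with planted target glyphs plus annotations.

    Planted objects overlap by at most ``spec.max_overlap`` of the smaller
    object's area (rejection sampling); every planted object is annotated
    with its centre, size and scale factor.  ``n_negative`` additional
    object-free scenes are emitted for non-target patch harvesting.
    """
    _validate_glyph_spec(glyphs)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.n_objects
    if lo < 0 or hi < lo:
        raise ValueError("n_objects must be a (lo, hi) range with 0 <= lo <= hi")
    images, annotations = [], []
    for s in range(n_scenes):
        scene = _background(spec.scene_size, spec.clutter, rng)
        anns = []
        boxes = []
        n_obj = int(rng.integers(lo, hi + 1))
        for _ in range(n_obj):
            for _attempt in range(200):
                factor = rng.uniform(*spec.object_scale_range)
                osize = int(round(spec.object_size * factor))
                osize += (osize + 1) % 2  # odd
                if osize > spec.scene_size:
                    raise ValueError(
                        f"object of size {osize} does not fit in a "
                        f"{spec.scene_size}-pixel scene")
                r0 = int(rng.integers(0, spec.scene_size - osize + 1))
                c0 = int(rng.integers(0, spec.scene_size - osize + 1))
                box = (r0, c0, r0 + osize, c0 + osize)
                if all(_overlap_frac(box, b) <= spec.max_overlap
                       for b in boxes):
                    break
            else:
                continue  # could not place without excessive overlap
            crop_spec = dataclasses.replace(glyphs, image_size=osize)
            crop = _render_instance(spec.target_class, crop_spec, rng)
            region = scene[r0:r0 + osize, c0:c0 + osize]
            scene[r0:r0 + osize, c0:c0 + osize] = np.maximum(region, crop)
            boxes.append(box)
            anns.append(Annotation(image_id=f"scene_{s:03d}",
                                   row=r0 + (osize - 1) / 2.0,
                                   col=c0 + (osize - 1) / 2.0,
                                   width=float(osize), height=float(osize),
                                   scale=float(factor)))
        images.append(scene)
        annotations.append(anns)
    negatives = [_background(spec.scene_size, spec.clutter, rng)
                 for _ in range(n_negative)]
    return SceneDataset(images=images, annotations=annotations,
                        negatives=negatives)


def _overlap_frac(a: tuple, b: tuple) -> float:
    """Intersection area as a fraction of the smaller box's area."""
    h = min(a[2], b[2]) - max(a[0], b[0])
    w = min(a[3], b[3]) - max(a[1], b[1])
    if h <= 0 or w <= 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return h * w / min(area_a, area_b)
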