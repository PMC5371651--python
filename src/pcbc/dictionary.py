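"""Patch extraction, agglomerative template clustering and stage-1 weights.

Training patches are either whole images (fixed-location tasks) or
fixed-size windows cut around Harris corners (localisation tasks, with an
optional ladder of image rescales).  Patches are grouped per label and
per scale, clustered by complete-linkage agglomeration under the ZMNCC
similarity, and each surviving cluster's mean patch becomes one
dictionary element, i.e. the receptive field of one stage-1 prediction
neuron.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from skimage.feature import corner_harris, corner_peaks
from skimage.transform import rescale

from pcbc.conv import build_conv_network
from pcbc.core import DEFAULT_EPSILON2, build_network
from pcbc.preprocess import local_contrast

__all__ = [
    "Patch", "DictionaryElement", "Dictionary",
    "extract_whole_image_patches", "harris_keypoints",
    "extract_keypoint_patches", "agglomerative_cluster",
    "build_stage1_network",
]


@dataclasses.dataclass
class Patch:
    """A training patch with its class/target label and provenance."""

    pixels: np.ndarray
    label: str
    scale_index: int = 0
    source: tuple | None = None


@dataclasses.dataclass
class DictionaryElement:
    """Mean patch of one surviving cluster."""

    pixels: np.ndarray
    label: str
    scale_index: int
    member_count: int


@dataclasses.dataclass
class Dictionary:
    """Clustered dictionary plus the parameters that produced it."""

    elements: list
    kappa: float
    lambda_min: int

    def __len__(self) -> int:
        return len(self.elements)


def extract_whole_image_patches(images: Sequence, labels: Sequence[str]
                                ) -> list[Patch]:
    """Treat each training image as a single patch carrying its label."""
    if len(images) != len(labels):
        raise ValueError("images and labels must have equal length")
    patches: list[Patch] = []
    shape = None
    for i, (img, lab) in enumerate(zip(images, labels)):
        arr = np.asarray(img, dtype=np.float64)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(
                f"image {i} has shape {arr.shape}, expected {shape}")
        patches.append(Patch(pixels=arr, label=str(lab), scale_index=0,
                             source=(i, 0, 0)))
    return patches


def harris_keypoints(image, k: float = 0.05, threshold_rel: float = 0.01,
                     min_distance: int = 3, exclude_border: int = 0
                     ) -> np.ndarray:
    """Positions (row, col) of Harris corner response maxima.

    Local maxima of the Harris response above ``threshold_rel`` times the
    global maximum, non-max suppressed within ``min_distance`` pixels and
    at least ``exclude_border`` pixels from the image border.  A blank
    image yields an empty array.
    """
    img = np.asarray(image, dtype=np.float64)
    response = corner_harris(img, k=k)
    if response.max() <= 1e-12:
        return np.empty((0, 2), dtype=int)
    border = exclude_border if exclude_border > 0 else False
    coords = corner_peaks(response, min_distance=min_distance,
                          threshold_rel=threshold_rel,
                          exclude_border=border)
    return coords


def extract_keypoint_patches(images: Sequence, labels: Sequence[str],
                             patch_size: int = 15,
                             scales: Sequence[float] = (1.0,),
                             **harris_params) -> list[Patch]:
    """Cut ``patch_size`` windows around Harris keypoints at each scale.

    Each image is resized by every factor in ``scales`` and square patches
    are extracted around the detected corners.  Patches are tagged with
    the ordinal ``scale_index`` of the resize factor; keypoints closer
    than half a patch to the border are excluded so no patch straddles it.
    """
    if len(images) != len(labels):
        raise ValueError("images and labels must have equal length")
    if patch_size < 3 or patch_size % 2 == 0:
        raise ValueError("patch_size must be an odd integer >= 3")
    half = patch_size // 2
    params = dict(harris_params)
    params["exclude_border"] = max(half, params.get("exclude_border", 0))
    patches: list[Patch] = []
    for si, scale in enumerate(scales):
        for i, (img, lab) in enumerate(zip(images, labels)):
            arr = np.asarray(img, dtype=np.float64)
            if scale == 1.0:
                resized = arr
            else:
                resized = rescale(arr, scale, order=1,
                                  anti_aliasing=scale < 1.0)
            if min(resized.shape) < patch_size:
                raise ValueError(
                    f"patch_size {patch_size} exceeds image {i} rescaled to "
                    f"{resized.shape} at scale {scale}")
            for r, c in harris_keypoints(resized, **params):
                window = resized[r - half:r + half + 1, c - half:c + half + 1]
                if window.shape != (patch_size, patch_size):
                    continue  # defensive: keypoint too close to border
                patches.append(Patch(pixels=window.copy(), label=str(lab),
                                     scale_index=si, source=(i, int(r), int(c))))
    return patches


def _cluster_group(arrays: list[np.ndarray], kappa: float) -> list[list[int]]:
    """Greedy best-first complete-linkage clustering under ZMNCC similarity.

    Inter-cluster similarity is the ZMNCC of the most different member
    pair; the most similar pair of clusters is merged while that
    similarity is at least ``kappa``.  Ties break on the lowest index
    pair (row-major argmax), which makes the result deterministic.
    """
    n = len(arrays)
    if n == 1:
        return [[0]]
    flat = np.stack([a.ravel() for a in arrays])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        centred = flat - flat.mean(axis=1, keepdims=True)
        norms = np.sqrt((centred ** 2).sum(axis=1))
        safe = np.where(norms > 0, norms, 1.0)
        unit = centred / safe[:, None]
        sims = np.clip(unit @ unit.T, -1.0, 1.0)
        # snap round-off so identical patches merge at kappa = 1
        sims[sims > 1.0 - 1e-12] = 1.0
        sims[norms == 0, :] = 0.0   # zero-variance patches never merge
        sims[:, norms == 0] = 0.0
    np.fill_diagonal(sims, -np.inf)
    sims[np.tril_indices(n)] = -np.inf
    members: list[list[int]] = [[i] for i in range(n)]
    while len(members) > 1:
        idx = int(np.argmax(sims))
        i, j = divmod(idx, sims.shape[1])
        if sims[i, j] < kappa:
            break
        members[i] = members[i] + members[j]
        del members[j]
        # complete linkage: similarity to the merged cluster is the
        # minimum of the similarities to its parts
        row = np.minimum(np.maximum(sims[i, :], sims[:, i]),
                         np.maximum(sims[j, :], sims[:, j]))
        sims[i, :] = -np.inf
        sims[:, i] = -np.inf
        sims[i, i + 1:] = row[i + 1:]
        sims[:i, i] = row[:i]
        sims = np.delete(np.delete(sims, j, axis=0), j, axis=1)
    return members


def agglomerative_cluster(patches: Sequence[Patch], kappa: float,
                          lambda_min: int = 0) -> Dictionary:
    """Cluster patches per (label, scale) group and keep cluster means.

    Clusters with fewer than ``lambda_min`` members are discarded.  The
    output is invariant to the order of the input patches (group keys are
    sorted and elements within a group are sorted canonically).
    """
    if not 0 < kappa <= 1:
        raise ValueError("kappa must be in (0, 1]")
    patches = list(patches)
    if not patches:
        return Dictionary(elements=[], kappa=kappa, lambda_min=lambda_min)
    shape = patches[0].pixels.shape
    by_scale_shape: dict[int, tuple] = {}
    for p in patches:
        expected = by_scale_shape.setdefault(p.scale_index, p.pixels.shape)
        if p.pixels.shape != expected:
            raise ValueError("all patches within a scale must share a shape")
    keys = sorted({(p.label, p.scale_index) for p in patches})
    elements: list[DictionaryElement] = []
    for label, si in keys:
        group = [p for p in patches if p.label == label and p.scale_index == si]
        clusters = _cluster_group([p.pixels for p in group], kappa)
        built = []
        for member_idx in clusters:
            if len(member_idx) < lambda_min:
                continue
            # sort member arrays canonically so the mean is bit-stable
            # under input permutations
            arrs = sorted((group[i].pixels for i in member_idx),
                          key=lambda a: a.tobytes())
            mean = np.mean(np.stack(arrs), axis=0)
            built.append(DictionaryElement(pixels=mean, label=label,
                                           scale_index=si,
                                           member_count=len(member_idx)))
        built.sort(key=lambda el: (-el.member_count,
                                   np.round(el.pixels, 9).tobytes()))
        elements.extend(built)
    return Dictionary(elements=elements, kappa=kappa, lambda_min=lambda_min)


def build_stage1_network(dictionary: Dictionary, sigma: float,
                         epsilon2: float = DEFAULT_EPSILON2,
                         form: str = "matrix"):
    """Turn dictionary elements into a stage-1 network.

    Every element is preprocessed exactly like an input image
    (:func:`pcbc.preprocess.local_contrast` with the same ``sigma``); the
    resulting ON/OFF maps become either one concatenated weight row
    (``form="matrix"``) or one 2-channel kernel (``form="conv"``).
    Constant elements have no contrast and are excluded with a warning.
    Element labels and scale indices are carried in ``net.meta``.
    """
    if form not in ("matrix", "conv"):
        raise ValueError("form must be 'matrix' or 'conv'")
    if len(dictionary) == 0:
        raise ValueError("dictionary is empty")
    rows, kernels, kept = [], [], []
    for idx, el in enumerate(dictionary.elements):
        ci = local_contrast(el.pixels, sigma)
        if ci.on.max() == 0 and ci.off.max() == 0:
            warnings.warn(
                f"dictionary element {idx} ({el.label!r}) has zero contrast; "
                "excluded from the network", stacklevel=2)
            continue
        if form == "matrix":
            rows.append(ci.as_vector())
        else:
            kernels.append(ci.as_channels())
        kept.append(el)
    if not kept:
        raise ValueError("no dictionary element has non-zero contrast")
    meta = {
        "labels": [el.label for el in kept],
        "scale_indices": [el.scale_index for el in kept],
        "member_counts": [el.member_count for el in kept],
        "patch_shape": tuple(kept[0].pixels.shape),
        "sigma": float(sigma),
    }
    if form == "matrix":
        return build_network(np.stack(rows), epsilon2, meta=meta)
    return build_conv_network(np.stack(kernels), epsilon2, meta=meta)
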