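"""Inference with a trained hierarchy: class decisions and detections.

Classification takes the argmax of the stage-2 responses.  Detection
analyses the stage-2 response maps: contiguous regions of activity above
a floor are found, each region is decoded by population-vector decoding
(response-weighted mean of the coordinates its neurons represent) and
scored by its total response.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from pcbc.conv import conv_solve_steady_state
from pcbc.core import DEFAULT_RESPONSE_FLOOR, solve_steady_state
from pcbc.hierarchy import ClassHierarchy, DetectionHierarchy
from pcbc.preprocess import local_contrast

__all__ = [
    "Classification", "Region", "Detection", "classify",
    "nms_same_element", "find_regions", "decode_region", "detect",
]


@dataclasses.dataclass
class Classification:
    """Class decision plus both stages' responses for inspection."""

    label: str | None
    stage1: np.ndarray
    stage2: np.ndarray


@dataclasses.dataclass
class Region:
    """Connected component of supra-floor stage-2 activity."""

    coords: np.ndarray     # (n, 2) or (n, 3) integer coordinates
    responses: np.ndarray  # (n,) responses


@dataclasses.dataclass
class Detection:
    """Decoded object hypothesis."""

    row: float
    col: float
    score: float
    scale: float | None = None


def classify(hierarchy: ClassHierarchy, image) -> Classification:
    """Run both stages and return the argmax class.

    An all-zero stage-2 response yields ``label=None`` ("no decision"),
    distinct from any class.
    """
    ci = local_contrast(image, hierarchy.sigma)
    s1 = solve_steady_state(hierarchy.stage1, ci.as_vector(),
                            hierarchy.n_iter, hierarchy.response_floor)
    s2 = solve_steady_state(hierarchy.stage2, s1.y,
                            hierarchy.n_iter, hierarchy.response_floor)
    if not np.any(s2.y > 0):
        label = None
    else:
        label = hierarchy.class_labels[int(np.argmax(s2.y))]
    return Classification(label=label, stage1=s1.y, stage2=s2.y)


def nms_same_element(stage1_maps) -> np.ndarray:
    """Keep only local maxima within each dictionary element's map.

    Non-maximum suppression over the 8-neighbourhood, applied per map
    (i.e. among responses of prediction neurons sharing one dictionary
    element).  On a plateau of tied values, the first pixel in scan order
    is kept.
    """
    maps = np.asarray(stage1_maps, dtype=np.float64)
    if maps.ndim != 3:
        raise ValueError(f"expected (p, H, W) maps, got shape {maps.shape}")
    out = np.zeros_like(maps)
    eight = np.ones((3, 3), dtype=bool)
    for p in range(maps.shape[0]):
        m = maps[p]
        if m.max() <= 0:
            continue
        peak_mask = (m >= ndimage.maximum_filter(m, size=3, mode="constant")) \
            & (m > 0)
        labelled, n = ndimage.label(peak_mask, structure=eight)
        if n == 0:
            continue
        flat_labels = labelled.ravel()
        values, first = np.unique(flat_labels, return_index=True)
        keep = first[values > 0]
        out[p].ravel()[keep] = m.ravel()[keep]
    return out


def find_regions(stage2_maps, floor: float = DEFAULT_RESPONSE_FLOOR
                 ) -> list[Region]:
    """Connected components of responses above ``floor``.

    4-connectivity in 2-D, 6-connectivity in 3-D (scale, row, col).
    """
    maps = np.asarray(stage2_maps, dtype=np.float64)
    if maps.ndim not in (2, 3):
        raise ValueError(f"expected 2-D or 3-D maps, got shape {maps.shape}")
    structure = ndimage.generate_binary_structure(maps.ndim, 1)
    labelled, n = ndimage.label(maps > floor, structure=structure)
    regions = []
    for i in range(1, n + 1):
        coords = np.argwhere(labelled == i)
        responses = maps[tuple(coords.T)]
        regions.append(Region(coords=coords, responses=responses))
    return regions


def decode_region(region: Region, scales=None) -> Detection:
    """Population-vector decoding of one region.

    Position (and scale coordinate, in 3-D) is the response-weighted mean
    of the member coordinates; the score is the summed response.  For 3-D
    regions, ``scales`` (the resize-factor ladder) maps the continuous
    scale index to a scale factor by linear interpolation.
    """
    if region.coords.size == 0:
        raise ValueError("cannot decode an empty region")
    weights = region.responses / region.responses.sum()
    centroid = weights @ region.coords
    score = float(region.responses.sum())
    if region.coords.shape[1] == 2:
        return Detection(row=float(centroid[0]), col=float(centroid[1]),
                         score=score)
    scale_idx = float(centroid[0])
    if scales is not None and len(scales) > 0:
        scale = float(np.interp(scale_idx, np.arange(len(scales)),
                                np.asarray(scales, dtype=float)))
    else:
        scale = scale_idx
    return Detection(row=float(centroid[1]), col=float(centroid[2]),
                     score=score, scale=scale)


def detect(hierarchy: DetectionHierarchy, image,
           score_threshold: float = 0.0) -> list[Detection]:
    """Locate objects in a scene image.

    Stage 1 is run convolutionally, optionally followed by per-element
    non-maximum suppression; stage 2 votes for object centres; regions of
    stage-2 activity are decoded and detections with a score of at least
    ``score_threshold`` are returned sorted by descending score.
    """
    ci = local_contrast(image, hierarchy.sigma)
    s1 = conv_solve_steady_state(hierarchy.stage1, ci.as_channels(),
                                 hierarchy.n_iter, hierarchy.response_floor)
    y1 = nms_same_element(s1.Y) if hierarchy.nms else s1.Y
    s2 = conv_solve_steady_state(hierarchy.stage2, y1,
                                 hierarchy.n_iter, hierarchy.response_floor)
    maps = s2.Y[0] if s2.Y.shape[0] == 1 else s2.Y
    scales = hierarchy.scales if s2.Y.shape[0] > 1 else None
    detections = [decode_region(rg, scales=scales)
                  for rg in find_regions(maps, hierarchy.response_floor)]
    detections = [d for d in detections if d.score >= score_threshold]
    detections.sort(key=lambda d: -d.score)
    return detections
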