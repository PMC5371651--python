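"""Training of the two-stage hierarchy.

Stage 1 matches dictionary elements to the image.  Stage 2 generalises
over those matches: for classification one prediction neuron per class
pools the summed stage-1 responses to that class's training images; for
detection one prediction neuron per pixel (and per scale) pools stage-1
responses expressed as offsets from the object centre — a Hough-style
voting kernel, smoothed with a Gaussian across space (and scale) and
replicated convolutionally.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from pcbc.conv import ConvNetwork, build_conv_network, conv_solve_steady_state
from pcbc.core import (DEFAULT_EPSILON2, DEFAULT_N_ITER,
                       DEFAULT_RESPONSE_FLOOR, DIMNetwork, build_network,
                       solve_steady_state)
from pcbc.dictionary import (agglomerative_cluster, build_stage1_network,
                             extract_keypoint_patches,
                             extract_whole_image_patches)
from pcbc.preprocess import local_contrast

__all__ = [
    "ClassHierarchy", "DetectionHierarchy",
    "collect_stage1_responses", "collect_stage1_response_maps",
    "learn_class_weights", "learn_location_weights",
    "train_classifier", "train_detector",
]


@dataclasses.dataclass
class ClassHierarchy:
    """Trained two-stage network for fixed-location classification."""

    stage1: DIMNetwork
    stage2: DIMNetwork
    class_labels: list
    sigma: float
    n_iter: int = DEFAULT_N_ITER
    response_floor: float = DEFAULT_RESPONSE_FLOOR


@dataclasses.dataclass
class DetectionHierarchy:
    """Trained two-stage network for object localisation."""

    stage1: ConvNetwork
    stage2: ConvNetwork
    sigma: float
    nms: bool = True
    n_iter: int = DEFAULT_N_ITER
    response_floor: float = DEFAULT_RESPONSE_FLOOR
    scales: tuple = (1.0,)


def collect_stage1_responses(net: DIMNetwork, images: Sequence,
                             labels: Sequence | None = None,
                             n_iter: int = DEFAULT_N_ITER,
                             response_floor: float = DEFAULT_RESPONSE_FLOOR,
                             ) -> list:
    """Floored steady-state stage-1 response vector for each image.

    Returns ``(y, label)`` pairs (``label`` is None when no labels are
    given).  Preprocessing failures are re-raised with the image index.
    """
    sigma = net.meta.get("sigma")
    if sigma is None:
        raise ValueError("stage-1 network metadata lacks 'sigma'")
    if labels is None:
        labels = [None] * len(images)
    if len(labels) != len(images):
        raise ValueError("images and labels must have equal length")
    out = []
    for i, (img, lab) in enumerate(zip(images, labels)):
        try:
            x = local_contrast(img, sigma).as_vector()
            state = solve_steady_state(net, x, n_iter, response_floor)
        except ValueError as exc:
            raise ValueError(f"image {i}: {exc}") from exc
        out.append((state.y, lab))
    return out


def collect_stage1_response_maps(net: ConvNetwork, images: Sequence,
                                 n_iter: int = DEFAULT_N_ITER,
                                 response_floor: float = DEFAULT_RESPONSE_FLOOR,
                                 ) -> list:
    """Floored steady-state stage-1 response maps (p, H, W) per image."""
    sigma = net.meta.get("sigma")
    if sigma is None:
        raise ValueError("stage-1 network metadata lacks 'sigma'")
    out = []
    for i, img in enumerate(images):
        try:
            X = local_contrast(img, sigma).as_channels()
            state = conv_solve_steady_state(net, X, n_iter, response_floor)
        except ValueError as exc:
            raise ValueError(f"image {i}: {exc}") from exc
        out.append(state.Y)
    return out


def learn_class_weights(responses: Sequence, epsilon2: float = DEFAULT_EPSILON2
                        ) -> DIMNetwork:
    """One stage-2 prediction neuron per class from summed responses.

    ``responses`` holds ``(y, label)`` pairs; the raw weight vector of a
    class is the sum of the stage-1 response vectors over its images,
    then normalised as any other stage.
    """
    responses = list(responses)
    if not responses:
        raise ValueError("no responses given")
    classes = sorted({str(lab) for _, lab in responses})
    n1 = len(responses[0][0])
    raw = np.zeros((len(classes), n1))
    index = {c: i for i, c in enumerate(classes)}
    for y, lab in responses:
        raw[index[str(lab)]] += np.asarray(y, dtype=np.float64)
    zero = np.flatnonzero(raw.sum(axis=1) <= 0)
    if zero.size:
        names = [classes[i] for i in zero]
        raise ValueError(
            f"summed stage-1 response is all-zero for class(es) {names}")
    return build_network(raw, epsilon2, meta={"class_labels": classes})


def learn_location_weights(responses, smoothing_sigma: float = 2.0,
                           scale_sigma: float | None = None,
                           epsilon2: float = DEFAULT_EPSILON2) -> ConvNetwork:
    """Hough-style voting kernels from stage-1 responses to object crops.

    ``responses`` is a sequence of (p, h, w) stage-1 response maps for
    training images registered so the object centre is the image centre
    (odd h and w are required so the centre is a pixel).  With
    ``scale_sigma`` set, ``responses`` is instead a sequence over scales
    of such sequences, and the per-scale kernels are additionally
    smoothed along the scale axis (3-D Gaussian).  The Gaussian has unit
    integral, so smoothing conserves voting mass ahead of the stage's
    weight normalisation.
    """
    if scale_sigma is None:
        stacks = [list(responses)]
    else:
        stacks = [list(group) for group in responses]
    kernels = []
    shape = None
    for maps in stacks:
        if not maps:
            raise ValueError("empty response group")
        arrs = [np.asarray(m, dtype=np.float64) for m in maps]
        for a in arrs:
            if a.ndim != 3:
                raise ValueError("each response must be a (p, h, w) map stack")
            if shape is None:
                shape = a.shape
            if a.shape != shape:
                raise ValueError(
                    f"unregistered training responses: {a.shape} != {shape}")
        if shape[1] % 2 == 0 or shape[2] % 2 == 0:
            raise ValueError(
                "training maps must have odd spatial size (centred object)")
        acc = np.sum(arrs, axis=0)
        acc = ndimage.gaussian_filter(
            acc, sigma=(0, smoothing_sigma, smoothing_sigma), mode="constant")
        kernels.append(acc)
    K = np.stack(kernels)  # (S, p, h, w)
    if scale_sigma is not None and scale_sigma > 0 and K.shape[0] > 1:
        K = ndimage.gaussian_filter1d(K, sigma=scale_sigma, axis=0,
                                      mode="constant")
    meta = {"smoothing_sigma": float(smoothing_sigma),
            "scale_sigma": None if scale_sigma is None else float(scale_sigma)}
    return build_conv_network(K, epsilon2, meta=meta)


def train_classifier(images: Sequence, labels: Sequence, *, sigma: float,
                     kappa: float, lambda_min: int = 0,
                     epsilon2: float = DEFAULT_EPSILON2,
                     n_iter: int = DEFAULT_N_ITER,
                     response_floor: float = DEFAULT_RESPONSE_FLOOR,
                     ) -> ClassHierarchy:
    """Full training pipeline for fixed-location classification."""
    patches = extract_whole_image_patches(images, labels)
    dictionary = agglomerative_cluster(patches, kappa, lambda_min)
    stage1 = build_stage1_network(dictionary, sigma, epsilon2, form="matrix")
    responses = collect_stage1_responses(stage1, images, labels,
                                         n_iter, response_floor)
    stage2 = learn_class_weights(responses, epsilon2)
    return ClassHierarchy(stage1=stage1, stage2=stage2,
                          class_labels=stage2.meta["class_labels"],
                          sigma=sigma, n_iter=n_iter,
                          response_floor=response_floor)


def train_detector(object_images: Sequence, negative_images: Sequence, *,
                   sigma: float, kappa: float, lambda_min: int = 0,
                   patch_size: int = 15, scales: Sequence[float] = (1.0,),
                   smoothing_sigma: float = 2.0,
                   scale_sigma: float | None = None, nms: bool = True,
                   train_nms: bool = False,
                   epsilon2: float = DEFAULT_EPSILON2,
                   stage2_epsilon2: float | None = None,
                   n_iter: int = DEFAULT_N_ITER,
                   response_floor: float = DEFAULT_RESPONSE_FLOOR,
                   harris_params: dict | None = None) -> DetectionHierarchy:
    """Full training pipeline for object detection.

    ``object_images`` are crops registered so the object centre is the
    crop centre (odd sizes required); ``negative_images`` contain no
    object and supply the non-target patch set.

    ``train_nms`` applies the same per-element non-maximum suppression to
    the training responses that ``nms`` applies at test time, keeping the
    voting kernels consistent with the test-time input statistics.
    ``stage2_epsilon2`` overrides the division floor of the voting stage,
    whose inputs (sparse stage-1 responses) are typically much smaller
    than [0, 1]-normalised images; None keeps ``epsilon2``.
    """
    harris_params = harris_params or {}
    obj = [np.asarray(im, dtype=np.float64) for im in object_images]
    if not obj:
        raise ValueError("no object images")
    if any(o.shape != obj[0].shape for o in obj):
        raise ValueError("object images must share a common size")
    if obj[0].shape[0] % 2 == 0 or obj[0].shape[1] % 2 == 0:
        raise ValueError("object images must have odd dimensions "
                         "(object centred on a pixel)")
    pos = extract_keypoint_patches(obj, ["target"] * len(obj), patch_size,
                                   scales, **harris_params)
    neg = extract_keypoint_patches(negative_images,
                                   ["non-target"] * len(negative_images),
                                   patch_size, scales, **harris_params)
    dictionary = agglomerative_cluster(pos + neg, kappa, lambda_min)
    stage1 = build_stage1_network(dictionary, sigma, epsilon2, form="conv")
    eps2_2 = epsilon2 if stage2_epsilon2 is None else stage2_epsilon2

    def _collect(images):
        maps = collect_stage1_response_maps(stage1, images, n_iter,
                                            response_floor)
        if train_nms:
            from pcbc.recognize import nms_same_element
            maps = [nms_same_element(m) for m in maps]
        return maps

    multi = len(scales) > 1 and scale_sigma is not None
    if multi:
        groups = []
        for s in scales:
            resized = [_resize_to_odd(o, s, obj[0].shape) for o in obj]
            groups.append(_collect(resized))
        stage2 = learn_location_weights(groups, smoothing_sigma, scale_sigma,
                                        eps2_2)
    else:
        stage2 = learn_location_weights(_collect(obj), smoothing_sigma, None,
                                        eps2_2)
    return DetectionHierarchy(stage1=stage1, stage2=stage2, sigma=sigma,
                              nms=nms, n_iter=n_iter,
                              response_floor=response_floor,
                              scales=tuple(scales))


def _resize_to_odd(image: np.ndarray, scale: float, base_shape) -> np.ndarray:
    """Rescale and centre-crop/zero-pad back to the reference odd shape."""
    from skimage.transform import rescale as _rescale
    if scale == 1.0:
        return image
    resized = _rescale(image, scale, order=1, anti_aliasing=scale < 1.0)
    out = np.zeros(base_shape)
    # centre-aligned copy of the overlapping region
    r_off = (base_shape[0] - resized.shape[0]) // 2
    c_off = (base_shape[1] - resized.shape[1]) // 2
    rs = max(0, -r_off); cs = max(0, -c_off)
    rd = max(0, r_off); cd = max(0, c_off)
    h = min(resized.shape[0] - rs, base_shape[0] - rd)
    w = min(resized.shape[1] - cs, base_shape[1] - cd)
    out[rd:rd + h, cd:cd + w] = resized[rs:rs + h, cs:cs + w]
    return out
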