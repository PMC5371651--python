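"""File formats: images, IDX archives, annotations, model archives.

Annotation text format (one object per line, whitespace separated)::

    image_id row col width height scale

Detections CSV: ``image_id,row,col,scale,score`` with a header line.
Model archives are NumPy ``.npz`` files with a JSON metadata entry and a
version field checked on load.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from pathlib import Path

import numpy as np
from PIL import Image

from pcbc.conv import ConvNetwork
from pcbc.core import DIMNetwork
from pcbc.dictionary import Dictionary, DictionaryElement

ARCHIVE_VERSION = "1"

__all__ = [
    "Annotation", "load_image", "save_image", "load_labelled_dir",
    "write_labelled_dir", "read_idx_images", "read_idx_labels",
    "read_annotations", "write_annotations", "read_detections_csv",
    "write_detections_csv", "save_dictionary", "load_dictionary",
    "save_hierarchy", "load_hierarchy",
]


@dataclasses.dataclass
class Annotation:
    """Ground-truth object: centre position, size and scale factor."""

    image_id: str
    row: float
    col: float
    width: float
    height: float
    scale: float = 1.0


def load_image(path) -> np.ndarray:
    """Read an image as a float64 grayscale array in [0, 1].

    Colour images are converted by averaging the channels.
    """
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        # integer-coded image; scale by the dtype range
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    return arr


def save_image(path, image) -> None:
    """Write a [0, 1] float image as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 65535.0 + 0.5).astype(np.uint16)).save(path)


def write_labelled_dir(directory, images, labels) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = []
    for i, (img, lab) in enumerate(zip(images, labels)):
        name = f"img_{i:05d}.png"
        save_image(directory / name, img)
        lines.append(f"{name}\t{lab}")
    (directory / "labels.tsv").write_text("\n".join(lines) + "\n")


def load_labelled_dir(directory):
    """Read a directory of images listed in ``labels.tsv``.

    Returns ``(images, labels, names)``.
    """
    directory = Path(directory)
    tsv = directory / "labels.tsv"
    if not tsv.exists():
        raise FileNotFoundError(f"missing {tsv}")
    images, labels, names = [], [], []
    for line in tsv.read_text().splitlines():
        if not line.strip():
            continue
        name, label = line.split("\t")
        images.append(load_image(directory / name))
        labels.append(label)
        names.append(name)
    return images, labels, names


def read_idx_images(path) -> np.ndarray:
    """Read an IDX image archive (big-endian magic 2051) as floats in [0, 1]."""
    data = Path(path).read_bytes()
    if len(data) < 16:
        raise ValueError(f"truncated IDX image file {path}")
    magic, count, rows, cols = struct.unpack(">IIII", data[:16])
    if magic != 2051:
        raise ValueError(f"bad IDX image magic {magic:#x} in {path}")
    expected = 16 + count * rows * cols
    if len(data) < expected:
        raise ValueError(f"truncated IDX image file {path}: "
                         f"{len(data)} bytes, expected {expected}")
    pixels = np.frombuffer(data[16:expected], dtype=np.uint8)
    return pixels.reshape(count, rows, cols).astype(np.float64) / 255.0


def read_idx_labels(path) -> np.ndarray:
    """Read an IDX label archive (big-endian magic 2049)."""
    data = Path(path).read_bytes()
    if len(data) < 8:
        raise ValueError(f"truncated IDX label file {path}")
    magic, count = struct.unpack(">II", data[:8])
    if magic != 2049:
        raise ValueError(f"bad IDX label magic {magic:#x} in {path}")
    if len(data) < 8 + count:
        raise ValueError(f"truncated IDX label file {path}")
    return np.frombuffer(data[8:8 + count], dtype=np.uint8).copy()


def read_idx_dataset(image_path, label_path):
    """Read matching IDX image and label archives."""
    images = read_idx_images(image_path)
    labels = read_idx_labels(label_path)
    if len(images) != len(labels):
        raise ValueError(
            f"IDX count mismatch: {len(images)} images vs {len(labels)} labels")
    return [img for img in images], [str(int(l)) for l in labels]


def write_annotations(path, annotations) -> None:
    lines = ["# image_id row col width height scale"]
    for ann in annotations:
        lines.append(f"{ann.image_id} {ann.row:.3f} {ann.col:.3f} "
                     f"{ann.width:.3f} {ann.height:.3f} {ann.scale:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path) -> list[Annotation]:
    annotations = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(f"malformed annotation line: {line!r}")
        annotations.append(Annotation(image_id=parts[0],
                                      row=float(parts[1]), col=float(parts[2]),
                                      width=float(parts[3]),
                                      height=float(parts[4]),
                                      scale=float(parts[5])))
    return annotations


def write_detections_csv(path, detections_by_image: dict) -> None:
    lines = ["image_id,row,col,scale,score"]
    for image_id in sorted(detections_by_image):
        for d in detections_by_image[image_id]:
            scale = "" if d.scale is None else f"{d.scale:.4f}"
            lines.append(f"{image_id},{d.row:.3f},{d.col:.3f},{scale},"
                         f"{d.score:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_detections_csv(path) -> dict:
    from pcbc.recognize import Detection
    out: dict[str, list] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        image_id, row, col, scale, score = line.split(",")
        det = Detection(row=float(row), col=float(col), score=float(score),
                        scale=None if scale == "" else float(scale))
        out.setdefault(image_id, []).append(det)
    return out


def save_dictionary(path, dictionary: Dictionary) -> None:
    meta = {
        "version": ARCHIVE_VERSION,
        "kind": "dictionary",
        "kappa": dictionary.kappa,
        "lambda_min": dictionary.lambda_min,
        "labels": [el.label for el in dictionary.elements],
        "scale_indices": [el.scale_index for el in dictionary.elements],
        "member_counts": [el.member_count for el in dictionary.elements],
    }
    arrays = {f"element_{i:05d}": el.pixels
              for i, el in enumerate(dictionary.elements)}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(),
                                      dtype=np.uint8), **arrays)


def load_dictionary(path) -> Dictionary:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]))
        _check_version(meta, "dictionary", path)
        elements = [
            DictionaryElement(pixels=npz[f"element_{i:05d}"], label=lab,
                              scale_index=si, member_count=mc)
            for i, (lab, si, mc) in enumerate(zip(meta["labels"],
                                                  meta["scale_indices"],
                                                  meta["member_counts"]))
        ]
    return Dictionary(elements=elements, kappa=meta["kappa"],
                      lambda_min=meta["lambda_min"])


def _check_version(meta: dict, kind: str, path) -> None:
    if meta.get("version") != ARCHIVE_VERSION:
        raise ValueError(
            f"incompatible artifact version {meta.get('version')!r} in "
            f"{path} (expected {ARCHIVE_VERSION})")
    if meta.get("kind") != kind:
        raise ValueError(f"{path} holds a {meta.get('kind')!r} archive, "
                         f"expected {kind!r}")


def save_hierarchy(path, hierarchy) -> None:
    """Serialise a trained hierarchy (class or detection) to ``.npz``."""
    from pcbc.hierarchy import ClassHierarchy, DetectionHierarchy
    if isinstance(hierarchy, ClassHierarchy):
        meta = {
            "version": ARCHIVE_VERSION, "kind": "class_hierarchy",
            "class_labels": list(hierarchy.class_labels),
            "sigma": hierarchy.sigma, "n_iter": hierarchy.n_iter,
            "response_floor": hierarchy.response_floor,
            "stage1_meta": _json_safe(hierarchy.stage1.meta),
            "stage2_meta": _json_safe(hierarchy.stage2.meta),
            "epsilon1": [hierarchy.stage1.epsilon1, hierarchy.stage2.epsilon1],
            "epsilon2": [hierarchy.stage1.epsilon2, hierarchy.stage2.epsilon2],
        }
        np.savez(path,
                 meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 W1=hierarchy.stage1.W, V1=hierarchy.stage1.V,
                 W2=hierarchy.stage2.W, V2=hierarchy.stage2.V)
    elif isinstance(hierarchy, DetectionHierarchy):
        meta = {
            "version": ARCHIVE_VERSION, "kind": "detection_hierarchy",
            "sigma": hierarchy.sigma, "nms": hierarchy.nms,
            "n_iter": hierarchy.n_iter,
            "response_floor": hierarchy.response_floor,
            "scales": list(hierarchy.scales),
            "stage1_meta": _json_safe(hierarchy.stage1.meta),
            "stage2_meta": _json_safe(hierarchy.stage2.meta),
            "epsilon1": [hierarchy.stage1.epsilon1, hierarchy.stage2.epsilon1],
            "epsilon2": [hierarchy.stage1.epsilon2, hierarchy.stage2.epsilon2],
        }
        np.savez(path,
                 meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 w1=hierarchy.stage1.kernels_w, v1=hierarchy.stage1.kernels_v,
                 w2=hierarchy.stage2.kernels_w, v2=hierarchy.stage2.kernels_v)
    else:
        raise TypeError(f"cannot serialise {type(hierarchy).__name__}")


def load_hierarchy(path):
    from pcbc.hierarchy import ClassHierarchy, DetectionHierarchy
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]))
        if meta.get("version") != ARCHIVE_VERSION:
            raise ValueError(
                f"incompatible artifact version {meta.get('version')!r} in "
                f"{path} (expected {ARCHIVE_VERSION})")
        kind = meta.get("kind")
        if kind == "class_hierarchy":
            stage1 = DIMNetwork(W=npz["W1"], V=npz["V1"],
                                epsilon1=meta["epsilon1"][0],
                                epsilon2=meta["epsilon2"][0],
                                v_row_sums=npz["V1"].sum(axis=1),
                                meta=meta["stage1_meta"])
            stage2 = DIMNetwork(W=npz["W2"], V=npz["V2"],
                                epsilon1=meta["epsilon1"][1],
                                epsilon2=meta["epsilon2"][1],
                                v_row_sums=npz["V2"].sum(axis=1),
                                meta=meta["stage2_meta"])
            return ClassHierarchy(stage1=stage1, stage2=stage2,
                                  class_labels=meta["class_labels"],
                                  sigma=meta["sigma"], n_iter=meta["n_iter"],
                                  response_floor=meta["response_floor"])
        if kind == "detection_hierarchy":
            stage1 = ConvNetwork(kernels_w=npz["w1"], kernels_v=npz["v1"],
                                 epsilon1=meta["epsilon1"][0],
                                 epsilon2=meta["epsilon2"][0],
                                 meta=meta["stage1_meta"])
            stage2 = ConvNetwork(kernels_w=npz["w2"], kernels_v=npz["v2"],
                                 epsilon1=meta["epsilon1"][1],
                                 epsilon2=meta["epsilon2"][1],
                                 meta=meta["stage2_meta"])
            return DetectionHierarchy(stage1=stage1, stage2=stage2,
                                      sigma=meta["sigma"], nms=meta["nms"],
                                      n_iter=meta["n_iter"],
                                      response_floor=meta["response_floor"],
                                      scales=tuple(meta["scales"]))
        raise ValueError(f"unknown archive kind {kind!r} in {path}")


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
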