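"""Hierarchical predictive-coding networks with divisive input modulation.

Two-stage explaining-away inference over learned dictionaries of image
features: a matching stage that infers which dictionary elements are
present in an image, and a voting stage that pools those responses into
class decisions or spatial object hypotheses.
"""

from pcbc.core import (
    DIMNetwork,
    DIMState,
    build_network,
    dim_step,
    kl_divergence,
    solve_steady_state,
)
from pcbc.conv import (
    ConvNetwork,
    ConvState,
    build_conv_network,
    conv_solve_steady_state,
    conv_step,
)
from pcbc.preprocess import ContrastInput, local_contrast, zmncc
from pcbc.dictionary import (
    Dictionary,
    DictionaryElement,
    Patch,
    agglomerative_cluster,
    build_stage1_network,
    extract_keypoint_patches,
    extract_whole_image_patches,
    harris_keypoints,
)
from pcbc.hierarchy import (
    ClassHierarchy,
    DetectionHierarchy,
    collect_stage1_response_maps,
    collect_stage1_responses,
    learn_class_weights,
    learn_location_weights,
    train_classifier,
    train_detector,
)
from pcbc.recognize import (
    Classification,
    Detection,
    Region,
    classify,
    decode_region,
    detect,
    find_regions,
    nms_same_element,
)
from pcbc.metrics import (
    MatchResult,
    PRPoint,
    classification_error,
    equal_error_rate,
    f_score,
    match_detections,
    pr_curve,
)
from pcbc.synthetic import (
    GlyphDataset,
    GlyphSpec,
    SceneDataset,
    SceneSpec,
    make_glyph_dataset,
    make_scene_dataset,
    make_target_crops,
)
from pcbc.config import PipelineConfig

__version__ = "0.1.0"

__all__ = [
    "DIMNetwork", "DIMState", "build_network", "dim_step", "kl_divergence",
    "solve_steady_state",
    "ConvNetwork", "ConvState", "build_conv_network", "conv_step",
    "conv_solve_steady_state",
    "ContrastInput", "local_contrast", "zmncc",
    "Patch", "Dictionary", "DictionaryElement", "extract_whole_image_patches",
    "harris_keypoints", "extract_keypoint_patches", "agglomerative_cluster",
    "build_stage1_network",
    "ClassHierarchy", "DetectionHierarchy", "collect_stage1_responses",
    "collect_stage1_response_maps", "learn_class_weights",
    "learn_location_weights", "train_classifier", "train_detector",
    "Classification", "Detection", "Region", "classify", "detect",
    "nms_same_element", "find_regions", "decode_region",
    "MatchResult", "PRPoint", "match_detections", "pr_curve", "f_score",
    "equal_error_rate", "classification_error",
    "GlyphSpec", "SceneSpec", "GlyphDataset", "SceneDataset",
    "make_glyph_dataset", "make_scene_dataset", "make_target_crops",
    "PipelineConfig",
]
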