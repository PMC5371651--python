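import numpy as np
import pytest

from pcbc import (GlyphSpec, SceneSpec, make_glyph_dataset, make_scene_dataset,
                  make_target_crops, train_classifier, train_detector)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


# ---------------------------------------------------------------------------
# Shared small end-to-end fixtures (module-scoped in the files that need
# the big ones; these are deliberately tiny to keep the suite fast).
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_glyphs():
    spec = GlyphSpec(n_classes=4, image_size=24, jitter_px=1.5, jitter_deg=6.0,
                     scale_range=(0.95, 1.05), noise_sigma=0.02,
                     illum_range=(0.0, 0.2), seed=11)
    return spec, make_glyph_dataset(spec, 48, 24)


@pytest.fixture(scope="session")
def small_classifier(small_glyphs):
    _, ds = small_glyphs
    return train_classifier(ds.train_images, ds.train_labels,
                            sigma=3.0, kappa=0.85)


@pytest.fixture(scope="session")
def small_detection_setup():
    glyphs = GlyphSpec(n_classes=10, image_size=21, jitter_px=1.0,
                       jitter_deg=5.0, scale_range=(1.0, 1.0),
                       noise_sigma=0.02, illum_range=(0.0, 0.15), seed=3)
    crops = make_target_crops(glyphs, 21, 25)
    scenes = make_scene_dataset(
        SceneSpec(scene_size=64, n_objects=(1, 2), clutter=0.08,
                  object_size=21, seed=5), glyphs, 6, n_negative=10)
    detector = train_detector(crops, scenes.negatives, sigma=2.0, kappa=0.7,
                              lambda_min=2, patch_size=9, train_nms=True,
                              stage2_epsilon2=1e-4, response_floor=5e-5)
    return detector, scenes
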