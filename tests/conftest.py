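import numpy as np
import pytest

from microvasc import synth


@pytest.fixture(scope="session")
def small_canvas():
    return (64, 64)


@pytest.fixture(scope="session")
def demo_tree():
    return synth.generate_tree(synth.TreeParams(generations=5, seed=7))


@pytest.fixture(scope="session")
def demo_mask(demo_tree):
    mask, fov = synth.rasterize_tree(demo_tree, canvas=(128, 128))
    return mask, fov


@pytest.fixture(scope="session")
def demo_image(demo_mask):
    mask, fov = demo_mask
    return synth.render_fundus(mask, fov, seed=5)


@pytest.fixture(scope="session")
def tiny_labeled_images():
    """Small clean/degraded image set at 64x64 for fast QC training."""
    clean = synth.simulate_image_dataset(24, 0.0, seed=301, canvas=(64, 64))
    poor = synth.simulate_image_dataset(24, 1.0, seed=302, canvas=(64, 64))
    return clean, poor


@pytest.fixture(scope="session")
def tiny_seg_ensemble():
    """One-member ensemble trained briefly on 20 small images."""
    from microvasc import segmentation as seg

    recs = synth.simulate_image_dataset(20, 0.0, seed=303, canvas=(64, 64))
    cfg = seg.SegConfig(ensemble_size=1, epochs=3, patch_size=32, depth=2,
                        base_channels=8, seed=11)
    ens = seg.train_segmentation_ensemble([r.image for r in recs], [r.mask for r in recs], cfg)
    return ens, recs
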