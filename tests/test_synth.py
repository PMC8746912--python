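"""Synthetic vascular tree, rasterization, rendering, degradations."""

import numpy as np
import pytest

from microvasc import synth
from microvasc.synth import (
    Appearance,
    DegradeSpec,
    FundusImage,
    Segment,
    TreeParams,
    VascularTree,
    degrade_image,
    generate_tree,
    make_fov,
    rasterize_tree,
    render_fundus,
)


class TestGenerateTree:
    def test_no_branching_single_trunk(self):
        tree = generate_tree(TreeParams(generations=0, n_roots=1, seed=0))
        assert len(tree) == 1

    @pytest.mark.parametrize("g", [1, 2, 3, 5])
    def test_full_binary_tree_segment_count(self, g):
        # enumeration: a binary tree of depth g rooted at one trunk
        expected = sum(2**k for k in range(g + 1))
        tree = generate_tree(TreeParams(generations=g, n_roots=1, seed=1))
        assert len(tree) == expected
        # with r roots the count scales linearly
        tree4 = generate_tree(TreeParams(generations=g, n_roots=4, seed=1))
        assert len(tree4) == 4 * expected

    def test_deterministic_given_seed(self):
        p = TreeParams(generations=4, seed=42)
        assert generate_tree(p).segments == generate_tree(p).segments

    def test_different_seed_differs(self):
        a = generate_tree(TreeParams(generations=4, seed=1))
        b = generate_tree(TreeParams(generations=4, seed=2))
        assert a.segments != b.segments

    def test_children_attached_and_widths_non_increasing(self):
        tree = generate_tree(TreeParams(generations=5, seed=3))
        by_gen = {}
        for s in tree.segments:
            by_gen.setdefault(s.generation, []).append(s)
        ends = {s.end for s in tree.segments}
        for g in range(1, 6):
            for child in by_gen[g]:
                assert child.start in ends  # attached to some parent end
            w_parent = max(s.width_px for s in by_gen[g - 1])
            w_child = max(s.width_px for s in by_gen[g])
            assert w_child <= w_parent

    def test_murray_width_rule(self):
        p = TreeParams(generations=2, murray_exponent=3.0, width_root_px=8.0, seed=0)
        tree = generate_tree(p)
        w0 = next(s.width_px for s in tree.segments if s.generation == 0)
        w1 = next(s.width_px for s in tree.segments if s.generation == 1)
        assert w1 == pytest.approx(w0 * 2 ** (-1 / 3.0))

    @pytest.mark.parametrize("kwargs", [
        {"generations": 13},
        {"length_ratio": 0.0},
        {"length_ratio": 1.0},
        {"width_root_px": 0.5},
        {"n_roots": 0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TreeParams(**kwargs)


class TestRasterize:
    def test_empty_tree_gives_empty_mask(self):
        tree = VascularTree((), TreeParams(generations=0, n_roots=1, seed=0))
        mask, fov = rasterize_tree(tree, (128, 128))
        assert mask.sum() == 0 and fov.any()

    def test_straight_width1_segment_pixel_count(self):
        # 50-px horizontal width-1 line: the raster covers length+1 cells
        scale = 2 * 0.48 * 256
        seg = Segment((0.5, 0.5 - 25 / scale), (0.5, 0.5 + 25 / scale), 1.0, 0)
        tree = VascularTree((seg,), TreeParams(generations=0, n_roots=1,
                                               tortuosity_amp=0.0, seed=0))
        mask, _ = rasterize_tree(tree, (256, 256))
        assert abs(int(mask.sum()) - 50) <= 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_clipping_no_vessel_outside_fov(self, seed):
        tree = generate_tree(TreeParams(generations=6, seed=seed))
        mask, fov = rasterize_tree(tree, (128, 128))
        assert not (mask & ~fov).any()

    def test_deterministic(self, demo_tree):
        m1, _ = rasterize_tree(demo_tree, (128, 128))
        m2, _ = rasterize_tree(demo_tree, (128, 128))
        assert (m1 == m2).all()

    def test_offcanvas_tree_warns_empty(self):
        seg = Segment((5.0, 5.0), (6.0, 6.0), 1.0, 0)  # far outside unit FOV
        tree = VascularTree((seg,), TreeParams(generations=0, n_roots=1, seed=0))
        with pytest.warns(UserWarning, match="outside the canvas"):
            mask, _ = rasterize_tree(tree, (128, 128))
        assert mask.sum() == 0

    def test_small_canvas_rejected(self, demo_tree):
        with pytest.raises(ValueError):
            rasterize_tree(demo_tree, (32, 32))


class TestRender:
    def test_vessels_darker_than_background_in_green(self, demo_mask):
        mask, fov = demo_mask
        img = render_fundus(mask, fov, seed=1)
        green = img.pixels[:, :, 1]
        assert green[mask].mean() < green[fov & ~mask].mean()

    def test_same_seed_bit_identical(self, demo_mask):
        mask, fov = demo_mask
        a = render_fundus(mask, fov, seed=9)
        b = render_fundus(mask, fov, seed=9)
        assert (a.pixels == b.pixels).all()

    def test_blank_mask_has_no_vessel_dark_pixels(self):
        fov = make_fov((128, 128))
        app = Appearance()
        img = render_fundus(np.zeros((128, 128), bool), fov, appearance=app, seed=2)
        green = img.pixels[:, :, 1]
        floor = app.background_green - app.vessel_contrast / 2
        assert green[fov].min() > floor

    def test_metadata_and_validation(self, demo_mask):
        mask, fov = demo_mask
        img = render_fundus(mask, fov, seed=0, eye="left", participant_id="P1")
        assert img.eye == "left" and img.participant_id == "P1"
        with pytest.raises(ValueError):
            FundusImage(np.zeros((32, 32, 3)), np.zeros((32, 32), bool))


class TestDegrade:
    @pytest.mark.parametrize("mode", ["blur", "occlusion", "exposure"])
    def test_severity_zero_is_identity(self, demo_image, mode):
        out = degrade_image(demo_image, DegradeSpec(mode, 0.0, seed=4))
        assert (out.pixels == demo_image.pixels).all()
        assert (out.fov == demo_image.fov).all()

    def test_full_occlusion_covers_fov(self, demo_image):
        out = degrade_image(demo_image, DegradeSpec("occlusion", 1.0, seed=4))
        fov = demo_image.fov
        vals = out.pixels[fov][:, 1]
        covered = np.isclose(vals, np.median(vals)).mean()
        assert covered >= 0.95

    def test_blur_reduces_gradient_energy(self, demo_image):
        out = degrade_image(demo_image, DegradeSpec("blur", 0.8, seed=4))

        def energy(px):
            g = px[:, :, 1]
            return np.abs(np.diff(g, axis=0)).sum() + np.abs(np.diff(g, axis=1)).sum()

        assert energy(out.pixels) < energy(demo_image.pixels)

    def test_severity_monotone_blur(self, demo_image):
        def energy(px):
            g = px[:, :, 1]
            return np.abs(np.diff(g, axis=0)).sum() + np.abs(np.diff(g, axis=1)).sum()

        energies = [
            energy(degrade_image(demo_image, DegradeSpec("blur", s, seed=4)).pixels)
            for s in (0.2, 0.5, 0.9)
        ]
        assert energies[0] > energies[1] > energies[2]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            DegradeSpec("vignette", 0.5)

    def test_fov_preserved(self, demo_image):
        for mode in ("blur", "occlusion", "exposure"):
            out = degrade_image(demo_image, DegradeSpec(mode, 0.7, seed=1))
            assert (out.fov == demo_image.fov).all()


class TestDataset:
    def test_poor_label_rule_and_determinism(self):
        recs = synth.simulate_image_dataset(12, 0.5, seed=5, canvas=(64, 64))
        for r in recs:
            if r.degradation is not None and r.degradation.severity >= synth.POOR_SEVERITY_THRESHOLD:
                assert r.label == "poor"
            else:
                assert r.label == "good"
        recs2 = synth.simulate_image_dataset(12, 0.5, seed=5, canvas=(64, 64))
        assert all((a.image.pixels == b.image.pixels).all() for a, b in zip(recs, recs2))

    def test_manifest_roundtrip(self, tmp_path):
        import pandas as pd

        recs = synth.simulate_image_dataset(4, 0.5, seed=6, canvas=(64, 64))
        manifest = synth.write_image_dataset(recs, tmp_path)
        df = pd.read_csv(manifest, sep="\t")
        assert len(df) == 4
        assert set(["image", "mask", "fov", "participant_id", "eye", "label"]) <= set(df.columns)
        assert all((tmp_path / p).exists() for p in df["image"])
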