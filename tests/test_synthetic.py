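"""Synthetic cohort generator: determinism, anatomy, and self-consistency."""

import numpy as np
import pytest

from orthoface import synthetic as syn
from orthoface.calibration import Scale
from orthoface.io import BILATERAL_PAIRS, read_annotations
from orthoface.measurements import MEASUREMENT_IDS, compute_measurements
from orthoface.synthetic import (
    CANVAS,
    ConfigError,
    GeneratorConfig,
    ground_truth_measurements,
    render_face,
    sample_geometry,
)


class TestSampleGeometry:
    def test_deterministic_for_fixed_seed(self):
        cfg = GeneratorConfig(n_subjects=1, seed=5)
        g1 = sample_geometry(np.random.default_rng(5), cfg)
        g2 = sample_geometry(np.random.default_rng(5), cfg)
        np.testing.assert_array_equal(g1.landmarks, g2.landmarks)
        assert g1.pad_center == g2.pad_center
        assert g1.mm_per_px == g2.mm_per_px

    def test_zero_jitter_gives_exact_mirror_symmetry(self):
        cfg = GeneratorConfig(n_subjects=1, seed=2, asymmetry_jitter_px=0.0)
        g = sample_geometry(np.random.default_rng(2), cfg)
        mid = g.midline_x
        for r, l in BILATERAL_PAIRS:
            assert g.landmarks[r, 0] + g.landmarks[l, 0] == pytest.approx(2 * mid)
            assert g.landmarks[r, 1] == pytest.approx(g.landmarks[l, 1])

    def test_jitter_bounded(self):
        cfg = GeneratorConfig(n_subjects=1, seed=9, asymmetry_jitter_px=3.0)
        rng = np.random.default_rng(9)
        for _ in range(20):
            g = sample_geometry(rng, cfg)
            mid = g.midline_x
            for r, l in BILATERAL_PAIRS:
                assert abs(g.landmarks[r, 0] - (2 * mid - g.landmarks[l, 0])) <= 3.0
                assert abs(g.landmarks[r, 1] - g.landmarks[l, 1]) <= 3.0

    def test_anatomical_vertical_ordering(self):
        cfg = GeneratorConfig(n_subjects=1, seed=4)
        rng = np.random.default_rng(4)
        for _ in range(25):
            lm = sample_geometry(rng, cfg).landmarks
            brow_y = lm[[11, 12], 1].mean()
            eye_y = lm[[9, 10], 1].mean()
            assert brow_y < eye_y < lm[6, 1]          # brows < eyes < subnasale
            assert lm[6, 1] < lm[3, 1] <= lm[2, 1]    # nose < upper lip <= lower
            assert lm[2, 1] < lm[1, 1] < lm[0, 1]     # lower lip < menton

    def test_landmarks_inside_margin(self):
        cfg = GeneratorConfig(n_subjects=1, seed=6)
        rng = np.random.default_rng(6)
        for _ in range(25):
            lm = sample_geometry(rng, cfg).landmarks
            assert (lm >= 32).all() and (lm <= CANVAS - 32).all()

    def test_deformity_fraction_shifts_lower_third(self):
        """Populations with and without deformity differ in mean M7."""

        def mean_m7(frac, seed):
            cfg = GeneratorConfig(n_subjects=1, seed=seed, deformity_fraction=frac)
            rng = np.random.default_rng(seed)
            vals = [
                ground_truth_measurements(sample_geometry(rng, cfg), "s").values["M7"]
                for _ in range(50)
            ]
            return np.mean(vals)

        assert mean_m7(1.0, 8) > mean_m7(0.0, 8) + 3.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_subjects=0)
        with pytest.raises(ConfigError):
            GeneratorConfig(deformity_fraction=1.5)
        with pytest.raises(ConfigError):
            GeneratorConfig(mm_per_px_range=(0.2, 0.1))
        with pytest.raises(ConfigError):
            GeneratorConfig(asymmetry_jitter_px=5.0)


class TestRenderFace:
    def test_noiseless_render_bit_identical(self, sample_face):
        g = sample_face["geometry"]
        img1, _, _ = render_face(g, noise_sigma=0.0)
        img2, _, _ = render_face(g, noise_sigma=0.0)
        assert np.array_equal(img1.pixels, img2.pixels)

    def test_returned_landmarks_equal_geometry(self, sample_face):
        np.testing.assert_array_equal(
            sample_face["landmarks"].points, sample_face["geometry"].landmarks
        )

    def test_pad_foreground_pixel_count(self, sample_face):
        """Thresholded disc area within 5% of pi*(d/2)^2."""
        from orthoface.calibration import DEFAULT_PAD_COLOR

        img = sample_face["image"].pixels.astype(float)
        dist = np.linalg.norm(img - np.array(DEFAULT_PAD_COLOR), axis=-1)
        count = int((dist < 90).sum())
        d = sample_face["pad"].diameter_px
        expected = np.pi * (d / 2) ** 2
        assert count == pytest.approx(expected, rel=0.05)

    def test_landmarks_inside_face_outline(self, sample_face):
        g = sample_face["geometry"]
        cy = (g.face_top + g.landmarks[0, 1]) / 2
        ry = (g.landmarks[0, 1] - g.face_top) / 2
        r = ((g.landmarks[:, 0] - g.midline_x) / g.face_half_width) ** 2 + (
            (g.landmarks[:, 1] - cy) / ry
        ) ** 2
        assert (r <= 1.0 + 1e-9).all()

    def test_pad_does_not_overlap_landmarks(self, sample_face):
        g = sample_face["geometry"]
        d = np.linalg.norm(g.landmarks - np.array(g.pad_center), axis=1)
        assert (d > g.pad_diameter_px / 2).all()


class TestGenerateDataset:
    def test_files_and_splits(self, tiny_dataset):
        import json

        man = json.loads(tiny_dataset["manifest_path"].read_text())
        assert man["n_subjects"] == 6
        assert len(man["images"]) == 6
        splits = {e["split"] for e in man["images"]}
        assert splits == {"train", "test"}
        for entry in man["images"]:
            assert (tiny_dataset["dir"] / entry["image"]).exists()
        records = read_annotations(tiny_dataset["dir"] / man["annotations"])
        assert len(records) == 6

    def test_same_seed_byte_identical_annotations(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=3, seed=13)
        p1 = syn.generate_dataset(cfg, tmp_path / "a")
        p2 = syn.generate_dataset(cfg, tmp_path / "b")
        a = (tmp_path / "a" / "annotations.json").read_bytes()
        b = (tmp_path / "b" / "annotations.json").read_bytes()
        assert a == b
        img_a = (tmp_path / "a" / "images" / "subj0000.png").read_bytes()
        img_b = (tmp_path / "b" / "images" / "subj0000.png").read_bytes()
        assert img_a == img_b

    def test_ground_truth_matches_measurement_module(self, tiny_dataset):
        """Self-consistency: stored GT equals measurements recomputed from
        the true landmarks and true scale (well below caliper precision)."""
        from orthoface.measurements import measurements_from_csv

        records = {
            r.image_id: r
            for r in read_annotations(tiny_dataset["dir"] / "annotations.json")
        }
        gt = measurements_from_csv(tiny_dataset["dir"] / "ground_truth.csv")
        for vec in gt:
            rec = records[vec.subject_id]
            recomputed = compute_measurements(
                rec.landmarks, Scale(rec.mm_per_px, "manifest"), round_mm=False
            )
            for m in MEASUREMENT_IDS:
                # CSV carries 0.01 mm precision
                assert vec.values[m] == pytest.approx(recomputed.values[m], abs=0.006)

    def test_intercanthal_gt_by_construction(self, tiny_dataset):
        records = read_annotations(tiny_dataset["dir"] / "annotations.json")
        for rec in records:
            d_px = np.linalg.norm(rec.landmarks[9] - rec.landmarks[10])
            from orthoface.measurements import measurements_from_csv

            gt = {
                v.subject_id: v
                for v in measurements_from_csv(tiny_dataset["dir"] / "ground_truth.csv")
            }
            assert gt[rec.image_id].values["M3"] == pytest.approx(
                d_px * rec.mm_per_px, abs=0.006
            )


def test_exact_self_consistency_oracle():
    """Noiseless GT agrees with the measurements module to 1e-9 mm."""
    cfg = GeneratorConfig(n_subjects=1, seed=21)
    rng = np.random.default_rng(21)
    g = sample_geometry(rng, cfg)
    from orthoface.io import LandmarkSet

    gt = ground_truth_measurements(g, "s")
    direct = compute_measurements(
        LandmarkSet(g.landmarks, (CANVAS, CANVAS)),
        Scale(g.mm_per_px, "manifest"),
        round_mm=False,
    )
    np.testing.assert_allclose(gt.as_array(), direct.as_array(), atol=1e-9)
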