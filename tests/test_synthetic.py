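"""Phantom rendering, simulated raters and study assembly."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from echodim import (
    PhantomConfig,
    RaterModel,
    StudyConfig,
    compute_dimensions,
    generate_phantom_frame,
    generate_study_tables,
    generate_validation_study,
    grouped_train_split,
    sample_study_dimensions,
    simulate_ai_annotations,
    simulate_rater_annotations,
)
from echodim.phantom import PhantomGeometryError, StudyDimensions

DIMS = StudyDimensions(lvid_d_mm=47.0, lvid_s_mm=37.7, ivs_mm=11.7, pw_mm=11.0)


def _frame(phase="ED", angle=90.0, render=True, speckle=0.05, seed=0):
    cfg = PhantomConfig(speckle_noise_sd=speckle)
    return generate_phantom_frame(
        cfg, DIMS, phase, axis_angle_deg=angle, seed=seed, render=render
    )


class TestPhantom:
    def test_truth_lvid_matches_requested_dimension(self):
        """Vertical axis, isotropic 0.5 mm/px: LVID keypoints 94 px apart."""
        frame = _frame(render=False)
        d = frame.truth["pw_endo"] - frame.truth["sept_post"]
        assert np.hypot(*d) == pytest.approx(94.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [60.0, 90.0, 117.5])
    def test_truth_dimensions_exact_at_any_angle(self, angle):
        frame = _frame(angle=angle, render=False)
        rec = compute_dimensions(frame.truth, 0.5, 0.5)
        assert rec.lvid_mm == pytest.approx(47.0, abs=1e-9)
        assert rec.ivs_mm == pytest.approx(11.7, abs=1e-9)
        assert rec.pw_mm == pytest.approx(11.0, abs=1e-9)

    def test_cavity_darker_than_walls(self):
        """Noise-free rendering: cavity band strictly darker than wall bands."""
        frame = _frame(speckle=0.0)
        image = frame.image
        # sample at band midpoints along the (vertical) axis
        mid = lambda a, b: ((frame.truth[a] + frame.truth[b]) / 2).astype(int)
        cavity = image[tuple(mid("sept_post", "pw_endo")[::-1])]
        septum = image[tuple(mid("sept_ant", "sept_post")[::-1])]
        pw = image[tuple(mid("pw_endo", "pw_epi")[::-1])]
        assert cavity < septum and cavity < pw

    def test_same_seed_bit_identical(self):
        a, b = _frame(seed=3), _frame(seed=3)
        assert np.array_equal(a.image, b.image)
        for name in ("sept_ant", "sept_post", "pw_endo", "pw_epi"):
            assert np.array_equal(a.truth[name], b.truth[name])

    def test_oversized_ventricle_raises_naming_dimension(self):
        big = StudyDimensions(lvid_d_mm=200.0, lvid_s_mm=150.0, ivs_mm=11.7, pw_mm=11.0)
        with pytest.raises(PhantomGeometryError, match="lvid"):
            generate_phantom_frame(PhantomConfig(), big, "ED", render=False)

    def test_sampled_dimensions_positive_and_ordered(self, rng):
        cfg = PhantomConfig()
        for _ in range(200):
            d = sample_study_dimensions(cfg, rng)
            assert d.lvid_s_mm > 0 and d.ivs_mm > 0 and d.pw_mm > 0
            assert d.lvid_s_mm < d.lvid_d_mm


class TestRaterSimulation:
    def test_zero_noise_reproduces_truth(self):
        frame = _frame(render=False)
        rater = RaterModel(rater_id="E01")
        recs = simulate_rater_annotations(frame, rater, n_readings=2, seed=0)
        assert len(recs) == 2
        for rec in recs:
            for name in ("sept_ant", "sept_post", "pw_endo", "pw_epi"):
                np.testing.assert_allclose(rec.keypoints[name], frame.truth[name], atol=1e-9)

    def test_miss_prob_one_flags_everything_missing(self):
        frame = _frame(render=False)
        rater = RaterModel(rater_id="E01", miss_prob=1.0)
        (rec,) = simulate_rater_annotations(frame, rater, n_readings=1, seed=0)
        assert rec.keypoints.present() == []

    @pytest.mark.parametrize("angle", [90.0, 75.0])
    def test_lvid_bias_propagates_exactly(self, angle):
        """bias_mm={'lvid': +2}: LVID lengthens by 2 mm, IVS and PW untouched."""
        frame = _frame(angle=angle, render=False)
        ai = RaterModel(rater_id="AI", bias_mm={"lvid": 2.0})
        rec = simulate_ai_annotations(frame, ai, seed=0)
        got = compute_dimensions(rec.keypoints, 0.5, 0.5)
        assert got.lvid_mm == pytest.approx(47.0 + 2.0, abs=1e-9)
        assert got.ivs_mm == pytest.approx(11.7, abs=1e-9)
        assert got.pw_mm == pytest.approx(11.0, abs=1e-9)

    def test_scalar_bias_lengthens_every_dimension(self):
        frame = _frame(render=False)
        ai = RaterModel(rater_id="AI", bias_mm=1.5)
        rec = simulate_ai_annotations(frame, ai, seed=0)
        got = compute_dimensions(rec.keypoints, 0.5, 0.5)
        assert got.lvid_mm == pytest.approx(48.5, abs=1e-9)
        assert got.ivs_mm == pytest.approx(13.2, abs=1e-9)
        assert got.pw_mm == pytest.approx(12.5, abs=1e-9)

    def test_fixed_seed_reproducible(self):
        frame = _frame(render=False)
        rater = RaterModel(rater_id="E01", longitudinal_sd_frac=0.2, transverse_sd_frac=0.1)
        a = simulate_rater_annotations(frame, rater, n_readings=2, seed=5)
        b = simulate_rater_annotations(frame, rater, n_readings=2, seed=5)
        for ra, rb in zip(a, b):
            for name in ra.keypoints.present():
                np.testing.assert_array_equal(ra.keypoints[name], rb.keypoints[name])


class TestStudyAssembly:
    def test_counts_and_phase_pairing(self, noisy_tables):
        frames, ann = noisy_tables.frames, noisy_tables.annotations
        assert len(frames) == 2 * 20
        # every study contributes exactly one ED and one ES frame
        per_study = frames.groupby("study_id")["phase"].agg(sorted)
        assert all(p == ["ED", "ES"] for p in per_study)
        # (n_experts * n_readings + 1 AI) evaluations per frame, 4 keypoints each
        per_frame = ann.groupby("frame_id").size()
        assert (per_frame == (5 * 2 + 1) * 4).all()

    def test_default_configuration_evaluation_counts(self):
        cfg = StudyConfig(phantom=PhantomConfig(n_studies=2), render_images=False)
        t = generate_study_tables(cfg, seed=0)
        assert len(t.frames) == 4
        readings = t.annotations.groupby(["frame_id", "rater_id"])["reading_index"].nunique()
        expert_rows = t.annotations[t.annotations.rater_id != "AI"]
        # 13 experts x 2 blinded readings = 26 expert evaluations per frame
        evals = expert_rows.groupby("frame_id").apply(
            lambda g: len(g[["rater_id", "reading_index"]].drop_duplicates()),
            include_groups=False,
        )
        assert (evals == 26).all()

    def test_written_study_byte_identical_for_same_seed(self, tmp_path):
        cfg = StudyConfig(phantom=PhantomConfig(n_studies=2), n_experts=3)
        generate_validation_study(cfg, tmp_path / "a", seed=42)
        generate_validation_study(cfg, tmp_path / "b", seed=42)
        for name in ("frames.csv", "truth.csv", "annotations.csv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)
        png = "S001_ED.png"
        assert (tmp_path / "a" / "frames" / png).read_bytes() == (
            tmp_path / "b" / "frames" / png
        ).read_bytes()


class TestGroupedSplit:
    def test_singleton_videos_split_exactly(self):
        frames = pd.DataFrame(
            {"frame_id": [f"f{i}" for i in range(1894)], "video_id": [f"v{i}" for i in range(1894)]}
        )
        train, progress = grouped_train_split(frames, train_frac=0.8, seed=0)
        assert len(train) == 1515 and len(progress) == 379

    def test_two_videos_half_split(self):
        frames = pd.DataFrame(
            {
                "frame_id": [f"f{i}" for i in range(10)],
                "video_id": ["a"] * 5 + ["b"] * 5,
            }
        )
        train, progress = grouped_train_split(frames, train_frac=0.5, seed=1)
        assert len(train) == 5 and len(progress) == 5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_no_video_straddles_partitions(self, seed, rng):
        vids = rng.integers(0, 30, size=120)
        frames = pd.DataFrame(
            {"frame_id": [f"f{i}" for i in range(120)], "video_id": [f"v{v}" for v in vids]}
        )
        train, progress = grouped_train_split(frames, seed=seed)
        lookup = frames.set_index("frame_id")["video_id"]
        assert set(lookup[train]) & set(lookup[progress]) == set()
        assert sorted(train + progress) == sorted(frames["frame_id"])

    def test_fewer_than_two_videos_rejected(self):
        frames = pd.DataFrame({"frame_id": ["f0", "f1"], "video_id": ["v", "v"]})
        with pytest.raises(ValueError, match="2 videos"):
            grouped_train_split(frames)
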