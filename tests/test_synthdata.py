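"""Tests for the phantom thermogram generator and dataset plumbing."""

import json

import numpy as np
import pytest
from scipy import ndimage

from pfseg.calibration import WindowSpec
from pfseg.gamma import enhance_two_stage
from pfseg.synthdata import (
    PhantomConfig,
    background_crossing_time,
    build_dataset,
    make_foot_masks,
    sample_frames,
    simulate_recovery,
    split_sequences,
)


class TestFootMasks:
    def test_two_connected_components(self):
        mask = make_foot_masks(PhantomConfig())
        _, n = ndimage.label(mask)
        assert n == 2

    def test_mirror_symmetry(self):
        mask = make_foot_masks(PhantomConfig())
        assert np.array_equal(mask, mask[:, ::-1])

    def test_area_fraction_within_bounds(self):
        cfg = PhantomConfig()
        frac = make_foot_masks(cfg).mean()
        lo, hi = cfg.foot_area_fraction
        assert lo <= frac <= hi

    def test_clear_of_blackbody_regions(self):
        cfg = PhantomConfig()
        mask = make_foot_masks(cfg)
        for region in cfg.blackbody_regions:
            assert not mask[region.slices()].any()


class TestRecovery:
    def test_start_temperature_exact(self):
        cfg = PhantomConfig(frames=3, noise_sd_c=0.0, nonuniform_cooling=False)
        seq = simulate_recovery(cfg)
        assert np.allclose(seq.frames[0][seq.mask], cfg.foot_start_temp_c)

    def test_asymptote_near_body_temperature(self):
        cfg = PhantomConfig(frames=1, noise_sd_c=0.0, nonuniform_cooling=False,
                            recovery_time_constant_s=10.0)
        # closed form: after 20 time constants feet are at T_end to machine noise
        seq = simulate_recovery(cfg)
        assert seq.noise_free_foot_mean(200.0) == pytest.approx(36.0, abs=1e-6)

    def test_background_constant(self, short_phantom):
        seq = short_phantom
        bg = ~seq.mask
        for ref in seq.config.blackbody_regions:
            bg[ref.slices()] = False
        for t in (0, len(seq) // 2, len(seq) - 1):
            assert np.allclose(seq.frames[t][bg], seq.config.background_temp_c)

    def test_blackbody_patches_at_setpoints(self, short_phantom):
        for ref in short_phantom.config.blackbody_references:
            assert np.allclose(short_phantom.frames[0][ref.region.slices()], ref.setpoint_c)

    def test_foot_mean_strictly_increasing_and_bounded(self, short_phantom):
        seq = short_phantom
        means = seq.frames[:, seq.mask].mean(axis=1)
        assert np.all(np.diff(means) > 0)
        assert means[0] >= seq.config.foot_start_temp_c - 1e-9
        assert means[-1] < seq.config.foot_end_temp_c

    def test_crossing_time_closed_form(self):
        cfg = PhantomConfig(frames=400, noise_sd_c=0.0, nonuniform_cooling=False)
        t_star = background_crossing_time(cfg)
        expected = cfg.recovery_time_constant_s * np.log(
            (36.0 - 18.0) / (36.0 - 22.0)
        )
        assert t_star == pytest.approx(expected)
        seq = simulate_recovery(cfg)
        k = int(round(t_star))
        # at the crossing frame the foot/background contrast vanishes
        contrast = abs(seq.frames[k][seq.mask].mean() - cfg.background_temp_c)
        assert contrast < 0.05

    def test_noise_scale(self):
        cfg = PhantomConfig(frames=2, nonuniform_cooling=False, seed=3)
        seq = simulate_recovery(cfg)
        bg = ~seq.mask
        for ref in cfg.blackbody_regions:
            bg[ref.slices()] = False
        sd = seq.frames[0][bg].std()
        assert sd == pytest.approx(cfg.noise_sd_c, rel=0.1)

    def test_seeded_determinism(self):
        cfg = PhantomConfig(frames=4, seed=11)
        a = simulate_recovery(cfg)
        b = simulate_recovery(cfg)
        assert np.array_equal(a.frames, b.frames)
        c = simulate_recovery(PhantomConfig(frames=4, seed=12))
        assert not np.array_equal(a.frames, c.frames)

    def test_nonuniform_cooling_perturbs_feet_only(self):
        base = PhantomConfig(frames=2, noise_sd_c=0.0, nonuniform_cooling=False)
        bump = PhantomConfig(frames=2, noise_sd_c=0.0, nonuniform_cooling=True)
        a, b = simulate_recovery(base), simulate_recovery(bump)
        diff = np.abs(a.frames[0] - b.frames[0])
        assert diff[~a.mask].max() == 0.0
        assert diff[a.mask].max() > 0.1


class TestRegimeCoverage:
    def test_early_frames_beta_low_late_frames_beta_high(self):
        cfg = PhantomConfig(seed=5)
        seq = simulate_recovery(cfg)
        images, _, idx = sample_frames(seq, stride=10)
        betas = [enhance_two_stage(im)[1].beta for im in images]
        # earliest sampled frames: feet below the window -> beta <= 1
        assert all(b <= 1 for b in betas[:5])
        # last sampled frames: bright feet on dark background -> beta > 1
        assert all(b > 1 for b in betas[-5:])


class TestDatasetPlumbing:
    def test_stride_ten_yields_sixty_samples(self):
        cfg = PhantomConfig(seed=2, frames=600)
        seq = simulate_recovery(cfg)
        images, masks, idx = sample_frames(seq, stride=10)
        assert len(images) == len(masks) == 60

    def test_split_twenty_sequences(self):
        train, val, test = split_sequences(20)
        assert (len(train), len(val), len(test)) == (17, 1, 2)
        assert set(train) | set(val) | set(test) == set(range(20))
        assert not (set(train) & set(val) or set(train) & set(test) or set(val) & set(test))

    @pytest.mark.parametrize("n", [3, 7, 40])
    def test_split_partitions_without_overlap(self, n):
        buckets = split_sequences(n)
        flat = [i for b in buckets for i in b]
        assert sorted(flat) == list(range(n))
        assert all(len(b) >= 1 for b in buckets)

    def test_crop_excludes_blackbody_columns(self):
        cfg = PhantomConfig(seed=1, frames=2)
        seq = simulate_recovery(cfg)
        images, masks, _ = sample_frames(seq, stride=1)
        assert images[0].shape == (cfg.height, cfg.width - 2 * cfg.blackbody_margin_px)
        assert masks[0].shape == images[0].shape

    def test_build_dataset_counts_and_flip(self, tmp_path):
        cfg = PhantomConfig(seed=4, frames=40)
        manifest = build_dataset(cfg, n_subjects=3, root=tmp_path / "d1",
                                 sampling_stride=10, flip_augment=True)
        # 3 subjects x 4 sampled frames x 2 (flip) = 24 records
        assert len(manifest["records"]) == 24
        plain = build_dataset(cfg, n_subjects=3, root=tmp_path / "d2",
                              sampling_stride=10, flip_augment=False)
        assert len(plain["records"]) == 12

    def test_flipped_pairs_consistent(self, tmp_path):
        from pfseg.calibration import read_mask
        import imageio.v3 as iio

        cfg = PhantomConfig(seed=4, frames=20)
        build_dataset(cfg, n_subjects=3, root=tmp_path, sampling_stride=10)
        img_dir = tmp_path / "train" / "images"
        msk_dir = tmp_path / "train" / "masks"
        straight = sorted(p for p in img_dir.glob("*.png") if "_flip" not in p.name)
        assert straight
        for p in straight:
            q = img_dir / p.name.replace(".png", "_flip.png")
            assert np.array_equal(iio.imread(q), iio.imread(p)[:, ::-1])
            m = read_mask(msk_dir / p.name)
            mf = read_mask(msk_dir / q.name)
            assert np.array_equal(mf, m[:, ::-1])

    def test_bit_identical_datasets_for_same_seed(self, tmp_path):
        cfg = PhantomConfig(seed=9, frames=20)
        m1 = build_dataset(cfg, 3, tmp_path / "a", sampling_stride=10)
        m2 = build_dataset(cfg, 3, tmp_path / "b", sampling_stride=10)
        assert json.dumps(m1, sort_keys=True) == json.dumps(m2, sort_keys=True)
        for p in sorted((tmp_path / "a").rglob("*.png")):
            q = tmp_path / "b" / p.relative_to(tmp_path / "a")
            assert p.read_bytes() == q.read_bytes()

    def test_split_by_sequence_no_leakage(self, tmp_path):
        cfg = PhantomConfig(seed=4, frames=20)
        manifest = build_dataset(cfg, 4, tmp_path, sampling_stride=10)
        subj_buckets = {}
        for rec in manifest["records"]:
            subj_buckets.setdefault(rec["subject"], set()).add(rec["bucket"])
        assert all(len(b) == 1 for b in subj_buckets.values())
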