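"""Synthetic cold-recovery thermogram phantoms with ground-truth masks.

The clinical recordings this package targets are sequences of radiometric
frames of both plantar feet rewarming after a cold stress: a constant ~22 °C
background, foot regions climbing from below ambient (~18 °C) toward body
temperature (~36 °C) over 10-15 minutes at 1 Hz, sensor noise at the NETD
scale (~0.04 °C), and two black-body reference patches held at 28 °C and
36 °C at the frame margins.  No public dataset exists, so this module
generates seeded phantoms with that thermal structure, giving every other
module a reproducible test bed.

The rewarming law is exponential relaxation,

    T_foot(t) = T_end - (T_end - T_start) * exp(-t / tau),

the minimal physical model for passive return to equilibrium; it crosses the
background temperature at ``t* = tau * ln((T_end - T_start)/(T_end - T_bg))``,
the minimum-contrast instant that makes early frames hard to segment.
Optional Gaussian warm/cold patches inside the feet emulate the irregular
cooling a water/gel protocol produces.

Foot silhouettes are stylized (ellipse sole plus five toe disks, mirrored
left/right) — adequate for exercising windowing, enhancement and
segmentation, but not anatomically faithful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .calibration import (
    BlackbodyReference,
    RadiometricFrame,
    Rect,
    TemperatureMap,
    WindowSpec,
    crop_calibration_targets,
    temperature_to_grayscale,
    write_mask,
)
from .gamma import GrayscaleImage

__all__ = [
    "PhantomConfig",
    "PhantomSequence",
    "make_foot_masks",
    "simulate_recovery",
    "background_crossing_time",
    "frames_to_radiometric",
    "build_dataset",
    "split_sequences",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one phantom recording.

    Defaults mirror the acquisition they emulate: 22 °C ambient background,
    feet cooled to 18 °C recovering to 36 °C, 0.04 °C Gaussian sensor noise,
    1 Hz framing, black bodies at 28/36 °C parked at the left/right margins.
    ``recovery_time_constant_s`` (tau) defaults to 180 s so a 600-frame
    sequence spans the full dark-to-bright contrast evolution.
    """

    height: int = 128
    width: int = 160
    background_temp_c: float = 22.0
    foot_start_temp_c: float = 18.0
    foot_end_temp_c: float = 36.0
    recovery_time_constant_s: float = 180.0
    frames: int = 600
    frame_interval_s: float = 1.0
    noise_sd_c: float = 0.04
    blackbody_setpoints_c: tuple[float, float] = (28.0, 36.0)
    blackbody_margin_px: int = 10
    nonuniform_cooling: bool = True
    n_cooling_patches: int = 2
    cooling_patch_amp_c: float = 1.5
    foot_area_fraction: tuple[float, float] = (0.22, 0.42)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.foot_start_temp_c < self.background_temp_c < self.foot_end_temp_c):
            raise ValueError("require foot_start < background < foot_end")
        if self.noise_sd_c < 0:
            raise ValueError("noise_sd_c must be >= 0")
        if self.frames < 1:
            raise ValueError("need at least one frame")
        if self.height < 32 or self.width < 48:
            raise ValueError("phantom frames must be at least 32 x 48 pixels")

    @property
    def blackbody_regions(self) -> tuple[Rect, Rect]:
        """Vertical reference strips at the left and right frame margins."""
        m = self.blackbody_margin_px
        h4 = self.height // 4
        return (
            Rect(h4, self.height - h4, 0, m),
            Rect(h4, self.height - h4, self.width - m, self.width),
        )

    @property
    def blackbody_references(self) -> tuple[BlackbodyReference, BlackbodyReference]:
        lo, hi = sorted(self.blackbody_setpoints_c)
        r_lo, r_hi = self.blackbody_regions
        return (BlackbodyReference(r_lo, lo), BlackbodyReference(r_hi, hi))


@dataclass(frozen=True)
class PhantomSequence:
    """Time-ordered temperature frames with a static ground-truth mask."""

    frames: np.ndarray          # (T, H, W) temperatures in °C
    mask: np.ndarray            # (H, W) boolean, constant over the sequence
    timestamps_s: np.ndarray    # (T,)
    config: PhantomConfig

    def __post_init__(self) -> None:
        if self.frames.shape[0] != self.timestamps_s.shape[0]:
            raise ValueError("one timestamp per frame required")
        if self.frames.shape[1:] != self.mask.shape:
            raise ValueError("mask shape must match frames")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def temperature_map(self, t: int) -> TemperatureMap:
        return TemperatureMap(self.frames[t])

    def noise_free_foot_mean(self, t_s: float) -> float:
        """Closed-form mean foot temperature at time ``t_s`` (no noise)."""
        c = self.config
        return c.foot_end_temp_c - (c.foot_end_temp_c - c.foot_start_temp_c) * float(
            np.exp(-t_s / c.recovery_time_constant_s)
        )


def background_crossing_time(cfg: PhantomConfig) -> float:
    """Instant at which the rewarming foot matches the background temperature."""
    c = cfg
    return c.recovery_time_constant_s * float(
        np.log((c.foot_end_temp_c - c.foot_start_temp_c) / (c.foot_end_temp_c - c.background_temp_c))
    )


def _draw_foot(mask: np.ndarray, center_r: float, center_c: float, length: float,
               width: float, toe_sign: float) -> None:
    """Stamp one foot (ellipse sole + five toe disks) into ``mask`` in place."""
    h, w = mask.shape
    rr, cc = np.mgrid[0:h, 0:w]
    sole = ((rr - center_r) / (length / 2.0)) ** 2 + ((cc - center_c) / (width / 2.0)) ** 2 <= 1.0
    mask |= sole
    toe_row = center_r - toe_sign * (length / 2.0)
    toe_radius = width / 7.5
    for k in range(5):
        off = (k - 2) * width / 4.6
        toe_c = center_c + off
        r_k = toe_radius * (1.0 - 0.12 * abs(k - 2))
        toe = (rr - (toe_row - toe_sign * toe_radius * 0.8)) ** 2 + (cc - toe_c) ** 2 <= r_k ** 2
        mask |= toe


def make_foot_masks(cfg: PhantomConfig) -> np.ndarray:
    """Boolean mask with two mirror-symmetric foot silhouettes.

    The two feet sit in the central strip, clear of the black-body margins,
    and never touch; the pair is exactly mirror-symmetric about the vertical
    mid-line.  Geometry is deterministic for a given config.
    """
    h, w = cfg.height, cfg.width
    margin = cfg.blackbody_margin_px
    usable_w = w - 2 * margin
    length = 0.68 * h
    foot_w = 0.26 * usable_w
    center_r = h * 0.55
    center_left = w / 2.0 - 0.17 * usable_w
    half = np.zeros((h, w), dtype=bool)
    _draw_foot(half, center_r, center_left, length, foot_w, toe_sign=1.0)
    mask = half | half[:, ::-1]
    for region in cfg.blackbody_regions:
        sl = region.slices()
        if mask[sl].any():
            raise ValueError("foot geometry collides with a black-body region")
    frac = mask.mean()
    lo, hi = cfg.foot_area_fraction
    if not (lo <= frac <= hi):
        raise ValueError(
            f"foot area fraction {frac:.3f} outside configured bounds [{lo}, {hi}]"
        )
    return mask


def simulate_recovery(cfg: PhantomConfig) -> PhantomSequence:
    """Generate the noisy temperature sequence for one phantom subject.

    Foot pixels follow the exponential rewarming law; the background stays at
    ambient; black-body strips are held at their set points.  Zero-mean
    Gaussian noise of NETD scale is added everywhere.  With
    ``nonuniform_cooling`` enabled, a few Gaussian bumps inside the feet
    offset the start temperature (decaying with recovery), emulating patchy
    cooling.
    """
    rng = np.random.default_rng(cfg.seed)
    mask = make_foot_masks(cfg)
    h, w = cfg.height, cfg.width
    t = np.arange(cfg.frames, dtype=np.float64) * cfg.frame_interval_s
    base = np.full((h, w), cfg.background_temp_c)
    offsets = np.zeros((h, w))
    if cfg.nonuniform_cooling and cfg.n_cooling_patches > 0:
        rows, cols = np.nonzero(mask)
        rr, cc = np.mgrid[0:h, 0:w]
        for _ in range(cfg.n_cooling_patches):
            k = rng.integers(rows.size)
            amp = rng.uniform(-cfg.cooling_patch_amp_c, cfg.cooling_patch_amp_c)
            sigma = rng.uniform(0.05, 0.12) * min(h, w)
            offsets += amp * np.exp(-((rr - rows[k]) ** 2 + (cc - cols[k]) ** 2) / (2 * sigma ** 2))
        offsets *= mask
    frames = np.empty((cfg.frames, h, w))
    decay = np.exp(-t / cfg.recovery_time_constant_s)
    for idx in range(cfg.frames):
        frame = base.copy()
        foot_t = cfg.foot_end_temp_c - (
            cfg.foot_end_temp_c - (cfg.foot_start_temp_c + offsets)
        ) * decay[idx]
        frame[mask] = foot_t[mask]
        for ref in cfg.blackbody_references:
            frame[ref.region.slices()] = ref.setpoint_c
        if cfg.noise_sd_c > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sd_c, size=frame.shape)
        frames[idx] = frame
    return PhantomSequence(frames=frames, mask=mask, timestamps_s=t, config=cfg)


def frames_to_radiometric(
    seq: PhantomSequence, gain_counts_per_c: float = 800.0, offset_counts: float = 20000.0,
    bit_depth: int = 16,
) -> list[RadiometricFrame]:
    """Encode temperatures as integer sensor counts under a linear camera law.

    ``counts = round(gain * T + offset)``, clipped to the ADC range — the
    generating law the two-point calibration should invert exactly.
    """
    out = []
    top = 2 ** bit_depth - 1
    for frame in seq.frames:
        counts = np.clip(np.round(gain_counts_per_c * frame + offset_counts), 0, top)
        out.append(RadiometricFrame(counts.astype(np.uint16), bit_depth=bit_depth))
    return out


def split_sequences(n_sequences: int, fractions: tuple[float, float, float] = (0.85, 0.05, 0.10)
                    ) -> tuple[list[int], list[int], list[int]]:
    """Deterministic train/val/test split by sequence index.

    Train and validation take the floors of their fractions (at least one
    sequence each when possible); test receives the remainder.  Splitting by
    sequence, never by frame, prevents near-duplicate leakage between
    buckets: consecutive frames differ only by slow rewarming and noise.
    """
    if n_sequences < 3:
        raise ValueError("need at least 3 sequences for a 3-way split")
    n_train = min(max(1, int(np.floor(fractions[0] * n_sequences))), n_sequences - 2)
    n_val = min(max(1, int(np.floor(fractions[1] * n_sequences))), n_sequences - n_train - 1)
    idx = list(range(n_sequences))
    return idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:]


def _windowed_cropped(seq: PhantomSequence, t: int, window: WindowSpec
                      ) -> tuple[GrayscaleImage, np.ndarray]:
    gray = temperature_to_grayscale(seq.temperature_map(t), window)
    regions = list(seq.config.blackbody_regions)
    cropped = crop_calibration_targets(gray, regions)
    # the mask undergoes the identical crop
    mask_img = GrayscaleImage(seq.mask.astype(np.float64))
    mask_c = crop_calibration_targets(mask_img, regions)
    return cropped, mask_c.values > 0.5


def sample_frames(
    seq: PhantomSequence, stride: int = 10, window: WindowSpec = WindowSpec()
) -> tuple[list[GrayscaleImage], list[np.ndarray], list[int]]:
    """Window, crop and subsample a sequence (one frame in every ``stride``)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    images, masks, indices = [], [], []
    for t in range(0, len(seq), stride):
        img, m = _windowed_cropped(seq, t, window)
        images.append(img)
        masks.append(m)
        indices.append(t)
    return images, masks, indices


def build_dataset(
    cfg: PhantomConfig,
    n_subjects: int,
    root: str | Path,
    sampling_stride: int = 10,
    flip_augment: bool = True,
    window: WindowSpec = WindowSpec(),
) -> dict:
    """Generate ``n_subjects`` phantom sequences and write a split dataset.

    Each subject gets an independent noise realization (seed offset by
    subject index).  Frames are windowed to grayscale, cropped free of
    calibration targets, subsampled one-in-``stride``, optionally doubled by
    horizontal flipping (train bucket only), and written as 8-bit PNG
    image/mask pairs under ``root/{train,val,test}``.  Returns the manifest,
    which is also written to ``root/manifest.json``.
    """
    import imageio.v3 as iio

    root = Path(root)
    train_idx, val_idx, test_idx = split_sequences(n_subjects)
    buckets = {"train": train_idx, "val": val_idx, "test": test_idx}
    manifest: dict = {
        "seed": cfg.seed,
        "stride": sampling_stride,
        "flip_augment": flip_augment,
        "window": {"center_c": window.center_c, "width_c": window.width_c},
        "splits": {k: list(v) for k, v in buckets.items()},
        "records": [],
    }
    for bucket, indices in buckets.items():
        img_dir = root / bucket / "images"
        msk_dir = root / bucket / "masks"
        img_dir.mkdir(parents=True, exist_ok=True)
        msk_dir.mkdir(parents=True, exist_ok=True)
        for subject in indices:
            sub_cfg = replace(cfg, seed=cfg.seed + subject)
            seq = simulate_recovery(sub_cfg)
            images, masks, frame_ids = sample_frames(seq, sampling_stride, window)
            for img, m, fid in zip(images, masks, frame_ids):
                variants = [("", img.values, m)]
                if flip_augment:
                    variants.append(("_flip", img.values[:, ::-1], m[:, ::-1]))
                for tag, arr, mm in variants:
                    stem = f"s{subject:03d}_f{fid:05d}{tag}"
                    iio.imwrite(img_dir / f"{stem}.png", np.round(arr * 255).astype(np.uint8))
                    write_mask(msk_dir / f"{stem}.png", mm)
                    manifest["records"].append(
                        {"bucket": bucket, "subject": subject, "frame": fid,
                         "flipped": tag == "_flip", "stem": stem}
                    )
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
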