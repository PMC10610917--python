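"""Deep-supervision loss and evaluation metrics.

The training objective is a weighted sum of binary cross-entropies, one per
supervised side output plus one for the fused output:

    L = sum_m w_side[m] * e_side[m] + w_fuse * e_fuse

with each term the pixel-summed BCE between a sigmoid saliency map P_S and a
binary ground-truth mask P_G:

    e = - sum_{r,c} [ P_G log P_S + (1 - P_G) log(1 - P_S) ].

Segmentation quality is reported as Dice (DSC), intersection-over-union (IOU)
and Hausdorff distance between mask boundaries; enhancement quality as
256-bin Shannon entropy, MSE and PSNR on the 8-bit intensity scale.

The Hausdorff distance is exposed both raw (Euclidean pixels) and as a
normalized complement ``1 - HD / diag`` in [0, 1] with higher better, a
convenient score for tables that mix it with DSC/IOU.  The normalization is a
package convention, not a standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "LossWeights",
    "MetricReport",
    "bce",
    "total_loss",
    "dsc",
    "iou",
    "hd",
    "boundary_points",
    "entropy",
    "mse",
    "psnr",
    "evaluate_masks",
    "BCE_EPS",
]

#: Probability clip inside the BCE so log(0) never occurs.
BCE_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Per-side-output weights plus the fusion weight; all >= 0, not all 0."""

    w_side: tuple[float, ...]
    w_fuse: float = 1.0

    def __post_init__(self) -> None:
        ws = tuple(float(w) for w in self.w_side)
        if any(w < 0 for w in ws) or self.w_fuse < 0:
            raise ValueError("loss weights must be non-negative")
        if all(w == 0 for w in ws) and self.w_fuse == 0:
            raise ValueError("at least one loss weight must be positive")
        object.__setattr__(self, "w_side", ws)

    @classmethod
    def uniform(cls, n_side: int) -> "LossWeights":
        return cls(w_side=(1.0,) * n_side, w_fuse=1.0)


@dataclass(frozen=True)
class MetricReport:
    """One row of a segmentation/enhancement metric table."""

    dsc: float
    iou: float
    hd_raw: float
    hd_normalized: float


def _check_pair(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return p, g


def bce(p_s: np.ndarray, p_g: np.ndarray, eps: float = BCE_EPS) -> float:
    """Pixel-summed binary cross-entropy between a saliency map and a mask."""
    p, g = _check_pair(p_s, p_g)
    if not np.isin(np.unique(g), (0.0, 1.0)).all():
        raise ValueError("ground-truth mask must be binary")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.sum(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)))


def total_loss(
    side_maps: Sequence[np.ndarray],
    fused_map: np.ndarray,
    p_g: np.ndarray,
    weights: LossWeights | None = None,
) -> float:
    """Weighted deep-supervision loss over side maps plus the fused map."""
    if weights is None:
        weights = LossWeights.uniform(len(side_maps))
    if len(weights.w_side) != len(side_maps):
        raise ValueError(
            f"{len(weights.w_side)} side weights for {len(side_maps)} side maps"
        )
    loss = weights.w_fuse * bce(fused_map, p_g)
    for w, m in zip(weights.w_side, side_maps):
        loss += w * bce(m, p_g)
    return float(loss)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary")
        m = m.astype(bool)
    return m


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); two empty masks score 1."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B|; two empty masks score 1."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """(n, 2) row/col coordinates of boundary pixels (mask minus its erosion).

    Isolated pixels and one-pixel-thin structures are their own boundary.
    """
    m = _as_bool(mask)
    eroded = ndimage.binary_erosion(m, structure=np.ones((3, 3)), border_value=0)
    return np.argwhere(m & ~eroded).astype(np.float64)


def hd(a: np.ndarray, b: np.ndarray, normalized: bool = False) -> float:
    """Hausdorff distance between the boundaries of two non-empty masks.

    Raw mode returns ``max(sup_a inf_b d, sup_b inf_a d)`` in Euclidean
    pixels.  Normalized mode returns ``1 - HD / diag`` clipped to [0, 1],
    where ``diag`` is the image diagonal, so identical masks score 1.
    """
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    if not a.any() or not b.any():
        raise ValueError("Hausdorff distance undefined for an empty mask")
    pa, pb = boundary_points(a), boundary_points(b)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    raw = float(max(d_ab, d_ba))
    if not normalized:
        return raw
    diag = float(np.hypot(a.shape[0], a.shape[1]))
    return float(np.clip(1.0 - raw / diag, 0.0, 1.0))


def entropy(img: np.ndarray, n_bins: int = 256) -> float:
    """Shannon entropy (bits) of the intensity histogram over [0, 1]."""
    v = np.asarray(img, dtype=np.float64).ravel()
    if v.min() < 0 or v.max() > 1:
        raise ValueError("intensities must lie in [0, 1]")
    counts, _ = np.histogram(v, bins=n_bins, range=(0.0, 1.0))
    p = counts[counts > 0] / v.size
    return float(-np.sum(p * np.log2(p)) + 0.0)  # +0.0 normalizes -0.0


def mse(img: np.ndarray, ref: np.ndarray) -> float:
    """Mean squared error on the 8-bit (0-255) intensity scale."""
    a, b = _check_pair(img, ref)
    return float(np.mean((a * 255.0 - b * 255.0) ** 2))


def psnr(img: np.ndarray, ref: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB against a 255 peak; inf for MSE = 0."""
    err = mse(img, ref)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(255.0 ** 2 / err))


def evaluate_masks(pred: np.ndarray, truth: np.ndarray) -> MetricReport:
    """DSC/IOU/HD report for one predicted-vs-reference mask pair."""
    raw = hd(pred, truth, normalized=False)
    norm = hd(pred, truth, normalized=True)
    return MetricReport(dsc=dsc(pred, truth), iou=iou(pred, truth), hd_raw=raw, hd_normalized=norm)
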