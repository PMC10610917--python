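"""Two-stage adaptive gamma contrast enhancement for windowed thermograms.

Thermal sequences recorded while feet rewarm from a cold stress drift from
near-zero contrast (foot colder than or equal to the background) to strong
contrast (foot well above the background).  A single fixed tone curve cannot
serve both ends of that drift.  The transform implemented here picks a
power-law exponent per image from two statistics of the empirical intensity
CDF:

* ``x0`` — the intensity at which the CDF reaches 0.5 (the median),
* ``x1`` — the intensity at which the CDF reaches 0.75 (the upper quartile),

and the contrast ratio ``beta = (x1 - x0) / x0``.  Images with ``beta <= 1``
(flat histogram around the median; typically early, dark frames) are pushed
through a brightening branch, images with ``beta > 1`` (bright foot on a dark
background; late frames) through its reciprocal, compressing branch:

    beta <= 1:  gamma = 0.5 + x0        if x0 <= 0.5
                gamma = 1 / (1.5 - x0)  if x0 >  0.5
    beta  > 1:  gamma = 1 / (0.5 + x0)  if x0 <= 0.5
                gamma = 1.5 - x0        if x0 >  0.5

Both branches meet continuously at gamma = 1 when x0 = 0.5, and the two
regimes are exact reciprocals of each other at every x0.  The enhanced image
is ``v ** gamma`` pixelwise.

Baseline enhancers (fixed gamma, histogram equalization, and the one-regime
"adaptive" variant that always uses the beta <= 1 branch) are provided for
comparison harnesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import exposure

__all__ = [
    "GrayscaleImage",
    "CdfProfile",
    "GammaParams",
    "compute_cdf",
    "quantile_points",
    "compute_beta",
    "compute_gamma",
    "apply_gamma",
    "enhance_two_stage",
    "adaptive_gamma",
    "fixed_gamma",
    "histogram_equalization",
    "BETA_EPS",
    "DEFAULT_N_BINS",
]

#: Floor on the denominator of beta; guards all-black frames where x0 = 0.
BETA_EPS = 1e-6

#: Default number of uniform intensity bins for the empirical CDF.
DEFAULT_N_BINS = 256


@dataclass(frozen=True)
class GrayscaleImage:
    """A single-channel intensity field with values in [0, 1].

    Parameters
    ----------
    values
        2-D float array, every entry finite and inside [0, 1].
    provenance
        Either ``"raw-windowed"`` (straight out of the temperature window)
        or ``"enhanced"`` (after a contrast transform).
    """

    values: np.ndarray
    provenance: str = "raw-windowed"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("GrayscaleImage requires a non-empty 2-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("GrayscaleImage values must be finite")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("GrayscaleImage values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class CdfProfile:
    """Empirical intensity CDF sampled at uniform bin upper edges."""

    support: np.ndarray  # bin upper edges in (0, 1]
    cdf: np.ndarray      # P(value <= edge), non-decreasing, ends at 1

    def __post_init__(self) -> None:
        s = np.asarray(self.support, dtype=np.float64)
        c = np.asarray(self.cdf, dtype=np.float64)
        if s.shape != c.shape or s.ndim != 1 or s.size == 0:
            raise ValueError("support and cdf must be matching 1-D arrays")
        if np.any(np.diff(c) < -1e-12):
            raise ValueError("cdf must be non-decreasing")
        if not np.isclose(c[-1], 1.0):
            raise ValueError("cdf must reach 1 at the top of the support")
        object.__setattr__(self, "support", s)
        object.__setattr__(self, "cdf", c)


@dataclass(frozen=True)
class GammaParams:
    """Per-image statistics driving the adaptive transform."""

    x0: float
    x1: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x0 <= self.x1 <= 1.0 + 1e-12):
            raise ValueError("require 0 <= x0 <= x1 <= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def compute_cdf(img: GrayscaleImage, n_bins: int = DEFAULT_N_BINS) -> CdfProfile:
    """Empirical CDF of the image over ``n_bins`` uniform bins on [0, 1].

    The CDF is evaluated at bin upper edges: entry ``k`` equals
    ``count(values <= edge_k) / N`` (values sitting exactly on an interior
    edge are counted with the bin below, matching a right-closed reading).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    v = img.values.ravel()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # side="right" makes interior edges right-closed; the final bin picks up
    # the value 1.0 exactly.
    counts = np.searchsorted(np.sort(v), edges[1:], side="right")
    cdf = counts / v.size
    return CdfProfile(support=edges[1:], cdf=cdf)


def _quantile(profile: CdfProfile, q: float) -> float:
    """Smallest support value whose CDF reaches ``q`` (step rule).

    The step rule reproduces data values exactly when they coincide with a
    bin edge (e.g. a constant 0.5 image yields x0 = 0.5 and hence gamma = 1);
    any intensity is recovered to within one bin width.
    """
    c = profile.cdf
    s = profile.support
    k = int(np.searchsorted(c, q, side="left"))
    if k >= c.size:
        return float(s[-1])
    return float(s[k])


def quantile_points(profile: CdfProfile) -> tuple[float, float]:
    """(x0, x1): intensities where the CDF reaches 0.5 and 0.75."""
    x0 = _quantile(profile, 0.5)
    x1 = _quantile(profile, 0.75)
    if x1 < x0:  # can only happen through float round-off on flat CDFs
        x1 = x0
    return x0, x1


def compute_beta(x0: float, x1: float, eps: float = BETA_EPS) -> float:
    """Contrast ratio ``beta = (x1 - x0) / x0`` with an epsilon-floored denominator."""
    if x0 < 0 or x1 < x0:
        raise ValueError("require 0 <= x0 <= x1")
    return (x1 - x0) / max(x0, eps)


def compute_gamma(x0: float, beta: float) -> float:
    """Regime-dependent exponent; see the module docstring for the branches."""
    if not 0.0 <= x0 <= 1.0:
        raise ValueError("x0 must lie in [0, 1]")
    if beta <= 1.0:
        g = 0.5 + x0 if x0 <= 0.5 else 1.0 / (1.5 - x0)
    else:
        g = 1.0 / (0.5 + x0) if x0 <= 0.5 else 1.5 - x0
    return float(g)


def apply_gamma(img: GrayscaleImage, gamma: float) -> GrayscaleImage:
    """Pixelwise power law ``v ** gamma``; maps [0, 1] onto [0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    out = np.clip(np.power(img.values, gamma), 0.0, 1.0)
    return GrayscaleImage(out, provenance="enhanced")


def enhance_two_stage(
    img: GrayscaleImage, n_bins: int = DEFAULT_N_BINS
) -> tuple[GrayscaleImage, GammaParams]:
    """Full adaptive enhancement: CDF -> (x0, x1) -> beta -> gamma -> power law.

    Returns the enhanced image together with the per-image parameters, so a
    caller can log which regime each frame selected.
    """
    profile = compute_cdf(img, n_bins=n_bins)
    x0, x1 = quantile_points(profile)
    beta = compute_beta(x0, x1)
    gamma = compute_gamma(x0, beta)
    return apply_gamma(img, gamma), GammaParams(x0=x0, x1=min(x1, 1.0), beta=beta, gamma=gamma)


def adaptive_gamma(
    img: GrayscaleImage, n_bins: int = DEFAULT_N_BINS
) -> tuple[GrayscaleImage, GammaParams]:
    """One-regime baseline: always use the ``beta <= 1`` branch of the exponent.

    Kept for the enhancement-comparison harness; it ignores the measured beta
    when picking the branch (beta is still reported).
    """
    profile = compute_cdf(img, n_bins=n_bins)
    x0, x1 = quantile_points(profile)
    beta = compute_beta(x0, x1)
    gamma = 0.5 + x0 if x0 <= 0.5 else 1.0 / (1.5 - x0)
    return apply_gamma(img, gamma), GammaParams(x0=x0, x1=min(x1, 1.0), beta=beta, gamma=float(gamma))


def fixed_gamma(img: GrayscaleImage, gamma: float = 0.8) -> GrayscaleImage:
    """Constant-exponent baseline (``gamma=1`` is the identity)."""
    return apply_gamma(img, gamma)


def histogram_equalization(img: GrayscaleImage, n_bins: int = DEFAULT_N_BINS) -> GrayscaleImage:
    """Classical histogram equalization baseline (CDF remapping to [0, 1])."""
    out = exposure.equalize_hist(img.values, nbins=n_bins)
    return GrayscaleImage(np.clip(out, 0.0, 1.0), provenance="enhanced")
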