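"""Per-pixel perceptual descriptors: differential excitation, LBP^riu2,
the DE-LBP joint histogram, and the Weber-thresholded local ternary
pattern (WB-LTP) with its adaptive threshold, channel histograms and
entropies.

Differential excitation (DE) follows Weber's law: the perceptually
relevant quantity is the *relative* intensity change around a pixel,

    DE(x_c) = arctan( sum_i (x_i - x_c) / x_c ),

summed over the 8 neighbours of a 3x3 window.  The arctan compresses the
unbounded ratio into [-pi/2, pi/2].  LBP^riu2 is the rotation-invariant
uniform local binary pattern; WB-LTP is a local ternary pattern whose
three-way threshold tests relative contrast (g_i - g_c)/g_c against an
adaptive threshold t derived from the mean DE of the image.

All descriptors are computed only where the full neighbourhood exists:
output maps shrink by the neighbourhood margin on each side (no padding,
which would fabricate texture statistics at the border).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import DimensionError, ParameterError, PreconditionError

__all__ = [
    "LTPChannels",
    "WeberThreshold",
    "compute_de_map",
    "compute_lbp_map",
    "joint_de_lbp_histogram",
    "weber_threshold",
    "compute_wb_ltp",
    "channel_histogram",
    "pattern_entropy",
]

# grid neighbours of a 3x3 window in circular (counter-clockwise) order,
# used for R=1, P=8 instead of interpolated circle samples
_GRID8 = ((0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1))


@dataclass(frozen=True)
class LTPChannels:
    """Up / low / magnitude channels of a (WB-)LTP decomposition.

    ``up`` and ``low`` are binary-weighted pattern codes in [0, 2**P - 1];
    ``magnitude`` is sqrt(up**2 + low**2), hence pointwise >= both.
    """

    up: np.ndarray
    low: np.ndarray
    magnitude: np.ndarray


@dataclass(frozen=True)
class WeberThreshold:
    """Adaptive relative-contrast threshold t = tan(mean |DE|) / 256 and
    its per-scale values t_s = t / 2**s."""

    t: float
    t_s: tuple[float, ...]

    def for_scale(self, s: int) -> float:
        return self.t_s[s]


def _as_image(image: np.ndarray, margin: int) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise DimensionError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if min(img.shape) < 2 * margin + 1:
        raise DimensionError(
            f"image of shape {img.shape} smaller than the {2 * margin + 1}x"
            f"{2 * margin + 1} neighbourhood"
        )
    if not np.all(np.isfinite(img)):
        raise PreconditionError("image contains non-finite intensities")
    return img


def _neighbor_stack(img: np.ndarray, p: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (neighbours, centers): a (P, H-2m, W-2m) stack of circular
    neighbour samples and the matching interior center pixels.

    For the canonical R=1, P=8 case the 8 grid neighbours are used
    directly; otherwise samples are taken at angles 2*pi*i/P on the
    circle of radius R via bilinear interpolation.
    """
    m = int(math.ceil(r))
    h, w = img.shape
    centers = img[m : h - m, m : w - m]
    if p == 8 and r == 1:
        stack = np.stack(
            [img[m + dr : h - m + dr, m + dc : w - m + dc] for dr, dc in _GRID8]
        )
        return stack, centers
    rows, cols = np.mgrid[m : h - m, m : w - m].astype(np.float64)
    samples = []
    for i in range(p):
        theta = 2.0 * math.pi * i / p
        rr = rows - r * math.sin(theta)
        cc = cols + r * math.cos(theta)
        samples.append(ndimage.map_coordinates(img, [rr, cc], order=1, mode="nearest"))
    return np.stack(samples), centers


def compute_de_map(image: np.ndarray, p: int = 8) -> np.ndarray:
    """Differential-excitation map over the 3x3 (p=8) neighbourhood.

    Returns arctan(sum_i (x_i - x_c) / x_c) for every interior pixel;
    values lie in [-pi/2, pi/2] and the map is invariant to multiplying
    all intensities by a positive constant.  Zero-valued center pixels
    are rejected (apply a +1 intensity offset first, as the feature
    pipeline does).
    """
    if p != 8:
        raise ParameterError("differential excitation is defined on the 3x3 "
                             "8-neighbourhood (p=8)")
    img = _as_image(image, margin=1)
    stack, centers = _neighbor_stack(img, 8, 1)
    if np.any(centers <= 0):
        raise PreconditionError(
            "zero or negative center intensities: apply the +1 offset before "
            "computing differential excitation"
        )
    return np.arctan((stack - centers).sum(axis=0) / centers)


def compute_lbp_map(image: np.ndarray, p: int = 8, r: float = 1) -> np.ndarray:
    """Rotation-invariant uniform LBP (riu2) code map.

    Each interior pixel gets the number of neighbours >= center when the
    circular bit string is uniform (at most two 0<->1 transitions), and
    the overflow code P+1 otherwise; codes are integers in {0, ..., P+1}.
    """
    if p < 4:
        raise ParameterError(f"need at least 4 circular neighbours, got P={p}")
    if r <= 0:
        raise ParameterError(f"radius must be positive, got R={r}")
    img = _as_image(image, margin=int(math.ceil(r)))
    if r >= min(img.shape) / 2:
        raise DimensionError(f"radius {r} too large for image of shape {img.shape}")
    stack, centers = _neighbor_stack(img, p, r)
    bits = (stack >= centers)
    transitions = (bits != np.roll(bits, 1, axis=0)).sum(axis=0)
    codes = np.where(transitions <= 2, bits.sum(axis=0), p + 1)
    return codes.astype(np.int64)


def joint_de_lbp_histogram(
    lbp: np.ndarray, de: np.ndarray, m: int = 10, n: int = 10
) -> np.ndarray:
    """Joint relative-frequency histogram H(m, n) of LBP codes and
    absolute DE values.

    The LBP axis has ``m`` bins (one per code, 0..m-1); |DE| is split
    into ``n`` equal-width bins over [0, pi/2].  Entries are fractions
    of pixels and sum to 1.  Returned as an (m, n) array; flatten
    row-major for the feature block.
    """
    lbp = np.asarray(lbp)
    de = np.asarray(de)
    if lbp.shape != de.shape:
        raise DimensionError(
            f"LBP map {lbp.shape} and DE map {de.shape} are not aligned"
        )
    if lbp.size == 0:
        raise DimensionError("empty descriptor maps")
    if m < 2 or n < 2:
        raise ParameterError("histogram needs at least 2 bins per axis")
    de_bins = np.clip(
        (np.abs(de) / (math.pi / 2) * n).astype(np.int64), 0, n - 1
    )
    codes = np.clip(lbp, 0, m - 1)
    flat = codes.ravel() * n + de_bins.ravel()
    hist = np.bincount(flat, minlength=m * n).astype(np.float64)
    return (hist / hist.sum()).reshape(m, n)


def weber_threshold(de: np.ndarray, n_scales: int = 3) -> WeberThreshold:
    """Adaptive Weber threshold t = tan(mean |DE|) / 256.

    The mean absolute differential excitation is the average variation
    intensity of the image; tan() maps it back from angle space to a
    relative-contrast ratio and 1/256 rescales it to the working range
    of the ternary threshold test.  Per-scale thresholds halve per
    downsampling step: t_s = t / 2**s.
    """
    de = np.asarray(de, dtype=np.float64)
    if de.size == 0:
        raise DimensionError("empty DE map")
    t = math.tan(float(np.mean(np.abs(de)))) / 256.0
    return WeberThreshold(t=t, t_s=tuple(t / 2.0**s for s in range(n_scales)))


def compute_wb_ltp(
    image: np.ndarray, t: float, p: int = 8, r: float = 1
) -> LTPChannels:
    """Weber-thresholded local ternary pattern channels.

    Each neighbour is coded +1 / 0 / -1 by comparing the relative
    contrast (g_i - g_c)/g_c against +-t (ties |ratio| == t code 0).
    The +1 codes are binary-weighted into the up channel, the -1 codes
    into the low channel, and magnitude = sqrt(up**2 + low**2).
    Center intensities must be positive (apply the +1 offset first).
    """
    tval = float(t.t if isinstance(t, WeberThreshold) else t)
    if tval < 0:
        raise ParameterError(f"threshold must be non-negative, got {tval}")
    if p < 4 or p > 24:
        raise ParameterError(f"unsupported neighbour count P={p}")
    img = _as_image(image, margin=int(math.ceil(r)))
    stack, centers = _neighbor_stack(img, p, r)
    if np.any(centers <= 0):
        raise PreconditionError(
            "zero or negative center intensities: apply the +1 offset before "
            "the relative-contrast threshold test"
        )
    ratio = (stack - centers) / centers
    weights = (1 << np.arange(p, dtype=np.int64)).reshape(-1, 1, 1)
    up = ((ratio > tval) * weights).sum(axis=0)
    low = ((ratio < -tval) * weights).sum(axis=0)
    magnitude = np.sqrt(up.astype(np.float64) ** 2 + low.astype(np.float64) ** 2)
    return LTPChannels(up=up, low=low, magnitude=magnitude)


def channel_histogram(
    channel: np.ndarray,
    n_bins: int = 15,
    value_range: tuple[float, float] = (0.0, 255.0),
) -> np.ndarray:
    """Equal-width relative-frequency histogram of a pattern channel.

    The range defaults to the full theoretical range of an 8-bit pattern
    code; the magnitude channel uses (0, 255*sqrt(2)).  Entries sum to 1.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.size == 0:
        raise DimensionError("empty channel")
    if n_bins < 2:
        raise ParameterError(f"need at least 2 bins, got {n_bins}")
    counts, _ = np.histogram(channel, bins=n_bins, range=value_range)
    return counts / channel.size


def pattern_entropy(channel: np.ndarray) -> float:
    """Shannon entropy (bits) of the discrete level distribution of a
    pattern channel: E = -sum_i p_i log2 p_i with 0*log0 := 0.

    Non-integer channels (the magnitude) are rounded to the nearest
    integer level first.  E is 0 iff the channel is constant and at most
    log2(#levels) (8 bits for 256-level channels).
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise DimensionError("empty channel")
    levels = np.rint(channel).astype(np.int64).ravel()
    if np.any(levels < 0):
        raise PreconditionError("pattern channel has negative levels")
    counts = np.bincount(levels)
    p = counts[counts > 0] / levels.size
    return float(-(p * np.log2(p)).sum())
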