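"""Feature pipeline: inscribed-square cropping of the circular field of
view, 3-scale pyramid, per-scale DE-LBP (100-dim) and WB-LTP (48-dim)
feature blocks, batch extraction, and a scikit-learn transformer.

The per-scale layout is fixed and frozen for model portability:

    [100 DE-LBP joint-histogram entries |
     15 up-channel histogram | 15 low-channel histogram |
     15 magnitude-channel histogram |
     E_up | E_low | E_mag]                              (148 entries)

repeated for scales s = 0 (original), 1, 2 (each 2x2-mean downsampled
from the previous), for 444 entries at the default configuration.  The
adaptive Weber threshold t is computed once on the original-scale crop
and divided by 2**s per scale.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

try:  # sklearn is a hard dependency of the package, soft here for import order
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    BaseEstimator = object

    class TransformerMixin:  # type: ignore[no-redef]
        pass

from . import descriptors
from .exceptions import (
    DataError,
    DimensionError,
    UnusableImageError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CircularFOVImage",
    "ScaleConfig",
    "CEIQAFeatureExtractor",
    "crop_inscribed_square",
    "downsample",
    "extract_features",
    "extract_batch",
    "load_image",
    "detect_circle",
]


@dataclass(frozen=True)
class CircularFOVImage:
    """A raster whose valid imaging region is a circle (the fiber-bundle
    field of view); pixels outside the circle are black."""

    pixels: np.ndarray
    circle_center: tuple[float, float]  # (row, col)
    circle_radius: float

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise DimensionError(f"expected 2-D pixels, got shape {px.shape}")
        cy, cx = self.circle_center
        h, w = px.shape
        r = self.circle_radius
        if cy - r < -0.5 or cx - r < -0.5 or cy + r > h - 0.5 or cx + r > w - 0.5:
            raise DimensionError(
                f"circle (center=({cy}, {cx}), r={r}) does not fit in the "
                f"{h}x{w} raster"
            )


@dataclass(frozen=True)
class ScaleConfig:
    """Descriptor and layout parameters of the feature extractor.

    P, R: LBP / WB-LTP neighbourhood; M, N: joint-histogram bins
    (M defaults to P+2, the riu2 code count); n_bins: WB-LTP channel
    histogram bins; n_scales: pyramid depth.
    """

    n_scales: int = 3
    p: int = 8
    r: float = 1
    m: int | None = None
    n: int = 10
    n_bins: int = 15

    @property
    def m_eff(self) -> int:
        return self.m if self.m is not None else self.p + 2

    @property
    def feature_length(self) -> int:
        return self.n_scales * (self.m_eff * self.n + 3 * self.n_bins + 3)

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for s in range(self.n_scales):
            names += [f"s{s}_delbp_{i:03d}" for i in range(self.m_eff * self.n)]
            for ch in ("up", "low", "mag"):
                names += [f"s{s}_{ch}_{i:02d}" for i in range(self.n_bins)]
            names += [f"s{s}_E_up", f"s{s}_E_low", f"s{s}_E_mag"]
        return names

    def fingerprint(self) -> str:
        """Stable hash of the feature layout; embedded in trained models
        so that a model refuses features laid out differently."""
        key = "|".join(self.feature_names()).encode()
        return "ceiqa-v1:" + hashlib.sha256(key).hexdigest()[:16]


def detect_circle(pixels: np.ndarray, threshold: float = 2.0) -> tuple[tuple[float, float], float]:
    """Estimate the circular FOV from the near-black surround: the
    largest circle inscribed in the bounding box of above-threshold
    pixels.  Falls back to the full centered circle when nothing is
    below threshold (no visible mask)."""
    px = np.asarray(pixels)
    h, w = px.shape
    mask = px > threshold
    if not mask.any():
        raise UnusableImageError("image is entirely below the FOV threshold")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    cy = (rows[0] + rows[-1]) / 2.0
    cx = (cols[0] + cols[-1]) / 2.0
    radius = min(rows[-1] - rows[0], cols[-1] - cols[0]) / 2.0 + 0.5
    radius = min(radius, h / 2.0, w / 2.0)
    return (cy, cx), radius


def load_image(path, auto_detect_fov: bool = True) -> CircularFOVImage:
    """Read an 8-bit PNG/TIFF/JPEG as a circular-FOV grayscale image.

    Multi-channel inputs are averaged to one channel.  The FOV circle is
    auto-detected from the black surround by default; otherwise the
    largest centered circle is assumed.
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise DimensionError(f"cannot interpret {path} as a grayscale image")
    h, w = arr.shape
    if auto_detect_fov:
        center, radius = detect_circle(arr)
    else:
        center, radius = ((h - 1) / 2.0, (w - 1) / 2.0), min(h, w) / 2.0
    radius = min(radius, (h - 1) / 2.0, (w - 1) / 2.0)
    return CircularFOVImage(pixels=arr, circle_center=center, circle_radius=radius)


def crop_inscribed_square(image: CircularFOVImage, min_side: int = 3) -> np.ndarray:
    """Axis-aligned square of side floor(radius * sqrt(2)) centered on
    the circle center — the largest square fully inside the valid FOV,
    so no black mask pixels contaminate the texture statistics."""
    side = int(math.floor(image.circle_radius * math.sqrt(2.0)))
    if side < min_side:
        raise UnusableImageError(
            f"FOV radius {image.circle_radius} yields a {side}-pixel square, "
            f"smaller than the minimum usable side {min_side}"
        )
    cy, cx = image.circle_center
    r0 = int(round(cy - (side - 1) / 2.0))
    c0 = int(round(cx - (side - 1) / 2.0))
    h, w = image.pixels.shape
    r0 = min(max(r0, 0), h - side)
    c0 = min(max(c0, 0), w - side)
    return np.asarray(image.pixels[r0 : r0 + side, c0 : c0 + side], dtype=np.float64)


def downsample(image: np.ndarray) -> np.ndarray:
    """Halve both dimensions by 2x2 mean pooling (alias-suppressing,
    parameter-free); a trailing odd row/column is dropped."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 2:
        raise DimensionError(f"cannot downsample image of shape {img.shape}")
    h2, w2 = img.shape[0] // 2, img.shape[1] // 2
    blocks = img[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2)
    return blocks.mean(axis=(1, 3))


def _scale_features(img: np.ndarray, t_s: float, config: ScaleConfig) -> np.ndarray:
    """148-entry feature block of one pyramid level (default config)."""
    de = descriptors.compute_de_map(img)
    lbp = descriptors.compute_lbp_map(img, p=config.p, r=config.r)
    if lbp.shape != de.shape:  # R > 1: center-crop the DE map to match
        dr = (de.shape[0] - lbp.shape[0]) // 2
        dc = (de.shape[1] - lbp.shape[1]) // 2
        de = de[dr : dr + lbp.shape[0], dc : dc + lbp.shape[1]]
    joint = descriptors.joint_de_lbp_histogram(lbp, de, m=config.m_eff, n=config.n)
    ltp = descriptors.compute_wb_ltp(img, t_s, p=config.p, r=config.r)
    max_code = float(2**config.p - 1)
    h_up = descriptors.channel_histogram(ltp.up, config.n_bins, (0.0, max_code))
    h_low = descriptors.channel_histogram(ltp.low, config.n_bins, (0.0, max_code))
    h_mag = descriptors.channel_histogram(
        ltp.magnitude, config.n_bins, (0.0, max_code * math.sqrt(2.0))
    )
    entropies = [
        descriptors.pattern_entropy(ltp.up),
        descriptors.pattern_entropy(ltp.low),
        descriptors.pattern_entropy(ltp.magnitude),
    ]
    return np.concatenate([joint.ravel(), h_up, h_low, h_mag, entropies])


def extract_features(
    image: CircularFOVImage | np.ndarray, config: ScaleConfig | None = None
) -> np.ndarray:
    """Full multi-scale CEIQA feature vector of one image (444-dim at
    the default configuration).

    The inscribed square is cropped, a +1 intensity offset is applied
    once (removing zero-division instability in both the DE ratio and
    the ternary threshold test), the Weber threshold t is computed on
    the original-scale crop, and each pyramid level contributes its
    DE-LBP and WB-LTP block with threshold t / 2**s.
    """
    config = config or ScaleConfig()
    if isinstance(image, CircularFOVImage):
        crop = crop_inscribed_square(image, min_side=2 * int(math.ceil(config.r)) + 1)
    else:
        crop = np.asarray(image, dtype=np.float64)
    crop = crop + 1.0  # global Weber offset
    t = descriptors.weber_threshold(
        descriptors.compute_de_map(crop), n_scales=config.n_scales
    )
    blocks = []
    level = crop
    for s in range(config.n_scales):
        if s > 0:
            level = downsample(level)
        blocks.append(_scale_features(level, t.for_scale(s), config))
    vec = np.concatenate(blocks)
    if not np.all(np.isfinite(vec)):
        raise DataError("non-finite feature values produced")
    if vec.shape[0] != config.feature_length:
        raise DataError(
            f"internal layout error: {vec.shape[0]} != {config.feature_length}"
        )
    return vec


def extract_batch(
    manifest: pd.DataFrame | str | Path,
    config: ScaleConfig | None = None,
    images: dict | None = None,
    auto_detect_fov: bool = True,
) -> pd.DataFrame:
    """Extract one feature row per manifest entry.

    ``manifest`` is a DataFrame (or CSV path) with an ``image_path``
    column and optional ``mos`` / metadata columns, which are carried
    through.  ``images`` may map paths/ids to in-memory
    ``CircularFOVImage`` objects, bypassing file I/O.  Unreadable rows
    are logged and skipped; a batch where every row failed raises.
    """
    config = config or ScaleConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, comment="#")
    if "image_path" not in manifest.columns:
        raise DataError("manifest needs an 'image_path' column")
    names = config.feature_names()
    rows, kept = [], []
    for idx, rec in manifest.iterrows():
        key = rec["image_path"]
        try:
            if images is not None and key in images:
                img = images[key]
            else:
                img = load_image(key, auto_detect_fov=auto_detect_fov)
            rows.append(extract_features(img, config))
            kept.append(idx)
        except Exception as exc:  # noqa: BLE001 - row-level robustness
            logger.warning("feature extraction failed for %s: %s", key, exc)
    if not rows:
        raise DataError("feature extraction failed for every manifest row")
    feats = pd.DataFrame(np.vstack(rows), columns=names, index=kept)
    out = pd.concat([manifest.loc[kept].reset_index(drop=True),
                     feats.reset_index(drop=True)], axis=1)
    return out


class CEIQAFeatureExtractor(TransformerMixin, BaseEstimator):
    """scikit-learn transformer computing CEIQA feature vectors.

    Stateless (``fit`` only validates); ``transform`` maps a sequence of
    ``CircularFOVImage`` objects, 2-D arrays (pre-cropped squares) or
    image paths to an (n_samples, 444) feature matrix at the default
    parameters.

    Parameters mirror :class:`ScaleConfig`.
    """

    def __init__(self, n_scales: int = 3, p: int = 8, r: float = 1,
                 m: int | None = None, n: int = 10, n_bins: int = 15):
        self.n_scales = n_scales
        self.p = p
        self.r = r
        self.m = m
        self.n = n
        self.n_bins = n_bins

    def _config(self) -> ScaleConfig:
        return ScaleConfig(n_scales=self.n_scales, p=self.p, r=self.r,
                           m=self.m, n=self.n, n_bins=self.n_bins)

    def fit(self, X=None, y=None):
        cfg = self._config()
        self.config_ = cfg
        self.n_features_out_ = cfg.feature_length
        self.fingerprint_ = cfg.fingerprint()
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "config_"):
            self.fit()
        cfg = self.config_
        rows = []
        for item in X:
            if isinstance(item, (str, Path)):
                item = load_image(item)
            rows.append(extract_features(item, cfg))
        return np.vstack(rows) if rows else np.empty((0, cfg.feature_length))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self._config().feature_names(), dtype=object)
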