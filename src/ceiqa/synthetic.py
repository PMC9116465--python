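"""Synthetic circular-FOV confocal-endoscopy phantoms with graded
distortions and pseudo-MOS labels.

A phantom is a field of soft-edged elliptical blobs (a crude stand-in
for cell bodies and glands at confocal-endoscope resolution) rendered
inside a centered circular field of view with a black surround, exactly
like fiber-bundle endoscope frames.  Distortion ladders — defocus blur,
motion blur, additive Gaussian noise, contrast compression, or a mixed
cascade — degrade a phantom at increasing severity in [0, 1], and each
distorted image receives a pseudo mean-opinion score

    MOS = clip(5 - 4 * severity + N(0, 0.25^2), 1, 5),

a linear perceptual scale with small simulated inter-rater noise.  No
biological-realism claim is made; the texture is rich enough to give
LBP and differential-excitation statistics non-trivial structure, which
is all the descriptor pipeline needs for end-to-end testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ParameterError
from .features import CircularFOVImage

__all__ = [
    "PhantomSpec",
    "DistortionSpec",
    "SyntheticDataset",
    "DISTORTION_KINDS",
    "generate_phantom",
    "apply_distortion",
    "generate_dataset",
]

DISTORTION_KINDS = (
    "defocus_blur",
    "motion_blur",
    "gaussian_noise",
    "contrast_compression",
    "mixed",
)

# pseudo-MOS observer noise (simulates averaging over 8 raters)
MOS_NOISE_STD = 0.25


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the cell-blob texture phantom.

    blob_density is blobs per 1000 pixels of disk area; radii are drawn
    uniformly from radius_range (pixels); blob amplitudes from
    amplitude_range on the 8-bit scale, with dark_fraction of blobs
    subtracted instead of added (nucleus-like dark cores).
    """

    size: int = 256
    fov_radius_fraction: float = 0.95
    blob_density: float = 1.2
    radius_range: tuple[float, float] = (3.0, 12.0)
    amplitude_range: tuple[float, float] = (40.0, 160.0)
    dark_fraction: float = 0.3
    background: float = 40.0
    seed: int = 0


@dataclass(frozen=True)
class DistortionSpec:
    """One distortion kind at a severity in [0, 1]; severity 0 is the
    identity.  Kind-specific strengths scale linearly with severity:
    blur sigma up to 4 px, motion length up to 15 px, noise sigma up to
    25 gray levels, contrast gain down to 0.2."""

    kind: str
    severity: float
    max_blur_sigma: float = 4.0
    max_motion_length: int = 15
    motion_angle_deg: float = 30.0
    max_noise_sigma: float = 25.0
    max_contrast_loss: float = 0.8

    def __post_init__(self):
        if self.kind not in DISTORTION_KINDS:
            raise ParameterError(
                f"unknown distortion kind {self.kind!r}; "
                f"choose from {DISTORTION_KINDS}"
            )
        if not 0.0 <= self.severity <= 1.0:
            raise ParameterError(f"severity must be in [0, 1], got {self.severity}")


@dataclass
class SyntheticDataset:
    """Images plus manifest rows (image_path, mos, phantom, kind,
    severity, ladder); images are kept in memory keyed by image_path
    and optionally written to out_dir as 8-bit PNGs."""

    manifest: pd.DataFrame
    images: dict[str, CircularFOVImage]
    seed: int
    out_dir: Path | None = None


def _fov_geometry(size: int, fraction: float) -> tuple[tuple[float, float], float]:
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    return center, fraction * size / 2.0


def _fov_mask(size: int, center, radius) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def generate_phantom(spec: PhantomSpec) -> CircularFOVImage:
    """Render a deterministic cell-blob phantom inside a circular FOV."""
    if spec.size < 64:
        raise ParameterError(f"phantom size must be >= 64, got {spec.size}")
    if not 0 < spec.fov_radius_fraction <= 1:
        raise ParameterError("fov_radius_fraction must be in (0, 1]")
    rng = np.random.default_rng(spec.seed)
    center, radius = _fov_geometry(spec.size, spec.fov_radius_fraction)
    img = np.full((spec.size, spec.size), spec.background, dtype=np.float64)
    area = math.pi * radius**2
    n_blobs = rng.poisson(spec.blob_density * area / 1000.0)
    yy, xx = np.mgrid[0 : spec.size, 0 : spec.size].astype(np.float64)
    for _ in range(n_blobs):
        # rejection-free placement: uniform in the disk
        rho = radius * math.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * math.pi)
        by = center[0] + rho * math.sin(phi)
        bx = center[1] + rho * math.cos(phi)
        a = rng.uniform(*spec.radius_range)
        b = a * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0.0, math.pi)
        amp = rng.uniform(*spec.amplitude_range)
        if rng.uniform() < spec.dark_fraction:
            amp = -amp * 0.6
        dy, dx = yy - by, xx - bx
        u = math.cos(theta) * dx + math.sin(theta) * dy
        v = -math.sin(theta) * dx + math.cos(theta) * dy
        d2 = (u / a) ** 2 + (v / b) ** 2
        img += amp * np.exp(-(d2**2))  # quartic falloff: soft-edged plateau
    img = np.clip(img, 0.0, 255.0)
    img[~_fov_mask(spec.size, center, radius)] = 0.0
    return CircularFOVImage(
        pixels=np.rint(img).astype(np.float64),
        circle_center=center,
        circle_radius=radius,
    )


def _motion_kernel(length: int, angle_deg: float) -> np.ndarray:
    """Normalized line kernel of given pixel length and orientation."""
    size = length if length % 2 == 1 else length + 1
    kern = np.zeros((size, size))
    c = size // 2
    ang = math.radians(angle_deg)
    for i in np.linspace(-(length - 1) / 2.0, (length - 1) / 2.0, 4 * length):
        r = int(round(c + i * math.sin(ang)))
        col = int(round(c + i * math.cos(ang)))
        kern[r, col] = 1.0
    return kern / kern.sum()


def apply_distortion(
    image: CircularFOVImage, spec: DistortionSpec, seed: int = 0
) -> CircularFOVImage:
    """Degrade a phantom at the given severity; the FOV mask is
    re-applied afterwards so the surround stays black."""
    if spec.severity == 0.0:
        return CircularFOVImage(image.pixels.copy(), image.circle_center,
                                image.circle_radius)
    rng = np.random.default_rng(seed)
    px = np.asarray(image.pixels, dtype=np.float64)
    size = px.shape[0]
    mask = _fov_mask(size, image.circle_center, image.circle_radius)

    def blur(arr, s):
        return ndimage.gaussian_filter(arr, sigma=spec.max_blur_sigma * s)

    def motion(arr, s):
        length = 1 + int(round((spec.max_motion_length - 1) * s))
        if length < 2:
            return arr
        return ndimage.convolve(arr, _motion_kernel(length, spec.motion_angle_deg),
                                mode="nearest")

    def noise(arr, s):
        return arr + rng.normal(0.0, spec.max_noise_sigma * s, arr.shape)

    def contrast(arr, s):
        mu = arr[mask].mean()
        out = arr.copy()
        out[mask] = mu + (arr[mask] - mu) * (1.0 - spec.max_contrast_loss * s)
        return out

    s = spec.severity
    if spec.kind == "defocus_blur":
        px = blur(px, s)
    elif spec.kind == "motion_blur":
        px = motion(px, s)
    elif spec.kind == "gaussian_noise":
        px = noise(px, s)
    elif spec.kind == "contrast_compression":
        px = contrast(px, s)
    else:  # mixed: blur -> noise -> contrast cascade; fixed component
        # fractions keep the effective degradation monotone in severity
        px = contrast(noise(blur(px, 0.7 * s), 0.5 * s), 0.6 * s)
    px = np.clip(np.rint(px), 0.0, 255.0)
    px[~mask] = 0.0
    return CircularFOVImage(px, image.circle_center, image.circle_radius)


def generate_dataset(
    n_phantoms: int,
    severities=(0.0, 0.25, 0.5, 0.75, 1.0),
    kinds=DISTORTION_KINDS,
    seed: int = 0,
    out_dir=None,
    factorial: bool = False,
    phantom_spec: PhantomSpec | None = None,
    std_filter: float | None = None,
) -> SyntheticDataset:
    """Build a labeled synthetic quality dataset.

    Each phantom contributes one severity ladder per distortion kind
    when ``factorial`` is true, otherwise one ladder with kinds cycling
    across phantoms.  Pseudo-MOS is linear in severity with seeded
    observer noise, clipped to [1, 5].  With ``std_filter`` set, items
    whose simulated 8-rater score STD exceeds the cutoff are dropped
    (mirroring subjective-experiment screening).  Images are written as
    PNGs when ``out_dir`` is given and always kept in memory.
    """
    if n_phantoms < 1:
        raise ParameterError("need at least one phantom")
    severities = [float(s) for s in severities]
    kinds = list(kinds)
    base = phantom_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    rows, images = [], {}
    for i in range(n_phantoms):
        pspec = PhantomSpec(**{**base.__dict__, "seed": int(rng.integers(2**31))})
        phantom = generate_phantom(pspec)
        ladder_kinds = kinds if factorial else [kinds[i % len(kinds)]]
        for kind in ladder_kinds:
            ladder = f"p{i:03d}_{kind}"
            for sev in severities:
                dist = apply_distortion(
                    phantom, DistortionSpec(kind=kind, severity=sev),
                    seed=int(rng.integers(2**31)),
                )
                rater_scores = np.clip(
                    5.0 - 4.0 * sev
                    + rng.normal(0.0, MOS_NOISE_STD * math.sqrt(8.0), size=8),
                    1.0, 5.0,
                )
                if std_filter is not None and rater_scores.std(ddof=0) > std_filter:
                    continue
                mos = float(np.clip(rater_scores.mean(), 1.0, 5.0))
                name = f"{ladder}_s{sev:.2f}.png"
                key = str(out_path / name) if out_path is not None else name
                images[key] = dist
                rows.append({
                    "image_path": key, "mos": mos, "phantom": i,
                    "kind": kind, "severity": sev, "ladder": ladder,
                })
                if out_path is not None:
                    import imageio.v3 as iio

                    iio.imwrite(key, dist.pixels.astype(np.uint8))
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return SyntheticDataset(manifest=manifest, images=images, seed=seed,
                            out_dir=out_path)
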