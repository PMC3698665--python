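"""Synthetic micrograph-like grayscale images for testing and calibration.

Real TEM micrographs of cytoplasm are not bundled with the package, so the
pipeline is exercised on synthetic stand-ins: thresholded Gaussian random
fields with a controllable black fraction and spatial correlation length,
remapped to two well-separated intensity modes with additive noise.  These
reproduce the second-order statistics the downstream volume generator
consumes; they make no attempt at organelle morphology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging import GrayImage

__all__ = ["FixtureSpec", "make_tem_like", "make_noisy_and_smooth_pair", "save_fixture_set"]

#: Intensity modes of the two phases on an 8-bit scale: dark (object) and
#: bright (background), well separated for the isodata threshold.
DARK_MODE = 50.0
BRIGHT_MODE = 200.0


@dataclass
class FixtureSpec:
    """Parameters of a synthetic image set.

    target_blackness is the black (object) fraction after thresholding —
    cytoplasmic TEM data motivates the default 0.3755; corr_length_px is the
    Gaussian smoothing scale of the underlying random field in pixels.
    """

    target_blackness: float = 0.3755
    corr_length_px: float = 6.0
    size: int = 300
    n_images: int = 5
    noise_sd: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_blackness < 1.0:
            raise ValueError("target_blackness must lie strictly in (0, 1)")
        if self.corr_length_px < 1:
            raise ValueError("corr_length_px must be >= 1")
        if self.size < 4:
            raise ValueError("size must be >= 4")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _binary_field(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """Correlated {0,1} field with black fraction == target (by quantile)."""
    field = rng.standard_normal((spec.size, spec.size))
    field = ndimage.gaussian_filter(field, sigma=spec.corr_length_px, mode="wrap")
    cut = np.quantile(field, spec.target_blackness)
    return (field <= cut).astype(np.uint8)


def make_tem_like(spec: FixtureSpec) -> list[GrayImage]:
    """Generate seed-deterministic TEM-like grayscale images.

    The binary phase field is mapped to intensities DARK_MODE (object) and
    BRIGHT_MODE (background), plus Gaussian noise of scale ``noise_sd``,
    clipped to [0, 255].  Binarizing the result with the isodata threshold
    recovers ``target_blackness`` to within about +/-0.01.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_images):
        binary = _binary_field(spec, rng)
        gray = np.where(binary == 1, DARK_MODE, BRIGHT_MODE)
        if spec.noise_sd > 0:
            gray = gray + rng.normal(0.0, spec.noise_sd, gray.shape)
        gray = np.clip(gray, 0.0, 255.0)
        out.append(GrayImage(gray))
    return out


def make_noisy_and_smooth_pair(spec: FixtureSpec) -> tuple[list[GrayImage], list[GrayImage]]:
    """Raw images and their median-filtered (3x3) counterparts.

    Emulates the contrast between a frayed structure from a noisy,
    thresholded micrograph and the same structure after denoising: the
    filtered set loses most isolated single-pixel objects while keeping the
    black fraction nearly unchanged.
    """
    raw = make_tem_like(spec)
    smooth = [
        GrayImage(ndimage.median_filter(im.pixels, size=3, mode="reflect"))
        for im in raw
    ]
    return raw, smooth


def save_fixture_set(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write images as a multipage TIFF plus a JSON manifest; returns the TIFF path."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    imgs = make_tem_like(spec)
    stack = np.stack([im.pixels for im in imgs]).astype(np.float32)
    tif_path = out_dir / "fixtures.tif"
    tifffile.imwrite(tif_path, stack, photometric="minisblack")
    manifest = {"spec": asdict(spec), "n_pages": len(imgs)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return tif_path
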