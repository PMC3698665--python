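"""Binarization of micrograph-like grayscale images and neighbor statistics.

Electron micrographs of cytoplasm show electron-dense material (ribosomes,
membranes, cytoskeleton — collectively "non-reactive obstacles", NRO) as dark
pixels on a lighter background.  This module turns such grayscale images into
binary object/background masks with the iterative isodata threshold and then
learns the short-range directional statistics of the binary texture:

* ``cond3`` — the probability that a pixel is black given the states of its
  three predecessors along a scan line, for each of the 8 predecessor
  patterns;
* ``pairgap`` — the probability that a pixel is black given the states of two
  flanking pixels at distance ``j`` on either side, for each gap ``j`` and
  each of the 4 flank patterns;
* ``blackness`` — the mean fraction of black pixels.

These statistics are everything the 3D volume generator needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GrayImage",
    "BinaryImage",
    "NeighborStats",
    "isodata_threshold",
    "binarize",
    "learn_stats",
    "load_images",
]

#: Predecessor patterns (p1, p2, p3) = states of pixels i-1, i-2, i-3,
#: encoded as the integer p1*4 + p2*2 + p3 and keyed "p1p2p3" in JSON.
N_COND3 = 8
#: Flank patterns (left, right) encoded left*2 + right.
N_PAIR = 4


class DegenerateImageError(ValueError):
    """Raised when an image has fewer than two distinct intensities."""


@dataclass
class GrayImage:
    """A 2D grayscale image with non-negative, finite intensities."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2D")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ValueError("image must be at least 2x2 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("image intensities must be non-negative")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryImage:
    """A 2D {0,1} mask; 1 marks black/object (NRO) pixels."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2D")
        if not np.isin(self.pixels, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")

    @property
    def blackness(self) -> float:
        """Fraction of black (1) pixels; by construction the exact pixel mean."""
        return float(self.pixels.mean())


@dataclass
class NeighborStats:
    """Learned directional statistics of a binary texture.

    ``cond3[k]`` is P(pixel black | predecessors p1,p2,p3) with
    k = p1*4 + p2*2 + p3 (p1 the immediate predecessor).  ``pairgap[j][m]``
    is P(pixel black | flank at -j is l, flank at +j is r) with m = l*2 + r.
    Raw observation counts are kept so that unobserved patterns can be
    flagged and so the tables can be re-marginalized consistently.
    """

    cond3: np.ndarray                      # shape (8,)
    pairgap: dict[int, np.ndarray]         # gap j -> shape (4,)
    blackness: float
    cond3_counts: np.ndarray = field(default=None)        # (8,) windows seen
    cond3_black: np.ndarray = field(default=None)         # (8,) black outcomes
    pairgap_counts: dict[int, np.ndarray] = field(default=None)
    missing_cond3: tuple[int, ...] = ()
    missing_pairgap: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cond3 = np.asarray(self.cond3, dtype=float)
        if self.cond3.shape != (N_COND3,):
            raise ValueError("cond3 must have 8 entries")
        if np.any((self.cond3 < 0) | (self.cond3 > 1)):
            raise ValueError("cond3 probabilities must lie in [0, 1]")
        if not 0.0 <= self.blackness <= 1.0:
            raise ValueError("blackness must lie in [0, 1]")
        for j, tab in self.pairgap.items():
            tab = np.asarray(tab, dtype=float)
            if tab.shape != (N_PAIR,) or np.any((tab < 0) | (tab > 1)):
                raise ValueError(f"pairgap[{j}] must be 4 probabilities in [0,1]")
            self.pairgap[j] = tab

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "blackness": self.blackness,
            "cond3": {format(k, "03b"): float(self.cond3[k]) for k in range(N_COND3)},
            "pairgap": {
                str(j): {format(m, "02b"): float(tab[m]) for m in range(N_PAIR)}
                for j, tab in sorted(self.pairgap.items())
            },
            "missing_cond3": [format(k, "03b") for k in self.missing_cond3],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NeighborStats":
        doc = json.loads(text)
        cond3 = np.zeros(N_COND3)
        for key, p in doc["cond3"].items():
            cond3[int(key, 2)] = p
        pairgap = {}
        for j, tab in doc["pairgap"].items():
            arr = np.zeros(N_PAIR)
            for key, p in tab.items():
                arr[int(key, 2)] = p
            pairgap[int(j)] = arr
        missing = tuple(int(k, 2) for k in doc.get("missing_cond3", []))
        return cls(cond3=cond3, pairgap=pairgap,
                   blackness=doc["blackness"], missing_cond3=missing)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "NeighborStats":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Isodata threshold (iterative intermeans)
# ---------------------------------------------------------------------------

def isodata_threshold(img: GrayImage | np.ndarray) -> float:
    """Iterative isodata threshold.

    The threshold T splits the pixels into a dark class (<= T) and a bright
    class (> T); T starts at the minimum intensity and is incremented until
    it first exceeds the composite average (mean of the two class means),
    which is the isodata fixed point.  The increment is 1 intensity unit for
    integer-valued data and 1/256 of the intensity range otherwise,
    mirroring histogram-bin stepping on 8-bit images.

    Raises
    ------
    DegenerateImageError
        If the image has fewer than two distinct intensity values.
    """
    pix = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    pix = np.sort(pix.astype(float).ravel())
    if pix.size == 0:
        raise DegenerateImageError("empty image")
    lo, hi = float(pix[0]), float(pix[-1])
    if lo == hi:
        raise DegenerateImageError("constant image has no threshold")

    values_integral = np.allclose(pix, np.round(pix))
    step = 1.0 if values_integral and hi - lo >= 2.0 else (hi - lo) / 256.0
    start = np.floor(lo) if step == 1.0 else lo

    # Candidate thresholds on the increment grid, excluding those at or past
    # the maximum (there the bright class is empty).
    cand = start + step * np.arange(int(np.ceil((hi - start) / step)) + 1)
    cand = cand[cand < hi]
    # Class means for every candidate at once via prefix sums.
    csum = np.concatenate(([0.0], np.cumsum(pix)))
    total = csum[-1]
    n_dark = np.searchsorted(pix, cand, side="right")
    valid = n_dark > 0
    cand, n_dark = cand[valid], n_dark[valid]
    mean_dark = csum[n_dark] / n_dark
    mean_bright = (total - csum[n_dark]) / (pix.size - n_dark)
    composite = (mean_dark + mean_bright) / 2.0
    hit = np.flatnonzero(cand > composite)
    if hit.size == 0:
        # No crossing below the maximum: threshold just under the top class.
        return float(cand[-1] + step)
    return float(cand[hit[0]])


def binarize(img: GrayImage | np.ndarray, dark_is_object: bool = True) -> BinaryImage:
    """Binarize a grayscale image at its isodata threshold.

    With ``dark_is_object`` (the default, appropriate for TEM where
    electron-dense material is dark), pixels strictly below the threshold
    become 1.
    """
    pix = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    t = isodata_threshold(pix)
    mask = pix < t
    if not dark_is_object:
        mask = ~mask
    return BinaryImage(mask.astype(np.uint8))


# ---------------------------------------------------------------------------
# Neighbor statistics
# ---------------------------------------------------------------------------

def _scan_lines(pixels: np.ndarray) -> Iterable[np.ndarray]:
    """Yield every scan line in all four axis-aligned directions.

    Rows left-to-right and right-to-left, columns top-to-bottom and
    bottom-to-top; the volume generator draws lines along lattice axes, so
    diagonal directions are not collected.
    """
    for row in pixels:
        yield row
        yield row[::-1]
    for col in pixels.T:
        yield col
        yield col[::-1]


def _accumulate_cond3(line: np.ndarray, black: np.ndarray, total: np.ndarray) -> None:
    if line.size < 4:
        return
    # pattern index of pixel i uses predecessors i-1, i-2, i-3
    p1, p2, p3 = line[2:-1], line[1:-2], line[:-3]
    idx = p1.astype(np.int64) * 4 + p2 * 2 + p3
    out = line[3:]
    np.add.at(total, idx, 1)
    np.add.at(black, idx, out)


def _accumulate_pairgap(line: np.ndarray, j: int,
                        black: np.ndarray, total: np.ndarray) -> None:
    if line.size < 2 * j + 1:
        return
    left = line[: -2 * j]
    mid = line[j: -j]
    right = line[2 * j:]
    idx = left.astype(np.int64) * 2 + right
    np.add.at(total, idx, 1)
    np.add.at(black, idx, mid)


def learn_stats(imgs: Sequence[BinaryImage | np.ndarray], max_gap: int = 8) -> NeighborStats:
    """Learn ``cond3``/``pairgap``/``blackness`` from binary images.

    Length-4 windows are collected along both axes in both scan orders and
    pooled; pair statistics are collected for gaps j = 1..max_gap.  A
    conditioning pattern that is never observed is flagged missing and its
    probability falls back to the pooled blackness.
    """
    if len(imgs) == 0:
        raise ValueError("need at least one image")
    arrays = []
    for im in imgs:
        a = im.pixels if isinstance(im, BinaryImage) else np.asarray(im)
        a = a.astype(np.int64)
        if min(a.shape) <= max_gap + 2:
            raise ValueError(
                f"image of shape {a.shape} too small for max_gap={max_gap}")
        arrays.append(a)

    c3_black = np.zeros(N_COND3)
    c3_total = np.zeros(N_COND3)
    pg_black = {j: np.zeros(N_PAIR) for j in range(1, max_gap + 1)}
    pg_total = {j: np.zeros(N_PAIR) for j in range(1, max_gap + 1)}
    n_black = 0
    n_pix = 0

    for a in arrays:
        n_black += int(a.sum())
        n_pix += a.size
        for line in _scan_lines(a):
            _accumulate_cond3(line, c3_black, c3_total)
            for j in range(1, max_gap + 1):
                _accumulate_pairgap(line, j, pg_black[j], pg_total[j])

    blackness = n_black / n_pix

    missing_c3 = tuple(int(k) for k in np.flatnonzero(c3_total == 0))
    cond3 = np.where(c3_total > 0, c3_black / np.maximum(c3_total, 1), blackness)

    pairgap = {}
    missing_pg: dict[int, tuple[int, ...]] = {}
    for j in range(1, max_gap + 1):
        miss = tuple(int(m) for m in np.flatnonzero(pg_total[j] == 0))
        if miss:
            missing_pg[j] = miss
        pairgap[j] = np.where(pg_total[j] > 0,
                              pg_black[j] / np.maximum(pg_total[j], 1), blackness)

    return NeighborStats(
        cond3=cond3, pairgap=pairgap, blackness=blackness,
        cond3_counts=c3_total, cond3_black=c3_black,
        pairgap_counts=pg_total,
        missing_cond3=missing_c3, missing_pairgap=missing_pg,
    )


# ---------------------------------------------------------------------------
# Image file I/O
# ---------------------------------------------------------------------------

def load_images(path: str | Path) -> list[GrayImage]:
    """Read grayscale images from a TIFF/PNG file, multipage TIFF or directory."""
    import tifffile

    path = Path(path)
    out: list[GrayImage] = []
    if path.is_dir():
        for p in sorted(path.iterdir()):
            if p.suffix.lower() in {".tif", ".tiff", ".png"}:
                out.extend(load_images(p))
        if not out:
            raise FileNotFoundError(f"no TIFF/PNG images in {path}")
        return out
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        for page in data:
            out.append(GrayImage(page))
    elif path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("I"))
        out.append(GrayImage(arr))
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    return out
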