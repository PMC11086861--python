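"""Brightness normalization, nucleus detection, and the self-similar
color correlogram (SSCC) feature.

Radiologists judge a disc's nucleus relative to the surrounding
vertebrae, not in absolute intensity, so every image is first offset so
its mean vertebrae intensity matches a dataset reference (default 69):
``gl = gl_orig - (gl_vert - gl_vert_mean)``, clamped to [0, 255].

The bright nucleus pulposus inside each disc is located by shrinking
the disc mask ~20% by erosion and lowering an intensity threshold from
the region maximum until a sufficiently large contiguous bright
component emerges; a further erosion to ~90% area gives the inner
nucleus.  Discs whose nucleus is indistinguishable from the annulus
(severely degenerated, very dark) fall back to the eroded disc mask.

The SSCC feature quantizes intensities into ``n_gl`` bins capped at
``gl_max`` and tabulates, for ordered pixel pairs of the nucleus at
chessboard distance exactly ``d``, the conditional probability that a
pixel of bin i has a bin-j pixel at that distance.  Only the band
|i - j| <= w around the diagonal is kept, giving a vector of length
``N(2w+1) - w(w+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import NormalizationError
from .imaging_io import GreyImage
from .labelmap import _mask_ccrs

#: default dataset-wide reference mean of vertebrae intensity
DEFAULT_VERT_MEAN = 69.0
#: threshold decrement per pass of the nucleus-detection loop
THRESHOLD_STEP = 5.0


@dataclass(frozen=True)
class QuantizerConfig:
    """Greyscale quantization: ``n_gl`` bins, intensities capped at ``gl_max``."""

    n_gl: int = 30
    gl_max: float = 150.0

    def __post_init__(self):
        if self.n_gl <= 0 or self.gl_max <= 0:
            raise ValueError("quantizer parameters must be positive")

    @property
    def delta_gl(self) -> float:
        return self.gl_max / self.n_gl


@dataclass
class NucleusMask:
    mask: np.ndarray
    fallback: bool  # True when the eroded disc stood in for an invisible nucleus


@dataclass
class SSCCFeature:
    values: np.ndarray
    n_colours: int
    w: int
    d: int
    cells: list = field(default_factory=list)  # (i, j) band order of each value


def sscc_length(n_colours: int, w: int) -> int:
    """Feature length for N colours and band half-width w."""
    if n_colours < 1 or w < 0:
        raise ValueError("need N >= 1 and w >= 0")
    return n_colours * (2 * w + 1) - w * (w + 1)


def adjust_brightness(image: GreyImage, vert_mask: np.ndarray,
                      reference_mean: float = DEFAULT_VERT_MEAN) -> GreyImage:
    """Offset the image so its vertebrae mean matches ``reference_mean``."""
    if not np.asarray(vert_mask).any():
        raise NormalizationError("empty vertebrae mask: cannot normalize brightness")
    gl_vert = float(image.pixels[vert_mask].mean())
    adjusted = np.clip(image.pixels - (gl_vert - reference_mean), 0.0, 255.0)
    return GreyImage(adjusted, image.meta)


def estimate_reference_mean(studies) -> float:
    """Dataset reference mean: average of per-study vertebrae means.

    ``studies`` yields (pixels, vert_mask) pairs.
    """
    means = []
    for pixels, vert_mask in studies:
        pixels = np.asarray(pixels, float)
        if not vert_mask.any():
            raise NormalizationError("study with empty vertebrae mask")
        means.append(float(pixels[vert_mask].mean()))
    if not means:
        raise NormalizationError("empty dataset")
    return float(np.mean(means))


def quantize(gl, cfg: QuantizerConfig = QuantizerConfig()) -> np.ndarray:
    """Bin index floor(min(gl, gl_max) / delta_gl), clamped to n_gl - 1.

    The clamp keeps gl == gl_max from opening an extra (n_gl+1)-th bin,
    so exactly N = n_gl colours exist.
    """
    gl = np.asarray(gl, dtype=float)
    idx = np.floor(np.minimum(gl, cfg.gl_max) / cfg.delta_gl).astype(int)
    return np.clip(idx, 0, cfg.n_gl - 1)


def _erode_to_fraction(mask: np.ndarray, fraction: float) -> np.ndarray:
    """Iteratively erode (3x3) until area <= fraction of the original."""
    target = fraction * mask.sum()
    out = mask
    while out.sum() > target:
        nxt = ndimage.binary_erosion(out, structure=np.ones((3, 3), bool))
        if not nxt.any():
            break  # never return an empty nucleus
        out = nxt
    return out


def detect_nucleus(image: GreyImage, ivd_mask: np.ndarray) -> NucleusMask:
    """Locate the inner nucleus of one disc on the adjusted, upscaled image.

    Threshold loop: starting from the region maximum and stepping down
    by 5, accept the first threshold whose bright pixels cover >= 30% of
    the 80%-eroded disc AND whose largest closed component covers
    >= 20% of it; the component eroded to 90% area is the inner nucleus.
    Exhausting the loop flags fallback and returns the eroded disc.
    """
    if not ivd_mask.any():
        raise ValueError("empty IVD mask")
    shrunk = _erode_to_fraction(ivd_mask, 0.80)
    vals = image.pixels[shrunk]
    t = float(vals.max())
    t_min = float(vals.min())
    shrunk_area = shrunk.sum()
    # work in the disc bounding box for speed
    rows, cols = np.nonzero(shrunk)
    pad = 8
    r0, r1 = max(rows.min() - pad, 0), rows.max() + pad + 1
    c0, c1 = max(cols.min() - pad, 0), cols.max() + pad + 1
    img_c = image.pixels[r0:r1, c0:c1]
    shrunk_c = shrunk[r0:r1, c0:c1]
    close_struct = _disk(4)
    while t > t_min:
        t -= THRESHOLD_STEP
        cand = shrunk_c & (img_c > t)
        if cand.sum() < 0.30 * shrunk_area:
            continue
        ccrs = _mask_ccrs(cand)
        if not ccrs:
            continue
        blob = ndimage.binary_closing(ccrs[0].mask, structure=close_struct) & shrunk_c
        if blob.sum() < 0.20 * shrunk_area:
            continue
        inner_c = _erode_to_fraction(blob, 0.90)
        inner = np.zeros_like(ivd_mask)
        inner[r0:r1, c0:c1] = inner_c
        return NucleusMask(mask=inner, fallback=False)
    return NucleusMask(mask=shrunk, fallback=True)


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def _band_cells(n_colours: int, w: int) -> list:
    return [
        (i, j)
        for i in range(n_colours)
        for j in range(max(0, i - w), min(n_colours, i + w + 1))
    ]


def correlogram_matrix(image: GreyImage, mask: np.ndarray, cfg: QuantizerConfig = QuantizerConfig(),
                       d: int = 4) -> np.ndarray:
    """Full N x N correlogram of ordered in-mask pixel pairs at L-inf distance d.

    Entry (i, j) is the probability that a mask pixel of bin i has a
    bin-j mask pixel at chessboard distance exactly d.  Rows with no
    pairs are all-zero; every other row sums to 1.
    """
    if not mask.any():
        raise ValueError("empty mask")
    n = cfg.n_gl
    bins = quantize(image.pixels, cfg)
    counts = np.zeros((n, n), dtype=float)
    offsets = [
        (dr, dc)
        for dr in range(-d, d + 1)
        for dc in range(-d, d + 1)
        if max(abs(dr), abs(dc)) == d
    ]
    nrows, ncols = mask.shape
    for dr, dc in offsets:
        r0a, r1a = max(0, -dr), min(nrows, nrows - dr)
        c0a, c1a = max(0, -dc), min(ncols, ncols - dc)
        src = mask[r0a:r1a, c0a:c1a]
        dst = mask[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
        both = src & dst
        if not both.any():
            continue
        bi = bins[r0a:r1a, c0a:c1a][both]
        bj = bins[r0a + dr : r1a + dr, c0a + dc : c1a + dc][both]
        np.add.at(counts, (bi, bj), 1.0)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_sums > 0, counts / row_sums, 0.0)
    return probs


def sscc(image: GreyImage, mask: NucleusMask | np.ndarray, cfg: QuantizerConfig = QuantizerConfig(),
         w: int = 2, d: int = 4) -> SSCCFeature:
    """Self-similar color correlogram: the |i-j| <= w band, row-major."""
    m = mask.mask if isinstance(mask, NucleusMask) else mask
    probs = correlogram_matrix(image, m, cfg, d)
    cells = _band_cells(cfg.n_gl, w)
    values = np.array([probs[i, j] for i, j in cells])
    assert len(values) == sscc_length(cfg.n_gl, w)
    return SSCCFeature(values=values, n_colours=cfg.n_gl, w=w, d=d, cells=cells)


def extract_ivd_feature(image: GreyImage, vert_mask: np.ndarray, ivd_mask: np.ndarray,
                        cfg: QuantizerConfig = QuantizerConfig(), w: int = 2, d: int = 4,
                        reference_mean: float = DEFAULT_VERT_MEAN):
    """Brightness-adjust, detect the inner nucleus, and extract its SSCC.

    Returns (feature, nucleus_mask).  ``image`` is the x4-upscaled
    smoothed MRI; masks are in the same frame.
    """
    adjusted = adjust_brightness(image, vert_mask, reference_mean)
    nucleus = detect_nucleus(adjusted, ivd_mask)
    feature = sscc(adjusted, nucleus, cfg, w=w, d=d)
    return feature, nucleus
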