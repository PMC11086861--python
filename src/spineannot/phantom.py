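"""Synthetic mid-sagittal phantom studies.

Renders a simplified but topologically faithful lumbar spine: a sacrum
block at the bottom, then alternating disc/vertebra blocks stacked
upward, flanked by anterior and posterior filler regions so the six
region codes tile the frame.  Each disc contains a bright nucleus
ellipse whose mean intensity and texture spread follow its Pfirrmann
grade (grade 1 brightest and most homogeneous); grade-5 discs are
rendered collapsed, below the 3.0 mm height threshold.  Thin dark bands
on the bone side of every disc interface emulate the hypointense
cortical endplates of real T2 anatomy.

Geometric perturbations: per-disc tilt (each disc is a parallelogram
between two parallel interface lines), sinusoidal left-right curvature
of the whole column, and an optional lateral bump on one vertebra that
induces a branch in the thinned centerline.  Global exposure offsets
and additive Gaussian noise emulate acquisition variation.

Every study carries its ground truth: the rasterized height of each
disc (mm, perpendicular to its interfaces), its grade, and its
traversal name.  Generation is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import GreyImage, ImageMeta
from .labelmap import LabelMap, RegionCode
from .spine_topology import IVD_NAMES, VERTEBRA_NAMES

#: per-grade nucleus mean intensity (grade 1 = healthy, bright)
NUCLEUS_MEAN = {1: 160.0, 2: 130.0, 3: 95.0, 4: 60.0, 5: 45.0}
#: per-grade nucleus texture spread (grade 1 = homogeneous).  A collapsed
#: grade-5 disc has lost its nucleus: its residual tissue is uniformly
#: dark with a compressed dynamic range, so its spread is small.
NUCLEUS_SD = {1: 4.0, 2: 8.0, 3: 14.0, 4: 18.0, 5: 6.0}
#: typical disc height (mm) by grade.  Grade 5 is collapsed: it must sit
#: below the 3.0 mm rule threshold by more than the rendering raster
#: (0.73 mm/row) plus the measurement resolution, hence ~2 mm.
GRADE_HEIGHT_MM = {1: 9.0, 2: 8.0, 3: 6.5, 4: 5.0, 5: 1.9}

#: paper-like imbalanced grade distribution (grades 1..5)
IMBALANCED_SHARES = (0.039, 0.649, 0.108, 0.190, 0.014)


@dataclass
class PhantomConfig:
    n_ivds: int = 3
    grades: tuple = (2, 3, 4)
    heights_mm: tuple | None = None  # None: derived from grade (+/- jitter)
    tilt_deg: tuple | None = None  # per-disc interface tilt; None: drawn
    max_tilt_deg: float = 8.0
    curvature_amp_px: float = 5.0
    curvature_period_px: float = 300.0
    bump: bool = False  # lateral bump on a vertebra -> skeleton branch
    exposure_offset: float = 0.0
    noise_sd: float = 2.0
    pixel_spacing: float = 0.7292
    dim: int = 384
    seed: int = 0
    # intensity scheme (8-bit grey levels)
    vertebra_mean: float = 69.0
    vertebra_sd: float = 4.0
    sacrum_mean: float = 60.0
    annulus_mean: float = 40.0
    endplate_mean: float = 26.0
    background_mean: float = 32.0
    background_sd: float = 5.0
    # geometry (pixels at the working scale)
    spine_half_width_px: int = 24
    vertebra_height_px: float = 38.0
    sacrum_top_row: int = 330
    nucleus_width_frac: float = 0.62  # nucleus width / disc width

    def __post_init__(self):
        if not 3 <= self.n_ivds <= 5:
            raise ValueError("n_ivds must be between 3 and 5")
        if len(self.grades) != self.n_ivds:
            raise ValueError("one grade per disc required")
        if any(g not in (1, 2, 3, 4, 5) for g in self.grades):
            raise ValueError("grades must lie in 1..5")
        if self.heights_mm is not None and len(self.heights_mm) != self.n_ivds:
            raise ValueError("one height per disc required")


@dataclass
class PhantomStudy:
    image: GreyImage
    labels: LabelMap
    truth: pd.DataFrame  # columns: ivd_name, height_mm, grade
    config: PhantomConfig
    study_id: str = ""

    @property
    def ivd_names(self) -> list:
        return list(self.truth["ivd_name"])

    @property
    def vertebra_names(self) -> list:
        return list(VERTEBRA_NAMES[: self.config.n_ivds])


def _draw_heights(cfg: PhantomConfig, rng) -> np.ndarray:
    if cfg.heights_mm is not None:
        h = np.asarray(cfg.heights_mm, float)
    else:
        h = np.array([GRADE_HEIGHT_MM[g] for g in cfg.grades])
        h = h + rng.uniform(-0.4, 0.4, size=len(h))
    h = np.where(np.asarray(cfg.grades) == 5, np.clip(h, 1.7, 2.15), np.clip(h, 3.4, 11.0))
    return h


def _draw_tilts(cfg: PhantomConfig, rng) -> np.ndarray:
    if cfg.tilt_deg is not None:
        return np.asarray(cfg.tilt_deg, float)
    return rng.uniform(-cfg.max_tilt_deg, cfg.max_tilt_deg, size=cfg.n_ivds)


def generate(config: PhantomConfig) -> PhantomStudy:
    """Render one seeded phantom study (image + labels + truth table)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, dim = cfg.n_ivds, cfg.dim
    cx = dim // 2
    half_w = cfg.spine_half_width_px
    heights_mm = _draw_heights(cfg, rng)
    tilts = np.radians(_draw_tilts(cfg, rng))
    slopes = np.tan(tilts)
    ps = cfg.pixel_spacing * cfg.dim / 384  # working-frame spacing

    # vertical extent of each disc so its perpendicular height is heights_mm
    h_px = heights_mm / ps / np.cos(tilts)

    # interface rows at the centre column, bottom-up:
    # r[2i] = bottom of disc i, r[2i+1] = top of disc i, r[2i+2] = top of vertebra i
    r = np.empty(2 * n + 1)
    m = np.empty(2 * n + 1)
    r[0] = cfg.sacrum_top_row
    for i in range(n):
        r[2 * i + 1] = r[2 * i] - h_px[i]
        r[2 * i + 2] = r[2 * i + 1] - cfg.vertebra_height_px
        m[2 * i] = m[2 * i + 1] = slopes[i]
    m[2 * n] = 0.0
    if r[2 * n] < 12:
        raise ValueError("stack does not fit the frame: too many or too tall discs")

    labels = np.zeros((dim, dim), dtype=np.int32)
    image = np.zeros((dim, dim), dtype=float)

    # filler strips: anterior left, posterior elements + block right
    texture = ndimage.gaussian_filter(rng.normal(size=(dim, dim)), sigma=2.0)
    texture /= texture.std()
    texture = np.clip(texture, -2.5, 2.5)  # bounded tails keep offsets clamp-free
    noiseless_bg = cfg.background_mean + cfg.background_sd * texture
    labels[:, : cx - half_w] = RegionCode.ANTERIOR
    pb_right = cx + half_w + 28
    labels[:, cx + half_w : pb_right] = RegionCode.POSTERIOR_B
    labels[:, pb_right:] = RegionCode.POSTERIOR_A
    image[:, :] = noiseless_bg

    rows = np.arange(dim)
    nucleus_a = cfg.nucleus_width_frac * half_w  # ellipse semi-width
    endplate_px = 2.0
    spine_cols = range(cx - half_w, cx + half_w)
    for x in spine_cols:
        b = r + m * (x - cx)  # interface rows at this column
        col_lab = labels[:, x]
        col_img = image[:, x]
        # sacrum below the first interface
        sac = rows >= b[0]
        col_lab[sac] = RegionCode.SACRUM
        col_img[sac] = cfg.sacrum_mean + cfg.vertebra_sd * texture[sac, x]
        col_lab[rows < b[2 * n]] = RegionCode.ANTERIOR  # above the stack
        for i in range(n):
            disc = (rows >= b[2 * i + 1]) & (rows < b[2 * i])
            col_lab[disc] = RegionCode.IVD
            col_img[disc] = cfg.annulus_mean + 2.0 * texture[disc, x]
            # nucleus ellipse spans the disc's full height at its centre
            rc = (b[2 * i] + b[2 * i + 1]) / 2.0
            semi_h = h_px[i] / 2.0 + 0.5
            inside = disc & (
                ((x - cx) / nucleus_a) ** 2 + ((rows - rc) / semi_h) ** 2 <= 1.0
            )
            g = cfg.grades[i]
            col_img[inside] = NUCLEUS_MEAN[g] + NUCLEUS_SD[g] * texture[inside, x]
            vert = (rows >= b[2 * i + 2]) & (rows < b[2 * i + 1])
            col_lab[vert] = RegionCode.VERTEBRAE
            col_img[vert] = cfg.vertebra_mean + cfg.vertebra_sd * texture[vert, x]
            # dark endplates on the bone side of both disc interfaces
            ep_below = (rows >= b[2 * i]) & (rows < b[2 * i] + endplate_px)
            ep_above = (rows >= b[2 * i + 1] - endplate_px) & (rows < b[2 * i + 1])
            for ep in (ep_below, ep_above):
                col_img[ep] = cfg.endplate_mean + 1.5 * texture[ep, x]

    # optional lateral bump on the middle vertebra (skeleton branch driver)
    if cfg.bump:
        vi = n // 2
        rc_v = (r[2 * vi + 1] + r[2 * vi + 2]) / 2.0
        bump_r = 9.0
        yy, xx = np.mgrid[0:dim, 0:dim]
        bump_mask = ((yy - rc_v) ** 2 + (xx - (cx + half_w)) ** 2 <= bump_r**2) & (
            xx >= cx + half_w
        )
        labels[bump_mask] = RegionCode.VERTEBRAE
        image[bump_mask] = cfg.vertebra_mean + cfg.vertebra_sd * texture[bump_mask]

    # truth heights from the rasterized geometry, averaged over the
    # middle 30% of spine columns (what the boundary fits will see)
    win = max(3, int(round(0.30 * 2 * half_w)))
    win_cols = range(cx - win // 2, cx - win // 2 + win)
    truth_heights = []
    for i in range(n):
        counts = []
        for x in win_cols:
            b_lo = r[2 * i] + m[2 * i] * (x - cx)
            b_hi = r[2 * i + 1] + m[2 * i + 1] * (x - cx)
            counts.append(((rows >= b_hi) & (rows < b_lo)).sum())
        truth_heights.append(float(np.mean(counts) * np.cos(tilts[i]) * ps))

    # sinusoidal curvature: integer horizontal shift of each row
    if cfg.curvature_amp_px:
        phase = rng.uniform(0, 2 * np.pi)
        shifts = np.round(
            cfg.curvature_amp_px * np.sin(2 * np.pi * rows / cfg.curvature_period_px + phase)
        ).astype(int)
        cols_idx = np.arange(dim)
        for row, s in zip(rows, shifts):
            src = np.clip(cols_idx - s, 0, dim - 1)
            labels[row] = labels[row, src]
            image[row] = image[row, src]

    # recentre the vertebrae region mean onto the configured value, then
    # apply the global exposure offset and acquisition noise
    vmask = labels == RegionCode.VERTEBRAE
    image[vmask] += cfg.vertebra_mean - image[vmask].mean()
    image += cfg.exposure_offset
    if cfg.noise_sd:
        image += rng.normal(0.0, cfg.noise_sd, size=image.shape)
    image = np.clip(image, 0, 255)

    meta = ImageMeta(pixel_spacing_mm=cfg.pixel_spacing, dimension_px=cfg.dim)
    truth = pd.DataFrame(
        {
            "ivd_name": list(IVD_NAMES[:n]),
            "height_mm": truth_heights,
            "grade": list(cfg.grades),
        }
    )
    return PhantomStudy(
        image=GreyImage(image, meta),
        labels=LabelMap(labels, meta),
        truth=truth,
        config=cfg,
        study_id=f"phantom-{cfg.seed}",
    )


def _grade_sequence(n: int, distribution, rng) -> np.ndarray:
    """Per-disc grades for a batch of n discs."""
    if isinstance(distribution, str) and distribution == "balanced":
        base, rem = divmod(n, 5)
        grades = np.concatenate(
            [np.full(base + (1 if g <= rem else 0), g, dtype=int) for g in (1, 2, 3, 4, 5)]
        )
        rng.shuffle(grades)
        return grades
    if isinstance(distribution, str) and distribution == "imbalanced":
        probs = IMBALANCED_SHARES
    else:
        probs = np.asarray(distribution, float)
        probs = probs / probs.sum()
    return rng.choice(np.arange(1, 6), size=n, p=probs)


def generate_batch(n: int, distribution="balanced", seed: int = 0,
                   base_config: PhantomConfig | None = None) -> list:
    """Generate a seeded batch covering ``n`` discs in studies of 3-5.

    ``distribution`` is "balanced", "imbalanced" (the clinical
    3.9/64.9/10.8/19.0/1.4% mix), or an explicit 5-vector of grade
    probabilities.
    """
    if n < 1:
        raise ValueError("need at least one disc")
    rng = np.random.default_rng(seed)
    grades = _grade_sequence(n, distribution, rng)
    if len(grades) < 3:  # a study needs at least 3 discs
        grades = np.concatenate([grades, _grade_sequence(3 - len(grades), distribution, rng)])
    chunks = [grades[i : i + 3] for i in range(0, len(grades), 3)]
    if len(chunks) > 1 and len(chunks[-1]) < 3:
        chunks[-2] = np.concatenate([chunks[-2], chunks[-1]])
        chunks.pop()
    base = base_config if base_config is not None else PhantomConfig()
    studies = []
    for i, chunk in enumerate(chunks):
        cfg = replace(
            base,
            n_ivds=len(chunk),
            grades=tuple(int(g) for g in chunk),
            heights_mm=None,
            tilt_deg=None,
            exposure_offset=float(np.clip(rng.normal(0.0, 8.0), -20, 20)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        study = generate(cfg)
        study.study_id = f"batch-{seed}-{i:04d}"
        studies.append(study)
    return studies
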