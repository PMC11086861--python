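"""Geometric measurement of intervertebral disc height.

Two-phase procedure on a x4-upscaled frame.  Phase one builds a first
estimate of the segment bisecting the disc roughly parallel to the
spine line: the middle 30% of the disc's top and bottom boundary point
sets are averaged (centres C_T, C_B) and fitted with total-least-squares
lines; perpendiculars dropped from each centre onto the opposite fit
line give the projected points C'_T, C'_B, and the segment endpoints
are the midpoints M_T = (C_T + C'_B)/2 and M_B = (C_B + C'_T)/2.

Phase two slides each endpoint along its perpendicular direction to the
pixel with the strongest directed image gradient, scoring each candidate
p on the rasterized search segment by b_p = cos(beta_p - alpha) * m_p,
where (m_p, beta_p) is the Prewitt gradient and alpha the search
direction angle.  On a T2 slice this locks the endpoints onto the
bright-nucleus / endplate edges.  The disc height is the Euclidean
distance between the refined endpoints times the working pixel spacing
divided by the x4 scale factor.

All point coordinates here are (x, y) = (column, row) in the upscaled
frame, y increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import atan2, ceil, cos, degrees, radians

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .imaging_io import GreyImage, ImageMeta
from .labelmap import LabelMap, _STRUCT8

#: upscale factor applied before measuring
SCALE = 4
#: default Gaussian smoothing (original-scale pixels) applied before upscaling
DEFAULT_SIGMA = 0.5
#: default endpoint search range, in upscaled pixels
DEFAULT_K = 8
#: fraction of boundary points kept around the middle
MIDDLE_FRACTION = 0.30


@dataclass
class Line:
    """A 2-D line through ``point`` with unit ``direction`` (x, y)."""

    point: np.ndarray
    direction: np.ndarray


@dataclass
class BisectSegment:
    C_T: np.ndarray
    C_B: np.ndarray
    Cp_T: np.ndarray
    Cp_B: np.ndarray
    v_T: np.ndarray
    v_B: np.ndarray
    M_T: np.ndarray
    M_B: np.ndarray
    Mp_T: np.ndarray | None = None
    Mp_B: np.ndarray | None = None


@dataclass
class GradientField:
    """Per-pixel Prewitt gradient magnitude and direction (degrees)."""

    magnitude: np.ndarray
    direction_deg: np.ndarray  # in (-180, 180]


@dataclass
class HeightResult:
    ivd_name: str
    segment: BisectSegment
    height_mm: float
    search_range_k: int


def wrap_angle_deg(a: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def prepare_images(mri: GreyImage, labels: LabelMap, sigma: float = DEFAULT_SIGMA):
    """Smooth the MRI, then upscale MRI (cubic) and labels (nearest) x4."""
    from skimage.transform import resize

    smoothed = ndimage.gaussian_filter(mri.pixels.astype(float), sigma=sigma)
    n = mri.pixels.shape[0]
    up = resize(smoothed, (n * SCALE, n * SCALE), order=3, preserve_range=True, anti_aliasing=False)
    up = np.clip(up, 0, 255)
    lab_up = resize(
        labels.codes, (n * SCALE, n * SCALE), order=0, preserve_range=True, anti_aliasing=False
    ).astype(labels.codes.dtype)
    return GreyImage(up, mri.meta), LabelMap(lab_up, labels.meta)


def upscale_mask(mask: np.ndarray) -> np.ndarray:
    """Nearest-neighbour x4 upscale of a boolean mask."""
    return np.repeat(np.repeat(mask, SCALE, axis=0), SCALE, axis=1)


def boundary_points(ivd_mask: np.ndarray, above_mask: np.ndarray, below_mask: np.ndarray):
    """Disc pixels on the superior and inferior interfaces.

    Top boundary points are disc pixels 8-adjacent to the superior
    vertebra; bottom points are disc pixels 8-adjacent to the inferior
    structure (sacrum for L5/S1, a vertebra otherwise).  Returned as
    (n, 2) arrays of (x, y).
    """
    out = []
    for other in (above_mask, below_mask):
        touch = ivd_mask & ndimage.binary_dilation(other, structure=_STRUCT8)
        if not touch.any():
            raise GeometryError("empty disc boundary set: disc has no adjacent neighbour structure")
        rows, cols = np.nonzero(touch)
        out.append(np.column_stack([cols, rows]).astype(float))
    return out[0], out[1]


def middle_portion_fit(points: np.ndarray, fraction: float = MIDDLE_FRACTION):
    """Centre point and total-least-squares line of the middle portion.

    Points are sorted by x and the central ``ceil(fraction * n)`` kept;
    their mean coordinate is the centre and the principal axis of their
    scatter the best-fit line.  Orthogonal regression keeps the fit
    stable for steep boundaries, and coincides with ordinary least
    squares for the near-horizontal ones typical of disc interfaces.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 10:
        raise GeometryError(f"need at least 10 boundary points, got {len(points)}")
    order = np.argsort(points[:, 0], kind="stable")
    n_keep = ceil(fraction * len(points))
    lo = (len(points) - n_keep) // 2
    mid = points[order[lo : lo + n_keep]]
    if len(mid) < 3:
        raise GeometryError("fewer than 3 points retained for the middle-portion fit")
    centre = mid.mean(axis=0)
    centred = mid - centre
    # principal axis of the 2x2 scatter matrix = TLS direction
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    direction = direction / np.linalg.norm(direction)
    return centre, Line(point=centre, direction=direction)


def _perpendicular_into(line: Line, toward: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """Unit normal of ``line`` oriented from ``origin`` toward ``toward``."""
    n = np.array([-line.direction[1], line.direction[0]])
    if np.dot(n, toward - origin) < 0:
        n = -n
    return n


def _ray_line_intersection(origin: np.ndarray, direction: np.ndarray, line: Line) -> np.ndarray:
    """Intersection of the ray origin + t*direction with a line."""
    d, e = direction, line.direction
    denom = d[0] * e[1] - d[1] * e[0]
    if abs(denom) < 1e-12:
        raise GeometryError("search ray is parallel to the opposite boundary fit line")
    rhs = line.point - origin
    t = (rhs[0] * e[1] - rhs[1] * e[0]) / denom
    return origin + t * d


def initial_bisect(top_fit: Line, bottom_fit: Line, C_T: np.ndarray, C_B: np.ndarray,
                   ivd_centroid: np.ndarray) -> BisectSegment:
    """First estimate of the bisecting segment from the two boundary fits.

    v_T is the top-line normal pointing into the disc (toward its
    centroid), v_B likewise for the bottom line.  C'_T is the
    intersection of the ray from C_T along v_T with the bottom fit line;
    C'_B symmetrically with the top fit line.  The segment endpoints are
    the midpoints M_T = (C_T + C'_B)/2 and M_B = (C_B + C'_T)/2.
    """
    C_T = np.asarray(C_T, float)
    C_B = np.asarray(C_B, float)
    v_T = _perpendicular_into(top_fit, np.asarray(ivd_centroid, float), C_T)
    v_B = _perpendicular_into(bottom_fit, np.asarray(ivd_centroid, float), C_B)
    Cp_T = _ray_line_intersection(C_T, v_T, bottom_fit)
    Cp_B = _ray_line_intersection(C_B, v_B, top_fit)
    M_T = (C_T + Cp_B) / 2.0
    M_B = (C_B + Cp_T) / 2.0
    return BisectSegment(C_T=C_T, C_B=C_B, Cp_T=Cp_T, Cp_B=Cp_B, v_T=v_T, v_B=v_B, M_T=M_T, M_B=M_B)


def prewitt_field(image: np.ndarray) -> GradientField:
    """3x3 Prewitt gradient magnitude and direction of an image."""
    img = np.asarray(image, dtype=float)
    kx = np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=float)
    ky = kx.T
    # correlate, not convolve: keep the kernel unmirrored so gx ~ dI/dx
    gx = ndimage.correlate(img, kx, mode="nearest")
    gy = ndimage.correlate(img, ky, mode="nearest")
    mag = np.hypot(gx, gy)
    direction = np.degrees(np.arctan2(gy, gx))
    direction[direction <= -180.0] = 180.0
    return GradientField(magnitude=mag, direction_deg=direction)


def refine_endpoint(M: np.ndarray, v: np.ndarray, field: GradientField, k: int = DEFAULT_K) -> np.ndarray:
    """Move an endpoint to the strongest directed gradient along v.

    The search segment runs from A = M - u to B = M + k*u (u the unit
    vector of v), rasterized with Bresenham's algorithm and clipped to
    the image.  Each pixel p scores b_p = cos(beta_p - alpha) * m_p,
    averaged over a 3-pixel probe transverse to u (a real interface is
    transversely coherent, so the probe suppresses texture noise
    without moving the edge); the argmax wins, ties going to the pixel
    closest to M.
    """
    from skimage.draw import line as bresenham

    if k < 1:
        raise ValueError("search range k must be >= 1")
    M = np.asarray(M, float)
    u = np.asarray(v, float)
    u = u / np.linalg.norm(u)
    alpha = degrees(atan2(u[1], u[0]))
    A = M - u
    B = M + k * u
    rr, cc = bresenham(int(round(A[1])), int(round(A[0])), int(round(B[1])), int(round(B[0])))
    nrows, ncols = field.magnitude.shape
    keep = (rr >= 0) & (rr < nrows) & (cc >= 0) & (cc < ncols)
    rr, cc = rr[keep], cc[keep]
    if rr.size == 0:
        raise GeometryError("endpoint search segment lies entirely outside the image")

    def directed(r_idx, c_idx):
        delta = wrap_angle_deg(field.direction_deg[r_idx, c_idx] - alpha)
        return cos(radians(delta)) * field.magnitude[r_idx, c_idx]

    # transverse probe: the unit normal of u, sampled one and two
    # original-scale pixels to each side (4 and 8 upscaled px)
    normal = np.array([-u[1], u[0]])
    scores = np.empty(rr.size)
    for idx, (r_idx, c_idx) in enumerate(zip(rr, cc)):
        vals = [directed(r_idx, c_idx)]
        for step in (-8, -4, 4, 8):
            pc = int(round(c_idx + step * normal[0]))
            pr = int(round(r_idx + step * normal[1]))
            if 0 <= pr < nrows and 0 <= pc < ncols:
                vals.append(directed(pr, pc))
        scores[idx] = float(np.mean(vals))
    best = scores.max()
    cand = np.flatnonzero(scores >= best - 1e-9)
    d2 = (cc[cand] - M[0]) ** 2 + (rr[cand] - M[1]) ** 2
    pick = cand[np.argmin(d2)]
    return np.array([float(cc[pick]), float(rr[pick])])


def measure_height(segment: BisectSegment, meta: ImageMeta, k: int = DEFAULT_K,
                   ivd_name: str = "") -> HeightResult:
    """Disc height in mm from the refined bisecting segment."""
    if segment.Mp_T is None or segment.Mp_B is None:
        raise GeometryError("segment endpoints have not been refined")
    dist = float(np.linalg.norm(segment.Mp_T - segment.Mp_B))
    height = dist * meta.rescaled_spacing_mm / SCALE
    return HeightResult(ivd_name=ivd_name, segment=segment, height_mm=height, search_range_k=k)


def measure_disc_height(field: GradientField, ivd_mask_up: np.ndarray, above_mask_up: np.ndarray,
                        below_mask_up: np.ndarray, meta: ImageMeta, k: int = DEFAULT_K,
                        ivd_name: str = "") -> HeightResult:
    """Run both measurement phases for one disc in the upscaled frame."""
    top_pts, bottom_pts = boundary_points(ivd_mask_up, above_mask_up, below_mask_up)
    C_T, top_fit = middle_portion_fit(top_pts)
    C_B, bottom_fit = middle_portion_fit(bottom_pts)
    rows, cols = np.nonzero(ivd_mask_up)
    centroid = np.array([cols.mean(), rows.mean()])
    seg = initial_bisect(top_fit, bottom_fit, C_T, C_B, centroid)
    # never search past the disc midline: for a collapsed disc a long
    # range would tunnel through to the opposite interface's edge
    half_span = np.linalg.norm(seg.M_T - seg.M_B) / 2.0
    k_eff = int(max(1, min(k, np.floor(half_span) - 1)))
    seg.Mp_T = refine_endpoint(seg.M_T, seg.v_T, field, k_eff)
    seg.Mp_B = refine_endpoint(seg.M_B, seg.v_B, field, k_eff)
    return measure_height(seg, meta, k=k_eff, ivd_name=ivd_name)
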