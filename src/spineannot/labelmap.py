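"""Six-region label maps: validation, post-processing, and segmentation metrics.

A label map partitions a mid-sagittal slice into six anatomical regions:

====  ==========  =======================================================
code  name        anatomy
====  ==========  =======================================================
1     Anterior    everything anterior to the vertebral column
2     PosteriorA  posterior soft tissue block
3     PosteriorB  posterior elements (may be several components)
4     Vertebrae   lumbar vertebral bodies
5     IVD         intervertebral discs
6     Sacrum      topmost sacral bone
====  ==========  =======================================================

Ground-truth maps must satisfy six labelling requirements (single
hole-free Anterior / PosteriorA / Sacrum, hole-free PosteriorB
components, a single hole-free Vertebrae+IVD union, and bottom-up
IVD/vertebra alternation starting with a disc just above the sacrum).
Maps inferred by a segmentation backend are repaired by
:func:`postprocess` to meet the same requirements.

Connectivity convention: foreground components are 8-connected, hole
detection uses the 4-connected background (the standard dual pairing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from math import ceil, hypot

import numpy as np
from scipy import ndimage

from .errors import TopologyError
from .imaging_io import ImageMeta

_STRUCT8 = np.ones((3, 3), dtype=bool)


class RegionCode(IntEnum):
    ANTERIOR = 1
    POSTERIOR_A = 2
    POSTERIOR_B = 3
    VERTEBRAE = 4
    IVD = 5
    SACRUM = 6


@dataclass
class LabelMap:
    """Integer grid of :class:`RegionCode` values with geometry metadata."""

    codes: np.ndarray
    meta: ImageMeta

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.ndim != 2:
            raise ValueError("label map must be 2-D")

    @property
    def shape(self):
        return self.codes.shape

    def mask(self, code: int) -> np.ndarray:
        return self.codes == int(code)

    def copy(self) -> "LabelMap":
        return LabelMap(self.codes.copy(), self.meta)


@dataclass
class CCR:
    """A maximal 8-connected component of one region code."""

    code: int
    mask: np.ndarray
    area_px: int
    bbox: tuple  # (row_min, col_min, row_max, col_max), max exclusive

    @property
    def centroid(self) -> tuple:
        rows, cols = np.nonzero(self.mask)
        return (float(rows.mean()), float(cols.mean()))


@dataclass
class Violation:
    rule: int
    detail: str


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_json(self):
        return [{"rule": v.rule, "detail": v.detail} for v in self.violations]


def find_ccrs(label_map: LabelMap, code: int) -> list:
    """All 8-connected components of ``code``, largest first."""
    return _mask_ccrs(label_map.mask(code), int(code))


def _mask_ccrs(mask: np.ndarray, code: int = 0) -> list:
    lab, n = ndimage.label(mask, structure=_STRUCT8)
    out = []
    for sl, idx in zip(ndimage.find_objects(lab), range(1, n + 1)):
        m = lab == idx
        out.append(
            CCR(
                code=code,
                mask=m,
                area_px=int(m.sum()),
                bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
            )
        )
    out.sort(key=lambda c: -c.area_px)
    return out


def _has_holes(mask: np.ndarray) -> bool:
    return bool(ndimage.binary_fill_holes(mask).sum() > mask.sum())


def fill_holes(ccr: CCR, label_map: LabelMap) -> LabelMap:
    """Reassign the interior holes of ``ccr`` to its own code."""
    filled = ndimage.binary_fill_holes(ccr.mask)
    out = label_map.copy()
    out.codes[filled & ~ccr.mask] = ccr.code
    return out


def _boundary_mode_code(mask: np.ndarray, codes: np.ndarray, exclude=()) -> int:
    """Mode of the codes 8-adjacent to ``mask`` (ties -> smallest code)."""
    ring = ndimage.binary_dilation(mask, structure=_STRUCT8) & ~mask
    vals = codes[ring]
    vals = vals[~np.isin(vals, list(exclude))] if exclude else vals
    if vals.size == 0:
        raise TopologyError("component has no neighbouring region to merge into")
    counts = np.bincount(vals)
    return int(np.flatnonzero(counts == counts.max())[0])


def merge_ccr_into_surrounding(ccr: CCR, label_map: LabelMap, exclude=()) -> LabelMap:
    """Dissolve ``ccr`` into the most frequent code on its outer boundary."""
    target = _boundary_mode_code(ccr.mask, label_map.codes, exclude=exclude)
    out = label_map.copy()
    out.codes[ccr.mask] = target
    return out


def _keep_largest_and_fill(label_map: LabelMap, code: int) -> LabelMap:
    """Post-processing step 1 for one region: keep the largest component,
    merge the rest into their surroundings, then close holes."""
    ccrs = find_ccrs(label_map, code)
    if not ccrs:
        return label_map
    out = label_map
    for small in ccrs[1:]:
        out = merge_ccr_into_surrounding(small, out)
    largest = _mask_ccrs(out.mask(code), code)
    if largest:
        out = fill_holes(largest[0], out)
    return out


def _union_mask(label_map: LabelMap) -> np.ndarray:
    return label_map.mask(RegionCode.VERTEBRAE) | label_map.mask(RegionCode.IVD)


def _fill_union_holes(label_map: LabelMap) -> LabelMap:
    """Close holes in the Vert-IVD union.

    A hole whose pixels see Vertebrae directly above and below is the
    imprint of a missed disc and is filled with IVD; any other hole is
    filled with the mode of its adjacent codes.
    """
    union = _union_mask(label_map)
    filled = ndimage.binary_fill_holes(union)
    holes = filled & ~union
    if not holes.any():
        return label_map
    out = label_map.copy()
    for hole in _mask_ccrs(holes):
        rows, cols = np.nonzero(hole.mask)
        above = below = None
        r0, r1 = rows.min(), rows.max()
        c_mid = int(np.median(cols[rows == r0]))
        if r0 > 0:
            above = out.codes[r0 - 1, c_mid]
        c_mid = int(np.median(cols[rows == r1]))
        if r1 + 1 < out.shape[0]:
            below = out.codes[r1 + 1, c_mid]
        if above == RegionCode.VERTEBRAE and below == RegionCode.VERTEBRAE:
            out.codes[hole.mask] = RegionCode.IVD
        else:
            out.codes[hole.mask] = _boundary_mode_code(hole.mask, out.codes)
    return out


#: components of Vertebrae or IVD smaller than this many pixels are
#: merged into their surroundings during post-processing.
MIN_SPINE_CCR_PX = 20


def postprocess(label_map: LabelMap) -> LabelMap:
    """Repair an inferred label map to meet the labelling requirements.

    Steps, in order: (1) single hole-free Anterior; (2) likewise
    PosteriorA and Sacrum; (3) close holes in every PosteriorB component
    without merging; (4) keep the largest Vertebrae+IVD union component,
    dissolve detached vertebra/disc fragments, close union holes;
    (5) dissolve any vertebra/disc component smaller than 20 px.

    Idempotent on valid maps.  Raises :class:`TopologyError` if no
    Sacrum pixels exist, since bottom-up traversal is then impossible.
    """
    if not label_map.mask(RegionCode.SACRUM).any():
        raise TopologyError("label map contains no Sacrum region")

    out = _keep_largest_and_fill(label_map, RegionCode.ANTERIOR)
    out = _keep_largest_and_fill(out, RegionCode.POSTERIOR_A)
    out = _keep_largest_and_fill(out, RegionCode.SACRUM)

    for ccr in find_ccrs(out, RegionCode.POSTERIOR_B):
        out = fill_holes(ccr, out)

    # step 4: one contiguous spine column
    union_ccrs = _mask_ccrs(_union_mask(out))
    for detached in union_ccrs[1:]:
        target = _boundary_mode_code(
            detached.mask, out.codes, exclude=(int(RegionCode.VERTEBRAE), int(RegionCode.IVD))
        )
        out = out.copy()
        out.codes[detached.mask] = target
    out = _fill_union_holes(out)

    # step 5: dissolve sub-threshold vertebra/disc fragments
    changed = True
    while changed:
        changed = False
        for code in (RegionCode.VERTEBRAE, RegionCode.IVD):
            for ccr in find_ccrs(out, code):
                if ccr.area_px < MIN_SPINE_CCR_PX:
                    out = merge_ccr_into_surrounding(ccr, out)
                    changed = True
                    break
            if changed:
                break
    return out


def validate(label_map: LabelMap) -> ValidationReport:
    """Check the six ground-truth labelling requirements."""
    report = ValidationReport()

    singles = [
        (1, RegionCode.ANTERIOR, "Anterior"),
        (2, RegionCode.POSTERIOR_A, "PosteriorA"),
        (3, RegionCode.SACRUM, "Sacrum"),
    ]
    for rule, code, name in singles:
        ccrs = find_ccrs(label_map, code)
        if len(ccrs) != 1:
            report.violations.append(Violation(rule, f"{name}: expected 1 component, found {len(ccrs)}"))
        if ccrs and _has_holes(ccrs[0].mask):
            report.violations.append(Violation(rule, f"{name}: largest component has holes"))

    for i, ccr in enumerate(find_ccrs(label_map, RegionCode.POSTERIOR_B)):
        if _has_holes(ccr.mask):
            report.violations.append(Violation(4, f"PosteriorB component {i}: has holes"))

    union_ccrs = _mask_ccrs(_union_mask(label_map))
    if len(union_ccrs) != 1:
        report.violations.append(
            Violation(5, f"Vert-IVD union: expected 1 component, found {len(union_ccrs)}")
        )
    elif _has_holes(union_ccrs[0].mask):
        report.violations.append(Violation(5, "Vert-IVD union: has holes"))

    report.violations.extend(_check_alternation(label_map))
    return report


def _check_alternation(label_map: LabelMap) -> list:
    """Rule 6: bottom-up alternation IVD, Vertebra, IVD, ... above the Sacrum."""
    ivds = find_ccrs(label_map, RegionCode.IVD)
    verts = find_ccrs(label_map, RegionCode.VERTEBRAE)
    if not ivds:
        return [Violation(6, "no IVD components")]
    seq = sorted(ivds + verts, key=lambda c: -c.centroid[0])  # bottom first
    out = []
    if seq[0].code != RegionCode.IVD:
        out.append(Violation(6, "lowest spine component above the Sacrum is not an IVD"))
    sac = label_map.mask(RegionCode.SACRUM)
    if sac.any():
        near_sac = ndimage.binary_dilation(sac, structure=_STRUCT8)
        if not (near_sac & seq[0].mask).any():
            out.append(Violation(6, "lowest IVD is not adjacent to the Sacrum"))
    for a, b in zip(seq, seq[1:]):
        if a.code == b.code:
            out.append(Violation(6, "IVD/Vertebra alternation broken"))
            break
    return out


# ---------------------------------------------------------------------------
# segmentation-quality metrics


@dataclass
class SegScores:
    """Per-region accuracy / IoU / BFScore (all %) and their mean score."""

    accuracy: dict
    iou: dict
    bfscore: dict
    mean_score: float

    def to_json(self):
        return {
            "accuracy": self.accuracy,
            "iou": self.iou,
            "bfscore": self.bfscore,
            "mean_score": self.mean_score,
        }


def mean_score(values) -> float:
    """Arithmetic mean of the six Vertebrae/IVD metric values (%)."""
    values = list(values)
    if len(values) != 6:
        raise ValueError("mean score is defined over six metric values")
    return float(np.mean(values))


def _boundary(mask: np.ndarray) -> np.ndarray:
    er = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0)
    return mask & ~er


def bfscore(pred: np.ndarray, truth: np.ndarray, tol_px: float) -> float:
    """Boundary F1 (%) between two binary masks at tolerance ``tol_px``."""
    pb, tb = _boundary(pred), _boundary(truth)
    if not pb.any() and not tb.any():
        return 100.0
    if not pb.any() or not tb.any():
        return 0.0
    dist_to_t = ndimage.distance_transform_edt(~tb)
    dist_to_p = ndimage.distance_transform_edt(~pb)
    precision = float((dist_to_t[pb] <= tol_px).mean())
    recall = float((dist_to_p[tb] <= tol_px).mean())
    if precision + recall == 0:
        return 0.0
    return 100.0 * 2 * precision * recall / (precision + recall)


def seg_scores(predicted: LabelMap, truth: LabelMap, bf_tol_px: float | None = None) -> SegScores:
    """Per-region accuracy, IoU, and BFScore, plus the Vertebrae/IVD mean score.

    Accuracy is per-region recall (fraction of truth pixels of the
    region that are predicted as it); IoU the Jaccard index; BFScore the
    boundary F1 at tolerance ``bf_tol_px`` (default: 0.75% of the image
    diagonal, rounded up).  The mean score averages the six Vertebrae
    and IVD values, mirroring the model-selection criterion.
    """
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch {predicted.shape} vs {truth.shape}")
    if bf_tol_px is None:
        bf_tol_px = ceil(0.0075 * hypot(*truth.shape))
    acc, iou, bf = {}, {}, {}
    for code in RegionCode:
        p, t = predicted.mask(code), truth.mask(code)
        name = code.name
        acc[name] = 100.0 * float((p & t).sum() / t.sum()) if t.any() else float("nan")
        union = (p | t).sum()
        iou[name] = 100.0 * float((p & t).sum() / union) if union else float("nan")
        bf[name] = bfscore(p, t, bf_tol_px)
    ms = mean_score(
        [
            acc["VERTEBRAE"],
            iou["VERTEBRAE"],
            bf["VERTEBRAE"],
            acc["IVD"],
            iou["IVD"],
            bf["IVD"],
        ]
    )
    return SegScores(accuracy=acc, iou=iou, bfscore=bf, mean_score=ms)
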