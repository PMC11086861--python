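"""Spine centerline extraction, ordering, and anatomical naming.

The Sacrum, Vertebrae, and IVD regions are merged into one contiguous
column and reduced to a one-pixel-wide centerline by morphological
thinning.  The centerline's lowest endpoint (inside the sacrum) is the
traversal start; A* pathfinding over the skeleton pixels orders the
points bottom-to-top, pruning any thinning branches.  Walking the
ordered path and recording the region under each point yields the
bottom-up sequence of discs and vertebrae, which are named
L5/S1, L4/L5, ... and L5, L4, ... respectively.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from math import hypot, sqrt

import numpy as np
from scipy import ndimage

from .errors import AnatomyError, TopologyError
from .labelmap import CCR, LabelMap, RegionCode, _mask_ccrs, _STRUCT8

log = logging.getLogger(__name__)

IVD_NAMES = ("L5/S1", "L4/L5", "L3/L4", "L2/L3", "L1/L2")
VERTEBRA_NAMES = ("L5", "L4", "L3", "L2", "L1")

@dataclass
class SpineSkeleton:
    """Unit-width 8-connected skeleton of the merged spine region."""

    mask: np.ndarray
    endpoints: list  # (row, col) pixels with exactly one foreground neighbour


@dataclass
class SpinePath:
    """Ordered centerline points from the sacral (bottom) end to the top."""

    points: np.ndarray  # (n, 2) array of (row, col)
    start: tuple
    finish: tuple


@dataclass
class NamedStructure:
    name: str
    code: int
    ccr: CCR
    order: int
    truncated: bool = False


@dataclass
class NamedRegions:
    ivds: list = field(default_factory=list)
    vertebrae: list = field(default_factory=list)

    def ivd(self, name: str) -> NamedStructure:
        for s in self.ivds:
            if s.name == name:
                return s
        raise KeyError(name)

    def vertebra(self, name: str) -> NamedStructure:
        for s in self.vertebrae:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_json(self):
        return [
            {
                "name": s.name,
                "code": RegionCode(s.code).name,
                "area_px": s.ccr.area_px,
                "bbox": list(s.ccr.bbox),
                "truncated": s.truncated,
            }
            for s in self.ivds + self.vertebrae
        ]


def _neighbour_counts(mask: np.ndarray) -> np.ndarray:
    return ndimage.convolve(mask.astype(np.uint8), _STRUCT8.astype(np.uint8), mode="constant") - mask


def find_endpoints(mask: np.ndarray) -> list:
    """Skeleton pixels with exactly one 8-connected foreground neighbour."""
    counts = _neighbour_counts(mask)
    rows, cols = np.nonzero(mask & (counts == 1))
    return [(int(r), int(c)) for r, c in zip(rows, cols)]


def extract_skeleton(label_map: LabelMap) -> SpineSkeleton:
    """Thin the merged Sacrum+Vertebrae+IVD region to its centerline."""
    from skimage.morphology import thin

    merged = (
        label_map.mask(RegionCode.SACRUM)
        | label_map.mask(RegionCode.VERTEBRAE)
        | label_map.mask(RegionCode.IVD)
    )
    if not merged.any():
        raise TopologyError("merged spine region is empty")
    if len(_mask_ccrs(merged)) != 1:
        raise TopologyError("merged spine region is not contiguous")
    skel = thin(merged)
    endpoints = find_endpoints(skel)
    return SpineSkeleton(mask=skel, endpoints=endpoints)


def _astar(mask: np.ndarray, start: tuple, goal: tuple) -> list:
    """A* shortest path over foreground pixels.

    8-connected moves cost 1 (axial) or sqrt(2) (diagonal); the
    heuristic is the Euclidean distance, which is admissible for this
    metric.  On a unit-width skeleton the path is unique, so any exact
    pathfinder returns the same sequence.
    """
    h = lambda p: hypot(p[0] - goal[0], p[1] - goal[1])
    nrows, ncols = mask.shape
    open_heap = [(h(start), 0.0, start)]
    g = {start: 0.0}
    came = {}
    closed = set()
    while open_heap:
        _, gc, cur = heapq.heappop(open_heap)
        if cur == goal:
            path = [cur]
            while cur in came:
                cur = came[cur]
                path.append(cur)
            return path[::-1]
        if cur in closed:
            continue
        closed.add(cur)
        r, c = cur
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if not (0 <= nr < nrows and 0 <= nc < ncols) or not mask[nr, nc]:
                    continue
                step = sqrt(2.0) if dr and dc else 1.0
                ng = gc + step
                nb = (nr, nc)
                if ng < g.get(nb, float("inf")) - 1e-12:
                    g[nb] = ng
                    came[nb] = cur
                    heapq.heappush(open_heap, (ng + h(nb), ng, nb))
    raise TopologyError(f"no skeleton path between {start} and {goal}")


def order_path(skeleton: SpineSkeleton) -> SpinePath:
    """Order the skeleton bottom-to-top, pruning branch pixels.

    Start = endpoint with the highest y (ties: highest x); finish =
    endpoint with the lowest y (ties: lowest x).  Points off the unique
    start-finish path (thinning branches) are dropped.
    """
    if len(skeleton.endpoints) < 2:
        raise TopologyError(f"need at least 2 skeleton endpoints, found {len(skeleton.endpoints)}")
    start = max(skeleton.endpoints, key=lambda p: (p[0], p[1]))
    finish = min(skeleton.endpoints, key=lambda p: (p[0], p[1]))
    path = _astar(skeleton.mask, start, finish)
    return SpinePath(points=np.array(path, dtype=int), start=start, finish=finish)


def _plain_runs(codes: list, wanted: int) -> list:
    """Index ranges [i0, i1] of maximal runs of ``wanted``."""
    runs = []
    i, n = 0, len(codes)
    while i < n:
        if codes[i] == wanted:
            j = i
            while j + 1 < n and codes[j + 1] == wanted:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _structure_runs(codes: list, path: SpinePath, ccrs: list) -> list:
    """Merge path runs that thread the same connected component.

    Brief label noise on the centerline splits the run of one structure
    into pieces that still belong to the same component, so grouping by
    component identity re-merges them; a genuinely collapsed disc only
    two path points thick still separates the two vertebra components
    around it.  Returns (ccr, first_index) pairs in traversal order.
    """
    wanted = ccrs[0].code if ccrs else None
    out = []
    for i0, i1 in _plain_runs(codes, wanted):
        mid = tuple(path.points[(i0 + i1) // 2])
        ccr = _containing_ccr(ccrs, mid) or _containing_ccr(ccrs, tuple(path.points[i0]))
        if ccr is None:
            continue
        if out and out[-1][0] is ccr:
            continue
        out.append((ccr, i0))
    return out


def assign_names(path: SpinePath, label_map: LabelMap) -> NamedRegions:
    """Name each disc and vertebra by its bottom-up traversal order.

    The first disc component encountered is L5/S1, the second L4/L5,
    and so on; vertebra components are named L5, L4, ... likewise.
    Sacrum points are skipped.  Label noise briefly interrupting a run
    does not split a structure (runs of the same connected component
    merge).
    """
    codes = [int(label_map.codes[r, c]) for r, c in path.points]
    if all(c == RegionCode.SACRUM for c in codes):
        raise AnatomyError("traversal path lies entirely within the Sacrum")

    start_code = codes[0]
    if start_code != RegionCode.SACRUM:
        log.warning("traversal start point is not inside the Sacrum region (code %d)", start_code)

    named = NamedRegions()
    for code, names, out in (
        (int(RegionCode.IVD), IVD_NAMES, named.ivds),
        (int(RegionCode.VERTEBRAE), VERTEBRA_NAMES, named.vertebrae),
    ):
        ccrs = _mask_ccrs(label_map.mask(code), code)
        structures = _structure_runs(codes, path, ccrs) if ccrs else []
        if code == RegionCode.IVD and not structures:
            raise AnatomyError("no IVD region encountered along the spine line")
        if len(structures) > len(names):
            raise AnatomyError(
                f"{len(structures)} runs of {RegionCode(code).name} exceed the lumbar count"
            )
        for order, (ccr, _) in enumerate(structures):
            out.append(
                NamedStructure(
                    name=names[order],
                    code=code,
                    ccr=ccr,
                    order=order,
                    truncated=_touches_border(ccr.mask),
                )
            )
    return named


def _containing_ccr(ccrs: list, point: tuple):
    for c in ccrs:
        if c.mask[point[0], point[1]]:
            return c
    return None


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())
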