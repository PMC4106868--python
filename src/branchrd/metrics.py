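"""Quantification of simulated branching patterns.

Peaks of the activator field mark (pre-)branch sites; their spacing along
the stalk gives the side-branch period, frame-to-frame tracking of peaks
detects tip-split lineage events, and skeleton analysis of the binarized
differentiation field counts realized side branches and their left/right
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

__all__ = [
    "PeakSet",
    "SplitEvent",
    "SpacingStats",
    "BranchStats",
    "detect_peaks",
    "peak_spacing",
    "track_splits",
    "count_side_branches",
]


@dataclass
class PeakSet:
    """Detected activator peaks: centroids in space units, heights in A."""

    centroids: np.ndarray  # (n, 2) columns (x, y), space units
    heights: np.ndarray    # (n,)
    birth_step: np.ndarray | None = None

    def __len__(self) -> int:
        return int(self.centroids.shape[0])

    @property
    def xs(self) -> np.ndarray:
        return self.centroids[:, 0]

    @property
    def ys(self) -> np.ndarray:
        return self.centroids[:, 1]


@dataclass(frozen=True)
class SplitEvent:
    """One tip-split: a parent peak linked to two co-emerging children."""

    parent: int
    children: tuple[int, int]
    step: int
    generation: int


@dataclass(frozen=True)
class SpacingStats:
    """Successive gaps between axis-projected peak centroids (space units)."""

    gaps: np.ndarray
    mean: float


@dataclass(frozen=True)
class BranchStats:
    count: int
    alternation_index: float | None
    sides: tuple[int, ...]        # +1 / -1 per one-sided branch, along the path
    one_sided: bool
    n_symmetric_pairs: int


def default_threshold(fieldarr: np.ndarray, factor: float = 3.0) -> float:
    """Robust detection threshold: ``factor`` times the spatial median."""
    return factor * float(np.median(fieldarr))


def detect_peaks(
    fieldarr: np.ndarray,
    threshold: float | None = None,
    min_separation: float = 0.9,
    dx: float = 0.3,
) -> PeakSet:
    """Local maxima (8-neighbour) of a 2-D field above a threshold.

    Plateau maxima are merged into a single centroid; maxima closer than
    ``min_separation`` (space units) are merged keeping the higher.  With
    ``threshold=None`` a robust default (3x the spatial median) is used.
    """
    fieldarr = np.asarray(fieldarr, dtype=float)
    if not np.all(np.isfinite(fieldarr)):
        raise ValueError("detect_peaks: field contains non-finite values")
    if threshold is None:
        threshold = default_threshold(fieldarr)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    footprint = np.ones((3, 3), dtype=bool)
    local_max = fieldarr == ndimage.maximum_filter(
        fieldarr, footprint=footprint, mode="nearest"
    )
    candidates = local_max & (fieldarr >= threshold)
    labels, nlab = ndimage.label(candidates, structure=footprint.astype(int))
    cents, heights = [], []
    for lab in range(1, nlab + 1):
        mask = labels == lab
        value = float(fieldarr[mask][0])
        # reject constant regions that are not strict maxima of their border
        ring = ndimage.binary_dilation(mask, structure=footprint) & ~mask
        if ring.any() and fieldarr[ring].max() >= value:
            continue
        if not ring.any():  # the whole grid: a flat field, not a peak
            continue
        rows, cols = np.nonzero(mask)
        cents.append((cols.mean() * dx, rows.mean() * dx))
        heights.append(value)
    if not cents:
        return PeakSet(np.empty((0, 2)), np.empty(0))
    cents_arr = np.asarray(cents)
    heights_arr = np.asarray(heights)
    # merge near-coincident maxima, keeping the higher
    order = np.argsort(-heights_arr)
    kept: list[int] = []
    for i in order:
        if all(
            np.hypot(*(cents_arr[i] - cents_arr[j])) >= min_separation
            for j in kept
        ):
            kept.append(i)
    kept_arr = np.array(sorted(kept, key=lambda i: cents_arr[i, 0]))
    return PeakSet(cents_arr[kept_arr], heights_arr[kept_arr])


def peak_spacing(peaks: PeakSet, axis: str = "x") -> SpacingStats | None:
    """Mean and per-gap spacing of peaks projected on the stalk axis.

    Returns ``None`` (the undefined-spacing signal) with fewer than 2 peaks.
    """
    if len(peaks) < 2:
        return None
    proj = np.sort(peaks.xs if axis == "x" else peaks.ys)
    gaps = np.diff(proj)
    return SpacingStats(gaps=gaps, mean=float(gaps.mean()))


# ---------------------------------------------------------------------------
# Lineage tracking
# ---------------------------------------------------------------------------

@dataclass
class _Track:
    tid: int
    pos: np.ndarray
    generation: int


def track_splits(
    snapshots: list[tuple[int, PeakSet]],
    match_radius: float = 1.5,
) -> tuple[list[SplitEvent], int]:
    """Frame-to-frame peak linking; a split is one parent with two children.

    ``snapshots`` is a time-ordered list of (step, PeakSet).  Children of a
    split get generation ``parent + 1``; unmatched peaks found new lineages
    at generation 0.  Ambiguous links (two parents claiming one child) are
    resolved by distance, ties by the earlier track id.  Returns the events
    and the maximum generation reached.
    """
    events: list[SplitEvent] = []
    max_gen = 0
    tracks: list[_Track] = []
    next_id = 0
    for step, peaks in snapshots:
        pts = peaks.centroids
        assignments: dict[int, list[int]] = {}
        child_parent: list[int | None] = [None] * len(pts)
        for ci in range(len(pts)):
            best, best_d = None, match_radius
            for tr in tracks:
                d = float(np.hypot(*(pts[ci] - tr.pos)))
                if d < best_d or (best is not None and d == best_d and tr.tid < best.tid):
                    best, best_d = tr, d
            if best is not None:
                child_parent[ci] = best.tid
                assignments.setdefault(best.tid, []).append(ci)
        new_tracks: list[_Track] = []
        by_id = {tr.tid: tr for tr in tracks}
        for tid, children in assignments.items():
            parent = by_id[tid]
            if len(children) == 1:
                parent.pos = pts[children[0]].copy()
                new_tracks.append(parent)
            else:
                if len(children) > 2:
                    # keep the two nearest as the split pair
                    children = sorted(
                        children,
                        key=lambda ci: float(np.hypot(*(pts[ci] - parent.pos))),
                    )[:2]
                gen = parent.generation + 1
                kid_ids = []
                for ci in children:
                    new_tracks.append(_Track(next_id, pts[ci].copy(), gen))
                    kid_ids.append(next_id)
                    next_id += 1
                events.append(
                    SplitEvent(
                        parent=tid, children=(kid_ids[0], kid_ids[1]),
                        step=step, generation=gen,
                    )
                )
                max_gen = max(max_gen, gen)
        for ci in range(len(pts)):
            if child_parent[ci] is None:
                new_tracks.append(_Track(next_id, pts[ci].copy(), 0))
                next_id += 1
            elif len(assignments.get(child_parent[ci], [])) > 2:
                # extra children beyond the split pair count as births
                parent = by_id[child_parent[ci]]
                pair = {
                    tuple(pts[k]) for k in sorted(
                        assignments[child_parent[ci]],
                        key=lambda k: float(np.hypot(*(pts[k] - parent.pos))),
                    )[:2]
                }
                if tuple(pts[ci]) not in pair:
                    new_tracks.append(_Track(next_id, pts[ci].copy(), 0))
                    next_id += 1
        tracks = new_tracks
    return events, max_gen


# ---------------------------------------------------------------------------
# Side-branch counting
# ---------------------------------------------------------------------------

def _skeleton_graph(skel: np.ndarray):
    """Sparse 8-adjacency graph over skeleton pixels."""
    rows, cols = np.nonzero(skel)
    n = rows.size
    index = -np.ones(skel.shape, dtype=int)
    index[rows, cols] = np.arange(n)
    src, dst, wts = [], [], []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            r2, c2 = rows + di, cols + dj
            ok = (
                (r2 >= 0) & (r2 < skel.shape[0])
                & (c2 >= 0) & (c2 < skel.shape[1])
            )
            ok[ok] &= skel[r2[ok], c2[ok]]
            src.extend(np.arange(n)[ok])
            dst.extend(index[r2[ok], c2[ok]])
            wts.extend([np.hypot(di, dj)] * int(ok.sum()))
    graph = coo_matrix((wts, (src, dst)), shape=(n, n)).tocsr()
    return graph, rows, cols, index


def _main_path(skel: np.ndarray):
    """Longest geodesic (diameter path) through the skeleton."""
    graph, rows, cols, index = _skeleton_graph(skel)
    n = rows.size
    if n == 0:
        return [], rows, cols
    d0 = dijkstra(graph, indices=0)
    d0[~np.isfinite(d0)] = -1
    u = int(np.argmax(d0))
    du, pred = dijkstra(graph, indices=u, return_predecessors=True)
    du[~np.isfinite(du)] = -1
    v = int(np.argmax(du))
    path = [v]
    while path[-1] != u and pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    return [(int(rows[i]), int(cols[i])) for i in path[::-1]], rows, cols


def count_side_branches(
    yfield: np.ndarray,
    y_threshold: float = 0.5,
    min_branch_px: int = 2,
) -> BranchStats:
    """Count skeleton branches off the main path of the binarized Y field.

    The differentiation field is binarized at ``y_threshold`` (between the
    two stable states of the Y switch), thinned to a skeleton, and the main
    stalk is taken as the longest geodesic through it.  Each connected
    off-path component of at least ``min_branch_px`` pixels that touches the
    main path counts as one side branch.  The laterality score is the
    fraction of consecutive one-sided branches that alternate sides (+1 for
    perfect left/right alternation, 0 for same-sided or symmetric-pair
    emergence); branches emerging in opposite-sided pairs at the same
    station are reported as symmetric pairs.
    """
    mask = np.asarray(yfield, dtype=float) >= y_threshold
    if not mask.any():
        return BranchStats(0, None, (), False, 0)
    skel = skeletonize(mask)
    if not skel.any():
        return BranchStats(0, None, (), False, 0)
    path, rows, cols = _main_path(skel)
    path_set = set(path)
    off = skel.copy()
    for (r, c) in path:
        off[r, c] = False
    labels, nlab = ndimage.label(off, structure=np.ones((3, 3), int))
    path_arr = np.asarray(path)
    # local tangent along the main path (smoothed over +-2 stations)
    attach = []  # (station index, side sign)
    for lab in range(1, nlab + 1):
        rr, cc = np.nonzero(labels == lab)
        if rr.size < min_branch_px:
            continue
        # must touch the main path
        touching = None
        best_d = np.inf
        for r, c in zip(rr, cc):
            d = np.abs(path_arr[:, 0] - r) + np.abs(path_arr[:, 1] - c)
            k = int(np.argmin(d))
            if d[k] <= 2 and d[k] < best_d:
                best_d = d[k]
                touching = k
        if touching is None:
            continue
        k = touching
        k0, k1 = max(k - 2, 0), min(k + 2, len(path) - 1)
        tangent = path_arr[k1] - path_arr[k0]
        centroid = np.array([rr.mean(), cc.mean()])
        offset = centroid - path_arr[k]
        cross = tangent[0] * offset[1] - tangent[1] * offset[0]
        attach.append((k, int(np.sign(cross)) or 1))
    attach.sort()
    count = len(attach)
    if count == 0:
        return BranchStats(0, None, (), False, 0)
    # collapse opposite-sided branches at the same station into pairs
    singles: list[tuple[int, int]] = []
    n_pairs = 0
    used = [False] * count
    for i in range(count):
        if used[i]:
            continue
        paired = False
        for j in range(i + 1, count):
            if used[j]:
                continue
            if abs(attach[i][0] - attach[j][0]) <= 2 and attach[i][1] != attach[j][1]:
                n_pairs += 1
                used[i] = used[j] = True
                paired = True
                break
        if not paired:
            used[i] = True
            singles.append(attach[i])
    sides = tuple(s for _, s in singles)
    one_sided = len(sides) >= 1 and len(set(sides)) == 1 and count > 1
    if len(sides) >= 2:
        flips = sum(1 for a, b in zip(sides, sides[1:]) if a != b)
        alternation = flips / (len(sides) - 1)
    elif n_pairs:
        alternation = 0.0
    else:
        alternation = None
    return BranchStats(count, alternation, sides, one_sided, n_pairs)
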