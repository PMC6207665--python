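"""Collagen fiber segmentation and the 21 morphological features.

A "fiber" is an 8-connected component of the clean collagen mask.  Per
fiber we measure:

* length — geodesic diameter of the component's skeleton (longest shortest
  path, 8-connected steps weighted 1 / sqrt(2)), plus one pixel of extent;
* width — area / length (mean width of a tubular object);
* orientation — major-axis angle of the pixel second moments, degrees in
  (-90, 90] measured from the image x (column) axis;
* area, perimeter — pixel count and boundary-traced perimeter;
* mean source intensity over the fiber's pixels.

The 21-feature vector summarizes the fiber population: counts, medians,
totals and population variances of orientation/length/width/area, the total
perimeter, counts and ratios of long/short and thick/thin fibers (cut at
configurable thresholds, by default the dataset-median length and width),
the mean collagen intensity, and the collagen proportionate area (CPA) —
the fraction of the tissue area occupied by collagen, the classic scalar
measure of fibrosis burden.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from skimage import measure as skmeasure
from skimage.morphology import skeletonize

from .preprocess import ProcessedImage

__all__ = [
    "Fiber",
    "FiberSet",
    "MorphThresholds",
    "MORPH_FEATURE_NAMES",
    "segment_fibers",
    "morph_features",
    "skeleton_length",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class Fiber:
    label: int
    area: int
    length: float
    width: float
    orientation: float  # degrees in (-90, 90]
    perimeter: float
    mean_intensity: float
    # optional cross-link descriptors (skeleton branch points); not part of
    # the 21-feature vector by default
    n_branch_points: int = 0


@dataclass
class FiberSet:
    fibers: list[Fiber]
    labels: np.ndarray  # labeled component image
    source: ProcessedImage | None = None

    def __len__(self) -> int:
        return len(self.fibers)

    def lengths(self) -> np.ndarray:
        return np.array([f.length for f in self.fibers], dtype=float)

    def widths(self) -> np.ndarray:
        return np.array([f.width for f in self.fibers], dtype=float)


@dataclass(frozen=True)
class MorphThresholds:
    """Length/width cuts separating long vs short and thick vs thin fibers.

    Defaults are meant to be replaced by dataset medians (see
    :func:`dataset_thresholds`); ``ratio_cap`` bounds the short/long and
    thin/thick ratios when the denominator count is zero.
    """

    length_cut: float = 50.0
    width_cut: float = 3.5
    ratio_cap: float = 100.0


MORPH_FEATURE_NAMES = [
    "n_fibers",
    "orientation_median", "orientation_var",
    "length_median", "length_total", "length_var",
    "width_median", "width_total", "width_var",
    "perimeter_total",
    "n_long", "n_short", "n_thick", "n_thin",
    "ratio_short_long", "ratio_thin_thick",
    "area_median", "area_total", "area_var",
    "collagen_mean_intensity",
    "cpa",
]


def _skeleton_graph(skel: np.ndarray):
    pts = np.argwhere(skel)
    coords = {tuple(p): i for i, p in enumerate(pts)}
    nbrs: list[dict[int, float]] = [{} for _ in range(len(pts))]
    for (r, c), i in coords.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = coords.get((r + dr, c + dc))
                if j is not None:
                    nbrs[i][j] = _SQRT2 if dr and dc else 1.0
    return pts, nbrs


def _prune_spurs(nbrs, s_max: int) -> set[int]:
    """Drop terminal branches of <= s_max pixels that end at a branch
    point (the short Y-arms a skeleton grows at blunt fiber ends)."""
    alive = set(range(len(nbrs)))
    for e in [i for i in alive if len(nbrs[i]) <= 1]:
        if e not in alive:
            continue
        path = [e]
        cur, prev = e, None
        while True:
            nxt = [j for j in nbrs[cur] if j in alive and j != prev]
            if len(nxt) != 1:
                break
            prev, cur = cur, nxt[0]
            if sum(1 for j in nbrs[cur] if j in alive) >= 3:
                break
            path.append(cur)
            if len(path) > s_max + 1:
                break
        if len(path) <= s_max and cur not in path:
            alive.difference_update(path)
    return alive


def _geodesic_diameter(nbrs, alive: set[int]) -> float:
    """Double Dijkstra sweep (exact on tree-shaped skeletons)."""
    if len(alive) < 2:
        return 0.0

    def dijkstra(src: int) -> dict[int, float]:
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, i = heapq.heappop(heap)
            if d > dist.get(i, np.inf):
                continue
            for j, w in nbrs[i].items():
                if j not in alive:
                    continue
                nd = d + w
                if nd < dist.get(j, np.inf):
                    dist[j] = nd
                    heapq.heappush(heap, (nd, j))
        return dist

    start = next(iter(alive))
    d0 = dijkstra(start)
    u = max(d0, key=d0.get)
    d1 = dijkstra(u)
    return max(d1.values())


def skeleton_length(component: np.ndarray) -> tuple[float, int]:
    """Geodesic diameter of a binary component's skeleton, in pixels.

    Skeletonizes the component, prunes the short terminal spurs the
    skeleton grows toward the corners of blunt fiber ends (spur cutoff =
    a first-pass width estimate, area / raw diameter), then measures the
    longest shortest path with diagonal steps weighted sqrt(2).  Returns
    (length, branch point count); length includes +1 px of endpoint
    extent and is at least 1.
    """
    skel = skeletonize(component)
    pts, nbrs = _skeleton_graph(skel)
    if len(pts) < 2:
        return 1.0, 0
    full = set(range(len(pts)))
    d_raw = _geodesic_diameter(nbrs, full) + 1.0
    width_est = component.sum() / max(d_raw, 1.0)
    alive = _prune_spurs(nbrs, int(np.ceil(width_est)))
    if len(alive) < 2:
        alive = full
    diameter = _geodesic_diameter(nbrs, alive)
    n_branch = sum(1 for i in alive
                   if sum(1 for j in nbrs[i] if j in alive) > 2)
    return max(diameter, 0.0) + 1.0, n_branch


def _orientation_deg(rows: np.ndarray, cols: np.ndarray) -> float:
    """Major-axis angle from central second moments, degrees in (-90, 90].

    x is the column axis, y points up (negated rows), so the angle follows
    the usual mathematical convention.
    """
    x = cols - cols.mean()
    y = -(rows - rows.mean())
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    ang = 0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return float(ang)


def segment_fibers(proc: ProcessedImage) -> FiberSet:
    """One Fiber per 8-connected component of the collagen mask."""
    labels = skmeasure.label(proc.collagen_mask, connectivity=2)
    fibers: list[Fiber] = []
    for rp in skmeasure.regionprops(labels, intensity_image=proc.enhanced):
        comp = rp.image  # bbox-cropped boolean component
        length, n_branch = skeleton_length(comp)
        rows, cols = np.nonzero(comp)
        fibers.append(Fiber(
            label=rp.label,
            area=int(rp.area),
            length=length,
            width=float(rp.area) / length,
            orientation=_orientation_deg(rows.astype(float),
                                         cols.astype(float)),
            perimeter=float(rp.perimeter),
            mean_intensity=float(rp.intensity_mean),
            n_branch_points=n_branch,
        ))
    return FiberSet(fibers=fibers, labels=labels, source=proc)


def dataset_thresholds(fiber_sets: list[FiberSet],
                       ratio_cap: float = 100.0) -> MorphThresholds:
    """Long/short and thick/thin cuts = pooled per-fiber medians."""
    lengths = np.concatenate([fs.lengths() for fs in fiber_sets]) \
        if fiber_sets else np.array([])
    widths = np.concatenate([fs.widths() for fs in fiber_sets]) \
        if fiber_sets else np.array([])
    if lengths.size == 0:
        return MorphThresholds(ratio_cap=ratio_cap)
    return MorphThresholds(length_cut=float(np.median(lengths)),
                           width_cut=float(np.median(widths)),
                           ratio_cap=ratio_cap)


def _ratio(num: int, den: int, cap: float) -> float:
    if den > 0:
        return min(num / den, cap)
    return 0.0 if num == 0 else cap


def morph_features(fs: FiberSet, proc: ProcessedImage,
                   thresholds: MorphThresholds | None = None) -> np.ndarray:
    """The 21 morphological features, fixed order (see
    MORPH_FEATURE_NAMES).

    Empty-set convention: all counts, totals, medians and variances are 0,
    CPA is 0 — downstream classifiers never see missing values.  Variances
    are population variances; ``n_long = #{length >= L*}`` and
    ``n_short = count - n_long`` (thick/thin analogously), so the pairs
    always partition the fiber count.
    """
    thresholds = thresholds or MorphThresholds()
    n = len(fs)
    tissue_px = int(proc.tissue_mask.sum())
    collagen_px = int((proc.collagen_mask & proc.tissue_mask).sum())
    cpa = collagen_px / tissue_px if tissue_px > 0 else 0.0
    if n == 0:
        out = np.zeros(21)
        out[20] = cpa
        return out
    ori = np.array([f.orientation for f in fs.fibers])
    lng = fs.lengths()
    wid = fs.widths()
    area = np.array([f.area for f in fs.fibers], dtype=float)
    per = np.array([f.perimeter for f in fs.fibers])
    inten = np.array([f.mean_intensity for f in fs.fibers])
    n_long = int(np.sum(lng >= thresholds.length_cut))
    n_short = n - n_long
    n_thick = int(np.sum(wid >= thresholds.width_cut))
    n_thin = n - n_thick
    mean_int = float(np.sum(inten * area) / np.sum(area))
    return np.array([
        float(n),
        float(np.median(ori)), float(np.var(ori)),
        float(np.median(lng)), float(np.sum(lng)), float(np.var(lng)),
        float(np.median(wid)), float(np.sum(wid)), float(np.var(wid)),
        float(np.sum(per)),
        float(n_long), float(n_short), float(n_thick), float(n_thin),
        _ratio(n_short, n_long, thresholds.ratio_cap),
        _ratio(n_thin, n_thick, thresholds.ratio_cap),
        float(np.median(area)), float(np.sum(area)), float(np.var(area)),
        mean_int,
        float(cpa),
    ])
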