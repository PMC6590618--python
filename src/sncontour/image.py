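"""Preprocessing of single-strand images into single-width backbones.

The pipeline mirrors standard AFM practice: threshold the grayscale scan to
a binary mask, remove isolated pixel islands, keep the single strand, then
iteratively thin the mask to a one-pixel-wide skeleton and prune side
branches until one simple end-to-end path remains.  AFM tip broadening
widens the imaged strand; repeated thinning converges the mask onto the
strand midline.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from skimage import filters, measure, morphology

from .chaincode import PixelPath, validate_single_width

__all__ = [
    "BinaryImage",
    "EmptyImageError",
    "UnsupportedTopologyError",
    "DegenerateSkeletonError",
    "binarize_and_clean",
    "thin_and_debranch",
    "read_image",
    "write_mask",
]


class EmptyImageError(ValueError):
    """No foreground survives thresholding and island filtering."""


class UnsupportedTopologyError(ValueError):
    """The strand is a closed loop (skeleton has no endpoints)."""


class DegenerateSkeletonError(ValueError):
    """Pruning could not reduce the skeleton to a single-width path."""


@dataclass(frozen=True)
class BinaryImage:
    """Binary mask in Cartesian orientation plus its pixel resolution.

    ``grid[x, y]`` is indexed x-then-y with y increasing upward;
    ``pixel_size`` is the resolution r in nm/pixel.
    """

    grid: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim != 2:
            raise ValueError("grid must be 2-D")
        object.__setattr__(self, "grid", g)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def _rows_to_cartesian(arr: np.ndarray) -> np.ndarray:
    # image row/col (row 0 at top) -> grid[x, y] with y up
    return np.flipud(arr).T


def _cartesian_to_rows(grid: np.ndarray) -> np.ndarray:
    return np.flipud(grid.T)


def read_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale TIFF or PNG as a float array in [0, 1]."""
    import tifffile
    from PIL import Image

    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(p)
    else:
        arr = np.asarray(Image.open(p).convert("I"))
    arr = np.asarray(arr, dtype=float)
    lo, hi = arr.min(), arr.max()
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


def write_mask(img: BinaryImage, path) -> None:
    """Write a binary mask as an 8-bit PNG (foreground = 255)."""
    from PIL import Image

    rows = _cartesian_to_rows(img.grid).astype(np.uint8) * 255
    Image.fromarray(rows, mode="L").save(str(path))


def binarize_and_clean(
    image: np.ndarray,
    threshold: float | None = None,
    min_island: int = 5,
    pixel_size: float = 1.0,
) -> BinaryImage:
    """Threshold a grayscale image and keep the single largest strand.

    Parameters
    ----------
    image
        2-D grayscale array in row/column orientation (row 0 on top).
    threshold
        Fraction of the intensity range in (0, 1); foreground is strictly
        above it.  ``None`` selects an automatic Otsu threshold.
    min_island
        Connected components (8-connectivity) smaller than this pixel
        count are removed before the largest component is retained.
    pixel_size
        Resolution r in nm/pixel carried along with the mask.
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise EmptyImageError("empty input image")
    lo, hi = arr.min(), arr.max()
    span = hi - lo if hi > lo else 1.0
    if threshold is None:
        if hi == lo:
            raise EmptyImageError("constant image has no foreground")
        thr = filters.threshold_otsu(arr)
    else:
        if not 0.0 < threshold < 1.0:
            raise ValueError("threshold must be a fraction in (0, 1)")
        thr = lo + threshold * span
    mask = arr > thr
    if not mask.any():
        raise EmptyImageError("no foreground above threshold")

    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = counts >= min_island
    mask = keep[labels]
    if not mask.any():
        raise EmptyImageError("no component survives island filtering")

    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == np.argmax(counts)
    return BinaryImage(_rows_to_cartesian(mask), pixel_size)


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(coords: np.ndarray) -> dict[tuple[int, int], list[tuple[int, int]]]:
    pixel_set = set(map(tuple, coords))
    return {
        p: [q for d in _NEIGHBORS if (q := (p[0] + d[0], p[1] + d[1])) in pixel_set]
        for p in pixel_set
    }


def _bfs(graph, start):
    """Hop distances and parents from ``start`` over the pixel graph."""
    dist = {start: 0}
    parent = {start: None}
    q = deque([start])
    while q:
        u = q.popleft()
        for v in graph[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                parent[v] = u
                q.append(v)
    return dist, parent


def _straighten(pixels: list[tuple[int, int]]) -> list[tuple[int, int]]:
    # drop pixels whose neighbors in the path are mutually 8-adjacent
    # (redundant corner pixels left by thinning)
    changed = True
    while changed and len(pixels) > 2:
        changed = False
        out = [pixels[0]]
        i = 1
        while i < len(pixels) - 1:
            a, c = out[-1], pixels[i + 1]
            if max(abs(a[0] - c[0]), abs(a[1] - c[1])) == 1:
                changed = True  # skip pixels[i]
            else:
                out.append(pixels[i])
                i += 1
                continue
            i += 1
        out.append(pixels[-1])
        pixels = out
    return pixels


def thin_and_debranch(img: BinaryImage, return_skeleton: bool = False):
    """Thin a one-component mask to an ordered single-width backbone.

    Applies iterative two-subiteration morphological thinning, then prunes
    side branches by keeping the longest simple end-to-end path between
    skeleton endpoints (ties broken toward the lexicographically smallest
    endpoint).  Raises :class:`UnsupportedTopologyError` on closed loops
    and :class:`DegenerateSkeletonError` when no single-width path exists.

    With ``return_skeleton=True`` also returns the (n, 2) coordinates of
    the full thinned skeleton (pruned branch pixels included), letting
    callers judge how much the pruning discarded.
    """
    grid = img.grid
    if not grid.any():
        raise EmptyImageError("empty mask")
    skel = morphology.thin(grid)
    coords = np.argwhere(skel)
    if len(coords) == 1:
        path1 = PixelPath(coords)
        return (path1, coords) if return_skeleton else path1
    graph = _skeleton_graph(coords)

    endpoints = sorted(p for p, nb in graph.items() if len(nb) == 1)
    if not endpoints:
        raise UnsupportedTopologyError(
            "skeleton has no endpoints (closed-loop strand)")

    # farthest-endpoint pair by hop distance, deterministic tie-break
    best = None
    for a in endpoints:
        dist, parent = _bfs(graph, a)
        for b in endpoints:
            if b == a or b not in dist:
                continue
            key = (-dist[b], min(a, b), max(a, b))
            if best is None or key < best[0]:
                best = (key, a, b, parent)
    if best is None:
        raise DegenerateSkeletonError("skeleton endpoints are disconnected")

    _, a, b, parent = best
    path = []
    node = b
    while node is not None:
        path.append(node)
        node = parent[node]
    path.reverse()  # runs a -> b
    path = _straighten(path)

    result = PixelPath(np.array(path, dtype=np.int64))
    if not validate_single_width(result):
        raise DegenerateSkeletonError(
            "pruned skeleton still violates single-width invariants")
    return (result, coords) if return_skeleton else result
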