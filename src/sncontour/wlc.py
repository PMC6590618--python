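"""Synthetic DNA-like contours: 2D worm-like chains and their rasterization.

A discrete worm-like chain is generated as a heading walk: with
discretization step ``ds`` (nm), the heading increments are i.i.d.
zero-mean Gaussians of variance ``ds / l_p``, so the in-plane tangent
correlation decays as exp(-s / (2 l_p)) — the planar analogue of a chain
with persistence length ``l_p`` (50 nm for dsDNA).  Self-intersecting
realizations are rejected and redrawn, since a crossed strand cannot be
skeletonized into a simple backbone.

Rasterization is occupancy-based: the polyline is resampled densely
(r/10 spacing), its pixel trace marked on a grid at resolution ``r``
nm/pixel with a random sub-pixel phase, and the trace thinned and
debranched into a single-width path — the same preprocessing an imaged
strand receives.  Rasterizations whose skeleton is disconnected, looped,
self-touching, or eroded by more than 2 pixels at either end are rejected
and the contour redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from shapely.geometry import LineString

from .chaincode import ChainCode, PixelPath, trace_chain_code
from .image import (
    BinaryImage,
    DegenerateSkeletonError,
    UnsupportedTopologyError,
    thin_and_debranch,
)

__all__ = [
    "ContinuousContour",
    "SimulatedSample",
    "RasterizationError",
    "SimulationParameterError",
    "generate_wlc",
    "rasterize",
    "draw_sample",
    "generate_case",
    "generate_dataset",
    "DEFAULT_LC_GRID",
    "DEFAULT_R_GRID",
    "DEFAULT_PERSISTENCE_NM",
]

#: default persistence length of double-stranded DNA, nm
DEFAULT_PERSISTENCE_NM = 50.0

#: calibration grid of true contour lengths, nm (21 values)
DEFAULT_LC_GRID = np.round(np.arange(340.0, 1020.0 + 1, 34.0), 6)

#: calibration grid of pixel resolutions, nm/pixel (28 values)
DEFAULT_R_GRID = np.round(np.arange(5.1, 7.8 + 0.05, 0.1), 6)


class RasterizationError(ValueError):
    """The rasterized skeleton is unusable (loop, contact, erosion...)."""


class SimulationParameterError(ValueError):
    """Simulation parameters make acceptable realizations too rare."""


@dataclass(frozen=True)
class ContinuousContour:
    """Polyline realization of a 2D worm-like chain, coordinates in nm."""

    vertices: np.ndarray  # (n, 2) float, nm
    true_length: float    # l_c, nm
    persistence: float    # l_p, nm
    seed: int | None = None

    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.vertices, axis=0),
                                           axis=1)))


@dataclass(frozen=True)
class SimulatedSample:
    """Single-width digital skeleton with known ground truth."""

    path: PixelPath
    true_length: float   # nm
    resolution: float    # nm/pixel
    seed: int | None = None

    @property
    def chain_code(self) -> ChainCode:
        return trace_chain_code(self.path)


def _wlc_vertices(l_c, l_p, step, rng) -> np.ndarray:
    n = max(int(round(l_c / step)), 1)
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    dtheta = rng.normal(0.0, np.sqrt(step / l_p), size=n - 1)
    theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])
    steps = step * np.column_stack([np.cos(theta), np.sin(theta)])
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


def generate_wlc(
    l_c: float,
    l_p: float = DEFAULT_PERSISTENCE_NM,
    step: float = 1.0,
    rng=None,
    max_attempts: int = 1000,
) -> ContinuousContour:
    """Draw a non-self-intersecting 2D worm-like chain of length ``l_c``.

    Vertices accumulate ``step``-length moves until the arc length
    reaches ``l_c`` (within one step); self-intersecting realizations are
    rejected and redrawn.  Raises :class:`SimulationParameterError` when
    more than 99% of ``max_attempts`` draws are rejected.
    """
    if l_c <= 0 or l_p <= 0:
        raise ValueError("contour and persistence lengths must be positive")
    if step <= 0 or step > l_p:
        raise ValueError("step must be positive and small against l_p")
    rng = np.random.default_rng(rng)
    for _ in range(max_attempts):
        verts = _wlc_vertices(l_c, l_p, step, rng)
        if LineString(verts).is_simple:
            return ContinuousContour(verts, float(l_c), float(l_p))
    raise SimulationParameterError(
        f"rejected {max_attempts} self-intersecting draws at "
        f"l_c={l_c}, l_p={l_p}")


def _resample(verts: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    t = np.arange(0.0, total + spacing / 2, spacing)
    t[-1] = min(t[-1], total)
    x = np.interp(t, s, verts[:, 0])
    y = np.interp(t, s, verts[:, 1])
    return np.column_stack([x, y])


def rasterize(
    contour: ContinuousContour,
    r: float,
    rng=None,
    return_mask: bool = False,
):
    """Digitize a contour at resolution ``r`` into a single-width skeleton.

    The polyline is sampled every r/10 nm, shifted by a random sub-pixel
    phase (deterministic zero phase when ``rng`` is None), and its pixel
    occupancy trace thinned and debranched.  Raises
    :class:`RasterizationError` when the skeleton is looped,
    self-touching, or loses more than 2 pixels of extent at an end.
    """
    if r <= 0:
        raise ValueError("resolution must be positive")
    verts = contour.vertices
    if contour.true_length / r < 4:
        raise RasterizationError("contour spans fewer than 4 pixels")
    dense = _resample(verts, r / 10.0)
    offset = np.zeros(2) if rng is None else np.random.default_rng(rng).uniform(0, r, 2)
    px = np.floor((dense + offset) / r).astype(np.int64)

    lo = px.min(axis=0) - 1
    px -= lo
    shape = tuple(px.max(axis=0) + 2)
    grid = np.zeros(shape, dtype=bool)
    grid[px[:, 0], px[:, 1]] = True

    img = BinaryImage(grid, pixel_size=r)
    try:
        path, skel_coords = thin_and_debranch(img, return_skeleton=True)
    except (UnsupportedTopologyError, DegenerateSkeletonError) as exc:
        raise RasterizationError(str(exc)) from exc

    # debranching may only have removed short spurs; a skeleton pixel
    # farther than 2 px from the backbone means a self-contact shortcut
    # amputated part of the strand
    d_skel = np.max(
        np.abs(skel_coords[:, None, :] - path.pixels[None, :, :]), axis=2
    ).min(axis=1)
    if (d_skel > 2).any():
        raise RasterizationError(
            "pruning removed more than a short spur (self-contact shortcut)")

    ends = path.pixels[[0, -1]]
    raster_ends = px[[0, -1]]
    d = np.max(np.abs(ends[:, None, :] - raster_ends[None, :, :]), axis=2)
    if not (max(d[0, 0], d[1, 1]) <= 2 or max(d[0, 1], d[1, 0]) <= 2):
        raise RasterizationError("skeleton lost more than 2 pixels of extent")

    sample = SimulatedSample(path, contour.true_length, float(r))
    return (sample, img) if return_mask else sample


def draw_sample(
    l_c: float,
    r: float,
    l_p: float = DEFAULT_PERSISTENCE_NM,
    step: float = 1.0,
    rng=None,
    max_attempts: int = 1000,
) -> SimulatedSample:
    """One accepted simulated sample; contours are redrawn on rejection."""
    rng = np.random.default_rng(rng)
    for _ in range(max_attempts):
        contour = generate_wlc(l_c, l_p, step, rng, max_attempts=max_attempts)
        try:
            return rasterize(contour, r, rng=rng)
        except RasterizationError:
            continue
    raise SimulationParameterError(
        f"no acceptable rasterization in {max_attempts} draws at "
        f"l_c={l_c}, r={r}")


def case_seed(master_seed: int, case_index: int) -> np.random.SeedSequence:
    """Named deterministic substream for one (l_c, r) case."""
    return np.random.SeedSequence(entropy=int(master_seed),
                                  spawn_key=(int(case_index),))


def generate_case(
    l_c: float,
    r: float,
    n: int,
    seed,
    l_p: float = DEFAULT_PERSISTENCE_NM,
    step: float = 1.0,
) -> Iterator[SimulatedSample]:
    """Yield ``n`` seeded samples for one (l_c, r) case."""
    rng = np.random.default_rng(seed)
    for _ in range(n):
        yield draw_sample(l_c, r, l_p=l_p, step=step, rng=rng)


def generate_dataset(
    lc_grid=None,
    r_grid=None,
    n_per_case: int = 100,
    master_seed: int = 0,
    l_p: float = DEFAULT_PERSISTENCE_NM,
    step: float = 1.0,
) -> Iterator[tuple[int, float, float, list[SimulatedSample]]]:
    """Deterministic sample grid, yielding (case_index, l_c, r, samples).

    Cases enumerate the l_c grid (outer) by the r grid (inner); each case
    draws from its own substream of ``master_seed`` so any subset of
    cases reproduces identically.
    """
    lc_grid = DEFAULT_LC_GRID if lc_grid is None else np.asarray(lc_grid, float)
    r_grid = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, float)
    if len(lc_grid) == 0 or len(r_grid) == 0:
        raise ValueError("grids must be non-empty")
    case = 0
    for l_c in lc_grid:
        for r in r_grid:
            seed = case_seed(master_seed, case)
            samples = list(generate_case(l_c, r, n_per_case, seed,
                                         l_p=l_p, step=step))
            yield case, float(l_c), float(r), samples
            case += 1
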