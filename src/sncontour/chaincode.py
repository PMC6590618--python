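"""Freeman chain coding of single-width pixel backbones.

A digitized biopolymer backbone is an ordered run of 8-connected pixels in
which every pixel touches only its path predecessor and successor
("single-width").  The backbone is encoded as an 8-connect Freeman chain
code: one integer 0-7 per pixel connection, with 0 = +x and the codes
increasing counterclockwise, so even codes are horizontal/vertical unit
steps and odd codes are diagonal sqrt(2) steps.

Coordinates are Cartesian ``(x, y)`` with y increasing upward; image rows
are flipped on read so that code 2 is literally "up".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FREEMAN_STEPS",
    "PixelPath",
    "ChainCode",
    "InvalidPathError",
    "trace_chain_code",
    "follow_chain_code",
    "reverse_chain_code",
    "validate_single_width",
    "SingleWidthReport",
]

#: displacement (dx, dy) for each Freeman code 0..7 (counterclockwise from +x)
FREEMAN_STEPS = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)],
    dtype=np.int64,
)

_STEP_TO_CODE = {tuple(step): code for code, step in enumerate(FREEMAN_STEPS)}


class InvalidPathError(ValueError):
    """Raised when consecutive pixels are not 8-adjacent."""


@dataclass(frozen=True)
class PixelPath:
    """Ordered single-width 8-connected pixel backbone ``p_0 .. p_n``."""

    pixels: np.ndarray  # (n+1, 2) integer (x, y)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.int64)
        if px.ndim != 2 or px.shape[1] != 2 or len(px) == 0:
            raise ValueError("pixels must be a non-empty (n, 2) array")
        object.__setattr__(self, "pixels", px)

    def __len__(self) -> int:
        return len(self.pixels)

    def to_csv(self, path) -> None:
        """Write the path as CSV with columns index,x,y."""
        import pandas as pd

        pd.DataFrame(
            {"index": np.arange(len(self.pixels)),
             "x": self.pixels[:, 0], "y": self.pixels[:, 1]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PixelPath":
        import pandas as pd

        df = pd.read_csv(path).sort_values("index")
        return cls(df[["x", "y"]].to_numpy())


@dataclass(frozen=True)
class ChainCode:
    """Freeman code sequence ``c_1 .. c_n`` (integers 0-7)."""

    codes: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.codes, dtype=np.int64)
        if c.ndim != 1:
            raise ValueError("codes must be one-dimensional")
        if c.size and (c.min() < 0 or c.max() > 7):
            raise ValueError("chain codes must lie in 0..7")
        object.__setattr__(self, "codes", c)

    @classmethod
    def from_string(cls, s: str) -> "ChainCode":
        return cls(np.array([int(ch) for ch in s], dtype=np.int64))

    def __str__(self) -> str:
        return "".join(str(c) for c in self.codes)

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def n_even(self) -> int:
        """Number of horizontal/vertical (unit-length) connections."""
        return int(np.sum(self.codes % 2 == 0))

    @property
    def n_odd(self) -> int:
        """Number of diagonal (sqrt(2)-length) connections."""
        return int(np.sum(self.codes % 2 == 1))

    @property
    def n_corners(self) -> int:
        """Number of positions where consecutive codes differ."""
        return int(np.sum(self.codes[1:] != self.codes[:-1]))


def trace_chain_code(path: PixelPath) -> ChainCode:
    """Encode a pixel path as its Freeman chain code.

    ``codes[i]`` encodes the displacement ``p_{i+1} - p_i``.  Raises
    :class:`InvalidPathError` if any consecutive pair is not 8-adjacent.
    """
    px = path.pixels
    steps = np.diff(px, axis=0)
    codes = np.empty(len(steps), dtype=np.int64)
    for i, step in enumerate(map(tuple, steps)):
        code = _STEP_TO_CODE.get(step)
        if code is None:
            raise InvalidPathError(
                f"pixels {i} and {i + 1} are not 8-adjacent (step {step})"
            )
        codes[i] = code
    return ChainCode(codes)


def follow_chain_code(cc: ChainCode, origin=(0, 0)) -> PixelPath:
    """Reconstruct the pixel path obtained by walking ``cc`` from ``origin``."""
    steps = FREEMAN_STEPS[cc.codes]
    px = np.vstack([np.array(origin, dtype=np.int64),
                    np.array(origin, dtype=np.int64) + np.cumsum(steps, axis=0)])
    return PixelPath(px)


def reverse_chain_code(cc: ChainCode) -> ChainCode:
    """Chain code of the same backbone traversed tail-to-head.

    Reverses the order and replaces each code by its opposite direction
    ``(c + 4) mod 8``; an involution.
    """
    if len(cc) == 0:
        raise ValueError("cannot reverse an empty chain code")
    return ChainCode((cc.codes[::-1] + 4) % 8)


@dataclass
class SingleWidthReport:
    """Diagnostic result of :func:`validate_single_width`."""

    adjacency_failures: list = field(default_factory=list)
    duplicate_pixels: list = field(default_factory=list)
    thickness_failures: list = field(default_factory=list)
    endpoint_failures: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.adjacency_failures or self.duplicate_pixels
                    or self.thickness_failures or self.endpoint_failures)

    def __bool__(self) -> bool:
        return self.ok


def validate_single_width(path: PixelPath) -> SingleWidthReport:
    """Check all single-width backbone invariants, reporting offenders.

    Checks (a) consecutive pixels 8-adjacent, (b) all pixels distinct,
    (c) every *non*-consecutive pair at Chebyshev distance >= 2, and
    (d) each endpoint having exactly one 8-neighbor in the path.
    """
    px = path.pixels
    rep = SingleWidthReport()
    n = len(px)
    if n == 1:
        return rep

    cheb = np.max(np.abs(px[:, None, :] - px[None, :, :]), axis=2)

    diag = np.diagonal(cheb, offset=1)
    rep.adjacency_failures = list(np.nonzero(diag != 1)[0])

    dup_i, dup_j = np.nonzero(np.triu(cheb == 0, k=1))
    rep.duplicate_pixels = list(zip(dup_i.tolist(), dup_j.tolist()))

    close = np.triu(cheb == 1, k=2)
    thick_i, thick_j = np.nonzero(close)
    rep.thickness_failures = list(zip(thick_i.tolist(), thick_j.tolist()))

    for end in (0, n - 1):
        deg = int(np.sum(cheb[end] == 1))
        if deg != 1:
            rep.endpoint_failures.append(end)
    return rep
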