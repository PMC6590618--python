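"""Shape numbers of 4-pixel segments and the 12-class taxonomy.

Every interior connection of a single-width backbone sits inside a 4-pixel
segment described by three consecutive chain codes ``(c_{i-1}, c_i,
c_{i+1})``.  The segment's *shape number* is the triple of cyclic code
differences

    s_1 = (c_{i-1} - c_{i+1}) mod 8
    s_2 = (c_i     - c_{i-1}) mod 8
    s_3 = (c_{i+1} - c_i)     mod 8

which is invariant to translation and (after canonicalization) to
rotation, mirroring, and traversal direction.  Exactly 64 geometrically
distinct single-width 4-pixel segments exist; canonical shape-number
identity together with the parity of the middle code partitions them into
12 shape classes ``k_1 .. k_12``.  Classes k5, k8, k9, k12 own unique IDs
(026, 116, 206, 367); the ID pairs {k1,k2}=000, {k3,k4}=017, {k6,k7}=107,
{k10,k11}=277 are split by whether the center connection is direct (even
middle code) or diagonal (odd).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chaincode import ChainCode, FREEMAN_STEPS

__all__ = [
    "Segment",
    "ShapeTally",
    "InvalidSegmentError",
    "ChainTooShortError",
    "rolling_segments",
    "shape_number",
    "canonical_id",
    "classify",
    "classify_codes",
    "tally",
    "tally_matrix",
    "enumerate_valid_segments",
    "partition_into_classes",
    "CANONICAL_IDS",
    "CLASS_LABELS",
]

#: the eight canonical shape-number identifiers, in Table-order
CANONICAL_IDS = ("000", "017", "026", "107", "116", "206", "277", "367")

CLASS_LABELS = tuple(f"k{j}" for j in range(1, 13))

#: (canonical id, middle-code parity or None) -> class index j (1-based)
_ID_PARITY_TO_CLASS = {
    ("000", 0): 1, ("000", 1): 2,
    ("017", 0): 3, ("017", 1): 4,
    ("026", None): 5,
    ("107", 0): 6, ("107", 1): 7,
    ("116", None): 8,
    ("206", None): 9,
    ("277", 0): 10, ("277", 1): 11,
    ("367", None): 12,
}


class InvalidSegmentError(ValueError):
    """Segment geometry violates the single-width arrangement."""


class ChainTooShortError(ValueError):
    """Chain code too short to contain a full 4-pixel segment."""


@dataclass(frozen=True)
class Segment:
    """Three consecutive chain codes at interior position ``index``."""

    codes: tuple[int, int, int]
    index: int = 0

    def __post_init__(self) -> None:
        if len(self.codes) != 3 or any(not 0 <= c <= 7 for c in self.codes):
            raise ValueError("segment needs three chain codes in 0..7")


def rolling_segments(cc: ChainCode) -> list[Segment]:
    """All interior 4-pixel segments ``(c_{i-1}, c_i, c_{i+1})``.

    The window runs i = 2 .. n-1 (1-based), excluding the head and tail
    connections which lack a fourth pixel; a chain of n codes yields n-2
    segments.
    """
    codes = cc.codes
    if len(codes) < 3:
        raise ChainTooShortError(
            f"need at least 3 chain codes, got {len(codes)}")
    return [
        Segment((int(codes[i - 1]), int(codes[i]), int(codes[i + 1])), i + 1)
        for i in range(1, len(codes) - 1)
    ]


def shape_number(seg: Segment) -> tuple[int, int, int]:
    """Shape number (s1, s2, s3) of a segment, eight's-complemented to 0..7."""
    a, b, c = seg.codes
    return ((a - c) % 8, (b - a) % 8, (c - b) % 8)


def canonical_id(sn) -> str:
    """Canonical identifier of a shape number.

    Step one: if s1 > 4, replace every digit d by its eight's complement
    (8 - d) mod 8.  Step two: if s2 > s3, swap s2 and s3.  The result is
    identical for all rotations, mirrors, and traversal directions of the
    same segment.  Accepts a digit triple or a 3-character string.
    """
    if isinstance(sn, str):
        sn = tuple(int(ch) for ch in sn)
    s1, s2, s3 = sn
    if s1 > 4:
        s1, s2, s3 = (8 - s1) % 8, (8 - s2) % 8, (8 - s3) % 8
    if s2 > s3:
        s2, s3 = s3, s2
    return f"{s1}{s2}{s3}"


def _segment_pixels(codes) -> np.ndarray:
    steps = FREEMAN_STEPS[list(codes)]
    return np.vstack([[0, 0], np.cumsum(steps, axis=0)])


def _is_single_width_codes(codes) -> bool:
    px = _segment_pixels(codes)
    cheb = np.max(np.abs(px[:, None, :] - px[None, :, :]), axis=2)
    n = len(px)
    for i in range(n):
        for j in range(i + 1, n):
            if (cheb[i, j] == 0) or (j - i > 1 and cheb[i, j] < 2):
                return False
    return True


def classify(seg: Segment) -> int:
    """Shape class index j in 1..12 of a valid single-width segment.

    Raises :class:`InvalidSegmentError` when the three codes cannot arise
    from a single-width backbone (their canonical ID then falls outside
    the eight known identifiers).
    """
    cid = canonical_id(shape_number(seg))
    parity = seg.codes[1] % 2
    j = _ID_PARITY_TO_CLASS.get((cid, None)) or _ID_PARITY_TO_CLASS.get((cid, parity))
    if j is None or not _is_single_width_codes(seg.codes):
        raise InvalidSegmentError(
            f"segment {seg.codes} at index {seg.index} is not a "
            f"single-width 4-pixel arrangement (canonical id {cid})")
    return j


def _build_class_lut() -> np.ndarray:
    """(8,8,8) lookup: code triple -> class 1..12, or 0 if invalid."""
    lut = np.zeros((8, 8, 8), dtype=np.int64)
    for a in range(8):
        for b in range(8):
            for c in range(8):
                if not _is_single_width_codes((a, b, c)):
                    continue
                cid = canonical_id(shape_number(Segment((a, b, c))))
                j = _ID_PARITY_TO_CLASS.get((cid, None)) \
                    or _ID_PARITY_TO_CLASS.get((cid, b % 2))
                if j is not None:
                    lut[a, b, c] = j
    return lut


_CLASS_LUT = _build_class_lut()


def classify_codes(codes: np.ndarray) -> np.ndarray:
    """Vectorized class indices for interior positions of a code array.

    Returns one class index per rolling window; entries of 0 mark invalid
    (non-single-width) windows.
    """
    codes = np.asarray(codes)
    if len(codes) < 3:
        return np.zeros(0, dtype=np.int64)
    return _CLASS_LUT[codes[:-2], codes[1:-1], codes[2:]]


@dataclass(frozen=True)
class ShapeTally:
    """Occurrence counts n_k1..n_k12 plus the head and tail codes."""

    counts: np.ndarray  # length 12
    head_code: int
    tail_code: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (12,) or (c < 0).any():
            raise ValueError("counts must be 12 non-negative integers")
        object.__setattr__(self, "counts", c)

    @property
    def head_length(self) -> float:
        """Connection length of the head pixel pair (1 or sqrt 2)."""
        return 1.0 if self.head_code % 2 == 0 else float(np.sqrt(2.0))

    @property
    def tail_length(self) -> float:
        return 1.0 if self.tail_code % 2 == 0 else float(np.sqrt(2.0))

    def as_dict(self) -> dict:
        d = {lab: int(n) for lab, n in zip(CLASS_LABELS, self.counts)}
        d["head"] = int(self.head_code)
        d["tail"] = int(self.tail_code)
        return d


def tally(cc: ChainCode) -> ShapeTally:
    """Count shape-class occurrences along a chain.

    The rolling window covers interior positions only, so the counts sum
    to max(n - 2, 0); the head and tail connections are reported raw.
    Raises :class:`InvalidSegmentError` (with position) if any window is
    not a valid single-width arrangement.
    """
    codes = cc.codes
    if len(codes) == 0:
        raise ChainTooShortError("empty chain code")
    classes = classify_codes(codes)
    bad = np.nonzero(classes == 0)[0]
    if len(bad):
        i = int(bad[0])
        raise InvalidSegmentError(
            f"invalid segment {tuple(codes[i:i + 3])} at window {i + 2}")
    counts = np.bincount(classes, minlength=13)[1:13]
    return ShapeTally(counts, int(codes[0]), int(codes[-1]))


def tally_matrix(chains) -> np.ndarray:
    """Feature rows [n_k1..n_k12, l_H, l_T] (pixel units) for many chains."""
    rows = np.empty((len(chains), 14), dtype=float)
    for i, cc in enumerate(chains):
        t = tally(cc)
        rows[i, :12] = t.counts
        rows[i, 12] = t.head_length
        rows[i, 13] = t.tail_length
    return rows


def enumerate_valid_segments() -> dict[frozenset, list[tuple[int, int, int]]]:
    """All distinct single-width 4-pixel segments by brute force.

    Sweeps the 8**3 directed code triples, keeps those whose four pixels
    form a valid single-width arrangement, and merges triples describing
    the same undirected pixel set (translated so the lexicographically
    smallest pixel is the origin).  Returns a mapping from each canonical
    pixel set to the directed code triples producing it; there are 64.
    """
    shapes: dict[frozenset, list[tuple[int, int, int]]] = {}
    for a in range(8):
        for b in range(8):
            for c in range(8):
                if not _is_single_width_codes((a, b, c)):
                    continue
                px = _segment_pixels((a, b, c))
                anchor = min(map(tuple, px))
                key = frozenset(
                    (int(x - anchor[0]), int(y - anchor[1])) for x, y in px)
                shapes.setdefault(key, []).append((a, b, c))
    return shapes


def partition_into_classes(shapes=None) -> dict[int, list[frozenset]]:
    """Group the 64 segments into the 12 shape classes.

    Grouping key is (canonical id, middle-code parity), which coincides
    with the orbit of the pixel set under 90-degree rotations, mirrors,
    and traversal reversal.  Raises :class:`InvalidSegmentError` if any
    member's key falls outside the taxonomy.
    """
    if shapes is None:
        shapes = enumerate_valid_segments()
    groups: dict[int, list[frozenset]] = {j: [] for j in range(1, 13)}
    for key, triples in shapes.items():
        classes = {classify(Segment(t)) for t in triples}
        if len(classes) != 1:
            raise InvalidSegmentError(
                f"segment {sorted(key)} maps to multiple classes {classes}")
        groups[classes.pop()].append(key)
    return groups
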