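"""Geometry of overprinted gene pairs.

A *target* gene (the one to be knocked out) shares a contiguous stretch
of genome with an *overlapping* gene read in a different frame and/or on
the opposite strand.  :class:`OverlapGeometry` records the mapping
between the two coordinate systems; :func:`find_overlap` detects it as
the longest exact common substring; :func:`map_position` bridges a
target nucleotide position to the overlapping gene's codon grid.

Coordinates are 0-based, half-open; codon indices are 0-based (the
initiation codon is codon 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqcore import (
    SequenceError,
    clean_sequence,
    is_unambiguous,
    reverse_complement,
)

__all__ = [
    "OverlapGeometry",
    "GenePair",
    "OverlapError",
    "AmbiguousOverlapError",
    "find_overlap",
    "map_position",
]

SAME = "same"
OPPOSITE = "opposite"

DEFAULT_MIN_OVERLAP = 15


class OverlapError(ValueError):
    """No acceptable overlap between the two sequences."""


class AmbiguousOverlapError(OverlapError):
    """Two or more maximal matches of equal length: the caller must supply
    the geometry explicitly."""


@dataclass(frozen=True)
class OverlapGeometry:
    """Shared-region mapping between a target gene and its overlapping gene.

    target_span / overlap_span
        Half-open nucleotide intervals of the shared region in, respectively,
        target coordinates and the overlapping gene's own (sense-strand)
        coordinates.
    strand
        ``"same"`` or ``"opposite"``.
    frame_shift
        The overlapping gene's codon phase at the start of the shared
        region: ``overlap_span[0] % 3``.
    """

    target_span: tuple[int, int]
    overlap_span: tuple[int, int]
    strand: str
    frame_shift: int

    def __post_init__(self):
        ts, te = self.target_span
        os_, oe = self.overlap_span
        if not (0 <= ts < te and 0 <= os_ < oe):
            raise ValueError("spans must be non-empty half-open intervals")
        if (te - ts) != (oe - os_):
            raise ValueError("target_span and overlap_span differ in length")
        if self.strand not in (SAME, OPPOSITE):
            raise ValueError(f"strand must be 'same' or 'opposite', got {self.strand!r}")
        if self.frame_shift != os_ % 3:
            raise ValueError(
                f"frame_shift {self.frame_shift} inconsistent with "
                f"overlap_span start {os_} (expected {os_ % 3})"
            )

    @property
    def length(self) -> int:
        return self.target_span[1] - self.target_span[0]


@dataclass(frozen=True)
class GenePair:
    """A target gene and the overlapping gene whose protein must be
    preserved.  ``overlapping``/``geometry`` may be None for a target with
    no overlap constraint (every mutation is then unconstrained)."""

    target: str
    overlapping: str | None = None
    geometry: OverlapGeometry | None = None

    def __post_init__(self):
        object.__setattr__(self, "target", clean_sequence(self.target, what="target"))
        if len(self.target) < 3:
            raise ValueError("target must be at least one codon long")
        if (self.overlapping is None) != (self.geometry is None):
            raise ValueError("overlapping and geometry must be given together")
        if self.overlapping is not None:
            object.__setattr__(
                self,
                "overlapping",
                clean_sequence(self.overlapping, what="overlapping gene"),
            )
            if len(self.overlapping) < 3:
                raise ValueError("overlapping gene must be at least one codon long")
            g = self.geometry
            if g.target_span[1] > len(self.target):
                raise ValueError("target_span exceeds target length")
            if g.overlap_span[1] > len(self.overlapping):
                raise ValueError("overlap_span exceeds overlapping gene length")
            shared_t = self.target[g.target_span[0] : g.target_span[1]]
            shared_o = self.overlapping[g.overlap_span[0] : g.overlap_span[1]]
            if g.strand == OPPOSITE:
                shared_o = reverse_complement(shared_o)
            if shared_t != shared_o:
                raise ValueError(
                    "geometry is inconsistent: shared regions of target and "
                    "overlapping gene differ"
                )

    @classmethod
    def detect(
        cls, target: str, overlapping: str, min_len: int = DEFAULT_MIN_OVERLAP
    ) -> "GenePair":
        """Build a pair by auto-detecting the overlap geometry."""
        target = clean_sequence(target, what="target")
        overlapping = clean_sequence(overlapping, what="overlapping gene")
        geom = find_overlap(target, overlapping, min_len=min_len)
        return cls(target, overlapping, geom)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _longest_common_substrings(a: str, b: str) -> tuple[int, list[tuple[int, int]]]:
    """Length of the longest common substring of ``a`` and ``b`` and the
    start positions ``(i, j)`` of every maximal-length occurrence.

    Row-vectorised dynamic programme: L[i, j] = run length of matches
    ending at (i, j).  Cells equal to the global maximum are exactly the
    ends of maximal occurrences.
    """
    if not a or not b:
        return 0, []
    av = _encode(a)
    bv = _encode(b)
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    cur = np.zeros(len(b) + 1, dtype=np.int32)
    best = 0
    ends: list[tuple[int, int]] = []
    for i in range(len(a)):
        match = bv == av[i]
        np.multiply(prev[:-1] + 1, match, out=cur[1:], casting="unsafe")
        row_max = int(cur.max())
        if row_max > best:
            best = row_max
            ends = [(i, int(j) - 1) for j in np.flatnonzero(cur == best)]
        elif row_max == best and best > 0:
            ends.extend((i, int(j) - 1) for j in np.flatnonzero(cur == best))
        prev, cur = cur, prev
    starts = [(i - best + 1, j - best + 1) for i, j in ends]
    return best, starts


def find_overlap(
    target: str, overlapping: str, min_len: int = DEFAULT_MIN_OVERLAP
) -> OverlapGeometry:
    """Detect the overlap as the longest exact common substring between the
    target and either strand of the overlapping gene.

    The match must be at least ``min_len`` nucleotides (default 15 — below
    that, chance matches between unrelated genes become likely) and unique
    on the winning strand.  Same-strand matches are preferred over
    opposite-strand matches of equal length.  Mismatches are never
    tolerated: the two inputs describe the same genomic region, so any
    discrepancy indicates user error and must surface.

    Raises :class:`OverlapError` when no match reaches ``min_len`` and
    :class:`AmbiguousOverlapError` when the maximal match is not unique
    (supply the geometry explicitly in that case).
    """
    target = clean_sequence(target, what="target")
    overlapping = clean_sequence(overlapping, what="overlapping gene")
    if not (is_unambiguous(target) and is_unambiguous(overlapping)):
        raise SequenceError("overlap detection requires unambiguous sequences")

    fwd_len, fwd_hits = _longest_common_substrings(target, overlapping)
    rc = reverse_complement(overlapping)
    rev_len, rev_hits = _longest_common_substrings(target, rc)

    if max(fwd_len, rev_len) < min_len:
        raise OverlapError(
            f"no overlap detected: longest shared stretch is "
            f"{max(fwd_len, rev_len)} nt (< min_len={min_len})"
        )

    if fwd_len >= rev_len:
        strand, length, hits = SAME, fwd_len, fwd_hits
    else:
        strand, length, hits = OPPOSITE, rev_len, rev_hits
    if len(hits) > 1:
        raise AmbiguousOverlapError(
            f"{len(hits)} distinct maximal matches of length {length} on the "
            f"{strand} strand; pass the geometry explicitly"
        )
    ti, oj = hits[0]
    if strand == OPPOSITE:
        # oj indexes the reverse complement; convert to sense-strand coords.
        oj = len(overlapping) - (oj + length)
    return OverlapGeometry(
        target_span=(ti, ti + length),
        overlap_span=(oj, oj + length),
        strand=strand,
        frame_shift=oj % 3,
    )


def map_position(
    geometry: OverlapGeometry, target_pos: int
) -> tuple[int, int, str]:
    """Map a target nucleotide position into the overlapping gene's codon
    grid: ``(codon_index, offset_in_codon, strand)``.

    On the opposite strand the mapping accounts for reversal (and the
    caller must complement any substituted base).
    """
    ts, te = geometry.target_span
    if not ts <= target_pos < te:
        raise ValueError(
            f"target position {target_pos} outside shared span [{ts}, {te})"
        )
    if geometry.strand == SAME:
        opos = geometry.overlap_span[0] + (target_pos - ts)
    else:
        opos = geometry.overlap_span[1] - 1 - (target_pos - ts)
    return opos // 3, opos % 3, geometry.strand
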