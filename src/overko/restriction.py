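"""Restriction-site scanning and tracer analysis.

Mutagenesis protocols routinely engineer a gained or lost restriction
site alongside the mutation of interest so clones can be screened by a
cheap diagnostic digest instead of sequencing.  This module scans
sequences for (possibly degenerate) 4–8 nt recognition sites, diffs the
sites of a wild-type/mutant pair, and filters knockout candidates by the
kind of tracer they carry.

Double-stranded DNA is cut regardless of the orientation the site is
written in, so non-palindromic enzymes are scanned on both strands;
positions are always reported in forward-strand coordinates of the
scanned sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

from .seqcore import (
    IUPAC_CODES,
    SequenceError,
    clean_sequence,
    reverse_complement,
)

__all__ = [
    "RestrictionEnzyme",
    "SiteMatch",
    "SiteChangeSet",
    "EnzymeTableError",
    "load_enzymes",
    "find_sites",
    "site_changes",
    "filter_by_site_change",
    "matches_site_mode",
    "annotate_candidates",
]

FORWARD = "forward"
REVERSE = "reverse"

_MIN_SITE, _MAX_SITE = 4, 8


class EnzymeTableError(ValueError):
    """Malformed enzyme table; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _iupac_regex(pattern: str) -> str:
    return "".join(
        ch if len(IUPAC_CODES[ch]) == 1 else "[" + "".join(sorted(IUPAC_CODES[ch])) + "]"
        for ch in pattern
    )


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A named recognition pattern, 4–8 nt, possibly degenerate."""

    name: str
    recognition: str

    def __post_init__(self):
        object.__setattr__(
            self, "recognition", clean_sequence(self.recognition, what=self.name)
        )
        if not _MIN_SITE <= len(self.recognition) <= _MAX_SITE:
            raise EnzymeTableError(
                f"{self.name}: recognition sequence must be "
                f"{_MIN_SITE}–{_MAX_SITE} nt, got {len(self.recognition)}"
            )

    @property
    def palindromic(self) -> bool:
        """True when the recognition pattern equals its reverse complement
        under IUPAC equality (the usual case for Type II enzymes)."""
        return self.recognition == reverse_complement(self.recognition)

    # Plain (non-lookahead) compiled patterns: full scans wrap them in a
    # lookahead so overlapping occurrences are found; positional checks use
    # Pattern.match(seq, pos) directly.  cached_property writes straight to
    # __dict__, which frozen dataclasses permit.
    @cached_property
    def _fwd_pat(self) -> re.Pattern:
        return re.compile(_iupac_regex(self.recognition))

    @cached_property
    def _rev_pat(self) -> re.Pattern:
        return re.compile(_iupac_regex(reverse_complement(self.recognition)))

    @cached_property
    def _fwd_scan(self) -> re.Pattern:
        return re.compile("(?=" + _iupac_regex(self.recognition) + ")")

    @cached_property
    def _rev_scan(self) -> re.Pattern:
        return re.compile(
            "(?=" + _iupac_regex(reverse_complement(self.recognition)) + ")"
        )


class SiteMatch(NamedTuple):
    """One recognition-site occurrence.  ``position`` is the 0-based index
    of the 5'-most matched base on the forward strand."""

    enzyme: str
    position: int
    strand: str


@dataclass(frozen=True)
class SiteChangeSet:
    """Sites present in only one of a wild-type/mutant sequence pair."""

    added: tuple[SiteMatch, ...] = ()
    removed: tuple[SiteMatch, ...] = ()

    def __post_init__(self):
        if set(self.added) & set(self.removed):
            raise ValueError("a site cannot be both added and removed")

    def __bool__(self) -> bool:
        return bool(self.added or self.removed)


def load_enzymes(source: str | Iterable[str] = "builtin") -> list[RestrictionEnzyme]:
    """Load an enzyme table.

    ``source`` may be the literal ``"builtin"`` (the bundled table of
    common commercial enzymes), a path-like string, or an iterable of
    lines.  The format is one ``Name<whitespace>Recognition`` pair per
    line; ``#`` comments and blank lines are ignored.  Duplicate names,
    malformed lines and out-of-range recognition lengths are errors with
    line numbers.
    """
    if source == "builtin":
        text = (
            resources.files("overko").joinpath("data/enzymes.txt").read_text()
        )
        lines: Iterable[str] = text.splitlines()
    elif isinstance(source, str):
        with open(source) as fh:
            lines = fh.read().splitlines()
    else:
        lines = [ln.rstrip("\r\n") for ln in source]

    enzymes: list[RestrictionEnzyme] = []
    seen: dict[str, int] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise EnzymeTableError(
                f"expected 'Name Recognition', got {raw.strip()!r}", line=lineno
            )
        name, rec = fields
        if name in seen:
            raise EnzymeTableError(
                f"duplicate enzyme name {name!r} (first at line {seen[name]})",
                line=lineno,
            )
        seen[name] = lineno
        try:
            enzymes.append(RestrictionEnzyme(name, rec))
        except (EnzymeTableError, SequenceError) as e:
            raise EnzymeTableError(str(e), line=lineno) from e
    return enzymes


def _scan_enzyme(seq: str, enzyme: RestrictionEnzyme) -> list[SiteMatch]:
    hits = [
        SiteMatch(enzyme.name, m.start(), FORWARD)
        for m in enzyme._fwd_scan.finditer(seq)
    ]
    if not enzyme.palindromic:
        hits += [
            SiteMatch(enzyme.name, m.start(), REVERSE)
            for m in enzyme._rev_scan.finditer(seq)
        ]
    return hits


def _sites_at(seq: str, enzyme: RestrictionEnzyme, start: int) -> list[SiteMatch]:
    """Site matches whose window begins exactly at ``start``."""
    hits = []
    if enzyme._fwd_pat.match(seq, start):
        hits.append(SiteMatch(enzyme.name, start, FORWARD))
    if not enzyme.palindromic and enzyme._rev_pat.match(seq, start):
        hits.append(SiteMatch(enzyme.name, start, REVERSE))
    return hits


def find_sites(
    seq: str, enzymes: Sequence[RestrictionEnzyme]
) -> list[SiteMatch]:
    """All recognition-site occurrences of ``enzymes`` in ``seq``.

    Degenerate positions match via their IUPAC sets.  Non-palindromic
    enzymes are also matched against their reverse-complemented pattern
    (reported with ``strand='reverse'``); palindromic enzymes yield one
    match per site, not two.  Sorted by (position, enzyme name).
    """
    seq = clean_sequence(seq)
    hits: list[SiteMatch] = []
    for enz in enzymes:
        hits.extend(_scan_enzyme(seq, enz))
    hits.sort(key=lambda h: (h.position, h.enzyme, h.strand))
    return hits


def site_changes(
    wild: str, mutant: str, enzymes: Sequence[RestrictionEnzyme]
) -> SiteChangeSet:
    """Restriction sites gained or lost going from ``wild`` to ``mutant``.

    The two sequences must be equal length (substitution-only model); the
    result is the set difference of their full site lists keyed by
    (enzyme, position, strand).  Because a substitution can only create or
    destroy a site whose window covers a changed base, the scan is
    restricted to windows around the differing positions — an internal
    optimisation; the contract (and the tests) remain whole-sequence set
    difference.
    """
    if len(wild) != len(mutant):
        raise SequenceError(
            f"wild ({len(wild)} nt) and mutant ({len(mutant)} nt) must be "
            "equal length: only substitutions are modelled"
        )
    diffs = [i for i, (a, b) in enumerate(zip(wild, mutant)) if a != b]
    if not diffs:
        return SiteChangeSet()

    wild_hits: set[SiteMatch] = set()
    mut_hits: set[SiteMatch] = set()
    for enz in enzymes:
        k = len(enz.recognition)
        starts: set[int] = set()
        for p in diffs:
            lo = max(0, p - k + 1)
            hi = min(p, len(wild) - k)
            starts.update(range(lo, hi + 1))
        for s in sorted(starts):
            wild_hits.update(_sites_at(wild, enz, s))
            mut_hits.update(_sites_at(mutant, enz, s))
    added = sorted(mut_hits - wild_hits, key=lambda h: (h.position, h.enzyme, h.strand))
    removed = sorted(wild_hits - mut_hits, key=lambda h: (h.position, h.enzyme, h.strand))
    return SiteChangeSet(tuple(added), tuple(removed))


def matches_site_mode(changes: SiteChangeSet, mode: str) -> bool:
    """Does a change set satisfy a site-change requirement?"""
    if mode == "none":
        return True
    if mode == "added":
        return bool(changes.added)
    if mode == "removed":
        return bool(changes.removed)
    if mode == "either":
        return bool(changes.added or changes.removed)
    raise ValueError(f"bad site-change mode {mode!r}")


def annotate_candidates(
    candidates: Sequence, wild_target: str, enzymes: Sequence[RestrictionEnzyme]
) -> list:
    """Fill each knockout candidate's ``site_changes`` by diffing its full
    mutant target gene against the wild type.

    The whole construct being cloned is scanned, not just the overlap
    region: tracer digests are run on the complete plasmid insert.
    """
    from dataclasses import replace

    return [
        replace(c, site_changes=site_changes(wild_target, c.mutant_target, enzymes))
        for c in candidates
    ]


def filter_by_site_change(candidates: Sequence, mode: str = "none") -> list:
    """Keep candidates whose annotated SiteChangeSet satisfies ``mode``
    ('none' keeps all); order is preserved."""
    if mode == "none":
        return list(candidates)
    out = []
    for c in candidates:
        if c.site_changes is None:
            raise ValueError(
                "candidates must be annotated (annotate_candidates) before "
                "site-change filtering"
            )
        if matches_site_mode(c.site_changes, mode):
            out.append(c)
    return out
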