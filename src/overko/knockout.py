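"""Constrained knockout mutagenesis of overprinted genes.

Enumerates minimal nucleotide edits that knock out a target gene —
either by converting an internal codon into a premature stop (TAA, TAG
or TGA) or by destroying the ATG initiation codon — subject to exact
preservation of the overlapping gene's amino-acid sequence.  Degeneracy
of the genetic code is what makes such edits possible at all; the search
simply enumerates the per-codon edit space and keeps the edits whose
projection through the overlap geometry is synonymous in the other
reading frame.

Edits are confined to a single target codon per candidate: the knockout
question is inherently per-codon (one codon must become a stop), and
compound multi-codon mutants would multiply cloning burden without
adding reachable stops.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .overlap import OPPOSITE, SAME, GenePair, map_position
from .seqcore import (
    STANDARD_CODON_TABLE,
    STOP_CODONS,
    SequenceError,
    complement_base,
    is_unambiguous,
    translate,
    translate_codon,
)

__all__ = [
    "Edit",
    "Mutation",
    "KnockoutCandidate",
    "SearchParams",
    "KnockoutError",
    "PREMATURE_STOP",
    "START_LOSS",
    "ALTERNATE_START_CODONS",
    "HYDROPHOBIC",
    "stop_substitutions",
    "apply_mutation",
    "preserves_overlap_protein",
    "find_knockouts",
    "first_knockout_codon",
    "enumerate_neutral_mutations",
    "constrained_codon_mutagenesis",
]

PREMATURE_STOP = "premature_stop"
START_LOSS = "start_loss"

#: Near-cognate codons some viruses are known to initiate from; start-loss
#: candidates mutating ATG into one of these are annotated, not filtered.
ALTERNATE_START_CODONS = frozenset({"ACG", "GTG", "TTG", "CTG", "ATT", "ATA"})

#: Conventional hydrophobic amino-acid class used by the residue-class
#: mutagenesis helper.  A documented convention, not a physical constant.
HYDROPHOBIC = frozenset("AVLIMFWP")

_BASES = "ACGT"


class KnockoutError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Edit:
    """One single-base substitution in target coordinates."""

    pos: int
    wt: str
    mut: str

    def __post_init__(self):
        if self.wt == self.mut:
            raise ValueError("edit must change the base")
        if self.wt not in _BASES or self.mut not in _BASES:
            raise ValueError("edits must substitute concrete bases")

    def __str__(self) -> str:
        return f"{self.pos}:{self.wt}>{self.mut}"


@dataclass(frozen=True)
class Mutation:
    """A set of 1–3 substitutions confined to one target codon."""

    edits: tuple[Edit, ...]

    def __post_init__(self):
        edits = tuple(sorted(self.edits))
        object.__setattr__(self, "edits", edits)
        if not 1 <= len(edits) <= 3:
            raise ValueError("a mutation carries 1–3 edits")
        positions = [e.pos for e in edits]
        if len(set(positions)) != len(positions):
            raise ValueError("edit positions must be distinct")
        if len({p // 3 for p in positions}) != 1:
            raise ValueError("all edits must fall in the same target codon")

    @property
    def codon_index(self) -> int:
        return self.edits[0].pos // 3

    def __str__(self) -> str:
        return ";".join(str(e) for e in self.edits)


def apply_mutation(seq: str, mutation: Mutation) -> str:
    """Apply the substitutions to a sequence, verifying wild-type bases."""
    chars = list(seq)
    for e in mutation.edits:
        if chars[e.pos] != e.wt:
            raise KnockoutError(
                f"edit {e} does not match wild-type base {chars[e.pos]!r}"
            )
        chars[e.pos] = e.mut
    return "".join(chars)


@dataclass(frozen=True)
class KnockoutCandidate:
    """One designed knockout: the mutation, its effect class, and (once
    annotated) the restriction-site changes usable as cloning tracers."""

    mutation: Mutation
    kind: str  # PREMATURE_STOP | START_LOSS
    new_target_codon: str
    stop_codon_index: int | None = None  # None for start_loss
    alternate_start: bool = False  # start_loss only: mutant codon is a
    # near-cognate start some viruses can initiate from
    mutant_target: str = ""
    mutant_overlapping: str | None = None
    site_changes: "object | None" = None  # restriction.SiteChangeSet

    @property
    def codon_index(self) -> int:
        return self.mutation.codon_index

    def sort_key(self) -> tuple:
        # start-loss first at codon 0, then by the fully specified ordering
        return (
            self.codon_index,
            0 if self.kind == START_LOSS else 1,
            len(self.mutation.edits),
            self.new_target_codon,
        )


@dataclass(frozen=True)
class SearchParams:
    """Knobs of the knockout search.

    max_edits_per_codon
        1 (a point mutation, the default and the survey setting) to 3.
    codon_window
        Search only target codons with index < codon_window; None means the
        whole gene.  The 20-codon window is the usual truncation criterion:
        a protein cut to ≤20 residues almost certainly retains no function.
    allow_start_loss
        Also report mutations of the initiation codon.
    site_change_mode
        'none' | 'added' | 'removed' | 'either' — post-filter requiring a
        restriction-site tracer (applied by the caller/CLI via the
        restriction module).
    require_atg_start
        Refuse targets that do not begin with ATG unless disabled.
    """

    max_edits_per_codon: int = 1
    codon_window: int | None = None
    allow_start_loss: bool = True
    site_change_mode: str = "none"
    require_atg_start: bool = True

    def __post_init__(self):
        if not 1 <= self.max_edits_per_codon <= 3:
            raise ValueError("max_edits_per_codon must be 1–3")
        if self.codon_window is not None and self.codon_window < 1:
            raise ValueError("codon_window must be ≥ 1")
        if self.site_change_mode not in ("none", "added", "removed", "either"):
            raise ValueError(f"bad site_change_mode {self.site_change_mode!r}")


def _codon_edits(codon: str, codon_index: int, new_codon: str) -> Mutation:
    edits = tuple(
        Edit(3 * codon_index + k, codon[k], new_codon[k])
        for k in range(3)
        if codon[k] != new_codon[k]
    )
    return Mutation(edits)


def stop_substitutions(
    codon: str, max_edits: int = 1
) -> list[tuple[str, Mutation]]:
    """Stop codons reachable from ``codon`` with ≤ ``max_edits``
    substitutions, as ``(stop_codon, mutation-with-codon-local-positions)``.

    Ordered by (edit count ascending, stop codon alphabetical).  The codon
    may not already be a stop.
    """
    codon = codon.upper()
    if len(codon) != 3 or not is_unambiguous(codon):
        raise SequenceError(f"need an unambiguous 3-mer, got {codon!r}")
    if codon in STOP_CODONS:
        raise KnockoutError(f"codon {codon} is already a stop")
    out = []
    for stop in sorted(STOP_CODONS):
        dist = sum(a != b for a, b in zip(codon, stop))
        if 0 < dist <= max_edits:
            out.append((stop, _codon_edits(codon, 0, stop)))
    out.sort(key=lambda t: (len(t[1].edits), t[0]))
    return out


def _project_edits(
    pair: GenePair, mutation: Mutation
) -> list[tuple[int, str, str]]:
    """Project target edits onto the overlapping gene's sense strand as
    ``(overlap_pos, wt_base, new_base)``; edits outside the shared span are
    dropped (they are unconstrained)."""
    g = pair.geometry
    if g is None:
        return []
    ts, te = g.target_span
    projected = []
    for e in mutation.edits:
        if not ts <= e.pos < te:
            continue
        codon_i, off, strand = map_position(g, e.pos)
        opos = 3 * codon_i + off
        if strand == SAME:
            projected.append((opos, e.wt, e.mut))
        else:
            projected.append(
                (opos, complement_base(e.wt), complement_base(e.mut))
            )
    return projected


def preserves_overlap_protein(pair: GenePair, mutation: Mutation) -> bool:
    """True iff the mutation leaves the overlapping gene's amino-acid
    sequence exactly unchanged.

    Edits are projected through the overlap geometry (complemented on the
    opposite strand) and only the affected overlapping-gene codons are
    re-translated.  Edits falling entirely outside the shared span are
    unconstrained.
    """
    projected = _project_edits(pair, mutation)
    if not projected:
        return True
    ov = pair.overlapping
    by_codon: dict[int, list[tuple[int, str]]] = {}
    for opos, wt, new in projected:
        if ov[opos] != wt:
            raise KnockoutError(
                f"geometry inconsistency: overlapping base at {opos} is "
                f"{ov[opos]!r}, expected {wt!r}"
            )
        by_codon.setdefault(opos // 3, []).append((opos % 3, new))
    for ci, subs in by_codon.items():
        codon = list(ov[3 * ci : 3 * ci + 3])
        if len(codon) < 3:
            # partial codon at the gene edge never codes; unconstrained
            continue
        wt_aa = translate_codon("".join(codon))
        for off, new in subs:
            codon[off] = new
        if translate_codon("".join(codon)) != wt_aa:
            return False
    return True


def _mutant_overlapping(pair: GenePair, mutation: Mutation) -> str | None:
    if pair.overlapping is None:
        return None
    chars = list(pair.overlapping)
    for opos, _wt, new in _project_edits(pair, mutation):
        chars[opos] = new
    return "".join(chars)


def _neighbours(codon: str, max_edits: int) -> Iterable[str]:
    """All codons within Hamming distance 1..max_edits of ``codon``."""
    for positions in itertools.chain.from_iterable(
        itertools.combinations(range(3), d) for d in range(1, max_edits + 1)
    ):
        choices = [
            [b for b in _BASES if b != codon[p]] for p in positions
        ]
        for bases in itertools.product(*choices):
            c = list(codon)
            for p, b in zip(positions, bases):
                c[p] = b
            yield "".join(c)


def _make_candidate(
    pair: GenePair, mutation: Mutation, kind: str, new_codon: str
) -> KnockoutCandidate:
    return KnockoutCandidate(
        mutation=mutation,
        kind=kind,
        new_target_codon=new_codon,
        stop_codon_index=mutation.codon_index if kind == PREMATURE_STOP else None,
        alternate_start=(kind == START_LOSS and new_codon in ALTERNATE_START_CODONS),
        mutant_target=apply_mutation(pair.target, mutation),
        mutant_overlapping=_mutant_overlapping(pair, mutation),
    )


def _check_target(pair: GenePair, params: SearchParams) -> None:
    t = pair.target
    if not is_unambiguous(t):
        raise SequenceError("knockout search requires an unambiguous target")
    if params.require_atg_start and t[:3] != "ATG":
        raise KnockoutError(
            f"target does not start with ATG (found {t[:3]}); pass "
            "require_atg_start=False to search anyway"
        )
    internal = translate(t)[:-1]
    if "*" in internal:
        warnings.warn(
            f"wild-type target already contains an internal stop at codon "
            f"{internal.index('*')}; the input may be misannotated",
            stacklevel=3,
        )


def find_knockouts(
    pair: GenePair, params: SearchParams | None = None
) -> list[KnockoutCandidate]:
    """Enumerate every knockout of the target compatible with the
    overlapping gene's protein.

    Premature-stop candidates come from codons 1..codon_window-1 (codon 0
    is the start codon: a stop there is a start-loss and is handled
    separately); start-loss candidates are every ≤max_edits mutation of
    codon 0 away from ATG.  Each candidate's mutant overlapping protein is
    verified to equal the wild type's.  The returned list is sorted by
    (codon index, start-loss before stops, edit count, mutant codon), so
    reports are reproducible byte for byte.
    """
    params = params or SearchParams()
    _check_target(pair, params)
    t = pair.target
    n_codons = len(t) // 3
    window = n_codons if params.codon_window is None else min(params.codon_window, n_codons)

    candidates: list[KnockoutCandidate] = []

    if params.allow_start_loss:
        start = t[0:3]
        seen: set[str] = set()
        for new_codon in _neighbours(start, params.max_edits_per_codon):
            if new_codon == "ATG" or new_codon in seen:
                continue
            seen.add(new_codon)
            mut = _codon_edits(start, 0, new_codon)
            if preserves_overlap_protein(pair, mut):
                candidates.append(_make_candidate(pair, mut, START_LOSS, new_codon))

    for ci in range(1, window):
        codon = t[3 * ci : 3 * ci + 3]
        if codon in STOP_CODONS:
            continue  # already a stop (e.g. the natural terminator)
        for stop, local in stop_substitutions(codon, params.max_edits_per_codon):
            mut = Mutation(
                tuple(Edit(3 * ci + e.pos, e.wt, e.mut) for e in local.edits)
            )
            if preserves_overlap_protein(pair, mut):
                candidates.append(_make_candidate(pair, mut, PREMATURE_STOP, stop))

    candidates.sort(key=KnockoutCandidate.sort_key)
    return candidates


def first_knockout_codon(
    pair: GenePair,
    params: SearchParams | None = None,
    *,
    enzymes: Sequence | None = None,
) -> int | None:
    """Smallest codon index at which a premature stop can be introduced
    (start-loss excluded), or None if no codon is reachable.

    This is the per-gene survey statistic.  When ``params.site_change_mode``
    is not 'none', ``enzymes`` must be given and a candidate only counts if
    it adds/removes a recognition site accordingly.  Scans codons in
    ascending order and returns at the first hit, so it is cheap even on
    long genes.
    """
    params = params or SearchParams()
    _check_target(pair, params)
    t = pair.target
    n_codons = len(t) // 3
    window = n_codons if params.codon_window is None else min(params.codon_window, n_codons)

    need_sites = params.site_change_mode != "none"
    if need_sites and enzymes is None:
        raise ValueError("site_change_mode requires an enzyme table")
    if need_sites:
        from .restriction import matches_site_mode, site_changes

    for ci in range(1, window):
        codon = t[3 * ci : 3 * ci + 3]
        if codon in STOP_CODONS:
            continue
        for _stop, local in stop_substitutions(codon, params.max_edits_per_codon):
            mut = Mutation(
                tuple(Edit(3 * ci + e.pos, e.wt, e.mut) for e in local.edits)
            )
            if not preserves_overlap_protein(pair, mut):
                continue
            if need_sites:
                changes = site_changes(t, apply_mutation(t, mut), enzymes)
                if not matches_site_mode(changes, params.site_change_mode):
                    continue
            return ci
    return None


def enumerate_neutral_mutations(pair: GenePair) -> list[Mutation]:
    """All single-base substitutions inside the shared span that leave the
    overlapping gene's protein unchanged, regardless of their effect on
    the target."""
    g = pair.geometry
    if g is None:
        return []
    out = []
    for pos in range(*g.target_span):
        wt = pair.target[pos]
        for b in _BASES:
            if b == wt:
                continue
            mut = Mutation((Edit(pos, wt, b),))
            if preserves_overlap_protein(pair, mut):
                out.append(mut)
    return out


def constrained_codon_mutagenesis(
    pair: GenePair,
    from_class: Callable[[str], bool],
    to_class: Callable[[str], bool],
    params: SearchParams | None = None,
) -> list[KnockoutCandidate]:
    """Residue-class mutagenesis: for every target codon whose amino acid
    satisfies ``from_class``, every codon reachable with ≤ max_edits edits
    whose amino acid satisfies ``to_class`` and which preserves the
    overlapping protein.

    Predicates receive a one-letter amino acid ('*' for stop), so e.g.
    ``from_class=lambda aa: aa == 'S', to_class=lambda aa: aa == '*'``
    specialises to the premature-stop search over serine codons.  The
    bundled :data:`HYDROPHOBIC` set supports hydrophobic→non-hydrophobic
    designs.
    """
    params = params or SearchParams(require_atg_start=False)
    t = pair.target
    if not is_unambiguous(t):
        raise SequenceError("mutagenesis requires an unambiguous target")
    n_codons = len(t) // 3
    window = n_codons if params.codon_window is None else min(params.codon_window, n_codons)

    records = []
    for ci in range(window):
        codon = t[3 * ci : 3 * ci + 3]
        if not from_class(translate_codon(codon)):
            continue
        seen: set[str] = set()
        for new_codon in _neighbours(codon, params.max_edits_per_codon):
            if new_codon in seen:
                continue
            seen.add(new_codon)
            if not to_class(translate_codon(new_codon)):
                continue
            mut = _codon_edits(codon, ci, new_codon)
            if preserves_overlap_protein(pair, mut):
                kind = PREMATURE_STOP if new_codon in STOP_CODONS else "substitution"
                rec = KnockoutCandidate(
                    mutation=mut,
                    kind=kind,
                    new_target_codon=new_codon,
                    stop_codon_index=ci if kind == PREMATURE_STOP else None,
                    mutant_target=apply_mutation(t, mut),
                    mutant_overlapping=_mutant_overlapping(pair, mut),
                )
                records.append(rec)
    records.sort(
        key=lambda c: (c.codon_index, len(c.mutation.edits), c.new_target_codon)
    )
    return records
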