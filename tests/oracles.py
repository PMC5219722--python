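"""Independent brute-force oracles used to cross-check the search code.

These deliberately avoid the package's own bookkeeping: mutant
overlapping genes are rebuilt by splicing sequence chunks through the
geometry (not via map_position), proteins are compared by full-length
translation, and degenerate patterns are expanded to concrete sets and
matched by string equality.
"""

from __future__ import annotations

import itertools

from overko.overlap import GenePair
from overko.seqcore import IUPAC_CODES, STOP_CODONS, reverse_complement, translate

BASES = "ACGT"


def splice_mutant_overlapping(pair: GenePair, mutant_target: str) -> str:
    """Rebuild the overlapping gene implied by a mutant target by splicing
    the mutant's shared chunk into the wild-type overlapping gene."""
    g = pair.geometry
    ts, te = g.target_span
    os_, oe = g.overlap_span
    chunk = mutant_target[ts:te]
    if g.strand == "opposite":
        chunk = reverse_complement(chunk)
    return pair.overlapping[:os_] + chunk + pair.overlapping[oe:]


def overlap_protein_preserved(pair: GenePair, mutant_target: str) -> bool:
    if pair.overlapping is None:
        return True
    mutant_ov = splice_mutant_overlapping(pair, mutant_target)
    return translate(mutant_ov) == translate(pair.overlapping)


def all_single_base_variants(seq: str):
    """Yield (pos, new_base, variant) over all 3L single-base substitutions
    (9L including the identity-excluded alternatives per position is the
    conventional count 3 per position x L positions x 3 frames collapsed;
    here: every position, every non-wild base)."""
    for pos in range(len(seq)):
        for b in BASES:
            if b == seq[pos]:
                continue
            yield pos, b, seq[:pos] + b + seq[pos + 1 :]


def brute_force_knockouts(pair: GenePair, window: int | None = None) -> set:
    """Every single-substitution knockout, as tuples
    ``(kind, pos, new_base, new_codon)`` — the oracle for find_knockouts
    with max_edits_per_codon=1."""
    t = pair.target
    n_codons = len(t) // 3
    window = n_codons if window is None else min(window, n_codons)
    found = set()
    for pos, b, variant in all_single_base_variants(t):
        ci = pos // 3
        wt_codon = t[3 * ci : 3 * ci + 3]
        new_codon = variant[3 * ci : 3 * ci + 3]
        if ci == 0:
            if new_codon != "ATG" and overlap_protein_preserved(pair, variant):
                found.add(("start_loss", pos, b, new_codon))
        elif ci < window:
            if (
                wt_codon not in STOP_CODONS
                and new_codon in STOP_CODONS
                and overlap_protein_preserved(pair, variant)
            ):
                found.add(("premature_stop", pos, b, new_codon))
    return found


def brute_force_first_stop(pair: GenePair, window: int | None = None) -> int | None:
    stops = [
        pos // 3
        for kind, pos, _b, _c in brute_force_knockouts(pair, window)
        if kind == "premature_stop"
    ]
    return min(stops) if stops else None


def brute_force_neutral(pair: GenePair) -> set:
    """All single-base substitutions inside the shared span preserving the
    overlapping protein, as (pos, new_base)."""
    ts, te = pair.geometry.target_span
    out = set()
    for pos, b, variant in all_single_base_variants(pair.target):
        if ts <= pos < te and overlap_protein_preserved(pair, variant):
            out.add((pos, b))
    return out


def expand_pattern(pattern: str) -> set[str]:
    """Concrete sequence set of a degenerate pattern (independent of the
    package's expander)."""
    options = [sorted(IUPAC_CODES[ch]) for ch in pattern]
    return {"".join(p) for p in itertools.product(*options)}


def brute_force_sites(seq: str, enzymes) -> set:
    """Expand-and-scan oracle for find_sites: all (enzyme, position, strand)
    occurrences on both strands, palindromes reported once."""
    hits = set()
    for enz in enzymes:
        k = len(enz.recognition)
        fwd = expand_pattern(enz.recognition)
        rev = expand_pattern(reverse_complement(enz.recognition))
        palindromic = fwd == rev
        for s in range(len(seq) - k + 1):
            window = seq[s : s + k]
            if window in fwd:
                hits.add((enz.name, s, "forward"))
            if not palindromic and window in rev:
                hits.add((enz.name, s, "reverse"))
    return hits
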