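"""Bundled example data.

The worked example used throughout the documentation and tests is a
small synthetic overprinted gene pair.
"""

from __future__ import annotations

from .overlap import GenePair

__all__ = ["EXAMPLE_TARGET", "EXAMPLE_OVERLAPPING", "synthetic_example_pair"]

#: Target gene (7 codons, M G P S K H *); to be knocked out.
EXAMPLE_TARGET = "ATGGGGCCCTCAAAACATTAA"

#: Overlapping gene (10 codons, M Y G A L K T L T *); its protein must be
#: preserved.  The target sits wholly inside it at offset 4, same strand,
#: one frame off.
EXAMPLE_OVERLAPPING = "ATGTATGGGGCCCTCAAAACATTAACATAA"


def synthetic_example_pair() -> GenePair:
    """The package's canonical worked example: a synthetic overprinted pair.

    Both genes are valid ORFs sharing the full 21 nt of the target on the
    same strand in a shifted frame.  The pair is constructed so that its
    knockout search has a small, hand-checkable answer:

    * the only start-loss candidate is ATG→ACG (target position 1), which
      turns the overlapping gene's TAT codon into TAC — both tyrosine;
    * the earliest premature stop is at target codon index 3, where the
      serine codon TCA can become TGA or TAA while the overlapping gene's
      leucine codon CTC becomes CTG or CTA — all leucine;
    * no stop codon is reachable by a single substitution at codons 1–2.

    Returns the pair with its geometry auto-detected.
    """
    return GenePair.detect(EXAMPLE_TARGET, EXAMPLE_OVERLAPPING)
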