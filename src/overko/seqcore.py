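"""Core nucleic-acid primitives: alphabet, codon table, translation,
reverse complement, degenerate (IUPAC) matching and strict FASTA I/O.

Sequences are plain Python strings over the 15-letter IUPAC nucleotide
alphabet, validated and normalised (uppercase, U→T) at the package
boundary by :func:`clean_sequence`.  Keeping the container a ``str``
matches how the rest of the package (and most sequence tooling) slices
and rebuilds coding sequences.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, TextIO

__all__ = [
    "IUPAC_CODES",
    "STANDARD_CODON_TABLE",
    "STOP_CODONS",
    "FastaRecord",
    "SequenceError",
    "FastaError",
    "clean_sequence",
    "is_unambiguous",
    "complement_base",
    "reverse_complement",
    "translate",
    "translate_codon",
    "iupac_match",
    "expand_degenerate",
    "read_fasta",
    "write_fasta",
]


class SequenceError(ValueError):
    """Raised for residues outside the IUPAC nucleotide alphabet or for
    operations applied to sequences that violate their preconditions."""


class FastaError(ValueError):
    """Raised on malformed FASTA input; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


#: Degeneracy sets of the IUPAC nucleotide one-letter codes.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

STOP_CODONS = ("TAA", "TAG", "TGA")

# The standard genetic code. Bundled as a plain dict so an alternative
# code can be passed to translate() programmatically.
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
STANDARD_CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: _AMINO[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}
assert len(STANDARD_CODON_TABLE) == 64
assert sum(1 for aa in STANDARD_CODON_TABLE.values() if aa == "*") == 3


def clean_sequence(seq: str, *, what: str = "sequence") -> str:
    """Normalise and validate a nucleotide sequence.

    Uppercases, converts RNA U to T, and rejects any residue outside the
    IUPAC alphabet (including gaps and internal whitespace) with the
    0-based offending position in the message.
    """
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in IUPAC_CODES:
            raise SequenceError(
                f"invalid residue {ch!r} at position {i} in {what}"
            )
    return s


def is_unambiguous(seq: str) -> bool:
    """True if every residue is a concrete base A/C/G/T."""
    return all(ch in "ACGT" for ch in seq)


def complement_base(base: str) -> str:
    if base not in IUPAC_CODES:
        raise SequenceError(f"invalid residue {base!r}")
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement; ambiguity codes map to their
    complements (R↔Y, K↔M, S↔S, W↔W, B↔V, D↔H, N↔N)."""
    s = clean_sequence(seq)
    return s.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str, table: dict[str, str] | None = None) -> str:
    """One-letter amino acid of a single unambiguous codon ('*' = stop)."""
    table = table or STANDARD_CODON_TABLE
    if len(codon) != 3:
        raise SequenceError(f"codon must be 3 nt, got {codon!r}")
    aa = table.get(codon)
    if aa is None:
        raise SequenceError(f"cannot translate ambiguous codon {codon!r}")
    return aa


def translate(seq: str, table: dict[str, str] | None = None) -> str:
    """Translate frame 0, codon by codon, using the standard genetic code
    unless another table is supplied.

    Stop codons emit ``*`` and translation continues, so every stop in the
    frame is visible — knockout verification depends on full-length
    translation.  A trailing partial codon (<3 nt) is ignored.  Ambiguous
    bases inside a translated codon are an error.
    """
    s = clean_sequence(seq)
    table = table or STANDARD_CODON_TABLE
    protein = []
    for i in range(0, len(s) - len(s) % 3, 3):
        protein.append(translate_codon(s[i : i + 3], table))
    return "".join(protein)


def iupac_match(pattern: str, window: str) -> bool:
    """True iff ``window`` (unambiguous) matches the possibly degenerate
    ``pattern`` position by position under the IUPAC degeneracy sets."""
    if len(pattern) != len(window):
        raise SequenceError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    for p, w in zip(pattern, window):
        if w not in IUPAC_CODES[p]:
            return False
    return True


def expand_degenerate(pattern: str) -> list[str]:
    """All concrete sequences matching a degenerate pattern."""
    seqs = [""]
    for ch in clean_sequence(pattern):
        seqs = [s + b for s in seqs for b in sorted(IUPAC_CODES[ch])]
    return seqs


@dataclass(frozen=True)
class FastaRecord:
    """One FASTA record: ``>identifier description`` plus its sequence."""

    identifier: str
    description: str
    sequence: str

    def __post_init__(self):
        if not self.identifier:
            raise FastaError("record has an empty identifier")
        if len(self.sequence) < 1:
            raise FastaError(f"record {self.identifier!r} has no sequence")

    @property
    def header(self) -> str:
        return (
            f"{self.identifier} {self.description}"
            if self.description
            else self.identifier
        )


def read_fasta(source: TextIO | str) -> list[FastaRecord]:
    """Parse FASTA text into records.

    Accepts wrapped and unwrapped bodies and CRLF line endings. Gap
    characters or whitespace inside a body line are rejected — coding
    sequences must be contiguous. Errors carry 1-based line numbers.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    records: list[FastaRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(at_line: int):
        if header is None:
            return
        if not chunks:
            raise FastaError(
                f"record {header.split()[0]!r} has no sequence lines",
                line=header_line,
            )
        ident, _, desc = header.partition(" ")
        records.append(FastaRecord(ident, desc.strip(), "".join(chunks)))

    lineno = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush(lineno)
            header = line[1:].strip()
            if not header:
                raise FastaError("empty header", line=lineno)
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise FastaError(
                    "sequence data before any '>' header", line=lineno
                )
            try:
                chunks.append(clean_sequence(line, what="FASTA body"))
            except SequenceError as e:
                raise FastaError(str(e), line=lineno) from e
    if header is None:
        raise FastaError("no FASTA records found", line=lineno or 1)
    flush(lineno)
    return records


def write_fasta(
    records: Iterable[FastaRecord], sink: TextIO | None = None, width: int = 70
) -> str:
    """Write records as FASTA with 70-column wrapped sequence lines.

    Returns the text; also writes it to ``sink`` when given.
    """
    out = []
    for rec in records:
        out.append(f">{rec.header}\n")
        for i in range(0, len(rec.sequence), width):
            out.append(rec.sequence[i : i + width] + "\n")
    text = "".join(out)
    if sink is not None:
        sink.write(text)
    return text
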