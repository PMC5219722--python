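"""Seeded generator of synthetic overprinted gene pairs, and a desk-scale
survey of first-premature-stop positions over such pairs.

The generator plants a known :class:`~overko.overlap.OverlapGeometry` by
construction — a target ORF spliced into a second, longer ORF read in a
shifted frame (same strand) or on the opposite strand — so every stage
of the pipeline can be tested round-trip without any external data.
Interior codons are sampled uniformly over the 61 non-stop codons (under
the default uniform base composition), which is what the closed-form
oracle :func:`unconstrained_knockable_probability` assumes.

The survey aggregates, over many generated pairs, where the first
single-substitution premature stop can be placed with and without
requiring a restriction-site tracer.  Synthetic pairs carry no codon-
usage bias, no GC skew and no annotation noise, so survey *fractions*
are properties of the generator, not of any real genome collection;
what carries over to real data are the orderings and invariances the
tests assert (adding constraints never helps, distributions are stable
across seeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np

from .knockout import SearchParams, first_knockout_codon
from .overlap import OPPOSITE, SAME, GenePair, OverlapGeometry
from .seqcore import STOP_CODONS, reverse_complement, translate

__all__ = [
    "SimParams",
    "SurveySummary",
    "generate_pair",
    "generate_pairs",
    "run_survey",
    "unconstrained_knockable_probability",
    "write_survey_tsv",
    "write_histograms_tsv",
]

_BASES = "ACGT"
_STOPS = set(STOP_CODONS)


@dataclass(frozen=True)
class SimParams:
    """Conditions under which synthetic pairs are generated.

    n_pairs
        Number of pairs per survey.
    target_codons
        Inclusive range of target gene lengths, in codons including the
        terminator (viral accessory genes are typically tens to a few
        hundred codons; the default 30–90 keeps desk-scale surveys fast
        while leaving room for first-stop positions well beyond 20).
    overlap_frac
        Inclusive range of the fraction of the target covered by the
        overlap.  A sampled fraction of 0 plants no overlap at all (the
        unconstrained limit).
    p_opposite
        Probability that the overlapping gene runs on the opposite strand.
    same_frame_shifts
        Frame shifts (phase of the shared region in the overlapping gene's
        codon grid) drawn uniformly for same-strand pairs; 0 would put the
        two genes in the same frame, which is not overprinting, so the
        default is {1, 2}.
    base_probs
        Per-base sampling probabilities (A, C, G, T); uniform by default.
    """

    n_pairs: int = 1000
    target_codons: tuple[int, int] = (30, 90)
    overlap_frac: tuple[float, float] = (0.4, 0.9)
    p_opposite: float = 0.3
    same_frame_shifts: tuple[int, ...] = (1, 2)
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be ≥ 0")
        lo, hi = self.target_codons
        if not 10 <= lo <= hi:
            raise ValueError("target length must span ≥ 10 codons")
        flo, fhi = self.overlap_frac
        if not 0.0 <= flo <= fhi <= 1.0:
            raise ValueError("overlap_frac must lie in [0, 1]")
        if not 0.0 <= self.p_opposite <= 1.0:
            raise ValueError("p_opposite is a probability")
        if not set(self.same_frame_shifts) <= {0, 1, 2}:
            raise ValueError("frame shifts must be in {0, 1, 2}")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")


def _random_codon(rng: np.random.Generator, probs, *, allow_stop: bool = False) -> str:
    while True:
        codon = "".join(rng.choice(list(_BASES), size=3, p=probs))
        if allow_stop or codon not in _STOPS:
            return codon


def _random_orf(rng: np.random.Generator, n_codons: int, probs) -> str:
    """ATG + (n-2) random non-stop codons + one random stop codon."""
    body = [_random_codon(rng, probs) for _ in range(n_codons - 2)]
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + "".join(body) + stop


def _is_valid_orf(seq: str) -> bool:
    if len(seq) % 3 or len(seq) < 9 or not seq.startswith("ATG"):
        return False
    prot = translate(seq)
    return prot.endswith("*") and "*" not in prot[:-1]


def _complement(b: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[b]


def _build_overlapping(
    rng: np.random.Generator,
    shared: str,
    frame_shift: int,
    probs,
) -> tuple[str, int] | None:
    """Embed ``shared`` (already strand-adjusted) in a fresh ORF whose codon
    phase at the insertion point is ``frame_shift``.

    Returns (overlapping gene, offset of shared region) or None when the
    shared bases force a stop codon that pads cannot repair.
    """
    # left pad: starts with ATG, ends on the required phase, ≥ 2 codons so
    # the overlap never touches the start codon
    left_len = 6 + frame_shift
    right_len = 3 + (-(left_len + len(shared))) % 3 + 3  # filler + stop, ≥ 1 codon
    for _ in range(40):
        left = "ATG" + "".join(
            rng.choice(list(_BASES), size=left_len - 3, p=probs)
        )
        filler = "".join(rng.choice(list(_BASES), size=right_len - 3, p=probs))
        stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
        gene = list(left + shared + filler + stop)
        n = len(gene)
        assert n % 3 == 0
        ok = True
        for ci in range(1, n // 3 - 1):  # interior codons only
            codon = gene[3 * ci : 3 * ci + 3]
            if "".join(codon) not in _STOPS:
                continue
            # repair: resample any base of this codon lying in a pad
            pad_positions = [
                3 * ci + k
                for k in range(3)
                if not left_len <= 3 * ci + k < left_len + len(shared)
            ]
            repaired = False
            for _attempt in range(20):
                if not pad_positions:
                    break
                p = pad_positions[rng.integers(len(pad_positions))]
                gene[p] = _BASES[rng.integers(4)]
                if "".join(gene[3 * ci : 3 * ci + 3]) not in _STOPS:
                    repaired = True
                    break
            if not repaired:
                ok = False
                break
        if ok and _is_valid_orf("".join(gene)):
            if "".join(gene[left_len : left_len + len(shared)]) == shared:
                return "".join(gene), left_len
    return None


def generate_pair(params: SimParams, rng: np.random.Generator) -> GenePair:
    """Draw one synthetic overprinted pair with planted geometry.

    The target is a valid ORF (ATG start, single terminal stop); the
    overlapping gene, read over its own full length, is also a valid ORF
    containing the strand-adjusted shared region at a planted offset.
    Construction is by repair sampling (offending codons are resampled)
    and is reproducible from the generator state.
    """
    probs = np.asarray(params.base_probs)
    lo, hi = params.target_codons
    for _restart in range(200):
        n_codons = int(rng.integers(lo, hi + 1))
        target = _random_orf(rng, n_codons, probs)
        tlen = len(target)

        frac = float(rng.uniform(*params.overlap_frac))
        ov_len = int(round(frac * tlen))
        if ov_len < 1:
            return GenePair(target)  # unconstrained limit: no overlap
        ov_len = min(ov_len, tlen)

        s_t = int(rng.integers(0, tlen - ov_len + 1))
        opposite = bool(rng.random() < params.p_opposite)
        if opposite:
            frame_shift = int(rng.integers(0, 3))
        else:
            frame_shift = int(
                params.same_frame_shifts[rng.integers(len(params.same_frame_shifts))]
            )
            # avoid the degenerate same-frame case (codon grids coincide)
            if (frame_shift - s_t) % 3 == 0:
                s_t = s_t + 1 if s_t + 1 + ov_len <= tlen else s_t - 1
                if s_t < 0:
                    continue

        shared_target = target[s_t : s_t + ov_len]
        shared = (
            reverse_complement(shared_target) if opposite else shared_target
        )
        built = _build_overlapping(rng, shared, frame_shift, probs)
        if built is None:
            continue
        overlapping, off = built

        # keep the planted match maximal: the flanking bases must not extend it
        overlapping = _trim_extensions(
            rng, target, overlapping, s_t, off, ov_len, opposite
        )
        if overlapping is None:
            continue

        geometry = OverlapGeometry(
            target_span=(s_t, s_t + ov_len),
            overlap_span=(off, off + ov_len),
            strand=OPPOSITE if opposite else SAME,
            frame_shift=off % 3,
        )
        return GenePair(target, overlapping, geometry)
    raise RuntimeError("could not satisfy the generation parameters")


def _trim_extensions(
    rng: np.random.Generator,
    target: str,
    overlapping: str,
    s_t: int,
    off: int,
    ov_len: int,
    opposite: bool,
) -> str | None:
    """Resample overlapping-gene pad bases that would extend the planted
    match by chance, so overlap detection recovers the span exactly."""
    gene = list(overlapping)
    n = len(gene)

    def fix(opos: int, forbidden: str) -> bool:
        # resample gene[opos] away from `forbidden`, keeping the ORF valid
        if not 0 <= opos < n:
            return True
        if gene[opos] != forbidden:
            return True
        ci = opos // 3
        if ci == 0 or ci == n // 3 - 1:
            return False  # cannot touch start/stop codons
        for _ in range(20):
            b = _BASES[rng.integers(4)]
            if b == forbidden:
                continue
            old = gene[opos]
            gene[opos] = b
            if "".join(gene[3 * ci : 3 * ci + 3]) not in _STOPS:
                return True
            gene[opos] = old
        return False

    if not opposite:
        if s_t > 0 and not fix(off - 1, target[s_t - 1]):
            return None
        if s_t + ov_len < len(target) and not fix(off + ov_len, target[s_t + ov_len]):
            return None
    else:
        # overlapping[off + k] = complement(target[s_t + ov_len - 1 - k])
        if s_t + ov_len < len(target) and not fix(
            off - 1, _complement(target[s_t + ov_len])
        ):
            return None
        if s_t > 0 and not fix(off + ov_len, _complement(target[s_t - 1])):
            return None
    return "".join(gene)


def generate_pairs(params: SimParams) -> list[GenePair]:
    """All ``params.n_pairs`` pairs from the seeded stream."""
    rng = np.random.default_rng(params.seed)
    return [generate_pair(params, rng) for _ in range(params.n_pairs)]


@dataclass
class SurveySummary:
    """Aggregate of first-premature-stop positions over a pair set.

    ``first_stop`` / ``first_stop_with_site`` hold one entry per pair:
    the first codon index at which a single substitution can plant a stop
    (None when no codon is reachable), without and with the requirement
    that the mutation also add or remove a restriction site.
    """

    n_pairs: int
    first_stop: list[int | None] = field(default_factory=list)
    first_stop_with_site: list[int | None] = field(default_factory=list)
    gene_codons: list[int] = field(default_factory=list)

    def _stats(self, firsts: list[int | None]) -> dict:
        hit = [f for f in firsts if f is not None]
        ratios = [
            f / c for f, c in zip(firsts, self.gene_codons) if f is not None
        ]
        return {
            "n": self.n_pairs,
            "fraction_any": len(hit) / self.n_pairs if self.n_pairs else None,
            "fraction_lt20": (
                sum(f < 20 for f in hit) / self.n_pairs if self.n_pairs else None
            ),
            "index_histogram": np.bincount(hit).tolist() if hit else [],
            "ratio_values": ratios,
        }

    @property
    def unconstrained(self) -> dict:
        return self._stats(self.first_stop)

    @property
    def with_site_change(self) -> dict:
        return self._stats(self.first_stop_with_site)


def run_survey(
    params: SimParams,
    search: SearchParams | None = None,
    enzymes: Sequence | None = None,
) -> SurveySummary:
    """Generate pairs and record where the first premature stop can go,
    both without any tracer requirement and requiring a restriction-site
    change ('either' mode).

    ``search.codon_window`` defaults to the whole gene so the full
    first-stop distribution (not just the first-20-codons fraction) is
    observable.
    """
    search = search or SearchParams()
    if enzymes is None:
        from .restriction import load_enzymes

        enzymes = load_enzymes("builtin")
    base = SearchParams(
        max_edits_per_codon=search.max_edits_per_codon,
        codon_window=search.codon_window,
        allow_start_loss=False,
        site_change_mode="none",
    )
    with_site = SearchParams(
        max_edits_per_codon=search.max_edits_per_codon,
        codon_window=search.codon_window,
        allow_start_loss=False,
        site_change_mode="either",
    )

    summary = SurveySummary(n_pairs=params.n_pairs)
    rng = np.random.default_rng(params.seed)
    for _ in range(params.n_pairs):
        pair = generate_pair(params, rng)
        summary.gene_codons.append(len(pair.target) // 3)
        summary.first_stop.append(first_knockout_codon(pair, base))
        summary.first_stop_with_site.append(
            first_knockout_codon(pair, with_site, enzymes=enzymes)
        )
    return summary


def unconstrained_knockable_probability(
    window: int = 20, gene_codons: int | None = None
) -> float:
    """Closed-form probability that a random ORF (interior codons uniform
    over the 61 non-stop codons) has at least one codon with index in
    [1, window) that is a single substitution away from a stop codon.

    This is the no-overlap limit of the survey's fraction-knockable
    statistic: without an overlap constraint, a codon is knockable iff it
    is Hamming-1 from TAA, TAG or TGA.  When ``gene_codons`` is given, only
    the interior codons 1..gene_codons-2 that fall inside the window count.
    """
    near_stop = 0
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                codon = b1 + b2 + b3
                if codon in _STOPS:
                    continue
                if any(
                    sum(a != b for a, b in zip(codon, s)) == 1 for s in STOP_CODONS
                ):
                    near_stop += 1
    p_codon = near_stop / 61
    n_eligible = window - 1
    if gene_codons is not None:
        n_eligible = min(window - 1, max(gene_codons - 2, 0))
    return 1.0 - (1.0 - p_codon) ** n_eligible


def write_survey_tsv(summary: SurveySummary, sink: TextIO) -> None:
    """Headline survey numbers as a two-column TSV."""
    rows = []
    for label, stats in (
        ("no_site_requirement", summary.unconstrained),
        ("site_change_required", summary.with_site_change),
    ):
        rows.append((f"{label}.n_pairs", stats["n"]))
        rows.append((f"{label}.fraction_any_stop", stats["fraction_any"]))
        rows.append((f"{label}.fraction_first_stop_lt20", stats["fraction_lt20"]))
    sink.write("statistic\tvalue\n")
    for key, val in rows:
        sink.write(f"{key}\t{'' if val is None else val}\n")


def write_histograms_tsv(summary: SurveySummary, sink: TextIO, ratio_bins: int = 20) -> None:
    """First-stop histograms (absolute codon index and unit-length ratio),
    with and without the site-change requirement, as long-format TSV."""
    sink.write("panel\tbin\tcount\n")
    for label, stats in (
        ("index", summary.unconstrained),
        ("index_site_change", summary.with_site_change),
    ):
        for idx, count in enumerate(stats["index_histogram"]):
            if count:
                sink.write(f"{label}\t{idx}\t{count}\n")
    edges = np.linspace(0.0, 1.0, ratio_bins + 1)
    for label, stats in (
        ("ratio", summary.unconstrained),
        ("ratio_site_change", summary.with_site_change),
    ):
        counts, _ = np.histogram(stats["ratio_values"], bins=edges)
        for k, count in enumerate(counts):
            if count:
                sink.write(f"{label}\t{edges[k]:.2f}-{edges[k + 1]:.2f}\t{count}\n")
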