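# Methods

## The design problem

Two genes overprint when they occupy the same nucleotide span in different
reading frames (same strand, phase 1 or 2) or on opposite strands. The
*target* gene is the one to be knocked out; the *overlapping* gene's
polypeptide must be preserved exactly. A knockout is either a **premature
stop** — an internal codon of the target converted to TAA, TAG or TGA — or
a **start loss** — the ATG initiation codon converted to anything else.
Both are searched per codon: a candidate is a set of 1–3 substitutions
confined to one target codon. Compound multi-codon designs are out of
scope by construction; they complicate cloning without making additional
stop codons reachable at any single position.

A candidate is accepted iff every overlapping-gene codon it touches, after
projecting the edits through the overlap geometry (reverse-complementing
on the opposite strand), translates to the same amino acid as the wild
type. Preservation is *exact identity* of the protein: conservative
substitutions do not count. The hot path re-translates only the touched
codons; the emitted candidate additionally carries the full mutant
overlapping sequence, and tests verify full-length protein identity
independently of the search's bookkeeping.

Two caveats are annotated rather than decided by the software: start-loss
candidates whose mutant codon is a near-cognate start (ACG, GTG, TTG, CTG,
ATT, ATA) are flagged, since some viruses initiate from such codons; and a
wild-type target that already contains an internal stop triggers a warning
(not an error), since annotation errors are common in harvested genomes
and the caller may want the search anyway.

## Overlap geometry

Detection finds the longest exact common substring between the target and
either strand of the overlapping gene (a vectorised dynamic programme over
the match matrix). Exactness is deliberate: the two inputs describe the
same genomic region, so a mismatch is user error and must surface rather
than be smoothed over. Contracts:

* minimum overlap length 15 nt (configurable) — below that, chance matches
  between unrelated genes become likely;
* same-strand matches win ties against opposite-strand matches;
* a non-unique maximal match is an error instructing the caller to pass
  the geometry explicitly (repeated sequence cannot be resolved
  automatically);
* coordinates are 0-based half-open; codon indices 0-based (the start
  codon is codon 0); `frame_shift` is the overlapping gene's codon phase
  at the start of the shared region, i.e. `overlap_span.start % 3`.

Spliced overlaps, overlaps with indels, and three genes sharing one locus
are not modelled; a gene overlapping two partners is analysed as two
pairs.

## Search order and determinism

Candidates are sorted by (codon index, start-loss before premature-stop,
edit count, mutant codon alphabetically), making reports byte-reproducible.
Codon 0 is excluded from the premature-stop scan so the two knockout kinds
stay disjoint. Codons that are already stops (including the natural
terminator) are skipped. `first_knockout_codon` — the survey statistic —
scans codons in ascending order and returns at the first hit, optionally
requiring a restriction-site change, which keeps desk-scale surveys cheap.

## Restriction-site tracers

Recognition sites are 4–8 nt IUPAC-degenerate patterns matched on both
strands (palindromes reported once); positions are always forward-strand
coordinates of the scanned sequence. Site *changes* between a wild-type
and mutant target are the set difference of their site lists keyed by
(enzyme, position, strand). Because the model is substitution-only, any
gained or lost site must cover a changed base, so the implementation scans
only windows around the edits; the contract — and the tests — remain
whole-sequence set difference. The whole mutant target gene is scanned
(not just the overlap region): tracer digests are run on the complete
construct. The bundled table lists ~65 common commercial enzymes and is
versioned in the repository; there is no live database lookup. Cut
positions, overhangs, methylation sensitivity and isoschizomer grouping
are out of scope.

## Synthetic pair generator

`overko.synthgen` plants a known geometry by construction: a target ORF
(ATG start, no internal stop, single terminal stop) is spliced into a
fresh overlapping ORF at a chosen offset, phase and strand. Repair
sampling resamples pad bases (or, where impossible, restarts) until the
overlapping frame is stop-free over its interior, and flanking bases are
resampled so the planted match cannot extend by chance — detection must
recover the geometry *exactly*. Defaults: target length uniform on 30–90
codons (long enough that first-stop positions beyond codon 20 are
observable, short enough for desk-scale surveys), overlap fraction uniform
on 0.4–0.9 of the target, opposite-strand probability 0.3, same-strand
frame shifts 1 and 2 equiprobable, uniform base composition. All sampling
flows from one `numpy` `Generator`, so a seed fixes the pair set.

What the generator emulates is the *structure* of overprinted gene pairs,
not their statistics: real viral genes carry codon-usage bias, GC skew,
conserved motifs and annotation noise, none of which are modelled. Survey
fractions on synthetic pairs therefore say nothing quantitative about any
real genome collection; what passing tests establish is correctness of
the search (oracle equivalence), exact geometry recovery, and the
direction of constraint effects.

## Survey and its oracles

`run_survey` records, per generated pair, the first premature-stop codon
index with and without requiring a restriction-site change ('either'
mode), and aggregates: fraction of pairs knockable at all, fraction with
first stop before codon 20, histograms of the first-stop index and of the
index/gene-length ratio. Three properties are asserted at acceptance
scale:

* **Monotonicity** — requiring a site change can only delay or remove the
  first stop, never advance it (checked per pair on a fixed set).
* **Seed stability** — headline fractions agree across independent seeds
  within 3 binomial standard errors at n = 1000.
* **Closed-form limit** — with overlap fraction 0 the target is
  unconstrained, and the probability that some codon in 1..19 is a single
  substitution from a stop has the closed form
  `1 − (1 − k/61)^19`, where `k = 18` is the number of non-stop codons at
  Hamming distance 1 from a stop and interior codons are uniform over the
  61 non-stop codons (guaranteed by the generator under uniform base
  composition). The simulated fraction at n = 2000 must agree within 3
  standard errors.

## Numerical and edge-case choices

* Input is uppercased and RNA U normalised to T; gaps and internal
  whitespace in FASTA bodies are rejected, not stripped — coding sequences
  must be contiguous. FASTA errors carry line numbers; output wraps at 70
  columns.
* Translation uses the standard genetic code only, as a replaceable dict
  for programmatic alternatives; translation does **not** stop at the
  first `*`, because knockout verification needs every stop in frame to be
  visible. Ambiguous codons are not translated.
* Degenerate-pattern matching is definitional (IUPAC degeneracy sets);
  scanning compiles patterns to regular expressions inside a lookahead so
  overlapping occurrences are found.
* The hydrophobic residue class used by `constrained_codon_mutagenesis`
  is the convention {A, V, L, I, M, F, W, P}.
* "Within the first 20 codons" means first-stop index < 20, 0-based.

## Problem sizes

Default verification runs use 200 synthetic pairs for search/oracle
equivalence, 500 for geometry recovery, 100 random 500-mers for the
restriction oracle, and surveys of 1000 pairs (2000 for the closed-form
limit) — sizes chosen so the whole suite completes in about a minute and a
half on one core while keeping binomial error bars tight enough for the
3-standard-error checks to be meaningful.

## Known limitations

Only substitution mutants (no indels/frameshift knockouts); one contiguous
overlap per pair; exact-match overlap detection (diverged strain pairs
must pass geometry explicitly); no codon-usage optimisation of mutants; no
primer design. Start-loss efficacy depends on the absence of downstream
in-frame near-cognate initiation, which the software annotates but cannot
decide.
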