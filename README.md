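# overko

Design gene knockouts in sequences with **overlapping (overprinted) reading
frames**.

Viral genomes routinely encode two proteins in the same nucleotide span,
read in different frames or on opposite strands. That rules out excising a
gene to knock it out, and it constrains mutagenesis: a premature stop codon
placed in the *target* gene must not change a single amino acid of the
*overlapping* gene, or the knockout phenotype is confounded. Because the
genetic code is degenerate, such edits usually exist — but finding them by
hand, and finding ones that also add or remove a restriction site usable as
a cheap screening tracer, is slow and error-prone.

`overko` automates this. Given a target gene and its overlapping partner it:

1. detects the shared region (longest exact common substring, either
   strand) and the frame relationship between the two genes;
2. enumerates every minimal edit (1–3 substitutions inside one codon) that
   either converts an internal codon to a stop (TAA/TAG/TGA) or destroys
   the ATG start codon, keeping only edits whose projection into the
   overlapping frame is synonymous;
3. annotates each candidate with the restriction sites it gains or loses,
   against a bundled table of ~65 common commercial enzymes (IUPAC
   degenerate recognition sequences, 4–8 nt), and can filter on them.

Formally: let the target be codons $c_0 c_1 \dots c_{n-1}$ and let $\phi$
map each target nucleotide position to its position in the overlapping
gene's codon grid (with complementation on the opposite strand). An edit
set $E$ confined to codon $c_i$ is a valid knockout iff

* $i = 0$ and $c_0' \ne \mathrm{ATG}$ (start loss), or
  $i \ge 1$, $c_i \notin \{\mathrm{TAA,TAG,TGA}\}$ and
  $c_i' \in \{\mathrm{TAA,TAG,TGA}\}$ (premature stop); and
* for every overlapping-gene codon $d$ touched by $\phi(E)$,
  $\mathrm{aa}(d') = \mathrm{aa}(d)$.

The per-gene survey statistic is the *first knockout codon*: the smallest
$i \ge 1$ admitting a premature stop; the earlier it is, the more certain
the truncation is a functional null (a ≤20-residue product is the usual
criterion).

The package is aimed at virologists and molecular biologists planning
mutagenesis of overprinted genes, and comes with a seeded synthetic-pair
generator so every stage of the pipeline is testable without any database
access.

## Worked example

The bundled example pair (`overko.datasets.synthetic_example_pair`) is a
21 nt target (`MGPSKH*`) sitting inside a 30 nt overlapping gene
(`MYGALKTLT*`) on the same strand, one frame off:

```python
>>> from overko import find_knockouts, first_knockout_codon
>>> from overko.datasets import synthetic_example_pair
>>> pair = synthetic_example_pair()
>>> pair.geometry
OverlapGeometry(target_span=(0, 21), overlap_span=(4, 25), strand='same', frame_shift=1)
>>> for c in find_knockouts(pair):
...     print(c.kind, c.codon_index, str(c.mutation), c.new_target_codon)
start_loss 0 1:T>C ACG
premature_stop 3 10:C>A TAA
premature_stop 3 10:C>G TGA
>>> first_knockout_codon(pair)
3
```

Reading the output: the start codon can be mutated to ACG (target position
1, T→C) because the overlapping gene's TAT codon becomes TAC — both
tyrosine; note ACG is a known near-cognate start, so this design should be
validated biologically. Alternatively the serine codon TCA at index 3 can
become a stop (TGA or TAA) because the overlapping leucine codon CTC
becomes CTG or CTA — all leucine. No earlier codon admits a stop, so the
first knockout codon is 3.

The same analysis from the shell, batched over FASTA files:

```bash
$ overko find --target targets.fa --overlap overlaps.fa
pair_id rank kind           codon_index edits   mutant_codon stop_codon alternate_start ...
pair1   1    start_loss     0           1:T>C   ACG          .          yes
pair1   2    premature_stop 3           10:C>A  TAA          TAA        .
pair1   3    premature_stop 3           10:C>G  TGA          TGA        .
```

`overko scan` reports restriction sites per record; `overko simulate`
surveys first-stop positions over synthetic pairs (see
`docs/methods.md`).

## Enzyme tables

Plain text, one `Name Recognition` pair per line; whitespace-separated,
`#` starts a comment, recognition sequences are 4–8 nt and may use IUPAC
ambiguity codes:

```
EcoRI   GAATTC
HinfI   GANTC   # N matches any base
```

`--enzymes builtin` (the default) loads the bundled table at
`src/overko/data/enzymes.txt`.

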