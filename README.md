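# karyopool

Analysis of chromosomal inversion polymorphism in natural populations,
built around polytene-chromosome **banding-sequence pools** of the kind
used for *Chironomus* (Diptera, Chironomidae) cytogenetics.

In these species each chromosome arm carries a reproducible band
pattern; alternative banding sequences of an arm are related by
paracentric inversions and segregate like codominant alleles of one
locus (a heterozygous arm shows an inversion loop in the squash).
`karyopool` covers the full analysis chain for such data:

* **Notation algebra** (`karyopool.bandmap`) — parse listing lines such as
  `p'agiB1 25s-q 18n-16a 22a-r ... 15f-12v C`, infer the arm's band
  universe, expand runs to oriented band lists, verify that an arm's
  sequences are mutual band-set permutations, and refine two maps onto a
  shared segment alphabet.
* **Rearrangement analysis** (`karyopool.rearrange`) — exact reversal
  distance between two sequences by iterative-deepening search with
  breakpoint pruning, minimised over the orientations the notation
  leaves free; simple (d = 1) vs complex (d ≥ 2) inversion calls and
  inverted-block breakpoints in band coordinates.
* **Population statistics** (`karyopool.popstats`) — allele frequencies
  from genotype counts, percent heterozygous larvae and heterozygous
  inversions per larva, banding-sequence census, Hardy–Weinberg χ² tests
  (plus a conditional exact test for small samples), B-chromosome
  carriage.
* **Genetic distances and trees** (`karyopool.neiphylo`) — Nei (1972)
  standard distance D = −ln I with I = J_XY/√(J_X·J_Y), the J terms
  averaged across all seven arms before forming I; neighbor-joining
  trees with deterministic tie-breaking; Newick and PHYLIP-style
  matrix I/O.
* **Cytogenetic-structure typing** (`karyopool.cytostruct`) — type "0"
  when the main (serial-1) sequence holds a strict majority in every
  arm, otherwise the letters of arms dominated by an alternative
  sequence; frequency-polygon vectors for plotting.
* **Synthetic data** (`karyopool.synthgen`) — genotype samples under
  Hardy–Weinberg with a fixation-index deviation F, and maps with
  planted reversals, so every stage is testable without field material.
* **Fixtures** (`karyopool.fixtures`) — the complete 16-sequence
  *Ch. agilis* banding pool (arms A–F mapped, G catalogued unmapped),
  the 19 collection sites, the per-population frequency tables of the
  ten quantitative-panel populations, their polymorphism indices and
  the printed distance matrix, all as plain text, with the known
  internal inconsistencies of the printed tables preserved and flagged
  rather than reconciled.

## Worked example

```python
>>> from karyopool import fixtures, rearrange, neiphylo
>>> fx = fixtures.load_fixtures(warn=False)
>>> arr, res = rearrange.compare_maps(fx.sequence("B1"), fx.sequence("B2"))
>>> res.distance, res.classification
(1, 'simple')
>>> bp = rearrange.single_reversal_breakpoints(fx.sequence("B1"), fx.sequence("B2"))
>>> print(bp[0], "..", bp[1])
22c .. 23c
>>> m = neiphylo.distance_matrix(fx.tables)
>>> neiphylo.round3(m["YAR-RY", "KHA-EV"])
0.155
```

The two most common B sequences differ by one large paracentric
inversion spanning bands 22c–23c of the standard order, and the largest
genetic distance in the panel (0.155) separates the two range-border
populations (Rybinsk Reservoir and Evoron Lake).

The same analysis is available from the shell. `karyopool reproduce`
reruns everything on the packaged fixtures; an excerpt of its output:

```
pool size: 16 banding sequences
p'agiB1 -> p'agiB2: d=1 (simple)
p'agiC1 -> p'agiC2: d=2 (complex)
mean % heterozygous larvae: 45.1; mean heterozygous inversions per larva: 0.52
NSK-SH: expected B1.2 frequency 41.1%
NSK-LI: expected B1.2 frequency 46.0%
```

Other subcommands: `validate-pool`, `compare`, `pop-stats`, `hw-test`,
`nei-matrix`, `nj-tree`, `classify`, `simulate`.

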