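# junctura

Analysis of **copy-number-neutral complex chromosome rearrangements**
(chromoanagenesis-type events) from breakpoint-junction data: derivative
chromosome reconstruction, nucleotide-level junction-signature calling, and a
Monte Carlo null model that asks whether an event looks chromothripsis-like
(clustered breakpoints) or chromoplexy-like (enriched for protein-coding-gene
fusions).

It is written for geneticists and bioinformaticians who already have
breakpoint calls — from short-read SV callers, optical mapping, or Sanger
breakpoint PCR — and need to turn them into an interpretable architecture and
mechanism for a single rearranged chromosome.

## The model

**Derivative reconstruction.** A breakpoint junction joins two *breakends*;
each breakend is a 1-based reference position plus the side of the cut its
retained sequence lies on. Breakends within a configurable `merge_tolerance`
(default 100 bp, covering small resections) are unified into shared cut
sites, which partition the chromosome into segments. Junctions are then edges
between segment ends, and a valid rearrangement is the unique linear walk
from the p telomere to the q telomere; branched or cyclic junction sets are
rejected with the offending junction ids. Each inverted segment counts as one
inversion event; an event is *pericentric* if its reference interval contains
the centromere midpoint, else *paracentric*.

**Junction signatures.** For each junction, the observed read across the join
is aligned exactly to the two reference flanks. With `a` the longest prefix
following the proximal reference through its breakend, `b` the longest suffix
following the distal reference, and `n` the read length: `a + b − n > 0` is
microhomology of that many bases, `= 0` is a blunt fusion, and `< 0` leaves
an insertion, which is traced to a templated origin by exhaustive
exact-match search (both flanks, both strands, ±50 bp). A rule-based layer
labels the call set NHEJ-compatible (≤1 bp homology, short insertions,
copy-number neutral), MMEJ-compatible (2–25 bp homology) or replicative-
suspect (dosage change or templated insertion ≥10 nt).

**Null model.** The chromosome (length `L`) is broken into `n` segments at
`n − 1` uniform cut sites; the first and last segments stay fixed, the middle
segments are uniformly permuted and each inverted with probability 0.5. Over
10,000 replicates the model yields empirical p-values for

* *clustering*: fraction of replicates whose average breakpoint distance is
  strictly smaller than observed (both the all-pairs mean and the
  consecutive-gap mean are implemented), and
* *fusion enrichment*: fraction of replicates with at least as many
  protein-coding-gene fusions as observed (junction-level fusions of two
  distinct genes, or breakpoints-in-genes counting).

## Worked example

The package ships a worked index case: a de novo germline event on
chromosome 6 (hg19, 171,115,067 bp) with six breakpoint junctions, in which
one inversion disrupts *ARID1B* (the two breakpoints of that disruption,
chr6:157,240,695 and chr6:157,240,708, are exact published coordinates; the
remaining cut positions are reconstructed from published segment sizes, and
the junction sequence context is synthetic with the published signatures
planted — see `junctura/index_case.py`).

```bash
python examples/01_reconstruct_derivative.py
python examples/02_junction_signatures.py
python examples/03_null_model.py
```

prints, among other lines:

```
derivative path: A+ B- C- D- F+ E- G+
4 inversion events (1 pericentric, 3 paracentric) across 6 breakpoint junctions
ARID1B breakpoint chr6:157,240,695 falls in intron 4 (between exons 4 and 5), splitting the gene.

junction  class          mh  ins      template origin
      J3  insertion       0  TTTGAAG  proximal -9 bp (forward)
      J5  microhomology   1           -
mechanism: NHEJ_compatible

p(clustering), consecutive-gap statistic: 0.759
p(gene fusion), breakpoints-in-genes:     0.143
```

Reading: the derivative carries four inversions (one across the centromere);
the junctions show only blunt joins, 1 bp of homology and short insertions,
so canonical end joining suffices; and neither breakpoint clustering (p ≈
0.76 — *not* more clustered than chance) nor gene-fusion enrichment (p > 0.05)
is significant, so the event fits neither canonical chromothripsis nor
canonical chromoplexy cleanly.

A thin CLI mirrors the examples (`junctura reconstruct|signature|simulate|synth`),
e.g.

```bash
junctura reconstruct --junctions obs.tsv --length 171115067 \
    --centromere 58780166-61880166
junctura simulate --junctions obs.tsv --length 171115067 --segments 7 \
    --reps 10000 --seed 1 --genes genes.bed
```

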