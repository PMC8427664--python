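# Methods

This note documents the models, conventions and numerical choices behind
junctura, and what the synthetic generators do and do not emulate.

## Coordinates and breakend semantics

All in-memory positions are 1-based; intervals are closed. A *cut site* `x`
severs the chromosome between `x` and `x + 1`. A breakend records a position
and a side: `left_of_cut` at `p` retains `[.., p]` (cut site `p`);
`right_of_cut` at `p` retains `[p, ..]` (cut site `p − 1`). BED files are
converted from 0-based half-open at the IO boundary; VCF breakend bracket
notation maps onto the same two sides.

## Derivative assembly

Breakends from the two products of one double-strand break rarely share an
exact coordinate: end resection before ligation offsets them by a few bases
(13 bp at the ARID1B disruption of the shipped index case). Cut sites are
therefore clustered by single linkage with `merge_tolerance` (default
100 bp — an order of magnitude above typical resection lengths, three orders
below the Mb-scale segments being resolved); a cluster's unified position is
the midpoint of its extremes, rounded down. At toy scales (chromosomes of a
few hundred bp, as in some tests) the tolerance must be reduced or zeroed,
otherwise distinct cuts merge.

Assembly then walks segment ends: the segment containing position 1 is the
mandatory start (terminal segments of a telomere-to-telomere derivative are
positionally static), each junction is an edge between two segment ends, and
every internal end must be used exactly once. Reused breakends, dangling
ends, and edges forming side cycles or branches raise a "non-linear
architecture" error carrying the offending junction ids — deliberately a hard
error rather than a best-effort path, since a wrong walk would silently
change the inversion counts downstream.

Inversion counting is per inverted segment. Consecutive inverted segments
that are also reference-adjacent read as one larger inverted block; the
assembler canonicalises such paths (merging reference-like adjacencies), so
the ambiguity does not arise for assembled paths. Whether a multi-segment
inverted block "is" one event or several is not decidable from the derivative
alone; we follow per-segment counting, which matches the worked case's four
events. The pericentric test uses the centromere midpoint rather than
interval overlap, making it robust to the differing centromere-interval
dialects across reference releases.

`junctions_from_path` emits one junction per non-reference adjacency, so
`assemble_path ∘ junctions_from_path` is the identity on canonical paths.
The synthetic case generator, by contrast, emits a junction for *every*
adjacency (including reference-like ones), so its junction list reassembles
the truth path exactly, cut for cut.

## Junction signatures

The caller assumes the junction read aligns exactly to the proximal flank up
to some transition and to the distal flank after it (true of the synthetic
bundles; real reads must be pre-trimmed). It computes `a`, the maximal
prefix of the read matching the proximal reference *through* its breakend
into the continuation, and `b`, the mirrored suffix match on the distal side;
`a + b − n` gives microhomology length (positive), blunt (zero) or insertion
(negative). The scan is symmetric about the transition, so reported
microhomology is the *total* ambiguous overlap, including bases 3′ of the
nominal join that match the proximal continuation.

Matching is exact only. The signatures relevant here are 0–1 bp homologies
and short insertions, where one mismatch destroys the feature; fuzzy matching
is deliberately not implemented.

Template search is an exhaustive exact scan of the insertion and its reverse
complement against both flanks within ±50 bp of each breakend (window
configurable). Hits shorter than 3 nt are never reported — a 1–2 nt "template"
occurs by chance every few bases. Ties are resolved smallest |offset| first,
then proximal before distal, then forward before reverse-complement, making
the result deterministic.

Single-base features are formally ambiguous: a 1-nt insertion that duplicates
the base just inside either flank could equally be called 1 bp of
microhomology under a shifted breakend call. Such calls carry
`ambiguous=True` rather than being silently resolved.

Mechanism inference is rule-based with explicit thresholds (defaults:
`mh_max=1`, `ins_max=10`, MMEJ band 2–25 bp, `template_suspect_len=10`),
chosen from literature convention — NHEJ junctions show ≤1 bp homology and
small untemplated additions; MMEJ needs a few bases of homology; template
switching produces longer templated insertions and usually dosage change.
These are *compatibility* labels, not proof of mechanism.

## Null model

One replicate draws `n_segments − 1` distinct cut sites uniformly on
`[1, L − 1]`, permutes the middle segments uniformly (identity allowed) and
inverts each independently with probability 0.5. Cut sites are sampled
without replacement (coincident breakpoints have probability ~0 at
chromosome scale; distinctness keeps the segment partition well defined).
Each replicate `r` uses its own generator seeded `[seed, r]`, so replicate
streams are reproducible and parallelisable.

Two clustering statistics are implemented because "average distance between
breakpoints" admits two readings:

* `pairwise` (default): mean |xᵢ − xⱼ| over unordered pairs, the standard
  dispersion reading, sensitive to the full configuration;
* `gaps`: mean consecutive gap, which for fixed n is range/(n − 1) and hence
  depends only on the extreme breakpoints.

For the shipped index case they give markedly different tail positions
(observed mean gap 28.8 Mb vs null ~24.4 Mb; observed mean pairwise distance
57.8 Mb vs null ~57.0 Mb), which is why both are always reported. The
clustering p-value uses a strict inequality (a replicate counts only if
*more* clustered); the fusion p-value uses the conventional non-strict upper
tail. Plain proportions k/R are reported by default; the (k+1)/(R+1)
never-zero correction is available via `pvalue_correction`.

Fusion counting modes: `junction_fusion` counts junctions whose two breakend
positions fall in gene bodies of two distinct protein-coding genes (simulated
junctions come from the novel adjacencies of each replicate's derivative, so
a shuffle that happens to leave neighbours adjacent contributes fewer
candidate junctions); `breakpoint_in_gene` counts distinct cut sites inside
any gene body. When the observed annotation lives on a different assembly
than the simulated chromosome, the observed count can be supplied directly
(`fusion_count_override`) instead of being recomputed.

## Synthetic data: what it emulates, and what it does not

`generate_case` emulates exactly the null model's study conditions (7-segment
copy-number-neutral shuffles of a 171,115,067 bp chromosome with inversion
probability 0.5), plus arbitrary sizes for testing.

`chr6_like_genes` emulates a chromosome-6-scale protein-coding annotation
with 1,000 disjoint genes of exponential length (mean 62 kb), i.e. genic
coverage ≈ 0.36. The parameters were fixed once from published human gene
statistics (≈1,000 coding loci on chromosome 6; mean protein-coding gene
span in the low tens of kb with a long tail, commonly cited near 60–65 kb).
Real annotations differ in ways that matter for the fusion test: genes
overlap, cluster (e.g. the MHC region), and their *merged* coverage — which
alone determines the breakpoint-in-gene null — is uncertain at the ±5-point
level. The fusion p-value responds strongly: with observed count 4 of 6,
p = P(Bin(6, f) ≥ 4) moves from ~0.11 at coverage f = 0.345 to ~0.15 at
f = 0.37. Tests passing against the synthetic annotation therefore validate
the machinery and the direction/magnitude of the result, not annotation-exact
p-values; for publication-grade numbers supply a real gene BED.

`generate_junction_bundle` plants a signature so that it is the unique
maximal call: flank bases adjacent to a planted microhomology break the
overlap on both sides, insertion boundary bases cannot be absorbed into
either flank, and template absence/uniqueness within the search window is
enforced by rejection sampling (bounded at 1,000 retries, then a generation
error — notably, 3–5 nt insertions cannot plausibly be kept absent from
±50 bp of random sequence and will exhaust the budget). Bundles place the
junction read flush with the full retained flanks; they do not emulate
sequencing error, heterozygosity, or repeat context.

The shipped index case is a partial reconstruction: two breakpoints and the
chromosome length are exact published coordinates, the other cuts follow the
published segment sizes (~95 Mb, 46.21 Mb, ~1 Mb × 3), the junction sequences
are synthetic with the published signatures planted, and the ARID1B
transcript model is approximate except for the intron containing the
breakpoints. Conclusions that depend on base-exact positions of the *other*
four cuts should not be drawn from it.

## Problem sizes and determinism

Default analysis sizes: 10,000 Monte Carlo replicates (a few seconds on one
CPU; Monte Carlo standard error on a p-value near 0.1–0.75 is ~0.003–0.004),
±50 bp template windows, 60 bp synthetic flanks. The test suite exercises
500-case assembly round trips, 1,000 signature fixtures against a brute-force
oracle, 10,000-replicate conservation checks and 200×200 p-value uniformity,
and completes in well under a minute. Every stochastic component is a pure
function of an integer seed; reruns are byte-identical apart from output
timestamps.

## Known limitations

* Single-chromosome, copy-number-neutral events only: no translocations,
  no CNV-bearing rearrangements, no multi-chromosome chromoplexy chains.
* Junction reads must be pre-extracted and clean; there is no BAM/read-level
  processing, realignment, or Sanger trace parsing.
* Exact-match signature calling will understate microhomology in the
  presence of sequencing errors or nearby SNVs.
* The inversion-event count follows the per-segment convention; other
  conventions (collapsing adjacent inverted blocks) would report fewer
  events for some architectures.
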