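"""Synthetic inputs with known ground truth.

Everything downstream (assembly, signature calling, the Monte Carlo null
model) is testable against these generators without any download:

* :func:`generate_genes` — a disjoint protein-coding annotation of
  configurable density (a stand-in for a real annotation; real BED files can
  be supplied through :mod:`junctura.io` instead);
* :func:`generate_case` — a copy-number-neutral shuffle of one chromosome
  with the truth path, junction list and cut sites recorded;
* :func:`generate_junction_bundle` — reference flanks plus a junction read
  constructed so that a planted signature (blunt / k-bp microhomology /
  insertion with optional templated origin) is the unique maximal call.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, GenerationError, ValidationError
from .models import (
    ChromosomeModel,
    DerivativePath,
    GeneAnnotation,
    GeneRecord,
    Junction,
    Orientation,
    Segment,
)
from .rearrangement import junctions_from_path, segments_from_cuts
from .signature import (
    DEFAULT_TEMPLATE_WINDOW,
    MIN_TEMPLATE_LEN,
    SignatureCall,
    revcomp,
)

BASES = "ACGT"

#: hg19 chromosome 6: the span used by the chromosome-scale null model, with
#: an example centromere interval.
CHR6_LENGTH = 171_115_067
CHR6_CENTROMERE = (58_780_166, 61_880_166)

#: Defaults for a chr6-like protein-coding annotation: roughly one thousand
#: coding loci whose mean genomic span matches published human gene statistics
#: (~62 kb), giving a genic coverage fraction of ~0.36.
CHR6_N_GENES = 1000
CHR6_MEAN_GENE_LEN = 62_000

DEFAULT_RETRIES = 1000


def chr6_model(centromere: tuple[int, int] | None = CHR6_CENTROMERE) -> ChromosomeModel:
    return ChromosomeModel("chr6", CHR6_LENGTH, centromere)


@dataclass(frozen=True)
class RearrangementCase:
    """A generated rearrangement with its ground truth attached."""

    model: ChromosomeModel
    truth_path: DerivativePath
    junctions: tuple[Junction, ...]
    cut_sites: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.junctions) != len(self.cut_sites):
            raise ValidationError("junction count must equal cut-site count")


@dataclass(frozen=True)
class JunctionSequenceBundle:
    """Reference flanks and the observed read across one junction.

    ``proximal_ref`` and ``distal_ref`` each span ``2 * flank_len + 1`` bases
    with the breakend base at index ``flank_len``. On the proximal flank the
    retained sequence is the prefix up to and including the breakend base; on
    the distal flank it is the suffix from the breakend base.
    """

    proximal_ref: str
    distal_ref: str
    junction_obs: str
    flank_len: int
    truth: Optional[SignatureCall] = None

    def __post_init__(self) -> None:
        for name in ("proximal_ref", "distal_ref", "junction_obs"):
            seq = getattr(self, name)
            if set(seq) - set(BASES):
                raise ValidationError(f"{name} contains non-ACGT characters")
        span = 2 * self.flank_len + 1
        if len(self.proximal_ref) != span or len(self.distal_ref) != span:
            raise ValidationError(
                f"flanks must span 2*flank_len+1 = {span} bases"
            )
        if len(self.junction_obs) < 2:
            raise ValidationError("junction_obs must be at least 2 bases")

    @property
    def proximal_retained(self) -> str:
        return self.proximal_ref[: self.flank_len + 1]

    @property
    def proximal_continuation(self) -> str:
        return self.proximal_ref[self.flank_len + 1 :]

    @property
    def distal_continuation(self) -> str:
        return self.distal_ref[: self.flank_len]

    @property
    def distal_retained(self) -> str:
        return self.distal_ref[self.flank_len :]


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [BASES[i] for i in rng.integers(0, 4, size=n)]


def _distinct_uniform(rng: np.random.Generator, n: int, lo: int, hi: int) -> list[int]:
    """n distinct integers uniform on [lo, hi] (collisions redrawn)."""
    if hi - lo + 1 < n:
        raise ConfigurationError(f"cannot draw {n} distinct values from [{lo}, {hi}]")
    chosen: set[int] = set()
    while len(chosen) < n:
        for v in rng.integers(lo, hi + 1, size=n - len(chosen)):
            chosen.add(int(v))
    return sorted(chosen)


def generate_genes(
    model: ChromosomeModel,
    n_genes: int,
    mean_len: int,
    seed: int,
    max_retries: int = DEFAULT_RETRIES,
) -> GeneAnnotation:
    """Place ``n_genes`` disjoint protein-coding intervals on the chromosome.

    Lengths are exponential with mean ``mean_len`` (rounded, minimum 1 bp);
    starts are uniform, rejection-sampled until disjoint from all previously
    placed genes. The output is sorted by start and deterministic in the seed.
    """
    if n_genes < 0 or (n_genes > 0 and mean_len < 1):
        raise ConfigurationError("need n_genes >= 0 and mean_len >= 1")
    if n_genes * mean_len >= model.length:
        raise ConfigurationError(
            f"requested footprint {n_genes} * {mean_len} bp does not fit in "
            f"{model.length} bp"
        )
    rng = np.random.default_rng(seed)
    placed_starts: list[int] = []
    placed: list[tuple[int, int]] = []
    records: list[GeneRecord] = []
    width = len(str(n_genes))
    for i in range(n_genes):
        length = max(1, round(float(rng.exponential(mean_len))))
        length = min(length, model.length)
        for _ in range(max_retries):
            start = int(rng.integers(1, model.length - length + 2))
            end = start + length - 1
            k = bisect.bisect_left(placed_starts, start)
            if k > 0 and placed[k - 1][1] >= start:
                continue
            if k < len(placed) and placed[k][0] <= end:
                continue
            placed_starts.insert(k, start)
            placed.insert(k, (start, end))
            records.append(GeneRecord(f"G{i + 1:0{width}d}", start, end))
            break
        else:
            raise GenerationError(
                f"could not place gene {i + 1}/{n_genes} after {max_retries} tries"
            )
    return GeneAnnotation(records)


def chr6_like_genes(
    seed: int,
    n_genes: int = CHR6_N_GENES,
    mean_len: int = CHR6_MEAN_GENE_LEN,
) -> GeneAnnotation:
    """A synthetic chr6-scale protein-coding annotation (see module docstring)."""
    return generate_genes(chr6_model(), n_genes, mean_len, seed)


def generate_case(
    model: ChromosomeModel,
    n_segments: int,
    inversion_prob: float,
    seed: int,
) -> RearrangementCase:
    """Draw one copy-number-neutral shuffle of the chromosome.

    ``n_segments - 1`` distinct cut sites are uniform on ``[1, length - 1]``;
    the first and last segments keep position and orientation; the middle
    segments are permuted uniformly and each independently inverted with
    probability ``inversion_prob``. The emitted junction list covers every
    path adjacency (including reference-like ones), so reassembling it
    reproduces the truth path exactly.
    """
    if n_segments < 3:
        raise ConfigurationError(f"need at least 3 segments, got {n_segments}")
    if not (0.0 <= inversion_prob <= 1.0):
        raise ConfigurationError(f"inversion_prob must be in [0, 1], got {inversion_prob}")
    if n_segments - 1 > model.length - 1:
        raise ConfigurationError(
            f"cannot place {n_segments - 1} cuts on a {model.length} bp chromosome"
        )
    rng = np.random.default_rng(seed)
    cuts, path = _draw_path(rng, model, n_segments, inversion_prob)
    junctions = junctions_from_path(path, include_reference_adjacencies=True)
    return RearrangementCase(
        model=model,
        truth_path=path,
        junctions=tuple(junctions),
        cut_sites=tuple(cuts),
    )


def _draw_path(
    rng: np.random.Generator,
    model: ChromosomeModel,
    n_segments: int,
    inversion_prob: float,
) -> tuple[list[int], DerivativePath]:
    """Shared draw used by generate_case and the Monte Carlo null model."""
    cuts = _distinct_uniform(rng, n_segments - 1, 1, model.length - 1)
    reference = segments_from_cuts(cuts, model)
    middle = list(range(1, n_segments - 1))
    order = [middle[i] for i in rng.permutation(len(middle))]
    inverted = rng.random(len(middle)) < inversion_prob
    segments = [reference[0]]
    for idx, inv in zip(order, inverted):
        ref = reference[idx]
        orientation = Orientation.INVERTED if inv else Orientation.DIRECT
        segments.append(Segment(ref.id, ref.start, ref.end, orientation))
    segments.append(reference[-1])
    return cuts, DerivativePath(segments, model)


def generate_junction_bundle(
    spec: SignatureCall,
    flank_len: int = 60,
    seed: int = 0,
    search_window: int = DEFAULT_TEMPLATE_WINDOW,
    max_retries: int = DEFAULT_RETRIES,
) -> JunctionSequenceBundle:
    """Construct flanks and a junction read carrying the planted signature.

    The flanks are random but constrained so the planted call is the unique
    maximal one: a planted microhomology of length k is broken at base k+1 on
    both sides; planted insertions cannot be absorbed into either flank; a
    planted template origin is the only occurrence of the insertion (either
    strand) within the search window, and a plain insertion of reportable
    length has no such occurrence at all.

    Note that absence/uniqueness is enforced by rejection, so insertions of
    3-5 nt (too short to plausibly miss from +-window bp of random sequence)
    will exhaust the retry budget and raise :class:`GenerationError`.
    """
    k = spec.mh_len
    ins = spec.ins_seq
    if flank_len < k + len(ins) + (search_window if spec.template_hit or len(ins) >= MIN_TEMPLATE_LEN else 0):
        raise ConfigurationError(
            f"flank_len {flank_len} too short for mh_len {k}, insertion "
            f"{len(ins)} nt and search window {search_window}"
        )
    if spec.template_hit is not None and not ins:
        raise ConfigurationError("a template hit requires a non-empty insertion")
    rng = np.random.default_rng(seed)
    F = flank_len
    for _ in range(max_retries):
        prox = _random_seq(rng, 2 * F + 1)
        dist = _random_seq(rng, 2 * F + 1)
        mh = list(spec.mh_seq) if spec.mh_seq else _random_seq(rng, k)
        if k:
            prox[F + 1 - k : F + 1] = mh
            dist[F : F + k] = mh

        template_span: tuple[str, int, int] | None = None
        if spec.template_hit is not None:
            hit = spec.template_hit
            start = F + hit.offset
            if start < 0 or start + len(ins) > 2 * F + 1:
                raise ConfigurationError(
                    f"template offset {hit.offset} with {len(ins)} nt does not "
                    f"fit in a {F} bp flank"
                )
            planted = ins if hit.strand == "forward" else revcomp(ins)
            target = prox if hit.source == "proximal" else dist
            target[start : start + len(ins)] = list(planted)
            template_span = (hit.source, start, start + len(ins))

        if not _fix_boundary_bases(rng, prox, dist, F, k, ins, template_span):
            continue
        if not _template_constraints_ok(
            "".join(prox), "".join(dist), F, ins, spec.template_hit, search_window
        ):
            continue
        prox_s, dist_s = "".join(prox), "".join(dist)
        obs = prox_s[: F + 1] + ins + dist_s[F + k :]
        return JunctionSequenceBundle(
            proximal_ref=prox_s,
            distal_ref=dist_s,
            junction_obs=obs,
            flank_len=F,
            truth=spec,
        )
    raise GenerationError(
        f"could not satisfy bundle constraints for {spec} in {max_retries} tries"
    )


def _fix_boundary_bases(
    rng: np.random.Generator,
    prox: list[str],
    dist: list[str],
    F: int,
    k: int,
    ins: str,
    template_span: tuple[str, int, int] | None,
) -> bool:
    """Resample the bases that must break the alignment extensions.

    Returns False when a required base falls inside the planted template
    (caller retries with fresh randomness).
    """

    def protected(flank: str, index: int) -> bool:
        if template_span is None:
            return False
        source, lo, hi = template_span
        return flank == source and lo <= index < hi

    def set_not_equal(target: list[str], flank: str, index: int, forbidden: str) -> bool:
        if protected(flank, index):
            return target[index] != forbidden
        if target[index] == forbidden:
            choices = [b for b in BASES if b != forbidden]
            target[index] = choices[int(rng.integers(0, 3))]
        return True

    if ins:
        ok = set_not_equal(prox, "proximal", F + 1, ins[0])
        ok &= set_not_equal(dist, "distal", F - 1, ins[-1])
        return ok
    # blunt / microhomology: break the overlap at base k+1 on both sides
    ok = set_not_equal(dist, "distal", F + k, prox[F + 1])
    ok &= set_not_equal(prox, "proximal", F - k, dist[F - 1])
    return ok


def _template_constraints_ok(
    prox: str,
    dist: str,
    F: int,
    ins: str,
    hit,
    window: int,
) -> bool:
    """Planted origin unique within the window; none at all when unplanted."""
    if len(ins) < MIN_TEMPLATE_LEN:
        return True
    expected = set()
    if hit is not None:
        expected.add((hit.source, F + hit.offset, hit.strand))
    found = set()
    for source, flank in (("proximal", prox), ("distal", dist)):
        lo = max(0, F - window)
        hi = min(len(flank), F + window + 1)
        region = flank[lo:hi]
        for strand, query in (("forward", ins), ("reverse_complement", revcomp(ins))):
            start = region.find(query)
            while start != -1:
                found.add((source, lo + start, strand))
                start = region.find(query, start + 1)
    if hit is not None and ins == revcomp(ins):
        # palindromic insertions match both strands at the planted site
        found = {(s, p, "forward") for s, p, _ in found}
        expected = {(s, p, "forward") for s, p, _ in expected}
    return found == expected
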