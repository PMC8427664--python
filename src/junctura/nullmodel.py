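"""Monte Carlo null model for chromothripsis-like vs chromoplexy-like tests.

The null hypothesis is a copy-number-neutral shuffle of one chromosome:
``n_segments - 1`` cut sites uniform on the chromosome, the first and last
segments positionally static, the middle segments uniformly permuted and each
inverted with probability ``inversion_prob``. Two empirical tests are run
against an observed rearrangement:

* **breakpoint clustering** (chromothripsis-like): the observed average
  distance between breakpoints against its null distribution; a replicate
  counts as more clustered when its statistic is *strictly smaller*;
* **protein-coding-gene fusion enrichment** (chromoplexy-like): the number of
  junctions fusing two distinct protein-coding genes (or, alternatively, the
  number of cut sites landing inside gene bodies) against its null
  distribution; a replicate counts when its count is *at least* the observed
  one (upper tail).

Both readings of "average distance between breakpoints" are implemented: the
mean over all unordered pairs (default) and the mean consecutive gap, which
for fixed cut count is range/(n-1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .errors import ConfigurationError, ValidationError
from .models import ChromosomeModel, GeneAnnotation, Junction
from .rearrangement import (
    DEFAULT_MERGE_TOLERANCE,
    cluster_cut_sites,
    junctions_from_path,
    merged_cut_position,
)
from .synthetic import _draw_path

ClusteringMethod = Literal["pairwise", "gaps"]
FusionMode = Literal["junction_fusion", "breakpoint_in_gene"]


@dataclass(frozen=True)
class SimulationConfig:
    model: ChromosomeModel
    n_segments: int = 7
    inversion_prob: float = 0.5
    reps: int = 10_000
    seed: int = 0
    fusion_mode: FusionMode = "junction_fusion"
    clustering: ClusteringMethod = "pairwise"
    pvalue_correction: bool = False  # plain k/R by default; (k+1)/(R+1) if True
    merge_tolerance: int = DEFAULT_MERGE_TOLERANCE

    def __post_init__(self) -> None:
        if self.n_segments < 3:
            raise ConfigurationError(f"n_segments must be >= 3, got {self.n_segments}")
        if self.reps < 1:
            raise ConfigurationError(f"reps must be >= 1, got {self.reps}")
        if not (0.0 <= self.inversion_prob <= 1.0):
            raise ConfigurationError(
                f"inversion_prob must be in [0, 1], got {self.inversion_prob}"
            )


@dataclass(frozen=True)
class ObservedCase:
    """The observed rearrangement reduced to the two test statistics' inputs.

    ``fusion_count_override`` supplies an externally determined observed
    fusion count (e.g. taken from an annotation on a different assembly than
    the simulated chromosome); when ``None`` the count is computed from the
    gene annotation passed to :func:`run_simulation`.
    """

    cut_sites: tuple[int, ...]
    junction_breakend_pairs: tuple[tuple[int, int], ...]
    fusion_count_override: Optional[int] = None

    @classmethod
    def from_junctions(
        cls,
        junctions: Sequence[Junction],
        n_segments: int,
        merge_tolerance: int = DEFAULT_MERGE_TOLERANCE,
        fusion_count_override: Optional[int] = None,
    ) -> "ObservedCase":
        """Merge breakends into cut sites and keep the raw breakend pairs."""
        clusters = cluster_cut_sites({j.a.cut_site for j in junctions}
                                     | {j.b.cut_site for j in junctions},
                                     merge_tolerance)
        cuts = tuple(sorted(merged_cut_position(c) for c in clusters))
        if len(cuts) != n_segments - 1:
            raise ValidationError(
                f"observed junctions imply {len(cuts)} cut sites after merging, "
                f"expected n_segments - 1 = {n_segments - 1}"
            )
        pairs = tuple((j.a.pos, j.b.pos) for j in junctions)
        return cls(cuts, pairs, fusion_count_override)


@dataclass(frozen=True)
class SimulationResult:
    clustering_stats: np.ndarray = field(compare=False)
    fusion_counts: np.ndarray = field(compare=False)
    p_clustering: float
    p_fusion: float
    observed_clustering: float
    observed_fusion: int
    config: SimulationConfig
    seed: int

    def __post_init__(self) -> None:
        for p in (self.p_clustering, self.p_fusion):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"p-value {p} outside [0, 1]")

    def summary(self) -> dict:
        return {
            "p_clustering": self.p_clustering,
            "p_fusion": self.p_fusion,
            "observed_clustering_bp": self.observed_clustering,
            "observed_fusion_count": int(self.observed_fusion),
            "clustering_method": self.config.clustering,
            "clustering_tail": "strictly smaller",
            "fusion_mode": self.config.fusion_mode,
            "fusion_tail": "greater or equal",
            "pvalue_correction": self.config.pvalue_correction,
            "reps": self.config.reps,
            "n_segments": self.config.n_segments,
            "inversion_prob": self.config.inversion_prob,
            "chromosome_length": self.config.model.length,
            "seed": self.seed,
        }


def clustering_stat(cut_sites: Sequence[int], method: ClusteringMethod = "pairwise") -> float:
    """Average distance between breakpoints, in bp.

    ``pairwise``: mean of |x_i - x_j| over all unordered pairs (dispersion of
    the full configuration). ``gaps``: mean consecutive gap of the sorted
    sites, i.e. range/(n-1). Both are translation invariant.
    """
    sites = np.sort(np.asarray(cut_sites, dtype=np.float64))
    if sites.size < 2:
        raise ValidationError("clustering statistic needs at least 2 cut sites")
    if method == "gaps":
        return float(np.diff(sites).mean())
    if method != "pairwise":
        raise ConfigurationError(f"unknown clustering method {method!r}")
    # mean pairwise |x_i - x_j| via the order-statistic identity
    n = sites.size
    ranks = np.arange(1, n + 1)
    total = float(np.sum((2 * ranks - n - 1) * sites))
    return total / (n * (n - 1) / 2)


def gene_tree(genes: GeneAnnotation) -> IntervalTree:
    """Interval tree over gene bodies (1-based closed converted to half-open)."""
    return IntervalTree.from_tuples(
        (g.start, g.end + 1, g.gene_id) for g in genes
    )


def _genes_at(tree: IntervalTree, pos: int) -> set[str]:
    return {iv.data for iv in tree[pos]}


def fusion_count(
    junction_breakend_pairs: Sequence[tuple[int, int]],
    genes: GeneAnnotation | IntervalTree,
    mode: FusionMode = "junction_fusion",
    cut_sites: Optional[Sequence[int]] = None,
) -> int:
    """Observed/simulated fusion statistic.

    ``junction_fusion``: junctions whose two breakends fall inside gene bodies
    of two *distinct* genes. ``breakpoint_in_gene``: distinct cut sites inside
    any gene body (pass ``cut_sites``; falls back to deduplicated breakend
    positions otherwise).
    """
    tree = genes if isinstance(genes, IntervalTree) else gene_tree(genes)
    if mode == "breakpoint_in_gene":
        if cut_sites is None:
            cut_sites = sorted({p for pair in junction_breakend_pairs for p in pair})
        return sum(1 for c in cut_sites if tree[c])
    if mode != "junction_fusion":
        raise ConfigurationError(f"unknown fusion mode {mode!r}")
    count = 0
    for pa, pb in junction_breakend_pairs:
        ga, gb = _genes_at(tree, pa), _genes_at(tree, pb)
        if ga and gb and any(x != y for x, y in itertools.product(ga, gb)):
            count += 1
    return count


def draw_rearrangement(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[int], list[int], list[bool], list[tuple[int, int]]]:
    """One null replicate: cuts, middle-segment order, orientations, junctions.

    The middle-segment order is reported in reference index space (segment 0
    and segment ``n_segments - 1`` are static); junction breakend pairs come
    from the novel adjacencies of the resulting derivative path.
    """
    cuts, path = _draw_path(rng, config.model, config.n_segments, config.inversion_prob)
    label_to_index = {seg.id: i for i, seg in
                      enumerate(sorted(path.segments, key=lambda s: s.start))}
    order = [label_to_index[s.id] for s in path.segments[1:-1]]
    orientations = [s.inverted for s in path.segments[1:-1]]
    pairs = [j.breakend_pair for j in junctions_from_path(path)]
    return cuts, order, orientations, pairs


def replicate_rng(seed: int, rep: int) -> np.random.Generator:
    """Deterministic per-replicate stream, parallelizable by rep index."""
    return np.random.default_rng([seed, rep])


def run_simulation(
    config: SimulationConfig,
    observed: ObservedCase,
    genes: GeneAnnotation,
) -> SimulationResult:
    """Run the null model and return empirical p-values plus the statistic vectors."""
    if len(observed.cut_sites) != config.n_segments - 1:
        raise ValidationError(
            f"observed case has {len(observed.cut_sites)} cut sites but the "
            f"configuration simulates {config.n_segments} segments"
        )
    tree = gene_tree(genes)
    obs_clustering = clustering_stat(observed.cut_sites, config.clustering)
    if observed.fusion_count_override is not None:
        obs_fusion = int(observed.fusion_count_override)
    elif config.fusion_mode == "breakpoint_in_gene":
        obs_fusion = fusion_count((), tree, "breakpoint_in_gene", observed.cut_sites)
    else:
        obs_fusion = fusion_count(observed.junction_breakend_pairs, tree)

    clustering_stats = np.empty(config.reps, dtype=np.float64)
    fusion_counts = np.empty(config.reps, dtype=np.int64)
    for r in range(config.reps):
        rng = replicate_rng(config.seed, r)
        cuts, _, _, pairs = draw_rearrangement(config, rng)
        clustering_stats[r] = clustering_stat(cuts, config.clustering)
        if config.fusion_mode == "breakpoint_in_gene":
            fusion_counts[r] = fusion_count((), tree, "breakpoint_in_gene", cuts)
        else:
            fusion_counts[r] = fusion_count(pairs, tree)

    k_clust = int(np.sum(clustering_stats < obs_clustering))
    k_fus = int(np.sum(fusion_counts >= obs_fusion))
    if config.pvalue_correction:
        p_clust = (k_clust + 1) / (config.reps + 1)
        p_fus = (k_fus + 1) / (config.reps + 1)
    else:
        p_clust = k_clust / config.reps
        p_fus = k_fus / config.reps
    return SimulationResult(
        clustering_stats=clustering_stats,
        fusion_counts=fusion_counts,
        p_clustering=p_clust,
        p_fusion=p_fus,
        observed_clustering=obs_clustering,
        observed_fusion=obs_fusion,
        config=config,
        seed=config.seed,
    )
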