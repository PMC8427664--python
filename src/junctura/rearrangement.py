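"""Derivative-chromosome assembly from breakpoint junctions.

The assembler treats each junction as an edge joining two segment ends.
Breakends within ``merge_tolerance`` of a shared cut are unified into one cut
site first (real junction pairs at the same disruption differ by small
resections, e.g. 13 bp at the ARID1B site of the index case), then the unique
linear walk from the p terminus to the q terminus is recovered. Branched or
cyclic edge sets are rejected.
"""

from __future__ import annotations

from collections.abc import Sequence

from .errors import NonLinearArchitectureError, ValidationError
from .models import (
    Breakend,
    ChromosomeModel,
    DerivativePath,
    InversionSummary,
    Junction,
    Orientation,
    Segment,
    Side,
)

DEFAULT_MERGE_TOLERANCE = 100


def segment_label(index: int) -> str:
    """Spreadsheet-style labels: A..Z, AA, AB, ..."""
    label = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def segments_from_cuts(cuts: Sequence[int], model: ChromosomeModel) -> list[Segment]:
    """Partition ``[1, model.length]`` at the given cut sites.

    Cut site ``x`` severs between ``x`` and ``x + 1``; ``len(cuts) + 1``
    direct segments are returned in reference order.
    """
    cuts = list(cuts)
    if any(cuts[i] >= cuts[i + 1] for i in range(len(cuts) - 1)):
        raise ValidationError(f"cut sites must be strictly increasing, got {cuts}")
    if any(c < 1 or c > model.length - 1 for c in cuts):
        raise ValidationError(
            f"cut sites must lie in [1, {model.length - 1}], got {cuts}"
        )
    bounds = [0] + cuts + [model.length]
    return [
        Segment(segment_label(i), bounds[i] + 1, bounds[i + 1])
        for i in range(len(bounds) - 1)
    ]


def cluster_cut_sites(cut_sites: Sequence[int], tolerance: int) -> list[list[int]]:
    """Single-linkage clustering of cut sites: split where the gap > tolerance."""
    ordered = sorted(cut_sites)
    clusters: list[list[int]] = []
    for c in ordered:
        if clusters and c - clusters[-1][-1] <= tolerance:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    return clusters


def merged_cut_position(cluster: Sequence[int]) -> int:
    """Unified position of a breakend cluster: midpoint rounded down."""
    return (min(cluster) + max(cluster)) // 2


def assemble_path(
    junctions: Sequence[Junction],
    model: ChromosomeModel,
    merge_tolerance: int = DEFAULT_MERGE_TOLERANCE,
) -> DerivativePath:
    """Assemble the unique linear derivative path encoded by ``junctions``.

    Every internal segment end must be used by exactly one junction breakend;
    the walk starts at the segment containing reference position 1 and must
    terminate at the segment containing ``model.length``.

    Raises
    ------
    NonLinearArchitectureError
        If a breakend is used twice, a segment end dangles, or the junctions
        describe a cyclic or branched structure. The offending junction ids
        are attached to the exception.
    """
    if not junctions:
        # No novel adjacency: the derivative is the reference chromosome.
        return DerivativePath(segments_from_cuts([], model), model)

    ids = [j.id for j in junctions]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate junction ids: {dupes}")

    # 1. Unify breakend cut sites.
    raw_sites = [j.a.cut_site for j in junctions] + [j.b.cut_site for j in junctions]
    clusters = cluster_cut_sites(set(raw_sites), merge_tolerance)
    site_of: dict[int, int] = {}
    for cluster in clusters:
        merged = merged_cut_position(cluster)
        for c in cluster:
            site_of[c] = merged
    cuts = sorted({merged_cut_position(c) for c in clusters})
    segments = segments_from_cuts(cuts, model)

    # 2. Map each breakend to a segment end. Ends are (segment_index, "L"/"R").
    start_index = {s.start: i for i, s in enumerate(segments)}
    end_index = {s.end: i for i, s in enumerate(segments)}

    def end_of(be: Breakend, jid: str) -> tuple[int, str]:
        cut = site_of[be.cut_site]
        if be.side is Side.LEFT_OF_CUT:
            return (end_index[cut], "R")
        return (start_index[cut + 1], "L")

    # 3. Build the end-to-end adjacency induced by the junctions.
    edges: dict[tuple[int, str], tuple[tuple[int, str], str]] = {}
    for j in junctions:
        for here, there in ((end_of(j.a, j.id), end_of(j.b, j.id)),
                            (end_of(j.b, j.id), end_of(j.a, j.id))):
            if here in edges:
                raise NonLinearArchitectureError(
                    f"breakend at segment end {here} used by junctions "
                    f"{edges[here][1]} and {j.id}",
                    junction_ids=[edges[here][1], j.id],
                )
            edges[here] = (there, j.id)

    n = len(segments)
    terminal_p, terminal_q = (0, "L"), (n - 1, "R")
    for terminus in (terminal_p, terminal_q):
        if terminus in edges:
            jid = edges[terminus][1]
            raise NonLinearArchitectureError(
                f"junction {jid} uses a chromosome terminus", junction_ids=[jid]
            )

    # 4. Walk from the p terminus.
    ordered: list[Segment] = []
    used_junctions: set[str] = set()
    seen: set[int] = set()
    seg_idx, entry = 0, "L"
    while True:
        if seg_idx in seen:
            raise NonLinearArchitectureError(
                "cyclic architecture revisits a segment",
                junction_ids=sorted(set(ids) - used_junctions),
            )
        seen.add(seg_idx)
        ref = segments[seg_idx]
        orientation = Orientation.DIRECT if entry == "L" else Orientation.INVERTED
        ordered.append(Segment(ref.id, ref.start, ref.end, orientation))
        exit_end = (seg_idx, "R" if entry == "L" else "L")
        if exit_end == terminal_q:
            break
        if exit_end not in edges:
            raise NonLinearArchitectureError(
                f"dangling segment end {exit_end}: no junction continues the walk",
                junction_ids=sorted(set(ids) - used_junctions),
            )
        (seg_idx, far_end), jid = edges[exit_end]
        used_junctions.add(jid)
        entry = far_end

    if len(seen) != n or used_junctions != set(ids):
        leftover = sorted(set(ids) - used_junctions)
        raise NonLinearArchitectureError(
            f"junctions {leftover} form a branch or cycle disconnected from the "
            "p-to-q walk",
            junction_ids=leftover,
        )
    return DerivativePath(ordered, model)


def is_reference_adjacency(left: Segment, right: Segment) -> bool:
    """True when two consecutive path segments read as in the reference."""
    if not left.inverted and not right.inverted:
        return right.start == left.end + 1
    if left.inverted and right.inverted:
        return left.start == right.end + 1
    return False


def canonicalize_path(path: DerivativePath) -> DerivativePath:
    """Merge reference-like consecutive segments; relabel in reference order.

    The canonical form is the path whose cuts are exactly the observable ones
    (every internal adjacency is a genuine junction).
    """
    merged: list[Segment] = []
    for seg in path:
        if merged and is_reference_adjacency(merged[-1], seg):
            prev = merged.pop()
            lo, hi = min(prev.start, seg.start), max(prev.end, seg.end)
            merged.append(Segment(prev.id, lo, hi, prev.orientation))
        else:
            merged.append(seg)
    order = {s.id: i for i, s in enumerate(sorted(merged, key=lambda s: s.start))}
    relabelled = [
        Segment(segment_label(order[s.id]), s.start, s.end, s.orientation) for s in merged
    ]
    return DerivativePath(relabelled, path.model)


def junctions_from_path(
    path: DerivativePath,
    include_reference_adjacencies: bool = False,
    id_prefix: str = "J",
) -> list[Junction]:
    """Emit one junction per (by default, non-reference) path adjacency.

    Breakend positions and sides are determined by the flanking segment ends
    and orientations; ``assemble_path`` of the result reproduces the path
    (exactly when every adjacency is emitted; up to canonicalization when
    reference-like adjacencies are dropped).
    """
    chrom = path.model.name

    def exit_breakend(seg: Segment) -> Breakend:
        if seg.inverted:
            return Breakend(chrom, seg.start, Side.RIGHT_OF_CUT)
        return Breakend(chrom, seg.end, Side.LEFT_OF_CUT)

    def entry_breakend(seg: Segment) -> Breakend:
        if seg.inverted:
            return Breakend(chrom, seg.end, Side.LEFT_OF_CUT)
        return Breakend(chrom, seg.start, Side.RIGHT_OF_CUT)

    out: list[Junction] = []
    for left, right in zip(path.segments, path.segments[1:]):
        if not include_reference_adjacencies and is_reference_adjacency(left, right):
            continue
        out.append(
            Junction(f"{id_prefix}{len(out) + 1}", exit_breakend(left), entry_breakend(right))
        )
    return out


def classify_inversions(path: DerivativePath) -> InversionSummary:
    """Count inversion events and split them into pericentric vs paracentric.

    Each inverted segment counts as one event; an event is pericentric iff
    its reference interval contains the centromere midpoint. Junctions are
    the path adjacencies that differ from the reference.
    """
    inverted = [s for s in path if s.inverted]
    per_segment: list[tuple[str, str]] = []
    n_peri = 0
    if inverted:
        midpoint = path.model.centromere_midpoint  # raises if undefined
        for s in inverted:
            klass = "pericentric" if s.contains(midpoint) else "paracentric"
            if klass == "pericentric":
                n_peri += 1
            per_segment.append((s.id, klass))
    n_junctions = sum(
        0 if is_reference_adjacency(a, b) else 1
        for a, b in zip(path.segments, path.segments[1:])
    )
    return InversionSummary(
        n_inversions=len(inverted),
        n_pericentric=n_peri,
        n_paracentric=len(inverted) - n_peri,
        n_junctions=n_junctions,
        per_segment=tuple(per_segment),
    )
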