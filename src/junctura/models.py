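"""Core domain types for copy-number-neutral rearrangement analysis.

Coordinate convention: all positions are 1-based and all intervals are closed
``[start, end]``, matching karyotype/VCF usage (e.g. a breakpoint printed as
chr6:157,240,695 is the 157,240,695th base). BED input/output is converted at
the boundary by :mod:`junctura.io`.

A *cut site* ``x`` means the chromosome is severed between positions ``x`` and
``x + 1``; a :class:`Breakend` records which flank of that cut the retained
sequence lies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

from .errors import ValidationError


class Side(str, Enum):
    """Which flank of a cut a breakend retains.

    ``LEFT_OF_CUT`` at position p: the retained sequence ends at p (the cut is
    between p and p+1). ``RIGHT_OF_CUT`` at position p: the retained sequence
    starts at p (the cut is between p-1 and p).
    """

    LEFT_OF_CUT = "left_of_cut"
    RIGHT_OF_CUT = "right_of_cut"


class Orientation(str, Enum):
    DIRECT = "direct"
    INVERTED = "inverted"


@dataclass(frozen=True)
class ChromosomeModel:
    """A chromosome as a length plus an optional centromere interval."""

    name: str
    length: int
    centromere: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"chromosome length must be positive, got {self.length}")
        if self.centromere is not None:
            s, e = self.centromere
            if not (1 <= s <= e <= self.length):
                raise ValidationError(
                    f"centromere {self.centromere} outside [1, {self.length}] or inverted"
                )

    @property
    def centromere_midpoint(self) -> int:
        if self.centromere is None:
            raise ValidationError(f"chromosome {self.name} has no centromere defined")
        s, e = self.centromere
        return (s + e) // 2


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    start: int
    end: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


class GeneAnnotation:
    """An ordered collection of gene intervals with unique ids."""

    def __init__(self, records: Sequence[GeneRecord]):
        ids = [r.gene_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes}")
        self.records: list[GeneRecord] = sorted(records, key=lambda r: (r.start, r.end))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneAnnotation) and self.records == other.records

    def total_span(self) -> int:
        """Sum of gene body lengths (genes are not merged)."""
        return sum(r.length for r in self.records)

    def protein_coding(self) -> "GeneAnnotation":
        return GeneAnnotation([r for r in self.records if r.biotype == "protein_coding"])


@dataclass(frozen=True)
class Breakend:
    """One side of a double-strand break."""

    chrom: str
    pos: int
    side: Side

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"breakend position must be >= 1, got {self.pos}")

    @property
    def cut_site(self) -> int:
        """The cut site this breakend references (cut between x and x+1)."""
        return self.pos if self.side is Side.LEFT_OF_CUT else self.pos - 1


@dataclass(frozen=True)
class Junction:
    """A novel adjacency joining two breakends, optionally with inserted bases."""

    id: str
    a: Breakend
    b: Breakend
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValidationError(f"junction {self.id}: breakends a and b are identical")

    @property
    def breakend_pair(self) -> tuple[int, int]:
        return (self.a.pos, self.b.pos)


@dataclass(frozen=True)
class Segment:
    """An oriented reference interval within a derivative chromosome."""

    id: str
    start: int
    end: int
    orientation: Orientation = Orientation.DIRECT

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValidationError(
                f"segment {self.id}: invalid interval [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def inverted(self) -> bool:
        return self.orientation is Orientation.INVERTED

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class DerivativePath:
    """An ordered, oriented walk of reference segments forming the derivative.

    Invariants (checked on construction): the segment reference intervals are
    pairwise disjoint and partition ``[1, model.length]``; the path starts at
    reference position 1 (first segment direct, start == 1) and ends at
    ``model.length`` (last segment direct, end == length) — the terminal
    segments of a single-chromosome, telomere-to-telomere derivative are
    positionally static.
    """

    segments: tuple[Segment, ...]
    model: ChromosomeModel

    def __init__(self, segments: Sequence[Segment], model: ChromosomeModel):
        object.__setattr__(self, "segments", tuple(segments))
        object.__setattr__(self, "model", model)
        self._validate()

    def _validate(self) -> None:
        if not self.segments:
            raise ValidationError("derivative path has no segments")
        by_start = sorted(self.segments, key=lambda s: s.start)
        if by_start[0].start != 1:
            raise ValidationError("segment intervals do not start at position 1")
        for prev, cur in zip(by_start, by_start[1:]):
            if cur.start != prev.end + 1:
                raise ValidationError(
                    f"segment intervals are not a partition: gap/overlap between "
                    f"[{prev.start},{prev.end}] and [{cur.start},{cur.end}]"
                )
        if by_start[-1].end != self.model.length:
            raise ValidationError(
                f"segment intervals end at {by_start[-1].end}, "
                f"expected chromosome length {self.model.length}"
            )
        first, last = self.segments[0], self.segments[-1]
        if first.start != 1 or first.inverted:
            raise ValidationError("path must begin with the direct segment containing position 1")
        if last.end != self.model.length or last.inverted:
            raise ValidationError("path must end with the direct segment containing the q terminus")

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def cut_sites(self) -> tuple[int, ...]:
        """Reference cut sites implied by the segment partition (sorted)."""
        ends = sorted(s.end for s in self.segments)
        return tuple(ends[:-1])

    def describe(self) -> str:
        """Compact human-readable form, e.g. ``A B- C- D- F+ E- G``."""
        marks = {Orientation.DIRECT: "+", Orientation.INVERTED: "-"}
        return " ".join(f"{s.id}{marks[s.orientation]}" for s in self.segments)


@dataclass(frozen=True)
class InversionSummary:
    """Counts of inversion events in a derivative path."""

    n_inversions: int
    n_pericentric: int
    n_paracentric: int
    n_junctions: int
    per_segment: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_inversions != self.n_pericentric + self.n_paracentric:
            raise ValidationError("n_inversions must equal n_pericentric + n_paracentric")
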