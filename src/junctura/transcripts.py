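"""Placing breakpoints onto transcript models (exon/intron lookup)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .errors import ValidationError


@dataclass(frozen=True)
class TranscriptModel:
    """Genomic exon intervals of one transcript (1-based closed, sorted)."""

    name: str
    chrom: str
    strand: Literal["+", "-"]
    exons: tuple[tuple[int, int], ...]

    def __init__(self, name: str, chrom: str, strand: str, exons: Sequence[tuple[int, int]]):
        exons = tuple(sorted((int(s), int(e)) for s, e in exons))
        for s, e in exons:
            if s > e:
                raise ValidationError(f"{name}: exon [{s}, {e}] inverted")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValidationError(f"{name}: overlapping or abutting exons")
        if strand not in "+-":
            raise ValidationError(f"{name}: strand must be + or -")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "strand", strand)
        object.__setattr__(self, "exons", exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def locate(self, pos: int) -> tuple[str, int]:
        """Return ('exon'|'intron'|'upstream'|'downstream', 1-based index).

        Indices follow transcript order: on the minus strand exon 1 is the
        genomically last exon. Intron k lies between exons k and k+1.
        ``upstream``/``downstream`` carry index 0.
        """
        if pos < self.exons[0][0]:
            genomic = ("upstream", 0)
        elif pos > self.exons[-1][1]:
            genomic = ("downstream", 0)
        else:
            genomic = None
            for i, (s, e) in enumerate(self.exons):
                if s <= pos <= e:
                    genomic = ("exon", i + 1)
                    break
                if pos < s:
                    genomic = ("intron", i)  # between genomic exons i and i+1
                    break
            assert genomic is not None
        kind, idx = genomic
        if self.strand == "-":
            if kind == "exon":
                idx = self.n_exons - idx + 1
            elif kind == "intron":
                idx = self.n_exons - idx
            elif kind == "upstream":
                kind = "downstream"
            else:
                kind = "upstream"
        return kind, idx
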