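"""Exon-interval gene models and their derived feature chains."""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import FormatError

__all__ = ["GeneModel"]


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered chain of exon intervals (0-based half-open).

    Introns are implied between consecutive exons.  ``features()`` yields
    the alternating exon/intron chain in genomic order, which is what the
    proximity classification walks.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise FormatError(f"{self.gene_id}: gene model has no exons")
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        for start, end in exons:
            if start >= end:
                raise FormatError(f"{self.gene_id}: invalid exon {start}-{end}")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise FormatError(f"{self.gene_id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1]

    def features(self) -> list[tuple[str, int, int]]:
        """Alternating ('exon'|'intron', start, end) chain in genomic order."""
        chain: list[tuple[str, int, int]] = []
        for i, (s, e) in enumerate(self.exons):
            chain.append(("exon", s, e))
            if i < len(self.exons) - 1:
                ns = self.exons[i + 1][0]
                if ns > e:
                    chain.append(("intron", e, ns))
        return chain

    def intron_index(self, start: int, end: int) -> int | None:
        """Index of the intron matching (start, end) exactly, else None."""
        for i, (s, e) in enumerate(self.introns()):
            if (s, e) == (start, end):
                return i
        return None
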