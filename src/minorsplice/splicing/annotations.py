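"""Minor (U12-type) intron annotations and exact-coordinate merging."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from ..errors import FormatError

__all__ = ["IntronAnnotation", "merge_u12_annotations"]

_VALID_SUBTYPES = {"GT-AG", "AT-AC", "other", None}


@dataclass(frozen=True)
class IntronAnnotation:
    """One U12-type intron interval (0-based, half-open).

    ``sources`` records which database list(s) contributed the record;
    after a merge it is never empty.
    """

    chrom: str
    start: int
    end: int
    strand: str
    subtype: str | None = None
    sources: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"invalid strand {self.strand!r}")
        if self.subtype not in _VALID_SUBTYPES:
            raise FormatError(f"invalid intron subtype {self.subtype!r}")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    def overlaps(self, chrom: str, start: int, end: int, strand: str | None = None) -> bool:
        if chrom != self.chrom:
            return False
        if strand is not None and strand != self.strand:
            return False
        return start < self.end and end > self.start


def merge_u12_annotations(
    lists: Iterable[Iterable[IntronAnnotation]],
) -> list[IntronAnnotation]:
    """Merge several intron lists by exact coordinates.

    Records identical on (chrom, start, end, strand) collapse into one
    with the union of their source labels; no tolerance window is
    applied, so coordinate disagreements between databases surface as
    separate records.  Output is sorted by (chrom, start, end, strand).
    Subtypes are kept when the merged records agree, dropped to None on
    conflict.
    """
    merged: dict[tuple, IntronAnnotation] = {}
    for records in lists:
        for rec in records:
            prev = merged.get(rec.key)
            if prev is None:
                merged[rec.key] = rec
            else:
                subtype = prev.subtype if prev.subtype == rec.subtype else None
                merged[rec.key] = IntronAnnotation(
                    chrom=rec.chrom,
                    start=rec.start,
                    end=rec.end,
                    strand=rec.strand,
                    subtype=subtype,
                    sources=prev.sources | rec.sources,
                )
    out = sorted(merged.values(), key=lambda r: r.key)
    for rec in out:
        if not rec.sources:
            raise FormatError(
                f"merged intron {rec.chrom}:{rec.start}-{rec.end} has no source label"
            )
    return out
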