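"""Alternative-splicing events: significance filtering and minor-intron
proximity classification."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from ..errors import ConsistencyError, FormatError
from .annotations import IntronAnnotation
from .models import GeneModel

__all__ = [
    "ASEvent",
    "EventClass",
    "filter_significant_events",
    "classify_event",
    "classify_events",
    "EVENT_TYPES",
]

EVENT_TYPES = ("CE", "AA", "AD", "RI")


class EventClass(Enum):
    """Mutually exclusive position classes relative to U12-type introns."""

    WITHIN_U12 = "WITHIN_U12"
    PROXIMAL_U12 = "PROXIMAL_U12"
    U12_GENE_DISTAL = "U12_GENE_DISTAL"
    U2_ONLY_BACKGROUND = "U2_ONLY_BACKGROUND"


@dataclass(frozen=True)
class ASEvent:
    """One alternative-splicing event in a two-condition comparison.

    ``delta_psi`` is ``psi_b - psi_a`` (condition b minus condition a; in
    the synthetic pipeline b is the perturbed condition).  ``probability``
    is the caller's posterior that the event changed.
    """

    gene_id: str
    event_type: str
    chrom: str
    start: int
    end: int
    strand: str
    psi_a: float
    psi_b: float
    probability: float
    delta_psi: float | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(f"invalid event interval {self.start}-{self.end}")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"invalid strand {self.strand!r}")
        for name in ("psi_a", "psi_b", "probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FormatError(f"{name}={v} outside [0, 1]")
        if self.delta_psi is None:
            object.__setattr__(self, "delta_psi", self.psi_b - self.psi_a)
        if abs(self.delta_psi) > 1.0 + 1e-12:
            raise FormatError(f"|delta_psi|={abs(self.delta_psi)} exceeds 1")


def filter_significant_events(
    events: Sequence[ASEvent], pr_min: float = 0.9, dpsi_min: float = 0.05
) -> list[ASEvent]:
    """Keep events with probability > pr_min and |delta_psi| > dpsi_min.

    Both thresholds are strict inequalities; an event sitting exactly on
    a threshold is excluded.  Input order is preserved.
    """
    if not 0.0 <= pr_min <= 1.0 or not 0.0 <= dpsi_min <= 1.0:
        raise FormatError("thresholds must lie in [0, 1]")
    # the epsilon guards keep values exactly at a threshold excluded even
    # when psi arithmetic leaves them a few ulp above it
    eps = 1e-9
    return [
        ev
        for ev in events
        if ev.probability > pr_min + eps and abs(ev.delta_psi) > dpsi_min + eps
    ]


def _flanking_features(
    gene: GeneModel, intron: IntronAnnotation
) -> list[tuple[str, int, int]]:
    """Immediate up- and downstream exons and introns of a U12 intron.

    Returns up to two features per side of the intron in the gene's
    feature chain: the adjacent exon and the next intron beyond it.
    """
    chain = gene.features()
    idx = None
    for i, (kind, s, e) in enumerate(chain):
        if kind == "intron" and (s, e) == (intron.start, intron.end):
            idx = i
            break
    if idx is None:
        # Coordinate disagreement with the gene model: fall back to the
        # chain feature(s) overlapping the annotated intron.
        overlapping = [
            i
            for i, (kind, s, e) in enumerate(chain)
            if kind == "intron" and s < intron.end and e > intron.start
        ]
        if not overlapping:
            return []
        idx = overlapping[0]
    lo = max(idx - 2, 0)
    hi = min(idx + 2, len(chain) - 1)
    return [chain[i] for i in range(lo, hi + 1) if i != idx]


def classify_event(
    event: ASEvent,
    u12_set: Sequence[IntronAnnotation],
    gene_models: Mapping[str, GeneModel],
) -> EventClass:
    """Place one event relative to the U12-type intron annotation.

    Precedence: WITHIN_U12 (interval overlaps a U12 intron, same strand)
    > PROXIMAL_U12 (overlaps an immediately flanking exon or intron of a
    U12 intron in the host gene) > U12_GENE_DISTAL (host gene carries a
    U12 intron) > U2_ONLY_BACKGROUND.

    Raises
    ------
    ConsistencyError
        If the event's gene is absent from ``gene_models``.
    """
    gene = gene_models.get(event.gene_id)
    if gene is None:
        raise ConsistencyError(f"gene {event.gene_id!r} absent from gene models")

    for intron in u12_set:
        if intron.overlaps(event.chrom, event.start, event.end, event.strand):
            return EventClass.WITHIN_U12

    gene_u12 = [
        intron
        for intron in u12_set
        if intron.chrom == gene.chrom
        and intron.strand == gene.strand
        and intron.start >= gene.start
        and intron.end <= gene.end
    ]
    for intron in gene_u12:
        for _, s, e in _flanking_features(gene, intron):
            if event.chrom == gene.chrom and event.start < e and event.end > s:
                return EventClass.PROXIMAL_U12
    if gene_u12:
        return EventClass.U12_GENE_DISTAL
    return EventClass.U2_ONLY_BACKGROUND


def classify_events(
    events: Iterable[ASEvent],
    u12_set: Sequence[IntronAnnotation],
    gene_models: Mapping[str, GeneModel],
) -> tuple[list[tuple[ASEvent, EventClass]], list[ASEvent]]:
    """Classify a table of events; unclassifiable events go to a skip list."""
    classified: list[tuple[ASEvent, EventClass]] = []
    skipped: list[ASEvent] = []
    for ev in events:
        try:
            classified.append((ev, classify_event(ev, u12_set, gene_models)))
        except ConsistencyError:
            skipped.append(ev)
    return classified, skipped
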