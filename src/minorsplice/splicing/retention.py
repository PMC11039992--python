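"""Differential intron-retention summary from externally computed IR ratios."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ..errors import ConsistencyError, InvalidArgumentError

__all__ = ["IRRecord", "IRSummary", "differential_ir"]


@dataclass(frozen=True)
class IRRecord:
    """One intron's retention ratio and read support in one condition."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    ir_ratio: float
    depth: int

    def __post_init__(self):
        if not 0.0 <= self.ir_ratio <= 1.0:
            raise InvalidArgumentError(f"ir_ratio={self.ir_ratio} outside [0, 1]")
        if self.depth < 0:
            raise InvalidArgumentError("depth must be >= 0")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class IRSummary:
    """Gain/loss calls per intron, summarized per gene by the most
    extreme intron."""

    gained_introns: list[tuple]
    lost_introns: list[tuple]
    gained_genes: list[str]
    lost_genes: list[str]

    @property
    def n_gained_genes(self) -> int:
        return len(self.gained_genes)

    @property
    def n_lost_genes(self) -> int:
        return len(self.lost_genes)


def differential_ir(
    ir_a: Sequence[IRRecord],
    ir_b: Sequence[IRRecord],
    min_delta: float,
    min_depth: int,
) -> IRSummary:
    """Call retention gains and losses between two conditions.

    An intron is *gained* when ``ir_b - ir_a > min_delta`` (strict) with
    both depths >= min_depth, *lost* when ``ir_a - ir_b > min_delta``
    under the same depth rule.  Each gene is summarized by its most
    extreme intron (largest |delta| among called introns).

    Raises
    ------
    ConsistencyError
        If the two tables are not keyed by the identical intron set.
    InvalidArgumentError
        If ``min_delta`` is outside (0, 1].
    """
    if not 0.0 < min_delta <= 1.0:
        raise InvalidArgumentError(f"min_delta must be in (0, 1], got {min_delta}")
    a_by_key = {r.key: r for r in ir_a}
    b_by_key = {r.key: r for r in ir_b}
    if set(a_by_key) != set(b_by_key):
        only_a = set(a_by_key) - set(b_by_key)
        only_b = set(b_by_key) - set(a_by_key)
        raise ConsistencyError(
            f"IR tables keyed by different introns "
            f"({len(only_a)} only in a, {len(only_b)} only in b)"
        )

    gained: list[tuple] = []
    lost: list[tuple] = []
    gene_extreme: dict[str, float] = {}
    for key in sorted(a_by_key):
        ra, rb = a_by_key[key], b_by_key[key]
        if ra.depth < min_depth or rb.depth < min_depth:
            continue
        delta = rb.ir_ratio - ra.ir_ratio
        # epsilon guard: a delta exactly at min_delta stays uncalled even
        # when ratio arithmetic leaves it a few ulp above the threshold
        if delta > min_delta + 1e-9:
            gained.append(key + (delta,))
        elif -delta > min_delta + 1e-9:
            lost.append(key + (delta,))
        else:
            continue
        prev = gene_extreme.get(ra.gene_id)
        if prev is None or abs(delta) > abs(prev):
            gene_extreme[ra.gene_id] = delta

    gained_genes = sorted(g for g, d in gene_extreme.items() if d > 0)
    lost_genes = sorted(g for g, d in gene_extreme.items() if d < 0)
    return IRSummary(
        gained_introns=gained,
        lost_introns=lost,
        gained_genes=gained_genes,
        lost_genes=lost_genes,
    )
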