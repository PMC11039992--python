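"""Hypergeometric enrichment of event types in the minor-intron stratum.

The test stratum pools WITHIN_U12 and PROXIMAL_U12 events; the background
stratum is U2_ONLY_BACKGROUND.  U12_GENE_DISTAL events sit in neither
stratum, so they contaminate neither side of the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy.stats import hypergeom

from ..errors import InvalidArgumentError
from .events import ASEvent, EventClass

__all__ = ["EnrichmentResult", "enrichment_test", "benjamini_hochberg"]

_U12_STRATUM = {EventClass.WITHIN_U12, EventClass.PROXIMAL_U12}


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 enrichment of one event type in the U12 stratum.

    Counts: ``k`` type-matching events in the U12 stratum, ``n`` U12
    stratum size, ``K`` type-matching events overall, ``N`` all events
    (both strata).  ``fold`` compares the U12-stratum rate to the
    background-stratum rate, (k/n) / ((K-k)/(N-n)); ``fold_overall`` is
    the simpler (k/n) / (K/N) variant.  ``p_upper`` is P[X >= k]
    (enrichment), ``p_lower`` is P[X <= k] (depletion); ``p_two_sided``
    is min(1, 2 * min(tails)).
    """

    event_type: str
    k: int
    n: int
    K: int
    N: int
    fold: float
    fold_overall: float
    p_upper: float
    p_lower: float
    p_two_sided: float

    def to_dict(self) -> dict:
        return {
            "event_type": self.event_type,
            "counts": {"k": self.k, "n": self.n, "K": self.K, "N": self.N},
            "fold_vs_background": self.fold,
            "fold_vs_overall": self.fold_overall,
            "p_upper": self.p_upper,
            "p_lower": self.p_lower,
            "p_two_sided": self.p_two_sided,
        }


def enrichment_test(
    classified_events: Iterable[tuple[ASEvent, EventClass]], event_type: str
) -> EnrichmentResult:
    """Hypergeometric test for over-representation of one event type.

    Raises
    ------
    InvalidArgumentError
        If either stratum is empty.
    """
    u12_events = []
    background_events = []
    for ev, cls in classified_events:
        if cls in _U12_STRATUM:
            u12_events.append(ev)
        elif cls is EventClass.U2_ONLY_BACKGROUND:
            background_events.append(ev)
    if not u12_events or not background_events:
        raise InvalidArgumentError(
            f"empty stratum: |U12|={len(u12_events)}, "
            f"|background|={len(background_events)}"
        )

    n = len(u12_events)
    N = n + len(background_events)
    k = sum(ev.event_type == event_type for ev in u12_events)
    K = k + sum(ev.event_type == event_type for ev in background_events)

    bg_rate = (K - k) / (N - n)
    fold = (k / n) / bg_rate if bg_rate > 0 else float("inf") if k else float("nan")
    overall_rate = K / N
    fold_overall = (k / n) / overall_rate if overall_rate > 0 else float("nan")

    p_upper = float(hypergeom.sf(k - 1, N, K, n))
    p_lower = float(hypergeom.cdf(k, N, K, n))
    p_two = min(1.0, 2.0 * min(p_upper, p_lower))
    return EnrichmentResult(
        event_type=event_type,
        k=k,
        n=n,
        K=K,
        N=N,
        fold=fold,
        fold_overall=fold_overall,
        p_upper=p_upper,
        p_lower=p_lower,
        p_two_sided=p_two,
    )


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH-adjusted q-values, optional for multi-type sweeps."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, pvalues[i] * m / rank)
        q[i] = prev
    return q
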