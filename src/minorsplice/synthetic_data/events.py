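"""Synthetic gene models and alternative-splicing event tables.

The generator plants a controllable excess of alternative-acceptor (AA)
events in the minor-intron stratum: among events placed within or
immediately adjacent to a U12-type intron, the AA sampling probability is
``aa_enrichment_fold`` times the background AA weight (renormalizing the
other types), so the downstream rate-ratio estimate targets the planted
fold directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConsistencyError, InvalidArgumentError
from ..splicing.annotations import IntronAnnotation
from ..splicing.events import ASEvent, EVENT_TYPES
from ..splicing.models import GeneModel

__all__ = [
    "SignificanceModel",
    "SyntheticEventConfig",
    "simulate_gene_models",
    "simulate_as_events",
]

# Placement mix for events in U12-intron-containing genes:
# (within the U12 intron, in an immediately flanking feature, elsewhere).
_U12_PLACEMENT_WEIGHTS = (0.35, 0.35, 0.30)


@dataclass(frozen=True)
class SignificanceModel:
    """Distributions for the per-event probability and delta-PSI.

    probability ~ Beta(pr_alpha, pr_beta); psi_a ~ Uniform(0.05, 0.95);
    delta-PSI ~ Normal(0, dpsi_sd) with psi_b clipped into [0, 1].
    """

    pr_alpha: float = 6.0
    pr_beta: float = 0.8
    dpsi_sd: float = 0.15

    def __post_init__(self):
        if self.pr_alpha <= 0 or self.pr_beta <= 0 or self.dpsi_sd < 0:
            raise InvalidArgumentError("invalid significance model parameters")


@dataclass(frozen=True)
class SyntheticEventConfig:
    """Configuration for one synthetic AS-event table."""

    n_genes: int
    frac_u12_genes: float
    n_events: int
    event_type_weights: tuple[float, float, float, float] = (0.40, 0.15, 0.15, 0.30)
    aa_enrichment_fold: float = 1.0
    significance: SignificanceModel = field(default_factory=SignificanceModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_events < 0:
            raise InvalidArgumentError("n_genes must be >= 1 and n_events >= 0")
        if not 0.0 <= self.frac_u12_genes <= 1.0:
            raise InvalidArgumentError("frac_u12_genes must be in [0, 1]")
        if len(self.event_type_weights) != len(EVENT_TYPES):
            raise InvalidArgumentError(
                f"event_type_weights must have {len(EVENT_TYPES)} entries "
                f"(order {EVENT_TYPES})"
            )
        if abs(sum(self.event_type_weights) - 1.0) > 1e-9:
            raise InvalidArgumentError("event_type_weights must sum to 1")
        if any(w < 0 for w in self.event_type_weights):
            raise InvalidArgumentError("event_type_weights must be >= 0")
        if self.aa_enrichment_fold < 1.0:
            raise InvalidArgumentError("aa_enrichment_fold must be >= 1")


def simulate_gene_models(
    n_genes: int, frac_u12_genes: float, seed: int = 0
) -> tuple[dict[str, GeneModel], list[IntronAnnotation]]:
    """Build a deterministic synthetic gene set with optional U12 introns.

    Every gene has 7 exons of 200 bp separated by 1 kb introns, laid out
    head-to-tail along one chromosome.  The first
    ``round(frac_u12_genes * n_genes)`` genes carry a U12-type
    annotation on their middle (4th) intron, alternating GT-AG / AT-AC
    subtypes.
    """
    if n_genes < 1:
        raise InvalidArgumentError("n_genes must be >= 1")
    if not 0.0 <= frac_u12_genes <= 1.0:
        raise InvalidArgumentError("frac_u12_genes must be in [0, 1]")
    n_u12 = int(round(frac_u12_genes * n_genes))
    genes: dict[str, GeneModel] = {}
    u12: list[IntronAnnotation] = []
    exon_len, intron_len, n_exons = 200, 1000, 7
    gene_span = n_exons * exon_len + (n_exons - 1) * intron_len
    for i in range(n_genes):
        gene_id = f"gene{i + 1:05d}"
        offset = i * (gene_span + 10_000)
        strand = "+" if i % 2 == 0 else "-"
        exons = tuple(
            (offset + j * (exon_len + intron_len), offset + j * (exon_len + intron_len) + exon_len)
            for j in range(n_exons)
        )
        gene = GeneModel(gene_id=gene_id, chrom="chr1", strand=strand, exons=exons)
        genes[gene_id] = gene
        if i < n_u12:
            s, e = gene.introns()[3]
            u12.append(
                IntronAnnotation(
                    chrom="chr1",
                    start=s,
                    end=e,
                    strand=strand,
                    subtype="GT-AG" if i % 2 == 0 else "AT-AC",
                    sources=frozenset({"synthetic"}),
                )
            )
    return genes, u12


def _type_probs(weights, aa_fold: float) -> np.ndarray:
    """Type probabilities with the AA weight scaled by ``aa_fold``.

    The AA probability becomes min(aa_fold * w_AA, 0.95) and the other
    types are rescaled to fill the remainder, so the stratum-vs-background
    AA rate ratio equals ``aa_fold`` whenever no clamping occurs.
    """
    w = np.asarray(weights, dtype=float)
    aa_idx = EVENT_TYPES.index("AA")
    p_aa = min(aa_fold * w[aa_idx], 0.95)
    out = np.empty_like(w)
    rest = w.sum() - w[aa_idx]
    out[:] = w * (1.0 - p_aa) / rest if rest > 0 else 0.0
    out[aa_idx] = p_aa
    return out / out.sum()


def _random_subinterval(rng, start: int, end: int, length: int = 20) -> tuple[int, int]:
    length = min(length, end - start)
    s = int(rng.integers(start, end - length + 1))
    return s, s + length


def simulate_as_events(
    config: SyntheticEventConfig,
    u12_introns: list[IntronAnnotation],
    gene_models: dict[str, GeneModel],
) -> list[ASEvent]:
    """Sample an AS-event table over the given gene models.

    Events in U12-intron-containing genes are placed within the U12
    intron, in an immediately flanking feature, or elsewhere in the gene
    (mix ``_U12_PLACEMENT_WEIGHTS``); within/flanking placements draw
    their event type from AA-enriched weights.  Events in U2-only genes
    use the base weights and land anywhere in the gene.

    Raises
    ------
    ConsistencyError
        If a U12 intron lies outside every gene model.
    """
    rng = np.random.default_rng(config.seed)

    gene_ids = sorted(gene_models)
    u12_by_gene: dict[str, list[IntronAnnotation]] = {g: [] for g in gene_ids}
    for intron in u12_introns:
        host = None
        for gid in gene_ids:
            gene = gene_models[gid]
            if (
                gene.chrom == intron.chrom
                and gene.strand == intron.strand
                and intron.start >= gene.start
                and intron.end <= gene.end
            ):
                host = gid
                break
        if host is None:
            raise ConsistencyError(
                f"U12 intron {intron.chrom}:{intron.start}-{intron.end} "
                "lies outside every gene model"
            )
        u12_by_gene[host].append(intron)

    base_probs = np.asarray(config.event_type_weights, dtype=float)
    enriched_probs = _type_probs(config.event_type_weights, config.aa_enrichment_fold)
    sig = config.significance

    events: list[ASEvent] = []
    for _ in range(config.n_events):
        gid = gene_ids[int(rng.integers(len(gene_ids)))]
        gene = gene_models[gid]
        hosted = u12_by_gene[gid]
        if hosted:
            intron = hosted[int(rng.integers(len(hosted)))]
            placement = rng.choice(3, p=_U12_PLACEMENT_WEIGHTS)
            chain = gene.features()
            idx = next(
                (
                    i
                    for i, (kind, s, e) in enumerate(chain)
                    if kind == "intron" and (s, e) == (intron.start, intron.end)
                ),
                None,
            )
            if idx is None:
                raise ConsistencyError(
                    f"U12 intron {intron.start}-{intron.end} does not match an "
                    f"intron of gene {gid}"
                )
            flank_idx = [
                i for i in range(max(idx - 2, 0), min(idx + 2, len(chain) - 1) + 1) if i != idx
            ]
            distal_idx = [i for i in range(len(chain)) if i != idx and i not in flank_idx]
            if placement == 0:  # within the U12 intron
                start, end = _random_subinterval(rng, intron.start, intron.end)
            elif placement == 1 or not distal_idx:  # flanking feature
                _, fs, fe = chain[flank_idx[int(rng.integers(len(flank_idx)))]]
                start, end = _random_subinterval(rng, fs, fe)
            else:  # distal feature in the same gene
                _, fs, fe = chain[distal_idx[int(rng.integers(len(distal_idx)))]]
                start, end = _random_subinterval(rng, fs, fe)
            probs = enriched_probs if placement in (0, 1) else base_probs
        else:
            chain = gene.features()
            _, fs, fe = chain[int(rng.integers(len(chain)))]
            start, end = _random_subinterval(rng, fs, fe)
            probs = base_probs

        etype = EVENT_TYPES[int(rng.choice(len(EVENT_TYPES), p=probs))]
        pr = float(rng.beta(sig.pr_alpha, sig.pr_beta))
        psi_a = float(rng.uniform(0.05, 0.95))
        psi_b = float(np.clip(psi_a + rng.normal(0.0, sig.dpsi_sd), 0.0, 1.0))
        events.append(
            ASEvent(
                gene_id=gid,
                event_type=etype,
                chrom=gene.chrom,
                start=start,
                end=end,
                strand=gene.strand,
                psi_a=psi_a,
                psi_b=psi_b,
                probability=pr,
            )
        )
    return events
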