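"""Phylogenetic-profile co-evolution screening.

Profiles are binary presence/absence vectors of orthologous groups (OGs)
across a species panel.  OGs are ranked by cosine distance to a query
profile; recovery of a reference gene set is scored by rank statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError, UndefinedDistanceError

__all__ = [
    "PresenceAbsenceMatrix",
    "CoevolutionRanking",
    "RecoveryReport",
    "build_profiles",
    "cosine_distance",
    "cosine_similarity",
    "rank_coevolution",
    "evaluate_recovery",
    "permutation_pvalue",
]


@dataclass
class PresenceAbsenceMatrix:
    """Binary species x OG occupancy matrix.

    Attributes
    ----------
    og_ids
        Ordered unique OG identifiers (rows).
    species_ids
        Ordered unique species identifiers (columns).
    values
        Array of shape ``(len(og_ids), len(species_ids))`` with entries
        in {0, 1}.
    """

    og_ids: list[str]
    species_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if len(set(self.og_ids)) != len(self.og_ids):
            raise FormatError("duplicate OG ids")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise FormatError("duplicate species ids")
        if self.values.shape != (len(self.og_ids), len(self.species_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.og_ids)} OGs x {len(self.species_ids)} species"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise FormatError("matrix values must be 0 or 1")

    def profile(self, og_id: str) -> np.ndarray:
        try:
            i = self.og_ids.index(og_id)
        except ValueError:
            raise KeyError(f"unknown OG id: {og_id}") from None
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.og_ids, columns=self.species_ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "og_id"
        df.to_csv(path, sep="\t")


@dataclass
class CoevolutionRanking:
    """OGs ordered by ascending cosine distance to the query profile.

    ``entries`` excludes the query itself; OGs whose profile is all-zero
    are not rankable and are listed separately in ``unrankable``.
    """

    query_og: str
    entries: list[tuple[str, float]]
    unrankable: list[str] = field(default_factory=list)

    def ranks(self) -> dict[str, int]:
        """1-based rank per ranked OG id."""
        return {og: i for i, (og, _) in enumerate(self.entries, start=1)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(og, d, i) for i, (og, d) in enumerate(self.entries, start=1)],
            columns=["og_id", "cosine_distance", "rank"],
        )


@dataclass
class RecoveryReport:
    """Rank-based recovery of a reference OG set from a ranking."""

    reference_set: list[str]
    ranks: dict[str, int]
    top_k_hits: int
    k: int
    auc: float

    def to_dict(self) -> dict:
        return {
            "reference_set": list(self.reference_set),
            "ranks": dict(self.ranks),
            "k": self.k,
            "top_k_hits": self.top_k_hits,
            "auc": self.auc,
        }


def build_profiles(membership: pd.DataFrame, transpose: bool = False) -> PresenceAbsenceMatrix:
    """Binarize an orthology membership table into a profile matrix.

    Parameters
    ----------
    membership
        Table indexed by OG id with species columns (or the transpose if
        ``transpose`` is set).  Cells are occupancy counts; any count > 0
        maps to presence.
    transpose
        Set when the input is species x OG instead of OG x species.
        Orientation is never guessed.
    """
    if membership.size == 0:
        raise FormatError("empty membership table")
    if transpose:
        membership = membership.T
    vals = membership.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise FormatError("membership table has non-numeric cells")
    if (vals < 0).any():
        raise FormatError("membership counts must be >= 0")
    return PresenceAbsenceMatrix(
        og_ids=[str(i) for i in membership.index],
        species_ids=[str(c) for c in membership.columns],
        values=(vals > 0).astype(np.int8),
    )


def cosine_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Cosine distance ``1 - p.q / (|p| |q|)`` between two binary profiles.

    Raises
    ------
    UndefinedDistanceError
        If either profile is all-zero (the angle is undefined; never
        silently reported as 0 or 1).
    InvalidArgumentError
        If the profiles differ in length.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise InvalidArgumentError(f"profile lengths differ: {p.shape} vs {q.shape}")
    sp, sq = float(p @ p), float(q @ q)
    if sp == 0 or sq == 0:
        raise UndefinedDistanceError("cosine distance undefined for all-zero profile")
    # sqrt of the product (not product of sqrts) keeps identical binary
    # profiles at exactly distance 0
    d = 1.0 - float(p @ q) / math.sqrt(sp * sq)
    return min(max(d, 0.0), 1.0)


def cosine_similarity(p: Sequence[float], q: Sequence[float]) -> float:
    """Convenience: ``1 - cosine_distance(p, q)``."""
    return 1.0 - cosine_distance(p, q)


def rank_coevolution(query_og: str, matrix: PresenceAbsenceMatrix) -> CoevolutionRanking:
    """Rank every other OG by cosine distance to the query profile.

    Entries are sorted ascending by distance with lexicographic tie-break
    on OG id.  All-zero profiles cannot be ranked and are reported in
    ``unrankable`` instead of being assigned an arbitrary distance.
    """
    qvec = matrix.profile(query_og).astype(float)
    sq = float(qvec @ qvec)
    if sq == 0:
        raise UndefinedDistanceError(f"query profile {query_og!r} is all-zero")

    vals = matrix.values.astype(float)
    sums = (vals * vals).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dists = 1.0 - (vals @ qvec) / np.sqrt(sums * sq)
    np.clip(dists, 0.0, 1.0, out=dists)
    norms = np.sqrt(sums)

    entries = []
    unrankable = []
    for i, og in enumerate(matrix.og_ids):
        if og == query_og:
            continue
        if norms[i] == 0:
            unrankable.append(og)
        else:
            entries.append((og, float(dists[i])))
    entries.sort(key=lambda e: (e[1], e[0]))
    unrankable.sort()
    return CoevolutionRanking(query_og=query_og, entries=entries, unrankable=unrankable)


def evaluate_recovery(
    ranking: CoevolutionRanking, reference_set: Iterable[str], k: int
) -> RecoveryReport:
    """Score how early the reference OGs appear in a ranking.

    ``auc`` is the probability that a uniformly chosen reference member
    outranks (has a smaller rank than) a uniformly chosen non-reference
    member, counting rank ties as 1/2.  Unrankable OGs all share the
    worst rank ``len(entries) + len(unrankable)``.
    """
    reference = sorted(set(reference_set))
    if not reference:
        raise InvalidArgumentError("reference set is empty")
    ranked = ranking.ranks()
    worst = len(ranking.entries) + len(ranking.unrankable)
    universe = set(ranked) | set(ranking.unrankable)
    missing = [og for og in reference if og not in universe]
    if missing:
        raise InvalidArgumentError(f"reference OGs absent from ranking: {missing}")

    rank_of = dict(ranked)
    for og in ranking.unrankable:
        rank_of[og] = worst

    ref_ranks = np.array([rank_of[og] for og in reference], dtype=float)
    other_ranks = np.array(
        [r for og, r in rank_of.items() if og not in set(reference)], dtype=float
    )
    top_k_hits = int((ref_ranks <= k).sum())
    if other_ranks.size == 0:
        auc = 1.0
    else:
        wins = (ref_ranks[:, None] < other_ranks[None, :]).sum()
        ties = (ref_ranks[:, None] == other_ranks[None, :]).sum()
        auc = float((wins + 0.5 * ties) / (ref_ranks.size * other_ranks.size))
    return RecoveryReport(
        reference_set=reference,
        ranks={og: int(rank_of[og]) for og in reference},
        top_k_hits=top_k_hits,
        k=k,
        auc=auc,
    )


def permutation_pvalue(
    query_og: str,
    target_og: str,
    matrix: PresenceAbsenceMatrix,
    n_permutations: int,
    seed: int,
) -> float:
    """Permutation p-value for one query-target distance (extension).

    Shuffles species labels of the target profile ``n_permutations``
    times and reports the fraction of permuted distances at or below the
    observed one (add-one correction).  This is an artifact extension:
    the screen itself only ranks and carries no significance machinery.
    """
    rng = np.random.default_rng(seed)
    qvec = matrix.profile(query_og)
    tvec = matrix.profile(target_og)
    observed = cosine_distance(qvec, tvec)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(tvec)
        if perm.sum() == 0:
            continue
        if cosine_distance(qvec, perm) <= observed:
            hits += 1
    return (hits + 1) / (n_permutations + 1)
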