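"""Rank-based weighting of evidence-quality factors and journal venues.

Literature evidence for a protein-protein interaction is not all equal: an
in-vivo physicochemical result stated as fact carries more weight than a
hypothetical statement from a library screen, and the venue that published
the finding carries a community-confidence signal of its own.  Both kinds of
quality are expressed here as *ordinal ranks* (1 = most reliable) and turned
into normalized linear weights with the rank-sum scheme from multi-criteria
decision making:

    W_r = 2 (n + 1 - r) / (n (n + 1))

where ``r`` is the factor's rank and ``n`` the number of ranked factors.
Weights decrease linearly with rank and sum to one.

Two rankings are handled:

* the 12 evidence-quality categories, ranked by a panel of experts and
  aggregated into a consensus permutation (:func:`consensus_ranks`,
  :class:`FactorWeights`);
* journal impact factors, discretized into quantile bins whose bin rank is
  weighted with the same scheme (:func:`bin_impact_factors`,
  :class:`JournalImpactTable`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_FACTOR_CATEGORIES",
    "FactorWeights",
    "JournalImpactTable",
    "rank_sum_linear_weight",
    "rank_sum_weights",
    "consensus_ranks",
    "factor_weights_from_rankings",
    "bin_impact_factors",
]

#: Number of evidence-quality categories the annotation scheme distinguishes
#: (experiment type x fact/hypothesis status, flattened).
N_FACTOR_CATEGORIES = 12


def rank_sum_linear_weight(r: int, n: int) -> float:
    """Weight of the factor ranked ``r`` among ``n`` factors.

    Implements the rank-sum linear scheme ``W_r = 2(n + 1 - r) / (n(n + 1))``,
    i.e. the inverse rank ``n - r + 1`` normalized by the sum of all inverse
    ranks.  The weights over ``r = 1..n`` sum to exactly 1 and strictly
    decrease with ``r``.

    Parameters
    ----------
    r : int
        Rank of the factor, 1 (most reliable) through ``n`` (least reliable).
    n : int
        Total number of ranked factors, at least 1.

    Returns
    -------
    float
        Weight in ``(0, 1]``.
    """
    if n < 1:
        raise ValueError(f"number of ranked factors must be >= 1, got {n}")
    if not 1 <= r <= n:
        raise ValueError(f"rank must lie in 1..{n}, got {r}")
    return 2.0 * (n + 1 - r) / (n * (n + 1))


def rank_sum_weights(n: int) -> np.ndarray:
    """All ``n`` rank-sum weights, index 0 holding the weight of rank 1."""
    r = np.arange(1, n + 1)
    return 2.0 * (n + 1 - r) / (n * (n + 1))


def consensus_ranks(
    per_expert_ranks: Mapping[str, Sequence[int]] | pd.DataFrame,
) -> list[int]:
    """Aggregate several experts' rankings into one consensus permutation.

    Each expert supplies a permutation of ``1..n`` over the same ordered list
    of factors (rank 1 = most reliable).  The consensus is the arithmetic
    mean rank per factor, re-ranked into a permutation; ties in the mean are
    broken by factor listing order, so the factor listed first wins the
    better (smaller) rank.

    Parameters
    ----------
    per_expert_ranks
        Either a mapping ``expert id -> sequence of ranks`` (position ``i``
        is the rank that expert gives factor ``i``) or a long-format
        DataFrame with columns ``factor_id``, ``expert_id``, ``rank``.

    Returns
    -------
    list of int
        Consensus rank per factor, in factor listing order; a permutation
        of ``1..n``.
    """
    if isinstance(per_expert_ranks, pd.DataFrame):
        per_expert_ranks = _rankings_frame_to_mapping(per_expert_ranks)
    if not per_expert_ranks:
        raise ValueError("no expert rankings supplied")

    lengths = {len(v) for v in per_expert_ranks.values()}
    if len(lengths) != 1:
        raise ValueError(f"experts rank different numbers of factors: {sorted(lengths)}")
    n = lengths.pop()

    for expert, ranking in per_expert_ranks.items():
        if sorted(ranking) != list(range(1, n + 1)):
            raise ValueError(
                f"ranking of expert {expert!r} is not a permutation of 1..{n}: {list(ranking)}"
            )

    mean_ranks = np.mean([list(v) for v in per_expert_ranks.values()], axis=0)
    # stable argsort: ties in the mean fall back to factor listing order
    order = np.argsort(mean_ranks, kind="stable")
    consensus = np.empty(n, dtype=int)
    consensus[order] = np.arange(1, n + 1)
    return consensus.tolist()


def _rankings_frame_to_mapping(df: pd.DataFrame) -> dict[str, list[int]]:
    required = {"factor_id", "expert_id", "rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ranking table is missing columns: {sorted(missing)}")
    factor_ids = sorted(df["factor_id"].unique())
    out: dict[str, list[int]] = {}
    for expert, sub in df.groupby("expert_id", sort=True):
        sub = sub.set_index("factor_id")["rank"]
        if sorted(sub.index) != factor_ids:
            raise ValueError(f"expert {expert!r} does not rank every factor exactly once")
        out[str(expert)] = [int(sub.loc[f]) for f in factor_ids]
    return out


@dataclass(frozen=True)
class FactorWeights:
    """Consensus ranks and rank-sum weights for the evidence-quality factors.

    Attributes
    ----------
    n : int
        Number of ranked factors.
    rank_of : dict
        ``category_id -> rank`` (1 = most reliable); a permutation of 1..n.
    weight_of : dict
        ``category_id -> weight``; weights sum to 1.
    """

    n: int
    rank_of: dict[int, int] = field(repr=False)
    weight_of: dict[int, float] = field(repr=False)

    def __post_init__(self) -> None:
        if sorted(self.rank_of.values()) != list(range(1, self.n + 1)):
            raise ValueError("factor ranks must form a permutation of 1..n")
        total = sum(self.weight_of.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"factor weights must sum to 1, got {total!r}")

    @classmethod
    def from_ranks(cls, ranks: Mapping[int, int]) -> "FactorWeights":
        """Build weights from a ``category_id -> rank`` permutation."""
        n = len(ranks)
        weight_of = {cid: rank_sum_linear_weight(r, n) for cid, r in ranks.items()}
        return cls(n=n, rank_of=dict(ranks), weight_of=weight_of)

    @classmethod
    def uniform_default(cls, n: int = N_FACTOR_CATEGORIES) -> "FactorWeights":
        """Identity ranking: category id doubles as rank (1 most reliable)."""
        return cls.from_ranks({cid: cid for cid in range(1, n + 1)})


def factor_weights_from_rankings(
    per_expert_ranks: Mapping[str, Sequence[int]] | pd.DataFrame,
    factor_ids: Sequence[int] | None = None,
) -> FactorWeights:
    """Consensus-aggregate expert rankings and convert them to weights.

    ``factor_ids`` gives the category id of each position in the rankings;
    defaults to ``1..n`` in listing order (and to the sorted ``factor_id``
    column when a DataFrame is passed).
    """
    consensus = consensus_ranks(per_expert_ranks)
    if factor_ids is None:
        if isinstance(per_expert_ranks, pd.DataFrame):
            factor_ids = sorted(per_expert_ranks["factor_id"].unique())
        else:
            factor_ids = list(range(1, len(consensus) + 1))
    if len(factor_ids) != len(consensus):
        raise ValueError("factor_ids length does not match number of ranked factors")
    return FactorWeights.from_ranks(dict(zip(map(int, factor_ids), consensus)))


@dataclass(frozen=True)
class JournalImpactTable:
    """Journal impact factors discretized into rank bins with rank-sum weights.

    A journal's *community confidence* is the rank-sum weight of its
    impact-factor quantile bin (rank 1 = highest impact).  Journals absent
    from the table fall into the lowest-confidence bin rather than erroring,
    so every evidence line stays scoreable.
    """

    n_bins: int
    impact_of: dict[str, float] = field(repr=False)
    rank_of: dict[str, int] = field(repr=False)

    def rank(self, journal: str) -> int:
        """Bin rank of ``journal``; unknown journals get the worst rank."""
        return self.rank_of.get(journal, self.n_bins)

    def weight(self, journal: str) -> float:
        """Community-confidence weight of ``journal``'s bin."""
        return rank_sum_linear_weight(self.rank(journal), self.n_bins)

    @property
    def weight_of(self) -> dict[str, float]:
        return {j: self.weight(j) for j in self.rank_of}


def bin_impact_factors(
    table: Mapping[str, float] | pd.DataFrame,
    n_bins: int = N_FACTOR_CATEGORIES,
) -> JournalImpactTable:
    """Discretize journal impact factors into ``n_bins`` quantile ranks.

    The rank of a journal is its empirical-quantile bin,

        ``rank = floor(n_bins * q) + 1``,  ``q`` = fraction of journals with
        strictly greater impact factor,

    so the highest-impact journals get rank 1 and the lowest rank ``n_bins``.
    Binning depends only on the ordering of the impact factors (it is
    invariant to rescaling), and tied impact factors always share a rank.
    When there are fewer distinct impact-factor values than bins some bins
    are necessarily empty; the degenerate all-equal case collapses to a
    single rank and emits a warning.

    Parameters
    ----------
    table
        ``journal -> impact factor`` mapping, or a DataFrame with columns
        ``journal`` and ``impact_factor``.
    n_bins : int
        Number of quantile ranks; 12 by default, 5 for a quintile reading.
    """
    if isinstance(table, pd.DataFrame):
        required = {"journal", "impact_factor"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"journal table is missing columns: {sorted(missing)}")
        table = dict(zip(table["journal"].astype(str), table["impact_factor"].astype(float)))
    if not table:
        raise ValueError("journal impact-factor table is empty")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")

    journals = list(table)
    ifs = np.asarray([float(table[j]) for j in journals])
    if np.any(ifs < 0) or not np.all(np.isfinite(ifs)):
        raise ValueError("impact factors must be finite and non-negative")

    n_distinct = np.unique(ifs).size
    if n_distinct < n_bins:
        warnings.warn(
            f"only {n_distinct} distinct impact-factor values for {n_bins} bins; "
            "bins collapse",
            stacklevel=2,
        )

    # q in [0, 1): fraction of journals with strictly greater impact factor
    order = np.argsort(-ifs, kind="stable")
    greater = np.empty(len(ifs), dtype=float)
    sorted_ifs = ifs[order]
    # count of entries strictly greater than each sorted value
    n_greater = np.searchsorted(-sorted_ifs, -sorted_ifs, side="left")
    greater[order] = n_greater
    q = greater / len(ifs)
    ranks = np.minimum(np.floor(q * n_bins).astype(int) + 1, n_bins)

    rank_of = {j: int(r) for j, r in zip(journals, ranks)}
    return JournalImpactTable(n_bins=n_bins, impact_of=dict(table), rank_of=rank_of)
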