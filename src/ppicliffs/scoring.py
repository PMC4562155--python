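"""Per-edge literature-confidence scores for directed protein interactions.

Each evidence line contributes one signed term to the raw reliability score
of its directed pair:

    S = sum_e  sigma_e * w_factor(category_e) * w_journal(journal_e)

where ``sigma_e`` is +1 for supporting and -1 for contradicting evidence,
``w_factor`` is the rank-sum weight of the evidence-quality category, and
``w_journal`` the community-confidence weight of the publishing venue's
impact-factor bin.  The score is additive in evidence lines, so heavily
studied interactions accumulate large raw scores.

Because the raw scores are highly skewed towards the most-studied pairs,
they are compressed with a signed logarithm, ``sign(S) * ln(1 + |S|)``
(defined and strictly monotone for the negative totals that contradictions
can produce), and then min-max normalized to [0, 1] across the network.
Interactions near 1 are the established, frequently reported ones; scores
near 0 mark sparsely studied, emerging interactions.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .evidence_io import EvidenceCorpus, EvidenceRecord
from .graph import ScoredEdge, ScoredNetwork, Zone, ZoneConfig
from .weighting import FactorWeights, JournalImpactTable

__all__ = [
    "raw_edge_score",
    "log_transform",
    "normalize_scores",
    "score_network",
]


def raw_edge_score(
    evidence: Sequence[EvidenceRecord],
    fw: FactorWeights,
    jt: JournalImpactTable,
) -> float:
    """Raw reliability score S of one directed pair.

    Signed, weighted sum over the pair's evidence lines; each line
    contributes its default count of 1 scaled by its category weight and
    its journal's community-confidence weight.  Supporting lines add,
    contradicting lines subtract.

    Raises if the evidence list is empty or mixes directed pairs.
    """
    if not evidence:
        raise ValueError("cannot score an empty evidence list")
    pairs = {r.pair for r in evidence}
    if len(pairs) > 1:
        raise ValueError(f"evidence mixes directed pairs: {sorted(pairs)}")
    s = 0.0
    for r in evidence:
        s += r.polarity.sign * fw.weight_of[r.category_id] * jt.weight(r.journal)
    return s


def log_transform(s: float) -> float:
    """Signed log compression ``sign(S) * ln(1 + |S|)``.

    Strictly increasing, fixes 0, and odd-symmetric, so it stays defined for
    the non-positive totals produced by contradicting evidence while
    compressing the heavy right tail of the raw scores.
    """
    return math.copysign(math.log1p(abs(s)), s) if s != 0 else 0.0


def normalize_scores(log_scores: Sequence[float]) -> list[float]:
    """Min-max normalize log scores to [0, 1], preserving rank order.

    The minimum maps to 0 and the maximum to 1.  Degenerate inputs (fewer
    than two values, or all values equal) raise rather than emitting
    arbitrary output.
    """
    x = np.asarray(list(log_scores), dtype=float)
    if x.size < 2:
        raise ValueError(f"normalization needs at least 2 scores, got {x.size}")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("all log scores are equal; min-max normalization is undefined")
    return ((x - lo) / (hi - lo)).tolist()


def score_network(
    corpus: EvidenceCorpus,
    fw: FactorWeights,
    jt: JournalImpactTable,
    zone_cfg: ZoneConfig | None = None,
) -> ScoredNetwork:
    """Score every directed pair in a corpus and assemble the network.

    Evidence is pooled per ordered pair (duplicate pairs merge; reciprocal
    pairs stay distinct edges), raw scores are log-compressed and min-max
    normalized across the whole network, and each edge gets its knowledge
    zone from ``zone_cfg``.  Deterministic: the result depends only on the
    multiset of evidence per pair, not on corpus row order.
    """
    zone_cfg = zone_cfg or ZoneConfig()
    grouped = corpus.by_pair()
    if not grouped:
        raise ValueError("corpus contains no evidence records")

    pairs = sorted(grouped)  # canonical order: scores are order-invariant anyway
    raw = [raw_edge_score(grouped[p], fw, jt) for p in pairs]
    logs = [log_transform(s) for s in raw]
    norms = normalize_scores(logs)

    edges = []
    for (s, t), r, l, n in zip(pairs, raw, logs, norms):
        ev = grouped[(s, t)]
        n_sup = sum(1 for e in ev if e.polarity.sign > 0)
        n_con = len(ev) - n_sup
        edges.append(
            ScoredEdge(
                source=s,
                target=t,
                n_support=n_sup,
                n_contradict=n_con,
                raw_score=r,
                log_score=l,
                norm_score=n,
                zone=zone_cfg.zone(n),
            )
        )
    meta = dict(corpus.provenance)
    meta.update(
        {
            "n_factors": fw.n,
            "journal_bins": jt.n_bins,
            "zone_buffer_min": zone_cfg.buffer_min,
            "zone_established_min": zone_cfg.established_min,
        }
    )
    return ScoredNetwork(edges, metadata=meta)
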