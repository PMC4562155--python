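"""Knowledge-cliff detection and permutation-based significance testing.

A *knowledge cliff* is a unidirectional two-edge chain ``i -> j -> k`` in a
scored directed network where both edges carry positive normalized weight
and the upstream score exceeds the downstream score by at least a threshold
``c``:

    w_ij > 0,  w_jk > 0,  w_ij - w_jk >= c,      0.1 <= c <= 0.99.

Cliffs mark the interface between established knowledge (the heavily
studied upstream edge) and emerging knowledge (the sparsely studied
downstream edge); the downstream partner ``k`` is a candidate worth
investigating because it already sits in an established functional context.

Significance is assessed against a null of random edge placement: many
random networks are drawn that preserve every node's exact in- and
out-degree (directed double-edge swaps), the occurrence probability of each
original edge under this null is estimated, and a cliff's p-value is the
product of its edge probabilities under an edge-independence assumption.
Cliffs with p below a significance level (0.05 by default) are unlikely to
arise from degree structure alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import ScoredNetwork

__all__ = [
    "KnowledgeCliff",
    "PermutationConfig",
    "detect_knowledge_cliffs",
    "degree_preserving_randomize",
    "estimate_edge_probabilities",
    "cliff_pvalue",
    "test_cliffs",
    "cliffs_to_frame",
    "write_cliff_table",
]

#: threshold range within which the cliff definition is stated
C_MIN, C_MAX = 0.1, 0.99

Edge = tuple[str, str]


@dataclass(frozen=True)
class KnowledgeCliff:
    """One detected cliff: chain (i, j, k), its scores, drop, and p-value."""

    chain: tuple[str, ...]
    w_ij: float
    w_jk: float
    threshold_c: float
    p_value: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if len(self.chain) < 3:
            raise ValueError("a cliff chain needs at least three vertices")

    @property
    def drop(self) -> float:
        return self.w_ij - self.w_jk

    @property
    def edges(self) -> list[Edge]:
        return [(self.chain[t], self.chain[t + 1]) for t in range(len(self.chain) - 1)]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the degree-preserving permutation test.

    ``n_randomizations`` random networks are drawn (10,000 by default);
    each draw attempts ``swaps_per_edge * |E|`` directed double-edge swaps.
    ``pseudo_count`` regularizes edge-occurrence probabilities away from
    zero so cliff p-values stay strictly positive.
    """

    n_randomizations: int = 10_000
    seed: int = 0
    swaps_per_edge: int = 10
    pseudo_count: float = 1.0

    def __post_init__(self) -> None:
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")
        if self.pseudo_count < 0:
            raise ValueError("pseudo_count must be non-negative")


def detect_knowledge_cliffs(
    net: ScoredNetwork, c: float = 0.75, force: bool = False
) -> list[KnowledgeCliff]:
    """Every cliff triple in ``net`` at threshold ``c``.

    Returns all ordered triples ``(i, j, k)`` of distinct vertices with
    edges ``i->j`` and ``j->k``, both normalized weights positive, and a
    score drop ``w_ij - w_jk >= c``; sorted by drop descending, ties broken
    lexicographically by chain.  Longer descending paths appear as their
    qualifying constituent triples.

    ``c`` outside [0.1, 0.99] raises unless ``force`` is set.
    """
    if not force and not C_MIN <= c <= C_MAX:
        raise ValueError(
            f"cliff threshold must lie in [{C_MIN}, {C_MAX}] (got {c}); "
            "pass force=True to override"
        )
    succ: dict[str, list[Edge]] = {}
    for (s, t), e in net.edges.items():
        succ.setdefault(s, []).append((t, e.norm_score))  # type: ignore[arg-type]

    found: list[KnowledgeCliff] = []
    for (i, j), e_ij in net.edges.items():
        if e_ij.norm_score <= 0 or i == j:
            continue
        for k, w_jk in succ.get(j, ()):
            if k == i or k == j or w_jk <= 0:
                continue
            if e_ij.norm_score - w_jk >= c:
                found.append(
                    KnowledgeCliff(
                        chain=(i, j, k),
                        w_ij=e_ij.norm_score,
                        w_jk=w_jk,
                        threshold_c=c,
                    )
                )
    found.sort(key=lambda cl: (-cl.drop, cl.chain))
    return found


def _attempt_swaps(
    edges: list[Edge], edge_set: set[Edge], idx: np.ndarray
) -> int:
    """Apply directed double-edge swaps in place; returns number accepted."""
    accepted = 0
    for i, j in idx:
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b:  # would create a self-loop
            continue
        if (a, d) in edge_set or (c, b) in edge_set:  # would duplicate an edge
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
        accepted += 1
    return accepted


def degree_preserving_randomize(
    net: ScoredNetwork | Iterable[Edge],
    rng: np.random.Generator,
    swaps_per_edge: int = 10,
) -> set[Edge]:
    """One random edge set preserving every node's exact in/out-degree.

    Attempts ``swaps_per_edge * |E|`` directed double-edge swaps — each
    picks two edges (a,b), (c,d) and rewires them to (a,d), (c,b) — and
    rejects any swap that would create a self-loop or a duplicate edge, so
    the result is again a simple digraph on the same degree sequence.
    Scores are irrelevant under the null and are not carried.

    Networks admitting no swap at all are returned unchanged with a warning.
    """
    edges = _edge_list(net)
    if len(edges) < 2:
        raise ValueError("randomization needs at least 2 edges")
    edge_set = set(edges)
    attempts = swaps_per_edge * len(edges)
    idx = rng.integers(0, len(edges), size=(attempts, 2))
    accepted = _attempt_swaps(edges, edge_set, idx)
    if accepted == 0:
        warnings.warn(
            "no admissible double-edge swap found; returning the network unchanged",
            stacklevel=2,
        )
    return edge_set


def estimate_edge_probabilities(
    net: ScoredNetwork | Iterable[Edge], cfg: PermutationConfig
) -> dict[Edge, float]:
    """Null occurrence probability of every original edge.

    Draws ``cfg.n_randomizations`` degree-preserving random networks and,
    for each original edge, reports

        (number of draws containing the edge + pseudo_count)
        / (n_randomizations + pseudo_count),

    a value in (0, 1] when ``pseudo_count > 0``.
    """
    orig = _edge_list(net)
    if len(orig) < 2:
        raise ValueError("permutation test needs at least 2 edges")
    rng = np.random.default_rng(cfg.seed)
    m = len(orig)
    attempts = cfg.swaps_per_edge * m
    counts = np.zeros(m, dtype=np.int64)
    for _ in range(cfg.n_randomizations):
        edges = list(orig)
        edge_set = set(edges)
        idx = rng.integers(0, m, size=(attempts, 2))
        _attempt_swaps(edges, edge_set, idx)
        for t, e in enumerate(orig):
            if e in edge_set:
                counts[t] += 1
    denom = cfg.n_randomizations + cfg.pseudo_count
    return {e: float((counts[t] + cfg.pseudo_count) / denom) for t, e in enumerate(orig)}


def cliff_pvalue(cliff: KnowledgeCliff, probs: Mapping[Edge, float]) -> float:
    """p-value of a cliff: product of its edges' null occurrence probabilities.

    Assumes edge independence under the null.  Accepts chains of any length;
    the detector emits triples (two edges).
    """
    p = 1.0
    for e in cliff.edges:
        if e not in probs:
            raise KeyError(f"edge {e[0]}->{e[1]} missing from probability map")
        p *= probs[e]
    return p


def test_cliffs(
    net: ScoredNetwork | Iterable[Edge],
    cliffs: Sequence[KnowledgeCliff],
    cfg: PermutationConfig | None = None,
    alpha: float = 0.05,
) -> tuple[list[KnowledgeCliff], dict]:
    """Annotate cliffs with permutation p-values and significance flags.

    Runs the degree-preserving permutation test once on ``net`` and stamps
    each cliff with ``p_value`` (product of edge probabilities) and
    ``significant = p_value < alpha``.  Returns the annotated cliffs and a
    reproducibility report carrying the test configuration.
    """
    cfg = cfg or PermutationConfig()
    probs = estimate_edge_probabilities(net, cfg)
    annotated = []
    for cl in cliffs:
        p = cliff_pvalue(cl, probs)
        annotated.append(replace(cl, p_value=p, significant=bool(p < alpha)))
    report = {
        "n_randomizations": cfg.n_randomizations,
        "seed": cfg.seed,
        "swaps_per_edge": cfg.swaps_per_edge,
        "pseudo_count": cfg.pseudo_count,
        "alpha": alpha,
        "n_cliffs": len(annotated),
        "n_significant": sum(1 for cl in annotated if cl.significant),
    }
    return annotated, report


def cliffs_to_frame(cliffs: Sequence[KnowledgeCliff]) -> pd.DataFrame:
    """Cliff report table: i, j, k, scores, drop, p-value, significance."""
    rows = [
        {
            "i": cl.chain[0],
            "j": cl.chain[1],
            "k": cl.chain[2],
            "w_ij": cl.w_ij,
            "w_jk": cl.w_jk,
            "drop": cl.drop,
            "p_value": cl.p_value,
            "significant": cl.significant,
        }
        for cl in cliffs
    ]
    return pd.DataFrame(rows, columns=["i", "j", "k", "w_ij", "w_jk", "drop", "p_value", "significant"])


def write_cliff_table(cliffs: Sequence[KnowledgeCliff], path) -> None:
    from .evidence_io import _write_tsv

    _write_tsv(cliffs_to_frame(cliffs), path)


def _edge_list(net: ScoredNetwork | Iterable[Edge]) -> list[Edge]:
    if isinstance(net, ScoredNetwork):
        return list(net.edges)
    return [tuple(e) for e in net]  # type: ignore[return-value]
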