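"""Directed scored PPI network: container, knowledge zones, summaries.

A scored network is a simple directed graph ``G = (V, E)`` whose edges carry
the evidence tallies and the raw / log / normalized reliability scores.
Normalized scores segment the network into three knowledge zones:

* **established** — high-confidence, heavily studied interactions;
* **buffer** — intermediate scores between the two regimes;
* **emerging** — sparsely supported interactions, candidate new knowledge.

Reciprocal edges ``A->B`` and ``B->A`` are distinct; at most one scored edge
exists per ordered pair (evidence for duplicate pairs is pooled upstream).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Zone",
    "ZoneConfig",
    "ScoredEdge",
    "ScoredNetwork",
    "network_summary",
    "overlay_node_set",
]

#: Fixed histogram bin edges for normalized-score summaries.
SCORE_BIN_EDGES = np.round(np.linspace(0.0, 1.0, 11), 1)


class Zone(str, enum.Enum):
    """Knowledge zone of an interaction, from its normalized score."""

    ESTABLISHED = "ESTABLISHED"
    BUFFER = "BUFFER"
    EMERGING = "EMERGING"


@dataclass(frozen=True)
class ZoneConfig:
    """Normalized-score boundaries of the knowledge zones.

    Scores below ``buffer_min`` are emerging, scores in
    ``[buffer_min, established_min)`` are buffer, and scores at or above
    ``established_min`` are established.  Defaults 0.5 / 0.75: the bulk of
    sparsely studied interactions score below 0.5, and 0.75 matches the
    default knowledge-cliff threshold.
    """

    buffer_min: float = 0.5
    established_min: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 <= self.buffer_min < self.established_min <= 1.0:
            raise ValueError(
                "zone boundaries must satisfy 0 <= buffer_min < established_min <= 1, "
                f"got {self.buffer_min}, {self.established_min}"
            )

    def zone(self, norm_score: float) -> Zone:
        if norm_score >= self.established_min:
            return Zone.ESTABLISHED
        if norm_score >= self.buffer_min:
            return Zone.BUFFER
        return Zone.EMERGING


@dataclass(frozen=True)
class ScoredEdge:
    """One directed interaction with its evidence tallies and scores."""

    source: str
    target: str
    n_support: int
    n_contradict: int
    raw_score: float
    log_score: float
    norm_score: float
    zone: Zone

    def __post_init__(self) -> None:
        if self.n_support < 0 or self.n_contradict < 0:
            raise ValueError("evidence counts must be non-negative")
        if self.n_support + self.n_contradict < 1:
            raise ValueError("a scored edge needs at least one evidence line")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)


class ScoredNetwork:
    """Directed network of :class:`ScoredEdge`, keyed by ordered pair."""

    #: canonical column order of the scored-network TSV
    COLUMNS = (
        "source",
        "target",
        "n_support",
        "n_contradict",
        "raw_score",
        "log_score",
        "norm_score",
        "zone",
    )

    def __init__(self, edges: Iterable[ScoredEdge], metadata: dict | None = None):
        self._edges: dict[tuple[str, str], ScoredEdge] = {}
        for e in edges:
            if e.pair in self._edges:
                raise ValueError(f"duplicate scored edge for ordered pair {e.pair}")
            self._edges[e.pair] = e
        self.metadata: dict = dict(metadata or {})

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self) -> Iterator[ScoredEdge]:
        return iter(self._edges.values())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self._edges

    def __getitem__(self, pair: tuple[str, str]) -> ScoredEdge:
        return self._edges[tuple(pair)]

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for s, t in self._edges:
            out.add(s)
            out.add(t)
        return out

    @property
    def edges(self) -> dict[tuple[str, str], ScoredEdge]:
        return dict(self._edges)

    def weight(self, source: str, target: str) -> float:
        """Normalized score of the edge ``source -> target``."""
        return self._edges[(source, target)].norm_score

    def successors(self, node: str) -> list[str]:
        return [t for (s, t) in self._edges if s == node]

    # -- conversions --------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        """networkx view with the scored attributes on each edge."""
        g = nx.DiGraph(**{k: str(v) for k, v in self.metadata.items()})
        for e in self:
            g.add_edge(
                e.source,
                e.target,
                n_support=e.n_support,
                n_contradict=e.n_contradict,
                raw_score=e.raw_score,
                log_score=e.log_score,
                norm_score=e.norm_score,
                zone=e.zone.value,
            )
        return g

    def to_frame(self) -> pd.DataFrame:
        """Edge table in canonical column order, sorted by (source, target)."""
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "n_support": e.n_support,
                "n_contradict": e.n_contradict,
                "raw_score": e.raw_score,
                "log_score": e.log_score,
                "norm_score": e.norm_score,
                "zone": e.zone.value,
            }
            for e in self
        ]
        df = pd.DataFrame(rows, columns=list(self.COLUMNS))
        return df.sort_values(["source", "target"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None) -> "ScoredNetwork":
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"scored-network table is missing columns: {sorted(missing)}")
        edges = [
            ScoredEdge(
                source=str(r.source),
                target=str(r.target),
                n_support=int(r.n_support),
                n_contradict=int(r.n_contradict),
                raw_score=float(r.raw_score),
                log_score=float(r.log_score),
                norm_score=float(r.norm_score),
                zone=Zone(r.zone),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(edges, metadata=metadata)

    def relabel(self, mapping: dict[str, str]) -> "ScoredNetwork":
        """Copy with node names replaced via ``mapping`` (identity otherwise)."""
        edges = [
            replace(e, source=mapping.get(e.source, e.source), target=mapping.get(e.target, e.target))
            for e in self
        ]
        return ScoredNetwork(edges, metadata=dict(self.metadata))


def network_summary(net: ScoredNetwork, top_k: int = 5) -> dict:
    """Summary statistics of a scored network.

    Returns node and edge counts, the normalized-score histogram over fixed
    bin edges ``0, 0.1, ..., 1.0``, per-zone edge counts, and the ``top_k``
    edges by normalized score.
    """
    scores = np.array([e.norm_score for e in net], dtype=float)
    if scores.size:
        counts, _ = np.histogram(scores, bins=SCORE_BIN_EDGES)
    else:
        counts = np.zeros(len(SCORE_BIN_EDGES) - 1, dtype=int)
    zone_counts = {z.value: 0 for z in Zone}
    for e in net:
        zone_counts[e.zone.value] += 1
    top = sorted(net, key=lambda e: (-e.norm_score, e.source, e.target))[:top_k]
    return {
        "n_nodes": len(net.nodes),
        "n_edges": len(net),
        "score_histogram": {
            "bin_edges": [float(b) for b in SCORE_BIN_EDGES],
            "counts": [int(c) for c in counts],
        },
        "zone_counts": zone_counts,
        "top_edges": [
            {"source": e.source, "target": e.target, "norm_score": e.norm_score} for e in top
        ],
    }


def overlay_node_set(net: ScoredNetwork, candidates: Iterable[str]) -> dict:
    """Coverage of an external node set (e.g. putative biomarkers) by the network.

    Returns the fraction of ``candidates`` present as network nodes together
    with the sorted list of absentees.  Duplicate candidates are counted
    once.
    """
    cand = list(dict.fromkeys(candidates))
    if not cand:
        raise ValueError("candidate node set is empty")
    nodes = net.nodes
    missing = sorted(c for c in cand if c not in nodes)
    return {
        "n_candidates": len(cand),
        "n_present": len(cand) - len(missing),
        "coverage": (len(cand) - len(missing)) / len(cand),
        "missing": missing,
    }
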