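"""Shared fixtures: tiny corpora, weight tables, and scored toy networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ppicliffs.evidence_io import EvidenceCorpus, EvidenceRecord, Polarity
from ppicliffs.graph import ScoredEdge, ScoredNetwork, Zone
from ppicliffs.weighting import FactorWeights, bin_impact_factors


@pytest.fixture
def factor_weights() -> FactorWeights:
    """Identity ranking of the 12 categories (category id == rank)."""
    return FactorWeights.uniform_default()


@pytest.fixture
def journal_table():
    """12 journals with impact factors 12..1, hence ranks 1..12."""
    df = pd.DataFrame(
        {"journal": [f"JR{r:02d}" for r in range(1, 13)],
         "impact_factor": [float(13 - r) for r in range(1, 13)]}
    )
    return bin_impact_factors(df)


def record(source="A", target="B", polarity=Polarity.SUPPORT, category_id=1,
           journal="JR01", pmid="1") -> EvidenceRecord:
    return EvidenceRecord(source=source, target=target, polarity=polarity,
                          category_id=category_id, journal=journal, pmid=pmid)


@pytest.fixture
def small_corpus() -> EvidenceCorpus:
    """Three directed pairs with clearly ordered evidence volumes."""
    recs = []
    for _ in range(10):
        recs.append(record("APP", "BACE1", category_id=1, journal="JR01"))
    for _ in range(3):
        recs.append(record("APOE", "APP", category_id=3, journal="JR04"))
    recs.append(record("RTN4", "BACE1", category_id=11, journal="JR12"))
    return EvidenceCorpus(records=recs)


def weighted_network(weights: dict[tuple[str, str], float]) -> ScoredNetwork:
    """Scored network straight from a pair -> normalized-score mapping."""
    edges = [
        ScoredEdge(source=s, target=t, n_support=1, n_contradict=0,
                   raw_score=w, log_score=w, norm_score=w, zone=Zone.EMERGING)
        for (s, t), w in weights.items()
    ]
    return ScoredNetwork(edges)


@pytest.fixture
def toy_cliff_network() -> ScoredNetwork:
    """A->B (0.95), B->C (0.10), B->D (0.30), D->A (0.90)."""
    return weighted_network(
        {("A", "B"): 0.95, ("B", "C"): 0.10, ("B", "D"): 0.30, ("D", "A"): 0.90}
    )


def random_weighted_digraph(rng: np.random.Generator, n_nodes: int,
                            edge_prob: float) -> ScoredNetwork:
    """Random simple digraph with uniform weights in (0, 1]."""
    weights = {}
    for u in range(n_nodes):
        for v in range(n_nodes):
            if u != v and rng.random() < edge_prob:
                weights[(f"N{u}", f"N{v}")] = float(rng.uniform(0.001, 1.0))
    if not weights:  # guarantee at least one edge
        weights[("N0", "N1")] = 0.5
    return weighted_network(weights)


def brute_force_cliffs(net: ScoredNetwork, c: float) -> set[tuple[str, str, str]]:
    """Independent oracle: scan all |V|^3 ordered triples of distinct nodes."""
    nodes = sorted(net.nodes)
    found = set()
    for i in nodes:
        for j in nodes:
            for k in nodes:
                if i == j or j == k or i == k:
                    continue
                if (i, j) not in net or (j, k) not in net:
                    continue
                w_ij, w_jk = net.weight(i, j), net.weight(j, k)
                if w_ij > 0 and w_jk > 0 and w_ij - w_jk >= c:
                    found.add((i, j, k))
    return found
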