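"""Synthetic evidence corpora with the statistical shape of curated PPI literature.

The generator emulates a manually curated, literature-derived interaction
corpus: a sparse directed network whose edges attach preferentially to a few
hub proteins, per-edge evidence counts that are heavy-tailed (a handful of
famous interactions soak up most of the literature while the majority have
one or two reports), a small contradiction rate, evidence-quality categories
in which the most reliable classes are the rarest, and journal impact
factors that are approximately log-normal.  Everything is reproducible from
a single seed.

:func:`generate_cliff_testbed` additionally builds networks with *planted*
knowledge cliffs — triples engineered to show a near-maximal score drop
while all other adjacent score differences stay moderate — providing ground
truth for the cliff detector and its permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .evidence_io import EvidenceCorpus, EvidenceRecord, Polarity
from .graph import ScoredNetwork
from .scoring import score_network
from .weighting import (
    N_FACTOR_CATEGORIES,
    FactorWeights,
    bin_impact_factors,
    factor_weights_from_rankings,
)

__all__ = ["SimConfig", "generate_corpus", "generate_cliff_testbed"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic evidence corpus.

    Defaults mirror a curated disease-specific PPI corpus of roughly 300
    proteins and 340 interactions: few evidence lines per edge on average
    (``evidence_mean``) with a heavy negative-binomial tail
    (``evidence_tail`` is the NB size parameter; smaller = heavier tail),
    contradictions rare (``contradiction_rate``), most edges touching
    preferential-attachment hubs (``hub_fraction``), and log-normal journal
    impact factors (``if_log_mean``, ``if_log_sd`` on the log scale).
    """

    n_proteins: int = 300
    n_edges: int = 340
    evidence_mean: float = 3.0
    evidence_tail: float = 0.6
    contradiction_rate: float = 0.05
    hub_fraction: float = 0.7
    if_log_mean: float = 1.0
    if_log_sd: float = 0.6
    n_journals: int = 100
    n_experts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2 or self.n_edges < 1:
            raise ValueError("need at least 2 proteins and 1 edge")
        if self.n_edges > self.n_proteins * (self.n_proteins - 1):
            raise ValueError(
                f"{self.n_edges} edges exceed simple-digraph capacity of "
                f"{self.n_proteins} nodes"
            )
        for name in ("contradiction_rate", "hub_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.evidence_mean < 1.0:
            raise ValueError("evidence_mean must be >= 1 (every edge has >= 1 line)")
        if self.evidence_tail <= 0:
            raise ValueError("evidence_tail must be positive")


def _protein_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _draw_edges(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Directed simple edges with preferential attachment on busy nodes."""
    names = _protein_names(cfg.n_proteins)
    degree = np.zeros(cfg.n_proteins, dtype=float)
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    max_attempts = 200 * cfg.n_edges + 1000
    attempts = 0
    while len(edges) < cfg.n_edges and attempts < max_attempts:
        attempts += 1
        if rng.random() < cfg.hub_fraction:
            w = degree + 1.0
            p = w / w.sum()
            u = int(rng.choice(cfg.n_proteins, p=p))
            v = int(rng.choice(cfg.n_proteins, p=p))
        else:
            u = int(rng.integers(cfg.n_proteins))
            v = int(rng.integers(cfg.n_proteins))
        if u == v or (u, v) in seen:
            continue
        seen.add((u, v))
        edges.append((u, v))
        degree[u] += 1
        degree[v] += 1
    if len(edges) < cfg.n_edges:  # dense regime: fill deterministically
        for u in range(cfg.n_proteins):
            for v in range(cfg.n_proteins):
                if len(edges) >= cfg.n_edges:
                    break
                if u != v and (u, v) not in seen:
                    seen.add((u, v))
                    edges.append((u, v))
    return [(names[u], names[v]) for u, v in edges]


def _evidence_counts(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-edge evidence-line counts: 1 + negative binomial (heavy tail)."""
    extra_mean = cfg.evidence_mean - 1.0
    if extra_mean <= 0:
        return np.ones(n, dtype=int)
    k = cfg.evidence_tail
    p = k / (k + extra_mean)
    return 1 + rng.negative_binomial(k, p, size=n)


def _category_probs(n: int = N_FACTOR_CATEGORIES) -> np.ndarray:
    """Linearly increasing with category id: reliable categories are rarer."""
    w = np.arange(1, n + 1, dtype=float)
    return w / w.sum()


def _expert_rankings(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Long-format ranking table: near-identity permutations per expert."""
    rows = []
    for e in range(1, cfg.n_experts + 1):
        ranks = list(range(1, N_FACTOR_CATEGORIES + 1))
        for _ in range(int(rng.integers(0, 4))):  # a few adjacent disagreements
            pos = int(rng.integers(0, N_FACTOR_CATEGORIES - 1))
            ranks[pos], ranks[pos + 1] = ranks[pos + 1], ranks[pos]
        for fid, r in enumerate(ranks, start=1):
            rows.append({"factor_id": fid, "expert_id": f"E{e:02d}", "rank": r})
    return pd.DataFrame(rows, columns=["factor_id", "expert_id", "rank"])


def _journal_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    names = [f"J{i:03d}" for i in range(1, cfg.n_journals + 1)]
    ifs = np.round(rng.lognormal(cfg.if_log_mean, cfg.if_log_sd, size=cfg.n_journals), 3)
    return pd.DataFrame({"journal": names, "impact_factor": ifs})


def generate_corpus(cfg: SimConfig) -> tuple[EvidenceCorpus, pd.DataFrame, pd.DataFrame]:
    """Generate an evidence corpus plus matching ranking and journal tables.

    Returns ``(corpus, ranking_table, journal_table)``, fully determined by
    ``cfg.seed``.  The corpus has exactly ``cfg.n_edges`` distinct directed
    pairs, every pair at least one evidence line, and contradiction lines at
    rate ``cfg.contradiction_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    pairs = _draw_edges(cfg, rng)
    counts = _evidence_counts(cfg, len(pairs), rng)
    journals_df = _journal_table(cfg, rng)
    journal_names = journals_df["journal"].tolist()
    cat_p = _category_probs()

    records: list[EvidenceRecord] = []
    pmid = 10_000_000
    for (s, t), c in zip(pairs, counts):
        cats = rng.choice(np.arange(1, N_FACTOR_CATEGORIES + 1), size=c, p=cat_p)
        jidx = rng.integers(0, len(journal_names), size=c)
        contra = rng.random(c) < cfg.contradiction_rate
        for cat, ji, neg in zip(cats, jidx, contra):
            pmid += 1
            records.append(
                EvidenceRecord(
                    source=s,
                    target=t,
                    polarity=Polarity.CONTRADICT if neg else Polarity.SUPPORT,
                    category_id=int(cat),
                    journal=journal_names[ji],
                    pmid=str(pmid),
                )
            )
    corpus = EvidenceCorpus(
        records=records,
        provenance={"generator": "ppicliffs.synthetic", "seed": cfg.seed,
                    "config": asdict(cfg), "synthetic": True},
    )
    rankings = _expert_rankings(cfg, rng)
    return corpus, rankings, journals_df


# -- planted-cliff testbed ---------------------------------------------------

#: evidence volume of the "established" planted edges (and the high anchor)
_HI_COUNT = 300
#: journals spanning the full impact-factor range, ranks 1..12
_TESTBED_JOURNALS = pd.DataFrame(
    {
        "journal": [f"JR{r:02d}" for r in range(1, 13)],
        "impact_factor": [float(13 - r) for r in range(1, 13)],
    }
)


def generate_cliff_testbed(
    cfg: SimConfig, n_planted: int
) -> tuple[ScoredNetwork, list[tuple[str, str, str]]]:
    """A scored network with ``n_planted`` ground-truth knowledge cliffs.

    A random background network (``cfg.n_proteins`` nodes, ``cfg.n_edges``
    edges, moderate evidence volumes) is augmented with ``n_planted`` chains
    ``hub -> CJt -> CKt``: the upstream edge gets the corpus-maximal
    evidence volume (highest category and venue), the downstream edge a
    single line of the weakest category from an unlisted venue.  Two
    isolated anchor edges pin the extremes of the normalization range, so
    background score differences stay small (adjacent drops well below 0.5)
    while every planted triple drops by essentially the full unit range.
    The planted upstream edges attach to the highest-out-degree background
    nodes, keeping them rare under the degree-preserving null.

    Returns the scored network and the planted triples as ground truth.
    """
    if n_planted < 0:
        raise ValueError("n_planted must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    pairs = _draw_edges(cfg, rng)

    out_deg: dict[str, int] = {}
    for s, _ in pairs:
        out_deg[s] = out_deg.get(s, 0) + 1
    hubs = sorted(out_deg, key=lambda n: (-out_deg[n], n))
    if n_planted > len(hubs):
        raise ValueError(
            f"cannot plant {n_planted} cliffs: only {len(hubs)} source nodes available"
        )

    records: list[EvidenceRecord] = []

    def add_lines(s: str, t: str, count: int, category: int, journal: str) -> None:
        for _ in range(count):
            records.append(
                EvidenceRecord(
                    source=s, target=t, polarity=Polarity.SUPPORT,
                    category_id=category, journal=journal,
                )
            )

    # background: mid-band evidence volumes, mid-quality category and venue
    for s, t in pairs:
        add_lines(s, t, int(rng.integers(3, 9)), category=6, journal="JR06")

    # anchors: isolated edges pinning the min and max of the score range;
    # the low anchor is strictly weaker than any planted downstream edge so
    # planted edges keep positive normalized weight (the cliff definition
    # requires w > 0 on both edges)
    add_lines("ANCHOR_HI_A", "ANCHOR_HI_B", _HI_COUNT, category=1, journal="JR01")
    add_lines("ANCHOR_LO_A", "ANCHOR_LO_B", 1, category=12, journal="UNLISTED")

    planted: list[tuple[str, str, str]] = []
    for t in range(n_planted):
        i, j, k = hubs[t], f"CJ{t}", f"CK{t}"
        add_lines(i, j, _HI_COUNT, category=1, journal="JR01")
        add_lines(j, k, 1, category=11, journal="UNLISTED")
        planted.append((i, j, k))

    corpus = EvidenceCorpus(
        records=records,
        provenance={"generator": "ppicliffs.synthetic.cliff_testbed",
                    "seed": cfg.seed, "n_planted": n_planted, "synthetic": True},
    )
    fw = FactorWeights.uniform_default()
    jt = bin_impact_factors(_TESTBED_JOURNALS)
    net = score_network(corpus, fw, jt)
    net.metadata["planted"] = planted
    return net, planted
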