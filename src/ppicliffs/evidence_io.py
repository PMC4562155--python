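"""Tabular I/O for evidence corpora, rankings, journal tables, and exports.

All on-disk tables are UTF-8, tab-separated, ``.`` decimal mark, LF line
endings — a bit-exact contract so round-trips and repeated runs are
byte-identical.  Three input schemas are defined:

* evidence table: ``source  target  polarity  category_id  journal  pmid``,
  one row per literature evidence line for a directed protein pair;
* factor-ranking table: ``factor_id  expert_id  rank``;
* journal table: ``journal  impact_factor``.

Scored networks are written as an edge-attribute TSV and exported to SIF or
GraphML for downstream visualization (e.g. Cytoscape).

Protein identifiers are opaque, case-sensitive strings; no symbol
normalization is attempted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import pandas as pd

from .graph import ScoredNetwork

__all__ = [
    "Polarity",
    "EvidenceRecord",
    "EvidenceCorpus",
    "ValidationIssue",
    "EVIDENCE_COLUMNS",
    "read_evidence_table",
    "write_evidence_table",
    "read_ranking_table",
    "write_ranking_table",
    "read_journal_table",
    "write_journal_table",
    "read_scored_network",
    "write_scored_network",
    "export_network",
    "ExportFormat",
]

#: canonical evidence-table column order
EVIDENCE_COLUMNS = ("source", "target", "polarity", "category_id", "journal", "pmid")

#: valid range of evidence-quality categories
CATEGORY_RANGE = range(1, 13)


class Polarity(str, enum.Enum):
    """Whether an evidence line supports or contradicts the interaction."""

    SUPPORT = "SUPPORT"
    CONTRADICT = "CONTRADICT"

    @property
    def sign(self) -> int:
        return 1 if self is Polarity.SUPPORT else -1


@dataclass(frozen=True)
class EvidenceRecord:
    """One literature evidence line for a directed protein pair.

    ``category_id`` is the evidence-quality bin (1..12) combining experiment
    type (in vivo human/mouse/cell line; in vitro physicochemical, genetic,
    library-based) with the fact-vs-hypothesis status of the statement.
    ``journal`` and ``pmid`` may be empty.
    """

    source: str
    target: str
    polarity: Polarity
    category_id: int
    journal: str = ""
    pmid: str = ""

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("source and target protein symbols must be non-empty")
        if self.category_id not in CATEGORY_RANGE:
            raise ValueError(
                f"category_id must lie in 1..12, got {self.category_id}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class ValidationIssue:
    """A problem found while reading a table; ``row`` is 1-based data-row index."""

    row: int
    message: str


@dataclass
class EvidenceCorpus:
    """Ordered collection of evidence records plus provenance metadata."""

    records: list[EvidenceRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EvidenceRecord]:
        return iter(self.records)

    def pairs(self) -> list[tuple[str, str]]:
        """Distinct directed pairs, in first-appearance order."""
        return list(dict.fromkeys(r.pair for r in self.records))

    def by_pair(self) -> dict[tuple[str, str], list[EvidenceRecord]]:
        """Evidence grouped by directed pair, insertion order preserved."""
        out: dict[tuple[str, str], list[EvidenceRecord]] = {}
        for r in self.records:
            out.setdefault(r.pair, []).append(r)
        return out

    def self_interactions(self) -> list[tuple[str, str]]:
        return [p for p in self.pairs() if p[0] == p[1]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "target": r.target,
                    "polarity": r.polarity.value,
                    "category_id": r.category_id,
                    "journal": r.journal,
                    "pmid": r.pmid,
                }
                for r in self.records
            ],
            columns=list(EVIDENCE_COLUMNS),
        )


def _parse_evidence_row(row: dict, idx: int) -> EvidenceRecord:
    raw_cat = str(row["category_id"]).strip()
    try:
        cat = int(raw_cat)
    except ValueError:
        raise ValueError(f"category_id {raw_cat!r} is not an integer") from None
    pol_raw = str(row["polarity"]).strip().upper()
    try:
        pol = Polarity(pol_raw)
    except ValueError:
        raise ValueError(
            f"polarity must be SUPPORT or CONTRADICT, got {row['polarity']!r}"
        ) from None
    return EvidenceRecord(
        source=str(row["source"]).strip(),
        target=str(row["target"]).strip(),
        polarity=pol,
        category_id=cat,
        journal=str(row["journal"]).strip(),
        pmid=str(row["pmid"]).strip(),
    )


def read_evidence_table(
    path: str | Path, strict: bool = True
) -> tuple[EvidenceCorpus, list[ValidationIssue]]:
    """Read an evidence TSV into a corpus, validating every row.

    With ``strict=True`` (default) the first malformed row raises; with
    ``strict=False`` malformed rows are skipped and reported as warnings.
    Rows are never silently dropped: the number of accepted records plus the
    number of skip warnings always equals the number of data rows.
    Self-interactions are legal but flagged with an informational issue.

    Returns
    -------
    (EvidenceCorpus, list of ValidationIssue)
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"evidence table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence table is missing columns: {sorted(missing)}")

    records: list[EvidenceRecord] = []
    issues: list[ValidationIssue] = []
    for idx, row in enumerate(df.to_dict("records"), start=1):
        try:
            records.append(_parse_evidence_row(row, idx))
        except ValueError as exc:
            if strict:
                raise ValueError(f"row {idx}: {exc}") from exc
            issues.append(ValidationIssue(row=idx, message=str(exc)))

    corpus = EvidenceCorpus(records=records, provenance={"source_file": str(path)})
    for s, t in corpus.self_interactions():
        issues.append(ValidationIssue(row=0, message=f"self-interaction {s}->{t}"))
    return corpus, issues


def write_evidence_table(corpus: EvidenceCorpus, path: str | Path) -> None:
    """Write a corpus as a canonical evidence TSV (deterministic bytes)."""
    _write_tsv(corpus.to_frame(), path)


def read_ranking_table(path: str | Path) -> pd.DataFrame:
    """Read a factor-ranking TSV (columns factor_id, expert_id, rank)."""
    df = pd.read_csv(Path(path), sep="\t", dtype={"factor_id": int, "rank": int, "expert_id": str})
    missing = {"factor_id", "expert_id", "rank"} - set(df.columns)
    if missing:
        raise ValueError(f"ranking table is missing columns: {sorted(missing)}")
    return df


def write_ranking_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[["factor_id", "expert_id", "rank"]], path)


def read_journal_table(path: str | Path) -> pd.DataFrame:
    """Read a journal impact-factor TSV (columns journal, impact_factor)."""
    df = pd.read_csv(Path(path), sep="\t", dtype={"journal": str, "impact_factor": float})
    missing = {"journal", "impact_factor"} - set(df.columns)
    if missing:
        raise ValueError(f"journal table is missing columns: {sorted(missing)}")
    return df


def write_journal_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[["journal", "impact_factor"]], path)


def read_scored_network(path: str | Path) -> ScoredNetwork:
    """Read a scored-network edge TSV written by :func:`write_scored_network`."""
    df = pd.read_csv(Path(path), sep="\t", dtype={"source": str, "target": str, "zone": str})
    return ScoredNetwork.from_frame(df, metadata={"source_file": str(path)})


def write_scored_network(net: ScoredNetwork, path: str | Path) -> None:
    """Write the canonical scored-network TSV, sorted by (source, target)."""
    _write_tsv(net.to_frame(), path)


class ExportFormat(str, enum.Enum):
    SIF = "SIF"
    GRAPHML = "GRAPHML"
    EDGE_TSV = "EDGE_TSV"


def export_network(
    net: ScoredNetwork, fmt: ExportFormat | str, path: str | Path
) -> None:
    """Export a scored network for external tools.

    ``SIF`` writes ``source interacts target`` lines (Cytoscape simple
    interaction format); ``GRAPHML`` and ``EDGE_TSV`` carry the full edge
    attributes (evidence counts and all three scores plus zone).
    """
    fmt = ExportFormat(str(fmt).upper())
    path = Path(path)
    if fmt is ExportFormat.SIF:
        df = net.to_frame()
        lines = [f"{r.source}\tinteracts\t{r.target}" for r in df.itertuples(index=False)]
        path.write_text("".join(line + "\n" for line in lines), encoding="utf-8", newline="\n")
    elif fmt is ExportFormat.GRAPHML:
        nx.write_graphml(net.to_networkx(), path)
    elif fmt is ExportFormat.EDGE_TSV:
        write_scored_network(net, path)
    else:  # pragma: no cover - ExportFormat() already raises
        raise ValueError(f"unknown export format: {fmt}")


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    text = df.to_csv(sep="\t", index=False, lineterminator="\n")
    Path(path).write_text(text, encoding="utf-8", newline="\n")
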