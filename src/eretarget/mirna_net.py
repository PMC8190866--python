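"""miRNA-mRNA consensus target network.

Target predictions from independent predictors are combined by voting: a
(miRNA, gene) pair is retained when at least ``min_votes`` predictors call
it (default 2 of 3). The network keeps only edges whose miRNA and gene are
both estrogen-responsive (direction up or down) and is bipartite by
construction. miRNA abundances are normalized to transcripts per million
(TPM) within a sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .de_integrate import DERecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusPair:
    mirna_id: str
    gene_id: str
    votes: int


@dataclass
class NetworkEdge:
    mirna_id: str
    gene_id: str
    votes: int
    mirna_direction: str
    gene_direction: str


def read_prediction_table(path: str | Path) -> set[tuple[str, str]]:
    """Read one predictor's TSV (mirna_id, gene_id[, score]) as a pair set."""
    df = pd.read_csv(path, sep="\t")
    if {"mirna_id", "gene_id"} - set(df.columns):
        raise ValueError(f"{path}: prediction table needs mirna_id and gene_id columns")
    return set(zip(df["mirna_id"], df["gene_id"]))


def consensus_pairs(
    tables: dict[str, set[tuple[str, str]] | list[tuple[str, str]]],
    min_votes: int = 2,
) -> list[ConsensusPair]:
    """Vote over predictor tables; keep pairs seen in >= min_votes of them.

    Duplicate pairs within one table collapse (with a warning); the result
    is independent of table order.
    """
    if len(tables) < 2:
        raise ValueError("consensus voting needs at least two predictor tables")
    votes: dict[tuple[str, str], int] = {}
    for name, pairs in tables.items():
        pair_list = list(pairs)
        unique = set(pair_list)
        if len(unique) < len(pair_list):
            logger.warning(
                "predictor %s: %d duplicate pairs collapsed",
                name,
                len(pair_list) - len(unique),
            )
        for pair in unique:
            votes[pair] = votes.get(pair, 0) + 1
    return sorted(
        (
            ConsensusPair(mirna_id=m, gene_id=g, votes=v)
            for (m, g), v in votes.items()
            if v >= min_votes
        ),
        key=lambda p: (p.mirna_id, p.gene_id),
    )


def build_network(
    pairs: list[ConsensusPair],
    de_records: list[DERecord],
) -> tuple[list[NetworkEdge], pd.DataFrame]:
    """Restrict consensus pairs to estrogen-responsive miRNAs and genes.

    Returns the edge list and a node attribute table (node_id, node_type,
    direction) for rendering (e.g. gene nodes circular, miRNA nodes
    diamond, colored by up/down direction).
    """
    direction = {r.gene_id: r.direction for r in de_records}
    mirna_ids = {r.gene_id for r in de_records if r.biotype == "miRNA"}
    edges = []
    for p in pairs:
        mdir = direction.get(p.mirna_id, "ns")
        gdir = direction.get(p.gene_id, "ns")
        if mdir in {"up", "down"} and gdir in {"up", "down"}:
            edges.append(
                NetworkEdge(
                    mirna_id=p.mirna_id,
                    gene_id=p.gene_id,
                    votes=p.votes,
                    mirna_direction=mdir,
                    gene_direction=gdir,
                )
            )
    nodes = sorted(
        {e.mirna_id for e in edges} | {e.gene_id for e in edges}
    )
    node_table = pd.DataFrame(
        {
            "node_id": nodes,
            "node_type": ["miRNA" if n in mirna_ids else "gene" for n in nodes],
            "direction": [direction[n] for n in nodes],
        }
    )
    return edges, node_table


def to_graph(edges: list[NetworkEdge], node_table: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    for row in node_table.itertuples(index=False):
        g.add_node(row.node_id, node_type=row.node_type, direction=row.direction)
    for e in edges:
        g.add_edge(e.mirna_id, e.gene_id, votes=e.votes)
    return g


def write_network(
    edges: list[NetworkEdge],
    node_table: pd.DataFrame,
    edge_path: str | Path,
    node_path: str | Path,
    graphml_path: str | Path | None = None,
) -> None:
    pd.DataFrame([e.__dict__ for e in edges]).to_csv(edge_path, sep="\t", index=False)
    node_table.to_csv(node_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(to_graph(edges, node_table), graphml_path)


def tpm_normalize(counts) -> np.ndarray | pd.Series:
    """Scale non-negative counts to transcripts per million (sum = 1e6)."""
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("cannot TPM-normalize all-zero counts")
    tpm = arr / total * 1e6
    if isinstance(counts, pd.Series):
        return pd.Series(tpm, index=counts.index)
    return tpm
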