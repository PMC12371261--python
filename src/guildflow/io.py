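"""Readers and writers for the pipeline's plain-text interchange formats.

Long-format TSV for abundance/metabolite tables (participant, day, feature,
value), TSV for glucose traces and edge lists, GraphML for networks, JSON
for ground truth and manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .guilds import ConsensusNetwork, GuildSet
from .simulate import AbundanceTable, MetaboliteTable


def write_long_tsv(table: AbundanceTable | MetaboliteTable, path) -> None:
    table.to_long().to_csv(path, sep="\t", index=False)


def read_abundance_tsv(path) -> AbundanceTable:
    long = pd.read_csv(path, sep="\t")
    return AbundanceTable.from_long(long)


def read_metabolite_tsv(path) -> MetaboliteTable:
    long = pd.read_csv(path, sep="\t")
    return MetaboliteTable(AbundanceTable.from_long(long).values)


def write_glucose_tsv(traces: pd.DataFrame, path) -> None:
    traces.to_csv(path, sep="\t", index=False)


def read_glucose_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def consensus_to_graphml(network: ConsensusNetwork, path) -> None:
    g = nx.Graph(group=network.group)
    g.add_nodes_from(network.nodes)
    for _, e in network.edges.iterrows():
        g.add_edge(
            e["taxon_i"], e["taxon_j"],
            support=int(e["support"]), sign=int(e["sign"]),
            mean_rho=float(e["mean_rho"]),
        )
    nx.write_graphml(g, path)


def hits_to_graphml(hits: pd.DataFrame, path) -> None:
    """Time-delayed association network (only retained hits)."""
    g = nx.DiGraph()
    for _, h in hits[hits["hit"]].iterrows():
        src, dst = (h["x"], h["y"]) if h["delay"] >= 0 else (h["y"], h["x"])
        g.add_edge(src, dst, score=float(h["score"]), delay=int(abs(h["delay"])),
                   sign=int(h["sign"]), q=float(h["q"]))
    nx.write_graphml(g, path)


def write_guilds_tsv(guilds: GuildSet, path) -> None:
    rows = [{"taxon": t, "cag": c} for t, c in sorted(guilds.assignment.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
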