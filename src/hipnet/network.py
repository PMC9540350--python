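"""Functional interaction network construction over filtered gene sets.

Edges come from STRING-dialect files: a ``protein.aliases`` table mapping
STRING protein ids to alias strings (Entrez gene ids appear as aliases) and
a space-separated ``protein.links`` table with integer combined scores on
the 0-1000 scale. Gzip-compressed files are accepted transparently. The
network is undirected; isolated nodes are retained so unconnected
interactors remain visible and reportable.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .catalog import GeneRecord
from .errors import FileFormatError, InvalidThresholdError

BAIT_GENE = "HTT"


@dataclass(frozen=True)
class NetworkEdge:
    """Undirected gene-gene edge with a STRING combined score in [0, 1000].

    Stored with endpoints in lexical order; self-loops are rejected.
    """

    gene_a: str
    gene_b: str
    combined_score: int

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop on {self.gene_a}")
        if not 0 <= self.combined_score <= 1000:
            raise ValueError(f"score {self.combined_score} outside [0, 1000]")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_string_edges(
    aliases_file,
    links_file,
    entrez_ids: Mapping[str, int],
) -> tuple[list[NetworkEdge], dict]:
    """Load edges between the queried genes from STRING-dialect files.

    ``entrez_ids`` maps gene symbol -> Entrez id for the query set. Entrez
    ids are resolved to STRING protein ids through the aliases file; genes
    whose id has no alias row are skipped and counted. Duplicate directed
    pairs collapse to one undirected edge keeping the maximum score;
    malformed links rows are skipped and counted.

    Returns (edges, report) where report holds ``unresolved`` (gene list)
    and ``malformed_rows`` (count).
    """
    wanted = {str(int(eid)): gene for gene, eid in entrez_ids.items()
              if eid is not None}
    string_to_gene: dict[str, str] = {}
    try:
        with _open_text(aliases_file) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    continue
                sid, alias = parts[0], parts[1]
                gene = wanted.get(alias.strip())
                if gene is not None:
                    string_to_gene[sid] = gene
    except OSError as exc:
        raise FileFormatError(f"cannot read aliases file {aliases_file}: {exc}")

    resolved_genes = set(string_to_gene.values())
    unresolved = sorted(set(entrez_ids) - resolved_genes)

    best: dict[tuple[str, str], int] = {}
    malformed = 0
    try:
        with _open_text(links_file) as fh:
            lines = iter(fh)
            first = next(lines, "")
            # headerless files are accepted: the first line is then data
            if "combined_score" not in first:
                lines = iter([first, *lines])
            for line in lines:
                parts = line.split()
                if len(parts) != 3:
                    if line.strip():
                        malformed += 1
                    continue
                p1, p2, score_s = parts
                try:
                    score = int(score_s)
                except ValueError:
                    malformed += 1
                    continue
                g1 = string_to_gene.get(p1)
                g2 = string_to_gene.get(p2)
                if g1 is None or g2 is None or g1 == g2:
                    continue
                key = (g1, g2) if g1 < g2 else (g2, g1)
                if score > best.get(key, -1):
                    best[key] = score
    except OSError as exc:
        raise FileFormatError(f"cannot read links file {links_file}: {exc}")

    edges = [NetworkEdge(a, b, s) for (a, b), s in sorted(best.items())]
    return edges, {"unresolved": unresolved, "malformed_rows": malformed}


class Network:
    """Undirected network over a gene set with per-gene catalog records."""

    def __init__(self, graph: nx.Graph):
        self.graph = graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[NetworkEdge]:
        return sorted(
            (
                NetworkEdge(a, b, data["combined_score"])
                for a, b, data in self.graph.edges(data=True)
            ),
            key=lambda e: (e.gene_a, e.gene_b),
        )

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene)

    @property
    def unconnected(self) -> list[str]:
        return sorted(n for n, d in self.graph.degree() if d == 0)

    def record(self, gene: str) -> GeneRecord:
        return self.graph.nodes[gene]["record"]


def build_network(
    genes: Iterable[str],
    edges: Sequence[NetworkEdge],
    score_threshold: float = 0.4,
    catalog: Mapping[str, GeneRecord] | None = None,
) -> Network:
    """Assemble the network over ``genes`` keeping edges scoring at or above
    the threshold.

    ``score_threshold`` is on the user-facing 0-1 scale and compared as
    combined_score >= round(1000 * threshold). All input genes become
    nodes; genes with no passing edge stay as isolated nodes.
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise InvalidThresholdError("score_threshold", score_threshold, "[0, 1]")
    cutoff = round(1000 * score_threshold)
    genes = set(genes)
    g = nx.Graph()
    catalog = catalog or {}
    for gene in genes:
        g.add_node(gene, record=catalog.get(gene, GeneRecord(gene)))
    for e in edges:
        if e.gene_a in genes and e.gene_b in genes and e.combined_score >= cutoff:
            g.add_edge(e.gene_a, e.gene_b, combined_score=e.combined_score)
    return Network(g)


def top_nodes(network: Network, n: int) -> Network:
    """Subnetwork induced by the ``n`` nodes with highest study count.

    Ties break by ascending gene symbol; the bait gene HTT is always
    retained when present (in addition to the top ``n``).
    """
    if n < 1:
        raise InvalidThresholdError("n", n, ">= 1")
    ranked = sorted(
        network.nodes,
        key=lambda gene: (-network.record(gene).study_count, gene),
    )
    keep = set(ranked[:n])
    if BAIT_GENE in network.nodes:
        keep.add(BAIT_GENE)
    return Network(network.graph.subgraph(keep).copy())


def export_network(network: Network, nodes_path, edges_path) -> None:
    """Write node and edge TSV tables (Cytoscape-importable).

    The node table carries gene symbol, Entrez id, HIP status, study count
    and every annotation column present on any node; the edge table has
    gene_a, gene_b, combined_score. Round-trips losslessly through
    :func:`load_network`.
    """
    ann_labels = sorted(
        {label for gene in network.nodes
         for label in network.record(gene).annotations}
    )
    rows = []
    for gene in sorted(network.nodes):
        rec = network.record(gene)
        row = {
            "gene_symbol_human": gene,
            "entrez_id": "" if rec.entrez_id is None else int(rec.entrez_id),
            "is_hip": rec.is_hip,
            "study_count": rec.study_count,
        }
        for label in ann_labels:
            val = rec.annotations.get(label, "")
            if isinstance(val, (set, frozenset, list, tuple)):
                val = ",".join(sorted(str(v) for v in val))
            row[label] = val
        rows.append(row)
    cols = ["gene_symbol_human", "entrez_id", "is_hip", "study_count", *ann_labels]
    pd.DataFrame(rows, columns=cols).to_csv(nodes_path, sep="\t", index=False)

    pd.DataFrame(
        [
            {"gene_a": e.gene_a, "gene_b": e.gene_b,
             "combined_score": e.combined_score}
            for e in network.edges
        ],
        columns=["gene_a", "gene_b", "combined_score"],
    ).to_csv(edges_path, sep="\t", index=False)


def load_network(nodes_path, edges_path) -> Network:
    """Read a network exported by :func:`export_network`."""
    nodes = pd.read_csv(nodes_path, sep="\t", dtype={"gene_symbol_human": str})
    edges = pd.read_csv(edges_path, sep="\t")
    g = nx.Graph()
    core = {"gene_symbol_human", "entrez_id", "is_hip", "study_count"}
    for row in nodes.to_dict("records"):
        annotations = {}
        for label, val in row.items():
            if label in core or pd.isna(val) or val == "":
                continue
            if isinstance(val, str) and "," in val:
                val = set(val.split(","))
            annotations[label] = val
        eid = row.get("entrez_id")
        rec = GeneRecord(
            gene_symbol_human=row["gene_symbol_human"],
            entrez_id=None if pd.isna(eid) or eid == "" else int(eid),
            is_hip=bool(row["is_hip"]),
            study_count=int(row["study_count"]),
            annotations=annotations,
        )
        g.add_node(rec.gene_symbol_human, record=rec)
    for row in edges.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, combined_score=int(row.combined_score))
    return Network(g)
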