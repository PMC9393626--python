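"""Multipartite herbs-compounds-targets-pathways network assembly.

Nodes are typed (herb, compound, gene, pathway) and edges carry a
relation whose endpoint types are fixed: herb -contains-> compound,
compound -targets-> gene, gene -member_of-> pathway, and gene
-interacts- gene.  Node ids are namespaced by type prefix so a gene
symbol can never collide with a compound name.  Networks export to
GraphML, SIF and node-link JSON, all losslessly re-importable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .compounds import ActiveCompoundSet
from .errors import AssemblyError, ParameterError
from .targets import TherapeuticTargetSet

NODE_TYPES = ("herb", "compound", "gene", "pathway")
_PREFIX = {"herb": "herb", "compound": "cmpd", "gene": "gene", "pathway": "path"}

#: relation -> (source type, target type)
RELATION_TYPES = {
    "contains": ("herb", "compound"),
    "targets": ("compound", "gene"),
    "member_of": ("gene", "pathway"),
    "interacts": ("gene", "gene"),
}


def node_id(ntype: str, name: object) -> str:
    if ntype not in NODE_TYPES:
        raise ParameterError(f"unknown node type {ntype!r}")
    return f"{_PREFIX[ntype]}:{name}"


@dataclass
class MultipartiteNetwork:
    """Typed multipartite network backed by an undirected nx.Graph."""

    graph: nx.Graph

    def add_node(self, ntype: str, name: object, **attrs) -> str:
        nid = node_id(ntype, name)
        self.graph.add_node(nid, ntype=ntype, label=str(name), **attrs)
        return nid

    def add_edge(self, relation: str, source: str, target: str) -> None:
        if relation not in RELATION_TYPES:
            raise AssemblyError(f"unknown relation {relation!r}")
        for endpoint in (source, target):
            if endpoint not in self.graph:
                raise AssemblyError(
                    f"edge ({source} -{relation}- {target}) references unknown node {endpoint}"
                )
        src_t, tgt_t = RELATION_TYPES[relation]
        if (
            self.graph.nodes[source]["ntype"],
            self.graph.nodes[target]["ntype"],
        ) != (src_t, tgt_t):
            raise AssemblyError(
                f"relation {relation!r} requires ({src_t}, {tgt_t}) endpoints, "
                f"edge ({source}, {target}) violates it"
            )
        self.graph.add_edge(source, target, relation=relation)

    def nodes_of_type(self, ntype: str) -> list[str]:
        return sorted(
            n for n, t in self.graph.nodes(data="ntype") if t == ntype
        )

    def counts(self) -> dict[str, int]:
        out = {f"n_{t}": len(self.nodes_of_type(t)) for t in NODE_TYPES}
        out["n_edges"] = self.graph.number_of_edges()
        return out

    def validate(self) -> None:
        """Re-check type discipline for every edge."""
        for u, v, rel in self.graph.edges(data="relation"):
            src_t, tgt_t = RELATION_TYPES[rel]
            types = (self.graph.nodes[u]["ntype"], self.graph.nodes[v]["ntype"])
            if types not in ((src_t, tgt_t), (tgt_t, src_t)):
                raise AssemblyError(f"edge ({u}, {v}) violates relation {rel!r}")


def assemble_hctp(
    actives: ActiveCompoundSet,
    compound_targets: Mapping[str, Iterable] | None = None,
    therapeutic: TherapeuticTargetSet | None = None,
    pathways: Mapping[object, Iterable[str]] | None = None,
) -> MultipartiteNetwork:
    """Assemble the herbs-compounds-targets-pathways network.

    ``compound_targets`` maps mol_id -> gene keys, ``pathways`` maps
    gene key -> pathway ids.  Gene nodes are restricted to the
    therapeutic target union when one is supplied.
    """
    net = MultipartiteNetwork(graph=nx.Graph())
    records = actives.records
    for herb in dict.fromkeys(records["herb"]):
        net.add_node("herb", herb)
    for _, row in records.drop_duplicates("mol_id").iterrows():
        net.add_node("compound", row["mol_id"], compound_name=row["name"])
    for _, row in records.iterrows():
        net.add_edge(
            "contains", node_id("herb", row["herb"]), node_id("compound", row["mol_id"])
        )

    allowed_genes = set(therapeutic.union) if therapeutic is not None else None
    if compound_targets:
        for mol_id, genes in compound_targets.items():
            cmpd = node_id("compound", mol_id)
            if cmpd not in net.graph:
                raise AssemblyError(f"compound targets reference unknown compound {mol_id}")
            for gene in genes:
                if allowed_genes is not None and gene not in allowed_genes:
                    continue
                gid = node_id("gene", gene)
                if gid not in net.graph:
                    net.add_node("gene", gene)
                net.add_edge("targets", cmpd, gid)
    if pathways:
        for gene, terms in pathways.items():
            gid = node_id("gene", gene)
            if gid not in net.graph:
                continue
            for term in terms:
                pid = node_id("pathway", term)
                if pid not in net.graph:
                    net.add_node("pathway", term)
                net.add_edge("member_of", gid, pid)
    net.validate()
    return net


FORMATS = ("graphml", "sif", "node-link")


def export_network(net: MultipartiteNetwork, path: str | Path, fmt: str) -> Path:
    """Write the network as GraphML, SIF or node-link JSON."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "sif":
        lines = [
            f"{u}\t{rel}\t{v}"
            for u, v, rel in sorted(net.graph.edges(data="relation"))
        ]
        isolated = sorted(n for n in net.graph if net.graph.degree(n) == 0)
        path.write_text("\n".join(lines + isolated) + ("\n" if lines or isolated else ""))
    elif fmt == "node-link":
        data = nx.node_link_data(net.graph, edges="links")
        path.write_text(json.dumps(data, indent=1, sort_keys=True))
    else:
        raise ParameterError(f"unknown export format {fmt!r}; choose from {FORMATS}")
    return path


def load_network(path: str | Path, fmt: str) -> MultipartiteNetwork:
    """Read a network written by :func:`export_network`.

    SIF stores only ids and relations; node types are recovered from the
    id prefixes.
    """
    path = Path(path)
    if fmt == "graphml":
        graph = nx.read_graphml(path)
    elif fmt == "sif":
        graph = nx.Graph()
        rev = {v: k for k, v in _PREFIX.items()}
        for line in path.read_text().splitlines():
            parts = line.split("\t")
            ids = [parts[0]] if len(parts) == 1 else [parts[0], parts[2]]
            for nid in ids:
                prefix, _, label = nid.partition(":")
                graph.add_node(nid, ntype=rev[prefix], label=label)
            if len(parts) == 3:
                graph.add_edge(parts[0], parts[2], relation=parts[1])
    elif fmt == "node-link":
        graph = nx.node_link_graph(json.loads(path.read_text()), edges="links")
    else:
        raise ParameterError(f"unknown export format {fmt!r}; choose from {FORMATS}")
    net = MultipartiteNetwork(graph=graph)
    net.validate()
    return net
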