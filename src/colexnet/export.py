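"""Writers and readers for annotated colexification networks.

GML and GraphML files target external network-visualization tools
(Cytoscape, Gephi); since those formats only carry scalar attributes, the
per-node form listings and per-edge witness instances are embedded as JSON
strings.  The package's own interchange format is a JSON document with full
witness detail, read back losslessly by :func:`read_network_json`.  All
writers emit nodes and edges in sorted order, so identical networks produce
byte-identical files.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import networkx as nx

from .inference import ColexInstance, ColexNetwork, InferenceConfig


def _instance_to_dict(instance: ColexInstance) -> dict:
    record = dataclasses.asdict(instance)
    for key in ("tokens_a", "tokens_b", "shared", "sides"):
        record[key] = list(record[key])
    return record


def _instance_from_dict(record: dict) -> ColexInstance:
    return ColexInstance(
        language_id=record["language_id"],
        family=record["family"],
        concept_a=record["concept_a"],
        concept_b=record["concept_b"],
        form_a=record["form_a"],
        form_b=record["form_b"],
        tokens_a=tuple(record["tokens_a"]),
        tokens_b=tuple(record["tokens_b"]),
        shared=tuple(record["shared"]),
        sides=tuple(record["sides"]),  # type: ignore[arg-type]
    )


def network_to_dict(net: ColexNetwork) -> dict:
    """JSON-serializable representation with full witness detail."""
    nodes = []
    for concept in sorted(net.graph.nodes):
        data = net.graph.nodes[concept]
        nodes.append({"concept": concept, **{k: data[k] for k in sorted(data)}})
    edges = []
    for a, b in sorted(net.graph.edges):
        data = net.graph.edges[a, b]
        edges.append(
            {
                "concept_a": a,
                "concept_b": b,
                "weight_forms": data["weight_forms"],
                "weight_languages": data["weight_languages"],
                "weight_families": data["weight_families"],
                "witnesses": [_instance_to_dict(w) for w in data["witnesses"]],
            }
        )
    return {
        "kind": net.kind,
        "directed": net.directed,
        "config": dataclasses.asdict(net.config),
        "nodes": nodes,
        "edges": edges,
    }


def write_network_json(net: ColexNetwork, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(network_to_dict(net), ensure_ascii=False, indent=1, sort_keys=True)
        + "\n",
        encoding="utf-8",
    )


def read_network_json(path: str | Path) -> ColexNetwork:
    """Reconstruct a network written by :func:`write_network_json`."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    graph: nx.Graph | nx.DiGraph = (
        nx.DiGraph() if payload["directed"] else nx.Graph()
    )
    for node in payload["nodes"]:
        attrs = dict(node)
        concept = attrs.pop("concept")
        graph.add_node(concept, **attrs)
    for edge in payload["edges"]:
        graph.add_edge(
            edge["concept_a"],
            edge["concept_b"],
            weight_forms=edge["weight_forms"],
            weight_languages=edge["weight_languages"],
            weight_families=edge["weight_families"],
            witnesses=[_instance_from_dict(w) for w in edge["witnesses"]],
        )
    return ColexNetwork(
        kind=payload["kind"],
        graph=graph,
        config=InferenceConfig(**payload["config"]),
    )


def _flat_graph(net: ColexNetwork) -> nx.Graph | nx.DiGraph:
    """Copy with complex annotations JSON-encoded, for GML/GraphML."""
    graph: nx.Graph | nx.DiGraph = nx.DiGraph() if net.directed else nx.Graph()
    for concept in sorted(net.graph.nodes):
        data = net.graph.nodes[concept]
        graph.add_node(
            concept,
            n_forms=data.get("n_forms", 0),
            n_languages=data.get("n_languages", 0),
            n_families=data.get("n_families", 0),
            forms=json.dumps(data.get("forms", {}), ensure_ascii=False, sort_keys=True),
        )
    for a, b in sorted(net.graph.edges):
        data = net.graph.edges[a, b]
        graph.add_edge(
            a,
            b,
            weight_forms=data["weight_forms"],
            weight_languages=data["weight_languages"],
            weight_families=data["weight_families"],
            witnesses=json.dumps(
                [_instance_to_dict(w) for w in data["witnesses"]],
                ensure_ascii=False,
                sort_keys=True,
            ),
        )
    return graph


def write_gml(net: ColexNetwork, path: str | Path) -> None:
    nx.write_gml(_flat_graph(net), str(path))


def write_graphml(net: ColexNetwork, path: str | Path) -> None:
    nx.write_graphml(_flat_graph(net), str(path))


def write_edge_tsv(net: ColexNetwork, path: str | Path) -> None:
    """Flat edge table: one row per edge, directed rows marked ``->``."""
    direction = "->" if net.directed else "--"
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "concept_a",
                "concept_b",
                "direction",
                "weight_forms",
                "weight_languages",
                "weight_families",
            ]
        )
        for a, b in sorted(net.graph.edges):
            data = net.graph.edges[a, b]
            writer.writerow(
                [
                    a,
                    b,
                    direction,
                    data["weight_forms"],
                    data["weight_languages"],
                    data["weight_families"],
                ]
            )


FORMAT_WRITERS = {
    "json": write_network_json,
    "gml": write_gml,
    "graphml": write_graphml,
    "tsv": write_edge_tsv,
}


def write_network(net: ColexNetwork, path: str | Path, fmt: str) -> None:
    try:
        writer = FORMAT_WRITERS[fmt]
    except KeyError:
        raise ValueError(
            f"unknown format {fmt!r}; available: {sorted(FORMAT_WRITERS)}"
        ) from None
    writer(net, path)
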