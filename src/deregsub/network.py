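"""Directed-network data model, file I/O and graph primitives.

The model works on simple directed graphs without self-loops over opaque
string node identifiers (e.g. KEGG-style ``hsa:1234``).  Node scores are
plain ``dict`` mappings from node id to a real deregulation score; helpers
here align them with a network (missing nodes are scored 0).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedNetwork",
    "load_network",
    "load_scores",
    "write_scores",
    "load_node_list",
    "align_scores",
    "NetworkFormatError",
]


class NetworkFormatError(ValueError):
    """Raised when a network file cannot be parsed in the named dialect."""


class DirectedNetwork:
    """A simple directed graph with optional edge interaction labels.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    node.  Node iteration order is always sorted so downstream optimization
    models are built deterministically.
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
        edge_labels: Mapping[tuple[str, str], str] | None = None,
    ) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(str(v) for v in nodes)
        n_loops = 0
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                n_loops += 1
                continue
            g.add_edge(u, v)
        if n_loops:
            logger.warning("dropped %d self-loop(s)", n_loops)
        if edge_labels:
            for (u, v), lab in edge_labels.items():
                if g.has_edge(u, v):
                    g.edges[u, v]["interaction"] = lab
        self._g = g

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self._g.nodes))

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self._g.edges))

    def edge_label(self, u: str, v: str) -> str | None:
        return self._g.edges[u, v].get("interaction")

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __contains__(self, v: str) -> bool:
        return v in self._g

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def as_nx(self) -> nx.DiGraph:
        """The underlying networkx graph (do not mutate)."""
        return self._g

    # -- primitives --------------------------------------------------------

    def _check_subset(self, S: Iterable[str]) -> set[str]:
        S = set(S)
        extra = S - set(self._g.nodes)
        if extra:
            raise ValueError(f"nodes not in network: {sorted(extra)[:5]}")
        return S

    def out_neighbors(self, S: Iterable[str] | str) -> set[str]:
        """delta+(S): nodes outside S receiving an edge from S."""
        if isinstance(S, str):
            S = {S}
        S = self._check_subset(S)
        out: set[str] = set()
        for v in S:
            out.update(self._g.successors(v))
        return out - S

    def in_neighbors(self, S: Iterable[str] | str) -> set[str]:
        """delta-(S): nodes outside S with an edge into S."""
        if isinstance(S, str):
            S = {S}
        S = self._check_subset(S)
        inc: set[str] = set()
        for v in S:
            inc.update(self._g.predecessors(v))
        return inc - S

    def strongly_connected_components(
        self, restrict: Iterable[str] | None = None
    ) -> list[frozenset[str]]:
        """SCCs of the subgraph induced by ``restrict`` (default: all nodes).

        Deterministic order: sorted by the smallest member id of each
        component.
        """
        if restrict is None:
            sub = self._g
        else:
            sub = self._g.subgraph(self._check_subset(restrict))
        comps = [frozenset(c) for c in nx.strongly_connected_components(sub)]
        return sorted(comps, key=lambda c: min(c))

    def reverse(self) -> "DirectedNetwork":
        """Network with every edge orientation flipped; labels carried over."""
        labels = {
            (v, u): d["interaction"]
            for u, v, d in self._g.edges(data=True)
            if "interaction" in d
        }
        return DirectedNetwork(
            self._g.nodes, ((v, u) for u, v in self._g.edges), labels
        )

    def induced(self, nodes: Iterable[str]) -> "DirectedNetwork":
        """Subnetwork induced by a node subset."""
        S = self._check_subset(nodes)
        labels = {
            (u, v): d["interaction"]
            for u, v, d in self._g.subgraph(S).edges(data=True)
            if "interaction" in d
        }
        return DirectedNetwork(S, self._g.subgraph(S).edges, labels)

    def reachable_from(self, root: str, within: Iterable[str] | None = None) -> set[str]:
        """Nodes reachable from ``root`` by directed paths inside ``within``."""
        if within is None:
            sub = self._g
        else:
            within = self._check_subset(within)
            sub = self._g.subgraph(within)
        if root not in sub:
            return set()
        return set(nx.descendants(sub, root)) | {root}

    # -- serialization -----------------------------------------------------

    def write_graphml(self, path: str | Path, node_attrs: Mapping[str, Mapping] | None = None) -> None:
        """Write GraphML; ``node_attrs`` maps attribute name -> {node: value}."""
        g = self._g.copy()
        if node_attrs:
            for name, values in node_attrs.items():
                nx.set_node_attributes(g, {v: values[v] for v in g.nodes if v in values}, name)
        nx.write_graphml(g, str(path))

    def write_sif(self, path: str | Path, default_label: str = "interacts") -> None:
        with open(path, "w") as fh:
            for u, v in self.edges:
                lab = self.edge_label(u, v) or default_label
                fh.write(f"{u}\t{lab}\t{v}\n")


def _load_sif(path: Path) -> DirectedNetwork:
    nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    labels: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 'source<TAB>interaction<TAB>target', got {line!r}"
                )
            src, lab, dst = (p.strip() for p in parts)
            if not src or not dst:
                raise NetworkFormatError(f"{path}:{lineno}: empty node id")
            nodes.update((src, dst))
            edges.append((src, dst))
            labels[(src, dst)] = lab
    if not nodes:
        raise NetworkFormatError(f"{path}: no nodes found")
    return DirectedNetwork(nodes, edges, labels)


def _load_graphml(path: Path) -> DirectedNetwork:
    try:
        g = nx.read_graphml(str(path))
    except Exception as exc:  # lxml/expat errors vary
        raise NetworkFormatError(f"{path}: GraphML parse failure: {exc}") from exc
    if g.number_of_nodes() == 0:
        raise NetworkFormatError(f"{path}: empty node set")
    if not g.is_directed():
        raise NetworkFormatError(f"{path}: expected a directed GraphML graph")
    labels = {
        (u, v): d["interaction"]
        for u, v, d in g.edges(data=True)
        if "interaction" in d
    }
    return DirectedNetwork(g.nodes, g.edges, labels)


def load_network(path: str | Path, format: str | None = None) -> DirectedNetwork:
    """Load a network from SIF-like TSV (``sif-tsv``) or ``graphml``.

    The format is inferred from the file extension when not given.
    Self-loops are dropped with a warning; duplicate edges are collapsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "graphml" if path.suffix.lower() in (".graphml", ".xml") else "sif-tsv"
    if format == "sif-tsv":
        return _load_sif(path)
    if format == "graphml":
        return _load_graphml(path)
    raise ValueError(f"unknown network format: {format!r}")


def load_scores(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV ``node-id<TAB>score`` into a dict."""
    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 'id<TAB>score', got {line!r}"
                )
            try:
                scores[parts[0].strip()] = float(parts[1])
            except ValueError as exc:
                raise NetworkFormatError(f"{path}:{lineno}: bad score {parts[1]!r}") from exc
    return scores


def write_scores(scores: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k in sorted(scores):
            fh.write(f"{k}\t{scores[k]}\n")


def load_node_list(path: str | Path) -> frozenset[str]:
    """Plain-text node list, one id per line; blank lines ignored."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def align_scores(network: DirectedNetwork, scores: Mapping[str, float]) -> dict[str, float]:
    """Restrict a score table to the network's nodes.

    Network nodes missing from the table default to 0 (neutral); table ids
    absent from the network are dropped with a logged count.
    """
    node_set = network.node_set
    ignored = sum(1 for k in scores if k not in node_set)
    if ignored:
        logger.info("ignored %d score id(s) absent from the network", ignored)
    return {v: float(scores.get(v, 0.0)) for v in network.nodes}
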