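"""Signed interaction networks and their comparison across conditions.

A :class:`SignedNetwork` is the consensus object distilled from an
ensemble of admissible interaction matrices: nodes are taxa, a directed
edge ``j -> i`` means taxon ``j`` influences the growth of taxon ``i``,
with a sign (facilitation ``+`` / inhibition ``-``), a strength (the
consensus magnitude of ``a_ij``) and a support (the fraction of ensemble
solutions agreeing on the sign). Self-limitation terms (the diagonal of
``A``) are bookkept separately rather than drawn as self-loops.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = ["SignedEdge", "SignedNetwork", "NetworkDiff", "compare_networks"]


@dataclass(frozen=True)
class SignedEdge:
    source: str
    target: str
    sign: int  # +1 or -1
    weight: float  # >= 0, consensus |a_ij|
    support: float  # in [0, 1]

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")
        if not 0.0 <= self.support <= 1.0:
            raise ValueError("support must lie in [0, 1]")


@dataclass(frozen=True)
class SignedNetwork:
    """Consensus signed directed graph over a fixed taxon set."""

    nodes: tuple[str, ...]
    edges: tuple[SignedEdge, ...]
    self_limitation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("node labels must be unique")
        for e in self.edges:
            if e.source not in node_set or e.target not in node_set:
                raise ValueError(f"edge {e.source}->{e.target} uses unknown node")
            if e.source == e.target:
                raise ValueError(
                    "self-loops are not allowed in the consensus network; "
                    "diagonal terms belong in self_limitation"
                )

    def edge_dict(self) -> dict[tuple[str, str], SignedEdge]:
        return {(e.source, e.target): e for e in self.edges}

    # -- export / import -------------------------------------------------

    def to_edgelist_tsv(self, path: str | Path) -> None:
        lines = ["source\ttarget\tsign\tweight\tsupport"]
        for e in self.edges:
            sign = "+" if e.sign > 0 else "-"
            lines.append(
                f"{e.source}\t{e.target}\t{sign}\t{e.weight:.10g}\t{e.support:.10g}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_edgelist_tsv(
        cls, path: str | Path, nodes: tuple[str, ...] | None = None
    ) -> "SignedNetwork":
        text = Path(path).read_text().strip().splitlines()
        header = text[0].split("\t")
        if header != ["source", "target", "sign", "weight", "support"]:
            raise ValueError(f"unexpected edge-list header: {header}")
        edges = []
        seen_nodes: list[str] = []
        for line in text[1:]:
            src, tgt, sign, weight, support = line.split("\t")
            edges.append(
                SignedEdge(src, tgt, 1 if sign == "+" else -1, float(weight),
                           float(support))
            )
            for lbl in (src, tgt):
                if lbl not in seen_nodes:
                    seen_nodes.append(lbl)
        return cls(nodes=nodes if nodes is not None else tuple(seen_nodes),
                   edges=tuple(edges))

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    @classmethod
    def from_graphml(cls, path: str | Path) -> "SignedNetwork":
        g = nx.read_graphml(str(path))
        edges = tuple(
            SignedEdge(u, v, int(d["sign"]), float(d["weight"]), float(d["support"]))
            for u, v, d in g.edges(data=True)
        )
        self_lim = {
            n: float(d["self_limitation"])
            for n, d in g.nodes(data=True)
            if "self_limitation" in d
        }
        return cls(nodes=tuple(g.nodes()), edges=edges, self_limitation=self_lim)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            attrs = {}
            if n in self.self_limitation:
                attrs["self_limitation"] = float(self.self_limitation[n])
            g.add_node(n, **attrs)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, weight=e.weight,
                       support=e.support)
        return g

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": list(self.nodes),
                "edges": [
                    {"source": e.source, "target": e.target, "sign": e.sign,
                     "weight": e.weight, "support": e.support}
                    for e in self.edges
                ],
                "self_limitation": self.self_limitation,
            },
            indent=2,
        )


@dataclass(frozen=True)
class NetworkDiff:
    """Exhaustive edge-level classification of two aligned networks.

    Every directed pair present in either network falls in exactly one
    bucket: private to the first, private to the second, shared with a
    sign flip, shared with a same-sign weight change beyond tolerance,
    or unchanged (not listed).
    """

    edges_only_in_first: tuple[tuple[str, str], ...]
    edges_only_in_second: tuple[tuple[str, str], ...]
    sign_flips: tuple[tuple[str, str], ...]
    weight_changes: tuple[tuple[str, str], ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "edges_only_in_first": [list(e) for e in self.edges_only_in_first],
                "edges_only_in_second": [list(e) for e in self.edges_only_in_second],
                "sign_flips": [list(e) for e in self.sign_flips],
                "weight_changes": [list(e) for e in self.weight_changes],
            },
            indent=2,
        )


def compare_networks(
    n1: SignedNetwork, n2: SignedNetwork, weight_tol: float = 0.05
) -> NetworkDiff:
    """Classify every edge key of two networks over the same taxa.

    Parameters
    ----------
    weight_tol : float
        Same-sign edges whose absolute weight difference is below this
        tolerance are treated as unchanged.
    """
    if set(n1.nodes) != set(n2.nodes):
        only1 = sorted(set(n1.nodes) - set(n2.nodes))
        only2 = sorted(set(n2.nodes) - set(n1.nodes))
        raise ValueError(
            f"node sets differ: only in first {only1}, only in second {only2}"
        )
    e1, e2 = n1.edge_dict(), n2.edge_dict()
    only_first, only_second, flips, wchanges = [], [], [], []
    for key in sorted(set(e1) | set(e2)):
        if key not in e2:
            only_first.append(key)
        elif key not in e1:
            only_second.append(key)
        elif e1[key].sign != e2[key].sign:
            flips.append(key)
        elif abs(e1[key].weight - e2[key].weight) >= weight_tol:
            wchanges.append(key)
    return NetworkDiff(
        edges_only_in_first=tuple(only_first),
        edges_only_in_second=tuple(only_second),
        sign_flips=tuple(flips),
        weight_changes=tuple(wchanges),
    )
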