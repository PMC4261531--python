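"""Z-scores, mutual vs temporal dependence, and the contingency network.

A rate's *Z-score* is the percentage of dependent-model rj-MCMC samples in
which that transition rate sits in the zero bin: a high Z-score means the
transition is evolutionarily restricted.  Contingency between the gains of
two characters is read off the two critical rate pairs,

    q12 vs q34   (gain of character 2 on background 1 = 0 vs 1)
    q13 vs q24   (gain of character 1 on background 2 = 0 vs 1)

If the gain of one character is restricted on the other's ancestral
background but free on its derived background, the restricted character's
gain is contingent on the other's — a *temporal* (directed) dependency where
the unlocking character precedes.  If the gains are restricted symmetrically
on both empty backgrounds the pair is *mutually* dependent (undirected).
Loss-rate restrictions are computed and reported but never generate edges:
the events of interest are the 0 -> 1 changes.

Edges carry Z-score tiers (weak >= 70, moderate >= 90, strong >= 95) and
assemble into a directed network whose layering by longest-path depth puts
earlier changes at the top.  Cycles are possible in principle and are never
silently broken: any strongly connected component of size > 1 is reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .sampler import PosteriorSample

__all__ = [
    "Z_TIERS",
    "ZScoreTable",
    "PairClassification",
    "ContingencyEdge",
    "ContingencyNetwork",
    "z_scores",
    "classify_pair",
    "tier_for",
    "build_network",
    "export_network",
    "load_network_json",
]

#: Z-score tier boundaries (inclusive): weak / moderate / strong
Z_TIERS = (70.0, 90.0, 95.0)


@dataclass(frozen=True)
class ZScoreTable:
    """Per-rate zero-bin percentages for one character pair."""

    pair: tuple
    scores: dict  # rate name -> percentage in [0, 100]

    def __post_init__(self):
        for name, v in self.scores.items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"Z-score for {name} outside [0, 100]: {v}")

    def __getitem__(self, rate: str) -> float:
        return self.scores[rate]


def z_scores(dep_sample: PosteriorSample, pair=("char1", "char2")) -> ZScoreTable:
    """Zero-bin occupancy of each of the 8 dependent-model rates, as %."""
    if dep_sample.model != "dependent":
        raise ValueError(
            "Z-scores are defined on the 8-rate dependent model, "
            f"got a {dep_sample.model!r} sample"
        )
    if len(dep_sample) == 0:
        raise ValueError("empty sample")
    pct = 100.0 * dep_sample.zero.mean(axis=0)
    return ZScoreTable(
        pair=tuple(pair),
        scores={name: float(p) for name, p in zip(dep_sample.rate_names, pct)},
    )


def tier_for(z: float) -> str | None:
    """Tier label for a restricted rate's Z-score (inclusive boundaries)."""
    weak, moderate, strong = Z_TIERS
    if z >= strong:
        return "strong"
    if z >= moderate:
        return "moderate"
    if z >= weak:
        return "weak"
    return None


@dataclass(frozen=True)
class PairClassification:
    pair: tuple
    kind: str  # "temporal" | "mutual" | "dependent-unclassified"
    source: str | None = None  # for temporal: character whose gain precedes
    target: str | None = None
    tier: str | None = None
    zscores: ZScoreTable | None = None


def classify_pair(z: ZScoreTable, dep_flag: bool = True, threshold: float = 70.0) -> PairClassification:
    """Classify a dependent pair as temporal, mutual, or unclassified.

    Only the gain rates on the two empty backgrounds (q12, q13) can signal
    restriction; their critical partners (q34, q24) must be unrestricted for
    the signal to be directional.  ``threshold`` is strict (Z > threshold
    counts as restricted), matching the published >70% rule; the edge tier is
    then assigned from the restricted rate's Z-score with inclusive
    boundaries.  A pair restricted on both empty backgrounds symmetrically is
    mutual; a pair with no interpretable restriction stays in an explicit
    "dependent-unclassified" bucket.
    """
    if not dep_flag:
        raise ValueError("classification applies only to pairs that passed the log-BF rule")
    c1, c2 = z.pair
    r12, r34 = z["q12"], z["q34"]
    r13, r24 = z["q13"], z["q24"]
    gain2_blocked = r12 > threshold and r34 <= threshold
    gain1_blocked = r13 > threshold and r24 <= threshold
    if gain2_blocked and gain1_blocked:
        # both gains restricted on the other's ancestral background
        return PairClassification(
            pair=z.pair, kind="mutual", tier=tier_for(min(r12, r13)), zscores=z
        )
    if gain2_blocked:
        # gain of c2 requires c1 = 1: c1's change precedes c2's
        return PairClassification(
            pair=z.pair, kind="temporal", source=c1, target=c2,
            tier=tier_for(r12), zscores=z,
        )
    if gain1_blocked:
        return PairClassification(
            pair=z.pair, kind="temporal", source=c2, target=c1,
            tier=tier_for(r13), zscores=z,
        )
    return PairClassification(pair=z.pair, kind="dependent-unclassified", zscores=z)


# ---------------------------------------------------------------------------
# the network


def event_label(character: str) -> str:
    """A node of the network: the 0 -> 1 change of one character."""
    return f"{character}:0->1"


@dataclass(frozen=True)
class ContingencyEdge:
    source: str  # event label
    target: str
    kind: str    # "temporal" | "mutual"
    tier: str
    z: float

    def __post_init__(self):
        if self.source == self.target:
            raise ValueError("self-edges are not allowed")
        if self.kind not in ("temporal", "mutual"):
            raise ValueError(f"unknown edge kind {self.kind!r}")


class ContingencyNetwork:
    """Character-state-change events linked by temporal/mutual dependencies.

    Temporal edges are directed (source event precedes target event); mutual
    edges are undirected.  ``layers`` assigns each event a display depth by
    longest path over the temporal edges (earlier changes shallower);
    ``cycles`` lists any strongly connected component of size > 1, which the
    builder reports rather than breaking.
    """

    def __init__(self, edges):
        self.edges = list(edges)
        g = nx.DiGraph()
        for e in self.edges:
            if e.kind == "temporal":
                g.add_edge(e.source, e.target)
            else:
                g.add_node(e.source)
                g.add_node(e.target)
        self.graph = g
        self.cycles = [sorted(c) for c in nx.strongly_connected_components(g) if len(c) > 1]
        cond = nx.condensation(g)
        order = {}
        for comp in nx.topological_sort(cond):
            depth = max(
                (order[p] + 1 for p in cond.predecessors(comp)), default=0
            )
            order[comp] = depth
        self.layers = {
            node: order[comp]
            for comp, data in cond.nodes(data=True)
            for node in data["members"]
        }

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def temporal_edges(self) -> list:
        return [e for e in self.edges if e.kind == "temporal"]

    @property
    def mutual_edges(self) -> list:
        return [e for e in self.edges if e.kind == "mutual"]

    def has_edge(self, source: str, target: str) -> bool:
        return self.graph.has_edge(source, target)

    def __eq__(self, other) -> bool:
        return isinstance(other, ContingencyNetwork) and sorted(
            map(repr, self.edges)
        ) == sorted(map(repr, other.edges))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ContingencyNetwork: {len(self.nodes)} events, "
            f"{len(self.temporal_edges)} temporal + {len(self.mutual_edges)} mutual edges>"
        )


def build_network(classifications) -> ContingencyNetwork:
    """Assemble the network from per-pair classifications.

    Unclassified pairs contribute nothing; nodes are exactly the events
    appearing in at least one edge.
    """
    edges = []
    for cl in classifications:
        if cl.kind == "temporal":
            edges.append(
                ContingencyEdge(
                    source=event_label(cl.source), target=event_label(cl.target),
                    kind="temporal", tier=cl.tier,
                    z=cl.zscores["q12"] if cl.source == cl.pair[0] else cl.zscores["q13"],
                )
            )
        elif cl.kind == "mutual":
            a, b = cl.pair
            edges.append(
                ContingencyEdge(
                    source=event_label(a), target=event_label(b),
                    kind="mutual", tier=cl.tier,
                    z=min(cl.zscores["q12"], cl.zscores["q13"]),
                )
            )
    return ContingencyNetwork(edges)


_PENWIDTH = {"weak": 1.0, "moderate": 2.5, "strong": 4.0}


def export_network(net: ContingencyNetwork, path, format: str = "dot") -> None:
    """Write the network as Graphviz DOT, a TSV edge list, or JSON.

    DOT follows the display conventions: solid arrows for temporal edges with
    pen width by tier, dotted lines without arrowheads for mutual dependence,
    ranks by layer so earlier changes sit at the top.
    """
    path = Path(path)
    if format == "dot":
        lines = ["digraph contingency {", "  rankdir=TB;"]
        by_layer: dict = {}
        for node, layer in net.layers.items():
            by_layer.setdefault(layer, []).append(node)
        for layer in sorted(by_layer):
            members = "; ".join(f'"{n}"' for n in sorted(by_layer[layer]))
            lines.append(f"  {{ rank=same; {members}; }}")
        for e in net.edges:
            if e.kind == "temporal":
                attrs = f'[penwidth={_PENWIDTH[e.tier]}, label="Z={e.z:.0f}"]'
            else:
                attrs = '[dir=none, style=dotted]'
            lines.append(f'  "{e.source}" -> "{e.target}" {attrs};')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "tsv":
        pd.DataFrame(
            [
                {"source": e.source, "target": e.target, "kind": e.kind,
                 "tier": e.tier, "z": e.z}
                for e in net.edges
            ],
            columns=["source", "target", "kind", "tier", "z"],
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif format == "json":
        payload = {
            "nodes": net.nodes,
            "layers": net.layers,
            "cycles": net.cycles,
            "edges": [
                {"source": e.source, "target": e.target, "kind": e.kind,
                 "tier": e.tier, "z": e.z}
                for e in net.edges
            ],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    else:
        raise ValueError(f"unknown network format: {format!r}")


def load_network_json(path) -> ContingencyNetwork:
    payload = json.loads(Path(path).read_text())
    return ContingencyNetwork(
        ContingencyEdge(**{k: e[k] for k in ("source", "target", "kind", "tier", "z")})
        for e in payload["edges"]
    )
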