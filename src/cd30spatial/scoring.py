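"""Cohort-level scores and preference networks.

For every (PC, NPC) combination the images of a diagnosis group are scanned
for sh and sl calls; the integer score is (#sh − #sl) and the percent score
is the score over the number of images, rounded half away from zero. A
directed preference network connects PC i → NPC j wherever the absolute
percent score strictly exceeds the edge threshold (default 50% of the
maximum); green edges mark favored (positive) and red edges unfavored
(negative) relations, self-loops included.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .datamodel import N_CLASSES, ValidationError
from .significance import SignificanceMatrix


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass
class ScoreMatrix:
    """Aggregated sh/sl counts, scores and percent scores for one group."""

    group: str
    n_images: int
    n_sh: np.ndarray
    n_sl: np.ndarray

    @property
    def score(self) -> np.ndarray:
        return self.n_sh - self.n_sl

    @property
    def percent(self) -> np.ndarray:
        out = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
        for i in range(N_CLASSES):
            for j in range(N_CLASSES):
                out[i, j] = _round_half_away(
                    100.0 * self.score[i, j] / self.n_images
                )
        return out


def score_matrix(matrices: list[SignificanceMatrix], group: str) -> ScoreMatrix:
    """Count sh and sl calls per combination across a group's images."""
    if not matrices:
        raise ValidationError(f"no significance matrices for group {group!r}")
    n_sh = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    n_sl = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for m in matrices:
        n_sh += m.calls == "sh"
        n_sl += m.calls == "sl"
    return ScoreMatrix(group=group, n_images=len(matrices), n_sh=n_sh, n_sl=n_sl)


@dataclass(frozen=True)
class NetworkEdge:
    pc: int
    npc: int
    sign: int
    weight: int  # |percent score|


@dataclass
class NetworkSpec:
    """Directed preference network over the eight profile-class nodes."""

    group: str
    edges: list[NetworkEdge]
    edge_fraction: float


def build_network(scores: ScoreMatrix, edge_fraction: float = 0.5) -> NetworkSpec:
    """Keep edges whose |percent| strictly exceeds 100·edge_fraction."""
    if not 0.0 < edge_fraction <= 1.0:
        raise ValidationError("edge_fraction must lie in (0, 1]")
    threshold = 100.0 * edge_fraction
    percent = scores.percent
    edges = [
        NetworkEdge(
            pc=i,
            npc=j,
            sign=1 if percent[i, j] > 0 else -1,
            weight=int(abs(percent[i, j])),
        )
        for i in range(N_CLASSES)
        for j in range(N_CLASSES)
        if abs(percent[i, j]) > threshold
    ]
    return NetworkSpec(group=scores.group, edges=edges, edge_fraction=edge_fraction)


def to_networkx(network: NetworkSpec) -> nx.DiGraph:
    g = nx.DiGraph(group=network.group, edge_fraction=network.edge_fraction)
    g.add_nodes_from(range(N_CLASSES))
    for e in network.edges:
        g.add_edge(e.pc, e.npc, sign=e.sign, weight=e.weight)
    return g


def _to_dot(network: NetworkSpec) -> str:
    lines = [f'digraph "{network.group}" {{']
    for i in range(N_CLASSES):
        lines.append(f'  {i} [label="PC{i}"];')
    for e in network.edges:
        color = "green" if e.sign > 0 else "red"
        penwidth = max(1.0, e.weight / 20.0)
        lines.append(
            f"  {e.pc} -> {e.npc} [color={color}, penwidth={penwidth:.2f}, "
            f"weight={e.weight}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_network(network: NetworkSpec, path: str | Path, format: str = "dot") -> Path:
    """Serialize a preference network as DOT, GraphML or edge-list CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = format.lower()
    if fmt == "dot":
        path.write_text(_to_dot(network))
    elif fmt == "graphml":
        nx.write_graphml(to_networkx(network), path)
    elif fmt == "csv":
        lines = ["pc,npc,sign,weight"]
        lines += [f"{e.pc},{e.npc},{e.sign},{e.weight}" for e in network.edges]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown network format {format!r}")
    return path


def read_network_graphml(path: str | Path) -> NetworkSpec:
    """Read back a GraphML export (round-trip counterpart)."""
    g = nx.read_graphml(path)
    edges = [
        NetworkEdge(
            pc=int(u), npc=int(v), sign=int(d["sign"]), weight=int(d["weight"])
        )
        for u, v, d in g.edges(data=True)
    ]
    return NetworkSpec(
        group=g.graph.get("group", ""),
        edges=sorted(edges, key=lambda e: (e.pc, e.npc)),
        edge_fraction=float(g.graph.get("edge_fraction", 0.5)),
    )
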