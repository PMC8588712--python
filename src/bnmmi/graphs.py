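"""DAG structures, skeletons, Markov equivalence, and structure I/O.

A learned "missing data structure" is a directed acyclic graph over the
observed variables plus the missing indicator.  Arc orientation within a
Markov-equivalence class is not statistically identifiable from
observational data, so comparisons downstream work either on the skeleton
(unordered adjacencies) or on the CPDAG (completed partially directed
acyclic graph), the canonical class representative.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

__all__ = [
    "DagStructure",
    "Cpdag",
    "skeleton",
    "cpdag",
    "read_edge_list",
    "write_edge_list",
    "to_dot",
]

Pair = frozenset


@dataclass(frozen=True)
class DagStructure:
    """Node set plus acyclic directed arc set ``(parent, child)``."""

    nodes: frozenset
    arcs: frozenset

    def __post_init__(self):
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(
            self, "arcs", frozenset(tuple(a) for a in self.arcs)
        )
        for p, c in self.arcs:
            if p == c:
                raise ValueError(f"self-loop on {p!r}")
            if p not in self.nodes or c not in self.nodes:
                raise ValueError(f"arc ({p!r}, {c!r}) references unknown node")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("arc set contains a directed cycle")

    @classmethod
    def from_arcs(cls, nodes, arcs=()) -> "DagStructure":
        return cls(frozenset(nodes), frozenset(arcs))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def parents(self, node) -> frozenset:
        return frozenset(p for p, c in self.arcs if c == node)

    def children(self, node) -> frozenset:
        return frozenset(c for p, c in self.arcs if p == node)

    def adjacent(self, a, b) -> bool:
        return (a, b) in self.arcs or (b, a) in self.arcs

    def incident_pairs(self, node) -> frozenset:
        """Skeleton relations touching ``node``."""
        return frozenset(pr for pr in skeleton(self) if node in pr)


def skeleton(dag: DagStructure) -> frozenset:
    """Unordered adjacency pairs ``{{a, b} : (a,b) or (b,a) in arcs}``."""
    return frozenset(Pair((p, c)) for p, c in dag.arcs)


@dataclass(frozen=True)
class Cpdag:
    """Completed PDAG: skeleton plus the compelled (directed) arcs.

    Two DAGs are Markov equivalent iff their CPDAGs compare equal.
    """

    nodes: frozenset
    undirected: frozenset  # frozensets {a, b}
    directed: frozenset  # ordered (parent, child)


def cpdag(dag: DagStructure) -> Cpdag:
    """Equivalence-class representative of ``dag``.

    Compelled orientations are the v-structure arcs (colliders a -> c <- b
    with a, b non-adjacent) closed under the Meek orientation rules R1-R3.
    R4 only fires in the presence of background-knowledge orientations and
    cannot trigger when starting from v-structures alone.
    """
    skel = skeleton(dag)
    adj: dict = {n: set() for n in dag.nodes}
    for pr in skel:
        a, b = tuple(pr)
        adj[a].add(b)
        adj[b].add(a)

    directed: set = set()
    for c in dag.nodes:
        for a, b in combinations(sorted(dag.parents(c)), 2):
            if b not in adj[a]:
                directed.add((a, c))
                directed.add((b, c))
    undirected = {
        pr
        for pr in skel
        if not any(o in directed for o in (tuple(pr), tuple(pr)[::-1]))
    }

    def orient(a, b):
        directed.add((a, b))
        undirected.discard(Pair((a, b)))

    changed = True
    while changed:
        changed = False
        for pr in sorted(undirected, key=sorted):
            x, y = sorted(pr)
            for a, b in ((x, y), (y, x)):
                # R1: c -> a, a - b, c and b non-adjacent  =>  a -> b
                if any(
                    (c, a) in directed and b not in adj[c] and c != b
                    for c in adj[a]
                ):
                    orient(a, b)
                    changed = True
                    break
                # R2: a -> c -> b with a - b  =>  a -> b
                if any(
                    (a, c) in directed and (c, b) in directed
                    for c in adj[a] & adj[b]
                ):
                    orient(a, b)
                    changed = True
                    break
                # R3: a - c -> b, a - d -> b, c and d non-adjacent  =>  a -> b
                cands = [
                    c
                    for c in adj[a] & adj[b]
                    if Pair((a, c)) in undirected and (c, b) in directed
                ]
                if any(
                    d not in adj[c]
                    for c, d in combinations(cands, 2)
                ):
                    orient(a, b)
                    changed = True
                    break
            if changed:
                break
    return Cpdag(dag.nodes, frozenset(undirected), frozenset(directed))


# -- structure I/O --------------------------------------------------------


def write_edge_list(dag: DagStructure, path) -> None:
    """Write arcs as tab-separated ``parent<TAB>child`` lines."""
    with open(path, "w") as fh:
        for p, c in sorted(dag.arcs):
            fh.write(f"{p}\t{c}\n")


def read_edge_list(path, nodes=None) -> DagStructure:
    """Read a ``parent<TAB>child`` edge list.

    ``nodes`` extends the node set beyond arc endpoints (needed to
    represent isolated nodes, e.g. an unconnected missing indicator).
    """
    arcs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 fields")
            arcs.append((parts[0], parts[1]))
    node_set = set(nodes or ())
    for p, c in arcs:
        node_set.update((p, c))
    return DagStructure.from_arcs(node_set, arcs)


def to_dot(dag: DagStructure, name: str = "structure") -> str:
    """Render the DAG as a DOT digraph string (no renderer required)."""
    lines = [f"digraph {name} {{"]
    for node in sorted(dag.nodes):
        lines.append(f'  "{node}";')
    for p, c in sorted(dag.arcs):
        lines.append(f'  "{p}" -> "{c}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
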