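"""Independent tree utilities used as oracles by the phylogenetics tests.

These deliberately avoid the package's own bipartition/RF code paths: trees
are plain networkx graphs, splits are enumerated by edge removal, and
parsimony steps come from a direct Fitch recursion.
"""

from __future__ import annotations

import networkx as nx


def enumerate_unrooted_trees(leaves: list[str]) -> list[nx.Graph]:
    """All unrooted binary topologies on the given leaves (1, 3, 15, 105...)."""
    if len(leaves) < 3:
        raise ValueError("need >= 3 leaves")
    g0 = nx.Graph()
    root = ("I", 0)
    g0.add_edges_from([(root, leaves[0]), (root, leaves[1]), (root, leaves[2])])
    out: list[nx.Graph] = []

    def insert(g: nx.Graph, k: int) -> None:
        if k == len(leaves):
            out.append(g)
            return
        for i, (u, v) in enumerate(list(g.edges())):
            h = g.copy()
            node = ("I", k, i)
            h.remove_edge(u, v)
            h.add_edges_from([(u, node), (v, node), (node, leaves[k])])
            insert(h, k + 1)

    insert(g0, 3)
    return out


def graph_splits(g: nx.Graph, leaves: set[str]) -> set[frozenset[frozenset[str]]]:
    """Nontrivial bipartitions of a tree graph, by removing each internal edge."""
    splits = set()
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        side = {n for n in nx.node_connected_component(h, u) if n in leaves}
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset({frozenset(side), frozenset(leaves - side)}))
    return splits


def graph_to_newick(g: nx.Graph, leaves: set[str]) -> str:
    root = next(n for n in g.nodes() if n not in leaves)

    def rec(node, parent) -> str:
        kids = [x for x in g[node] if x != parent]
        if not kids:
            return str(node)
        return "(" + ",".join(rec(k, node) for k in kids) + ")"

    return rec(root, None) + ";"


def fitch_steps(g: nx.Graph, leaves: list[str], char: dict[str, str]) -> int:
    """Exact small-parsimony step count for one unordered character."""
    root = next(iter(g[leaves[0]]))
    steps = 0

    def post(node, parent) -> set[str]:
        nonlocal steps
        kids = [x for x in g[node] if x != parent]
        if not kids:
            return {char[node]}
        cur = post(kids[0], node)
        for k in kids[1:]:
            s = post(k, node)
            inter = cur & s
            if inter:
                cur = inter
            else:
                cur = cur | s
                steps += 1
        return cur

    post(root, None)
    return steps
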