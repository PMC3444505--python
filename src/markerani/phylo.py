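"""Tree congruence and recombination checks.

Neighbor-joining trees are built from ANI-derived distances (100 − ANI) as a
fast proxy for model-based phylogenies; topological agreement is measured by
the Robinson–Foulds bipartition distance. Within-alignment recombination is
probed with a pairwise homoplasy (PHI-style) permutation test: the refined
incompatibility of two aligned columns is the cycle rank E − V + C of their
bipartite state graph (0 iff the sites are compatible, generalizing the
four-gamete test); the statistic averages incompatibility over nearby
parsimony-informative site pairs, and the null permutes informative-site
order. Recombination concentrates compatibility locally, so significance is
an unusually LOW observed statistic relative to the permutation null.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np

from .ani import PairwiseANITable
from .seqio import GeneAlignment

__all__ = [
    "nj_tree",
    "rf_distance",
    "tree_bipartitions",
    "pair_incompatibility",
    "informative_sites",
    "phi_test",
    "PhiResult",
]

_VALID = {"A": 0, "C": 1, "G": 2, "T": 3}


def nj_tree(dist, ids: list[str] | None = None) -> dendropy.Tree:
    """Neighbor-joining tree from an ANI table or a distance matrix.

    A :class:`PairwiseANITable` is converted to distances as 100 − ANI.
    A raw matrix must be symmetric with a zero diagonal and no negative
    entries. Returns an unrooted dendropy tree with branch lengths.
    """
    import skbio

    if isinstance(dist, PairwiseANITable):
        ids = dist.ids
        n = len(ids)
        mat = np.zeros((n, n))
        for i, a in enumerate(ids):
            for j in range(i + 1, n):
                d = 100.0 - dist.get(a, ids[j])
                mat[i, j] = mat[j, i] = d
    else:
        mat = np.asarray(dist, dtype=float)
        if ids is None:
            raise ValueError("ids required with a raw matrix")
        if mat.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(mat, mat.T, atol=0.0):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(mat) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(mat < 0.0):
            raise ValueError("negative distances")
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa")
    dm = skbio.DistanceMatrix(mat, ids=ids)
    newick = skbio.tree.nj(dm).write(io.StringIO()).getvalue()
    return dendropy.Tree.get(data=newick, schema="newick")


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    """Nontrivial bipartitions of an (un)rooted tree as unordered split pairs."""
    leaves = frozenset(
        lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None
    )
    n = len(leaves)
    splits: set[frozenset[frozenset[str]]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None
        )
        if 1 < len(below) < n - 1:
            splits.add(frozenset({below, leaves - below}))
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree, normalize: bool = False) -> float:
    """Robinson–Foulds symmetric-difference distance between two topologies.

    With ``normalize`` the count is divided by 2(n−3), the maximum over fully
    resolved unrooted trees on n shared leaves.
    """
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter() if lf.taxon is not None}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter() if lf.taxon is not None}
    if l1 != l2:
        raise ValueError(
            f"leaf-set mismatch (only-first: {sorted(l1 - l2)[:3]}, "
            f"only-second: {sorted(l2 - l1)[:3]})"
        )
    b1 = tree_bipartitions(t1)
    b2 = tree_bipartitions(t2)
    rf = len(b1 ^ b2)
    if normalize:
        denom = 2 * (len(l1) - 3)
        return rf / denom if denom > 0 else 0.0
    return float(rf)


def _encode_column(column: dict[str, str]) -> dict[str, int]:
    """Taxon -> state code, dropping gaps/ambiguities (missing data)."""
    out = {}
    for taxon, ch in column.items():
        code = _VALID.get(ch.upper())
        if code is not None:
            out[taxon] = code
    return out


def pair_incompatibility(site_i: dict[str, str], site_j: dict[str, str]) -> int:
    """Refined incompatibility of two aligned columns (cycle rank E − V + C).

    Taxa where either site holds a gap or ambiguity are dropped pairwise.
    Zero iff the two sites could both evolve without homoplasy on a single
    tree; for two binary sites this is exactly the four-gamete test.
    """
    ci = _encode_column(site_i)
    cj = _encode_column(site_j)
    shared = [t for t in ci if t in cj]
    if len(shared) < 2:
        raise ValueError("fewer than 2 taxa after filtering gaps/ambiguities")
    edges = {(ci[t], cj[t]) for t in shared}
    return _cycle_rank(edges)


def _cycle_rank(edges: set[tuple[int, int]]) -> int:
    left = {e[0] for e in edges}
    right = {e[1] for e in edges}
    nodes = [("L", x) for x in left] + [("R", y) for y in right]
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    comps = len(nodes)
    for x, y in edges:
        a, b = find(("L", x)), find(("R", y))
        if a != b:
            parent[a] = b
            comps -= 1
    return len(edges) - len(nodes) + comps


def informative_sites(aln: GeneAlignment) -> list[int]:
    """Columns with at least two unambiguous states each seen at least twice."""
    out = []
    rows = list(aln.rows.values())
    for j in range(aln.length):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[j].upper()
            if ch in _VALID:
                counts[ch] = counts.get(ch, 0) + 1
        if sum(1 for c in counts.values() if c >= 2) >= 2:
            out.append(j)
    return out


@dataclass(frozen=True)
class PhiResult:
    statistic: float | None
    window_w: int
    n_informative: int
    n_permutations: int
    p_value: float | None
    seed: int
    status: str = "ok"

    def p_display(self) -> str:
        from .concordance import format_p

        return "undefined" if self.p_value is None else format_p(self.p_value)


def _incompatibility_matrix(codes: list[np.ndarray]) -> np.ndarray:
    """Pairwise cycle-rank matrix over informative columns (codes use -1 for
    missing)."""
    n = len(codes)
    mat = np.zeros((n, n))
    for i in range(n):
        ci = codes[i]
        for j in range(i + 1, n):
            cj = codes[j]
            ok = (ci >= 0) & (cj >= 0)
            if ok.sum() < 2:
                continue  # uninformative overlap scores 0
            edges = set(zip(ci[ok].tolist(), cj[ok].tolist()))
            mat[i, j] = mat[j, i] = _cycle_rank(edges)
    return mat


def phi_test(
    aln: GeneAlignment,
    window_w: int = 100,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PhiResult:
    """PHI-style permutation test for recombination within an alignment.

    The statistic is the mean pairwise incompatibility over informative-site
    pairs at most ``window_w`` apart in informative-site index space. The null
    permutes the order of informative sites; the p-value is the add-one
    corrected fraction of permutations whose statistic is <= the observed one
    (recombination makes nearby sites unusually compatible).
    """
    if len(aln.rows) < 4:
        raise ValueError("PHI test needs at least 4 sequences")
    sites = informative_sites(aln)
    n_inf = len(sites)
    if n_inf < 2:
        return PhiResult(
            statistic=None,
            window_w=window_w,
            n_informative=n_inf,
            n_permutations=n_permutations,
            p_value=None,
            seed=seed,
            status="too few informative sites",
        )
    taxa = list(aln.rows)
    codes = []
    for j in sites:
        codes.append(
            np.array([_VALID.get(aln.rows[t][j].upper(), -1) for t in taxa], dtype=np.int64)
        )
    mat = _incompatibility_matrix(codes)

    w = min(window_w, n_inf - 1)
    idx = np.arange(n_inf)

    def windowed_mean(order: np.ndarray) -> float:
        total = 0.0
        count = 0
        for d in range(1, w + 1):
            total += mat[order[:-d], order[d:]].sum()
            count += n_inf - d
        return total / count

    observed = windowed_mean(idx)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n_inf)
        if windowed_mean(perm) <= observed + 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PhiResult(
        statistic=float(observed),
        window_w=window_w,
        n_informative=n_inf,
        n_permutations=n_permutations,
        p_value=float(min(p, 1.0)),
        seed=seed,
    )
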