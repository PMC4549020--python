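"""Phylogenetic diversity (PD) statistics and maximum-PD subset selection.

PD of a tree is the sum of its branch lengths; PD of a leaf subset is the
total length of the subtree spanning those leaves.  Trees are inputs
(newick with branch lengths, handled by dendropy); tree inference is out
of scope.  PD is invariant to the root position, so unrooted trees are
traversed from an arbitrary rooting.

``greedy_max_pd_subset`` implements the classic greedy PD maximization:
start from the two leaves with the longest path, then repeatedly add the
leaf farthest from the current spanning subtree.  Greedy selection is
optimal for PD on trees, and is used here to cull an alignment to its k
most diverse sequences.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable

import dendropy

from .errors import TreeError


def read_tree(path_or_string, schema: str = "newick") -> dendropy.Tree:
    """Read a tree (path or newick string) and validate branch lengths."""
    if isinstance(path_or_string, str) and path_or_string.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=path_or_string, schema=schema)
    else:
        tree = dendropy.Tree.get(path=str(path_or_string), schema=schema)
    _validate(tree)
    return tree


def _validate(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeError(f"negative branch length {edge.length}")


def pd(tree: dendropy.Tree) -> float:
    """Phylogenetic diversity: the sum of all branch lengths."""
    _validate(tree)
    return float(
        sum(e.length for e in tree.preorder_edge_iter() if e.length is not None)
    )


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _adjacency(tree: dendropy.Tree):
    """Undirected adjacency (node -> [(neighbor, length)]) and leaf map."""
    adj = defaultdict(list)
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            w = child.edge.length or 0.0
            adj[node].append((child, w))
            adj[child].append((node, w))
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    return adj, leaves


def pd_subset(tree: dendropy.Tree, leaf_subset: Iterable[str]) -> float:
    """PD of the subtree spanning ``leaf_subset`` (unrooted definition).

    An edge contributes iff it lies on a path between two selected leaves,
    so stem edges above their common ancestor never count and the value is
    rooting-invariant.
    """
    wanted = set(leaf_subset)
    labels = set(leaf_labels(tree))
    unknown = wanted - labels
    if unknown:
        raise TreeError(f"unknown leaves: {sorted(unknown)}")
    if not wanted:
        raise TreeError("leaf subset must be non-empty")
    total_sel = len(wanted)
    below: dict = {}
    total = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = 1 if node.taxon.label in wanted else 0
        else:
            below[node] = sum(below[c] for c in node.child_nodes())
        if node.edge.length and 0 < below[node] < total_sel:
            total += node.edge.length
    return float(total)


def prune(tree: dendropy.Tree, leaf_subset: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on a leaf subset, unifurcations suppressed.

    The stem edge above the retained clade is removed so that
    ``pd(prune(t, S)) == pd_subset(t, S)``.
    """
    wanted = set(leaf_subset)
    labels = set(leaf_labels(tree))
    unknown = wanted - labels
    if unknown:
        raise TreeError(f"unknown leaves: {sorted(unknown)}")
    sub = tree.extract_tree_with_taxa_labels(wanted)
    sub.purge_taxon_namespace()
    # drop any stem above the first multifurcation/leaf split
    while len(sub.seed_node.child_nodes()) == 1:
        child = sub.seed_node.child_nodes()[0]
        child.edge.length = None
        sub.seed_node = child
        child.parent_node = None
    sub.seed_node.edge.length = None
    return sub


def path_length(tree: dendropy.Tree, leaf_a: str, leaf_b: str) -> float:
    """Branch-length distance between two leaves."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    try:
        return float(pdm.patristic_distance(taxa[leaf_a], taxa[leaf_b]))
    except KeyError as exc:
        raise TreeError(f"unknown leaf {exc}") from exc


def greedy_max_pd_subset(tree: dendropy.Tree, k: int) -> list[str]:
    """The k leaves whose spanning subtree maximizes PD.

    Ties (equal path lengths or gains) are broken by leaf-name order for
    determinism.  Returns leaf labels sorted by name.
    """
    labels = leaf_labels(tree)
    if not 2 <= k <= len(labels):
        raise TreeError(f"k={k} outside 2..{len(labels)}")
    adj, leaves = _adjacency(tree)

    def farthest(start_nodes):
        """Distance from a set of seed nodes to every node (Dijkstra-free:
        trees have unique paths, so a BFS with accumulated lengths works)."""
        dist = {n: 0.0 for n in start_nodes}
        stack = list(start_nodes)
        while stack:
            node = stack.pop()
            for nb, w in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + w
                    stack.append(nb)
        return dist

    # seed pair: maximize path length, ties by name order
    best = None
    for name in sorted(leaves):
        dist = farthest([leaves[name]])
        for other in sorted(leaves):
            if other == name:
                continue
            d = dist[leaves[other]]
            key = (-d, *sorted((name, other)))
            if best is None or key < best[0]:
                best = (key, tuple(sorted((name, other))))
    chosen = set(best[1])
    # nodes already inside the spanning subtree
    in_tree = set()
    a, b = (leaves[x] for x in best[1])
    # mark the path between a and b via parent pointers from a BFS
    prev = {a: None}
    stack = [a]
    while stack:
        node = stack.pop()
        for nb, _ in adj[node]:
            if nb not in prev:
                prev[nb] = node
                stack.append(nb)
    node = b
    while node is not None:
        in_tree.add(node)
        node = prev[node]

    while len(chosen) < k:
        dist = farthest(in_tree)
        cand = min(
            (name for name in sorted(leaves) if name not in chosen),
            key=lambda nm: (-dist[leaves[nm]], nm),
        )
        chosen.add(cand)
        # extend the spanning subtree along the path to the new leaf
        prev = {n: None for n in in_tree}
        stack = list(in_tree)
        while stack:
            node = stack.pop()
            for nb, _ in adj[node]:
                if nb not in prev:
                    prev[nb] = node
                    stack.append(nb)
        node = leaves[cand]
        while node is not None and node not in in_tree:
            in_tree.add(node)
            node = prev[node]
    return sorted(chosen)
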