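"""Small tree helpers: shapes, clade sets, rooted Robinson-Foulds.

dendropy does the newick parsing; comparisons here are on rooted trees, as
sets of non-trivial clades (leaf-label sets of internal nodes, excluding the
root set and singletons).
"""

from __future__ import annotations

import numpy as np


def balanced_newick(n_taxa: int, prefix: str = "t") -> str:
    """Fully balanced-ish rooted binary tree with unit branch lengths."""
    labels = [f"{prefix}{i + 1:02d}" for i in range(n_taxa)]

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"{labels[lo]}:1"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):1"

    return build(0, n_taxa)[:-2] + ";"


def pectinate_newick(n_taxa: int, prefix: str = "t") -> str:
    """Fully pectinate (ladder) rooted tree with unit branch lengths."""
    labels = [f"{prefix}{i + 1:02d}" for i in range(n_taxa)]
    s = f"({labels[-2]}:1,{labels[-1]}:1):1"
    for lab in reversed(labels[:-2]):
        s = f"({lab}:1,{s}):1"
    return s[:-2] + ";"


def random_newick(n_taxa: int, rng: np.random.Generator, prefix: str = "t") -> str:
    """Random binary topology by sequential random joins, unit lengths."""
    nodes = [f"{prefix}{i + 1:02d}:1" for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):1")
    return nodes[0][:-2] + ";"


def load_tree(newick: str):
    import dendropy

    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")


def clade_sets_from_newick(newick: str) -> set[frozenset]:
    """Non-trivial clades (rooted): leaf sets of internal non-root nodes."""
    tree = load_tree(newick)
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        s = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(s) < len(all_leaves):
            out.add(s)
    return out


def rf_rooted(clades_a: set[frozenset], clades_b: set[frozenset]) -> int:
    """Rooted Robinson-Foulds distance: symmetric difference of clade sets."""
    return len(clades_a ^ clades_b)
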