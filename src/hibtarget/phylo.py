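"""Tree utilities shared by the codon models and the comparative methods.

Trees are handled as dendropy objects; branch-class labels for the codon
branch models use CODEML-style ``#1`` suffixes on node labels, or an explicit
edge->class map.
"""

from __future__ import annotations

import re

import dendropy
import numpy as np

_LABEL_TAG = re.compile(r"\s*#\s*(\d+)\s*$")


def parse_labeled_tree(newick: str) -> tuple[dendropy.Tree, dict[int, int]]:
    """Parse newick with optional ``#k`` branch-class suffixes.

    Returns the tree and a map from edge id (id of the child node) to class
    index; unlabeled edges belong to class 0 (background).  A label on an
    internal node tags the edge subtending that node (CODEML convention).
    """
    # protect '#' through the parser by rewriting to a label suffix
    sanitized = newick.replace("#", "@HASH@")
    tree = dendropy.Tree.get(
        data=sanitized,
        schema="newick",
        suppress_internal_node_taxa=False,
        preserve_underscores=True,
    )
    classes: dict[int, int] = {}
    for node in tree:
        label = None
        if node.taxon is not None and node.taxon.label:
            label = node.taxon.label
        elif node.label:
            label = node.label
        if label and "@HASH@" in label:
            base, tag = label.split("@HASH@", 1)
            m = re.match(r"\s*(\d+)\s*$", tag)
            if not m:
                raise ValueError(f"malformed branch label on {label!r}")
            classes[id(node)] = int(m.group(1))
            base = base.strip()
            if node.taxon is not None:
                node.taxon.label = base
                if not base:
                    node.taxon = None
            node.label = base or None
        else:
            classes.setdefault(id(node), 0)
    return tree, classes


def tree_taxa(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def phylo_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance: C[i, j] = root-to-MRCA(i, j) path length."""
    leaves = list(tree.leaf_node_iter())
    taxa = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    # depth of every node
    depth = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    # leaf sets under each node
    C = np.zeros((n, n))
    index = {id(lf): i for i, lf in enumerate(leaves)}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leaf_idx = [index[id(node)]]
        else:
            kids = [ch._leaf_idx for ch in node.child_nodes()]
            merged = []
            for k in kids:
                merged.extend(k)
            node._leaf_idx = merged
            d = depth[id(node)]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        C[i, kids[b]] = d
                        C[np.ix_(kids[b], [i])] = d
    for i, lf in enumerate(leaves):
        C[i, i] = depth[id(lf)]
    return taxa, C


def pure_birth_tree(
    n_tips: int, seed: int, birth_rate: float = 1.0
) -> dendropy.Tree:
    """Seeded Yule tree on ``n_tips`` taxa, scaled to unit root-to-tip height."""
    rng = np.random.default_rng(seed)
    # Yule process: start from 2 lineages, split a random lineage at
    # exponential waiting times; assemble as nested dendropy nodes.
    taxa = [f"sp{i + 1:02d}" for i in range(n_tips)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    active = []
    for _ in range(2):
        ch = dendropy.Node()
        ch.edge.length = 0.0
        root.add_child(ch)
        active.append(ch)
    t = 0.0
    birth_times = {id(root): 0.0}
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active[rng.integers(k)]
        birth_times[id(node)] = t
        for _ in range(2):
            ch = dendropy.Node()
            ch.edge.length = 0.0
            node.add_child(ch)
            active.append(ch)
        active.remove(node)
    # final epoch: extend all to present
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        start = birth_times.get(id(node.parent_node), 0.0)
        end = birth_times.get(id(node), t_end)
        node.edge.length = end - start
    for leaf, name in zip(tree.leaf_node_iter(), taxa):
        leaf.taxon = tns.get_taxon(name)
    # scale to unit height
    height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    if height > 0:
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length /= height
    return tree
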