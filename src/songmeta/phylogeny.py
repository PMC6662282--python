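"""Tree handling: Newick IO, outgroup rooting, mean-edge consensus, pruning,
and the species relatedness (phylogenetic correlation) matrix.

Trees are `dendropy.Tree` objects throughout. The correlation matrix assumes
Brownian-motion evolution on a rooted tree: the covariance between two
species is the depth of their most recent common ancestor, and the matrix is
normalised to a correlation (unit diagonal), which on an ultrametric tree is
simply MRCA depth over total tree depth.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloCorrelation",
    "read_trees",
    "write_tree",
    "root_with_outgroup",
    "consensus_tree",
    "prune",
    "phylo_correlation",
]


@dataclass
class PhyloCorrelation:
    """Species-by-species phylogenetic correlation matrix."""

    taxa: list[str]
    A: np.ndarray

    def subset(self, taxa: Sequence[str]) -> "PhyloCorrelation":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCorrelation(taxa=list(taxa), A=self.A[np.ix_(idx, idx)])


def read_trees(path: str | Path) -> list[dendropy.Tree]:
    """Read one or more Newick trees sharing a taxon namespace."""
    tns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", taxon_namespace=tns,
        suppress_internal_node_taxa=True,
    )
    if len(trees) == 0:
        raise ValueError(f"no trees found in {path}")
    for tree in trees:
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate tip labels in tree from {path}")
    return list(trees)


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def root_with_outgroup(
    tree: dendropy.Tree, taxon: str, drop_outgroup: bool = False
) -> dendropy.Tree:
    """Root a tree on the edge subtending ``taxon``; optionally remove it after."""
    tree = tree.clone(depth=1)
    node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == taxon:
            node = leaf
            break
    if node is None:
        raise ValueError(f"outgroup taxon {taxon!r} not present in tree")
    length = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0,
                        update_bipartitions=False)
    tree.is_rooted = True
    if drop_outgroup:
        tree = prune(tree, [t for t in tip_labels(tree) if t != taxon])
    return tree


def _clade_sets(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Map each clade (set of tip labels below a node) to its subtending edge length."""
    out = {}
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        tips = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        out[tips] = node.edge.length if node.edge.length is not None else 0.0
    return out


def consensus_tree(
    trees: Sequence[dendropy.Tree], clade_threshold: float = 0.5
) -> dendropy.Tree:
    """Majority-rule consensus with mean edge lengths.

    A clade is retained when it appears in more than ``clade_threshold`` of
    the trees; its edge length is the arithmetic mean of the lengths of that
    clade's subtending edge over the trees that contain it. Terminal edges
    appear in every tree, so their lengths are means over all trees. For
    thresholds below 0.5 incompatible clades can both pass; they are admitted
    greedily in decreasing frequency order.
    """
    if len(trees) == 0:
        raise ValueError("need at least one tree")
    ref_tips = frozenset(tip_labels(trees[0]))
    counts: dict[frozenset, int] = defaultdict(int)
    length_sums: dict[frozenset, float] = defaultdict(float)
    for tree in trees:
        tips = frozenset(tip_labels(tree))
        if tips != ref_tips:
            raise ValueError("trees have mismatched tip sets")
        for clade, length in _clade_sets(tree).items():
            counts[clade] += 1
            length_sums[clade] += length

    n = len(trees)
    candidates = sorted(
        (c for c in counts if counts[c] / n > clade_threshold and len(c) > 1),
        key=lambda c: (-counts[c], -len(c), tuple(sorted(c))),
    )
    kept: list[frozenset] = []
    for clade in candidates:
        if all(
            clade <= other or other <= clade or not (clade & other)
            for other in kept
        ):
            kept.append(clade)

    # Build the rooted consensus by nesting clades by containment.
    tns = dendropy.TaxonNamespace(sorted(ref_tips))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    clades_by_size = sorted(kept, key=len, reverse=True)
    root_set = frozenset(ref_tips)
    node_of: dict[frozenset, dendropy.Node] = {root_set: tree.seed_node}
    for clade in clades_by_size:
        parent_set = min(
            (s for s in node_of if clade < s), key=len, default=root_set
        )
        node = dendropy.Node()
        node.edge.length = length_sums[clade] / counts[clade]
        node_of[parent_set].add_child(node)
        node_of[clade] = node
    for label in sorted(ref_tips):
        leaf_set = frozenset([label])
        parent_set = min((s for s in node_of if leaf_set < s), key=len)
        leaf = dendropy.Node(taxon=tns.get_taxon(label))
        leaf.edge.length = length_sums[leaf_set] / counts[leaf_set]
        node_of[parent_set].add_child(leaf)
    return tree


def prune(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on ``keep``; unifurcations collapsed with summed lengths."""
    keep = list(keep)
    tips = set(tip_labels(tree))
    unknown = sorted(set(keep) - tips)
    if unknown:
        raise ValueError(f"species not in tree: {unknown}")
    tree = tree.clone(depth=1)
    tree.retain_taxa_with_labels(keep)
    # retain_taxa may leave a unifurcate root edge; fold it into its child.
    root = tree.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        extra = (root.edge.length or 0.0)
        tree.seed_node = child
        child.parent_node = None
        child.edge.length = (child.edge.length or 0.0) + extra
        root = child
    return tree


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def phylo_correlation(tree: dendropy.Tree, taxa: Sequence[str]) -> PhyloCorrelation:
    """Brownian-motion correlation matrix over ``taxa``.

    Covariance between tips i and j is the root-to-MRCA(i, j) depth; the
    matrix is normalised to correlations, A_ij = S_ij / sqrt(S_ii S_jj),
    which equals MRCA depth over total depth on an ultrametric tree and
    keeps the diagonal at exactly 1 on slightly non-ultrametric consensus
    trees. Tiny negative values from rounding are clipped at 0.
    """
    taxa = list(taxa)
    tips = set(tip_labels(tree))
    missing = sorted(set(taxa) - tips)
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    if set(taxa) != tips:
        tree = prune(tree, taxa)
    depths = _node_depths(tree)
    if max(depths.values()) <= 0:
        raise ValueError("tree has zero depth; correlations undefined")

    leaf_of = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    # ancestor chains from root to each tip
    chains = {}
    for label in taxa:
        chain = []
        node = leaf_of[label]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        chains[label] = set(chain)

    k = len(taxa)
    S = np.zeros((k, k))
    for i, a in enumerate(taxa):
        S[i, i] = depths[leaf_of[a]]
        for j in range(i + 1, k):
            b = taxa[j]
            shared = chains[a] & chains[b]
            mrca_depth = max(depths[nd] for nd in shared)
            S[i, j] = S[j, i] = max(mrca_depth, 0.0)
    d = np.sqrt(np.diag(S))
    if np.any(d <= 0):
        bad = [taxa[i] for i in np.where(d <= 0)[0]]
        raise ValueError(f"zero root-to-tip depth for taxa {bad}")
    A = S / np.outer(d, d)
    A = np.clip(A, 0.0, None)
    np.fill_diagonal(A, 1.0)
    return PhyloCorrelation(taxa=taxa, A=A)
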