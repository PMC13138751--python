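"""Phylogeny handling: tree I/O, phylogenetic correlation matrices, maximum
clade credibility selection and grafting of fossil subtrees.

Trees are thin wrappers around :class:`dendropy.Tree`. Branch lengths are in
millions of years. The phylogenetic correlation matrix ``C`` holds, for each
pair of taxa, the shared root-to-MRCA path length divided by the maximum
root-to-tip depth, so that for an ultrametric tree the diagonal is 1 and for
a fossil-bearing tree fossil diagonal entries are < 1 (Brownian variance
accrues with time).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCov",
    "TreeFormatError",
    "read_trees",
    "phylo_correlation",
    "mcc_tree",
    "graft",
]


class TreeFormatError(ValueError):
    """Raised when a tree file cannot be parsed."""


def normalize_label(label: str) -> str:
    """Canonical taxon label: trimmed, underscores -> spaces, collapsed whitespace."""
    return re.sub(r"\s+", " ", label.replace("_", " ").strip())


class Phylogeny:
    """A rooted tree with nonnegative branch lengths.

    Parameters
    ----------
    tree : dendropy.Tree
        The underlying tree. Taken by reference; tip labels are normalized
        in place (underscores and spaces treated as equivalent).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None:
                raise TreeFormatError("tree has an unlabeled tip")
            leaf.taxon.label = normalize_label(leaf.taxon.label)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels after normalization")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        depths: dict[str, float] = {}
        for node in self._tree.preorder_node_iter():
            parent_depth = 0.0 if node.parent_node is None else node.parent_node._ph_depth
            node._ph_depth = parent_depth + (node.edge.length or 0.0)
            if node.is_leaf():
                depths[node.taxon.label] = node._ph_depth
        return depths

    @property
    def max_depth(self) -> float:
        return max(self.tip_depths().values())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = np.array(list(self.tip_depths().values()))
        dmax = depths.max()
        if dmax == 0:
            return True
        return bool(np.all(np.abs(depths - dmax) <= rel_tol * dmax))

    def clades(self) -> list[frozenset[str]]:
        """Tip-label sets of all internal nodes (including the root)."""
        out = []
        for node in self._tree.postorder_node_iter():
            if not node.is_leaf():
                out.append(frozenset(l.taxon.label for l in node.leaf_iter()))
        return out

    def as_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    def clone(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        return cls(tree)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips, max depth {self.max_depth:.3g}>"


@dataclass
class PhyloCov:
    """Phylogenetic correlation matrix over an ordered taxon list.

    ``C[i, j]`` is the shared root-to-MRCA path length of taxa i and j divided
    by the maximum root-to-tip depth of the source tree. Diagonal entries are
    1 for extant tips of an ultrametric tree and < 1 for fossil tips.
    """

    labels: list[str]
    C: np.ndarray
    max_depth: float = field(default=1.0)

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (len(self.labels), len(self.labels)):
            raise ValueError("C shape does not match label count")

    def cholesky(self, jitter: float = 1e-8) -> np.ndarray:
        """Lower Cholesky factor of C + jitter*I (stabilizes zero-length splits)."""
        return np.linalg.cholesky(self.C + jitter * np.eye(len(self.labels)))

    def subset(self, taxa: list[str]) -> "PhyloCov":
        idx = [self.labels.index(t) for t in taxa]
        return PhyloCov(list(taxa), self.C[np.ix_(idx, idx)], self.max_depth)


def read_trees(path, format: str = "newick") -> list[Phylogeny]:
    """Read all trees from a file, in file order.

    Raises :class:`TreeFormatError` naming the 1-based index of the first
    malformed tree, or an empty-input error for a file with no trees.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format: {format!r}")
    with open(path) as fh:
        text = fh.read()
    if format == "newick":
        chunks = [c.strip() for c in text.split(";") if c.strip()]
        if not chunks:
            raise TreeFormatError(f"empty tree file: {path}")
        trees = []
        for i, chunk in enumerate(chunks, start=1):
            try:
                trees.append(Phylogeny.from_newick(chunk + ";"))
            except Exception as exc:
                raise TreeFormatError(f"tree {i} in {path} failed to parse: {exc}") from exc
        return trees
    try:
        tl = dendropy.TreeList.get(data=text, schema="nexus")
    except Exception as exc:
        raise TreeFormatError(f"nexus file {path} failed to parse: {exc}") from exc
    if len(tl) == 0:
        raise TreeFormatError(f"empty tree file: {path}")
    return [Phylogeny(t) for t in tl]


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[node] = (depths[parent] if parent is not None else 0.0) + (
            node.edge.length or 0.0
        )
    return depths


def phylo_correlation(tree: Phylogeny, taxa: list[str] | None = None) -> PhyloCov:
    """Shared-path-length matrix for ``taxa`` scaled by the maximum tip depth.

    MRCA depths are computed by a single postorder sweep; the scaling depth is
    the maximum over *all* tips of the tree (the extant depth when fossils are
    present), so fossil diagonal entries come out < 1.
    """
    dtree = tree.dendropy_tree
    all_tips = tree.tips
    if taxa is None:
        taxa = all_tips
    else:
        taxa = [normalize_label(t) for t in taxa]
        missing = [t for t in taxa if t not in all_tips]
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
    depths = _node_depths(dtree)
    max_depth = max(depths[l] for l in dtree.leaf_node_iter())
    n = len(taxa)
    pos = {t: i for i, t in enumerate(taxa)}
    C = np.zeros((n, n))
    # postorder: at each internal node, tips in different child subtrees have
    # this node as their MRCA
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            node._sel = [pos[lbl]] if lbl in pos else []
            if lbl in pos:
                C[pos[lbl], pos[lbl]] = depths[node]
            continue
        children = node.child_nodes()
        merged: list[int] = []
        for ci, child in enumerate(children):
            for cj in range(ci):
                for i in children[cj]._sel:
                    for j in child._sel:
                        C[i, j] = C[j, i] = depths[node]
            merged.extend(child._sel)
        for child in children:
            del child._sel
        node._sel = merged
    del dtree.seed_node._sel
    if max_depth <= 0:
        raise ValueError("tree has zero depth")
    return PhyloCov(list(taxa), C / max_depth, max_depth)


def mcc_tree(trees: list[Phylogeny]) -> Phylogeny:
    """Maximum clade credibility member of a tree set.

    Scores each tree by the sum of log clade frequencies over its internal
    clades; ties resolve to the lowest input index. All trees must share an
    identical tip set.
    """
    if not trees:
        raise ValueError("mcc_tree requires at least one tree")
    tipset = frozenset(trees[0].tips)
    for i, t in enumerate(trees):
        if frozenset(t.tips) != tipset:
            raise ValueError(f"tree {i} has a different tip set")
    counts: dict[frozenset, int] = {}
    per_tree = []
    for t in trees:
        cl = t.clades()
        per_tree.append(cl)
        for c in cl:
            counts[c] = counts.get(c, 0) + 1
    ntree = len(trees)
    best_i, best_score = 0, -math.inf
    for i, cl in enumerate(per_tree):
        score = sum(math.log(counts[c] / ntree) for c in cl)
        if score > best_score + 1e-12:
            best_i, best_score = i, score
    return trees[best_i]


def graft(
    base: Phylogeny,
    addon: Phylogeny,
    shared_taxa: list[str],
    mode: str = "replace_clade",
) -> Phylogeny:
    """Replace the clade of ``shared_taxa`` in ``base`` with ``addon``.

    The addon (a calibrated subtree carrying fossil tips) is rescaled so the
    shared extant taxa keep their depths in ``base``; fossil tips then sit at
    shallower depths and the result is non-ultrametric. Depths of all base
    tips outside the replaced clade are untouched.
    """
    if mode != "replace_clade":
        raise ValueError(f"unknown graft mode: {mode!r}")
    shared = [normalize_label(t) for t in shared_taxa]
    base_tips, addon_tips = set(base.tips), set(addon.tips)
    missing = [t for t in shared if t not in base_tips or t not in addon_tips]
    if missing:
        raise KeyError(f"shared taxa absent from base or addon: {missing}")

    result = base.clone()
    dtree = result.dendropy_tree
    # MRCA = smallest-leafset node containing all shared taxa (postorder)
    shared_set = set(shared)
    mrca = None
    for node in dtree.postorder_node_iter():
        leafset = set(l.taxon.label for l in node.leaf_iter())
        if shared_set <= leafset:
            mrca = node
            break
    assert mrca is not None
    clade_tips = set(l.taxon.label for l in mrca.leaf_iter())
    if clade_tips != set(shared):
        if mrca.parent_node is None:
            raise ValueError("shared taxa straddle the base root")
        raise ValueError(
            f"shared taxa are not monophyletic in base; their clade also "
            f"contains {sorted(clade_tips - set(shared))}"
        )
    if mrca.parent_node is None:
        raise ValueError("shared taxa straddle the base root")

    base_depths = base.tip_depths()
    clade_height = max(base_depths[t] for t in shared) - _node_depths(dtree)[mrca]

    addon_depths = addon.tip_depths()
    shared_addon = [addon_depths[t] for t in shared]
    addon_height = max(shared_addon)
    if any(abs(d - addon_height) > 1e-6 * max(addon_height, 1.0) for d in shared_addon):
        raise ValueError("shared taxa have unequal depths in the addon tree")
    if addon_height <= 0 or clade_height < 0:
        raise ValueError("depth rescale factor is not positive")
    factor = clade_height / addon_height
    if factor <= 0:
        raise ValueError("depth rescale factor is not positive")

    new_sub = addon.clone().dendropy_tree
    for edge in new_sub.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor

    parent = mrca.parent_node
    stem = mrca.edge.length or 0.0
    parent.remove_child(mrca)
    # migrate addon taxa into the base namespace
    sub_root = new_sub.seed_node
    for leaf in sub_root.leaf_iter():
        lbl = leaf.taxon.label
        tax = dtree.taxon_namespace.get_taxon(lbl)
        if tax is None:
            tax = dtree.taxon_namespace.new_taxon(lbl)
        leaf.taxon = tax
    sub_root.edge.length = stem
    parent.add_child(sub_root)
    return Phylogeny(dtree)
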