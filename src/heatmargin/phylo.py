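"""Rooted-tree ingestion and phylogenetic covariance construction.

A :class:`Phylogeny` wraps a rooted dendropy tree with non-negative branch
lengths and unique tip labels.  The derived :class:`PhyloCovariance` holds
the shared root-to-tip path-length matrix with off-diagonals scaled by
Pagel's lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["Phylogeny", "PhyloCovariance", "read_newick", "phylo_covariance",
           "prune_and_match", "normalize_label", "NewickError"]


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


def normalize_label(label: str) -> str:
    """Canonical species label: stripped, spaces replaced by underscores."""
    return label.strip().replace(" ", "_")


@dataclass
class PhyloCovariance:
    """Lambda-scaled shared-path covariance among tips.

    ``matrix[i, j]`` is the root-to-MRCA path length of tips i and j,
    multiplied by ``lam`` off the diagonal; the diagonal holds raw
    root-to-tip depths.
    """

    labels: list[str]
    matrix: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.labels), len(self.labels)):
            raise ValueError("covariance shape does not match label count")

    def submatrix(self, names: list[str]) -> "PhyloCovariance":
        idx = [self.labels.index(n) for n in names]
        return PhyloCovariance(list(names), self.matrix[np.ix_(idx, idx)], self.lam)

    def correlation(self) -> "PhyloCovariance":
        """Scale to unit diagonal (correlation matrix of relatedness)."""
        d = np.sqrt(np.diag(self.matrix))
        if np.any(d <= 0):
            raise ValueError("zero root-to-tip depth: cannot form correlation")
        m = self.matrix / np.outer(d, d)
        return PhyloCovariance(list(self.labels), m, self.lam)


class Phylogeny:
    """Rooted tree with branch lengths; tip labels unique after normalization."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise NewickError("tree contains an unlabelled tip")
            labels.append(normalize_label(leaf.taxon.label))
            leaf.taxon.label = labels[-1]
        if len(set(labels)) != len(labels):
            dups = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickError(f"duplicated tip labels: {dups}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise NewickError(f"negative branch length {edge.length}")
        self._tips = labels

    @property
    def tips(self) -> list[str]:
        return list(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, missing_length: str = "error") -> "Phylogeny":
        """Parse a Newick string.

        ``missing_length`` is ``"error"`` (reject edges without a length)
        or ``"zero"`` (substitute 0.0 with a warning).
        """
        try:
            tree = dendropy.Tree.get(data=text, schema="newick",
                                     suppress_internal_node_taxa=True,
                                     preserve_underscores=True)
        except Exception as exc:  # dendropy raises several error types
            if "Duplicate taxon" in str(exc):
                raise NewickError(f"duplicated tip labels: {exc}") from exc
            raise NewickError(f"malformed Newick: {exc}") from exc
        missing = [e for e in tree.preorder_edge_iter()
                   if e.length is None and e.head_node is not tree.seed_node]
        if missing:
            if missing_length == "zero":
                import warnings
                warnings.warn(f"{len(missing)} edges without branch length set to 0")
                for e in missing:
                    e.length = 0.0
            else:
                raise NewickError(f"{len(missing)} edges lack a branch length")
        if tree.seed_node.edge.length is None:
            tree.seed_node.edge.length = 0.0
        return cls(tree)

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True,
                                 unquoted_underscores=True,
                                 suppress_internal_node_labels=True)
        return s.strip()

    # -- queries ------------------------------------------------------

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip."""
        depths = {}
        self._tree.seed_node._hm_depth = 0.0
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            node._hm_depth = node.parent_node._hm_depth + (node.edge.length or 0.0)
        for leaf in self._tree.leaf_node_iter():
            depths[leaf.taxon.label] = leaf._hm_depth
        return depths

    def distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Patristic distances between all tip pairs."""
        labels, shared = self._shared_path_matrix()
        depth = np.diag(shared)
        dist = depth[:, None] + depth[None, :] - 2.0 * shared
        np.fill_diagonal(dist, 0.0)
        return labels, dist

    def _shared_path_matrix(self) -> tuple[list[str], np.ndarray]:
        """Matrix of root-to-MRCA path lengths for every tip pair."""
        labels = self.tips
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        shared = np.zeros((n, n))
        self._tree.seed_node._hm_depth = 0.0
        for node in self._tree.preorder_node_iter():
            if node is not self._tree.seed_node:
                node._hm_depth = node.parent_node._hm_depth + (node.edge.length or 0.0)
        # postorder accumulation: tips under each child of a node share that
        # node's depth with tips under every other child
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = index[node.taxon.label]
                node._hm_tipset = [i]
                shared[i, i] = node._hm_depth
                continue
            children = [c._hm_tipset for c in node.child_nodes()]
            d = node._hm_depth
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    ia = np.asarray(children[a])
                    ib = np.asarray(children[b])
                    shared[np.ix_(ia, ib)] = d
                    shared[np.ix_(ib, ia)] = d
            node._hm_tipset = [i for c in children for i in c]
        return labels, shared

    # -- operations ---------------------------------------------------

    def covariance(self, lam: float = 1.0, normalize: bool = False) -> PhyloCovariance:
        """Shared-path covariance with off-diagonals scaled by ``lam``.

        With ``normalize=True`` the raw matrix is first scaled to unit
        diagonal (relatedness correlation) before lambda scaling.
        """
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
        labels, shared = self._shared_path_matrix()
        if normalize:
            d = np.sqrt(np.diag(shared))
            if np.any(d <= 0):
                raise ValueError("zero-depth tip: cannot normalize covariance")
            shared = shared / np.outer(d, d)
        off = shared * lam
        np.fill_diagonal(off, np.diag(shared))
        return PhyloCovariance(labels, off, lam)

    def prune(self, names: list[str], on_missing: str = "error") -> "Phylogeny":
        """Induced subtree on ``names``; pairwise path lengths preserved.

        ``on_missing``: ``"error"`` rejects names absent from the tree,
        ``"drop"`` silently ignores them.
        """
        wanted = [normalize_label(n) for n in names]
        have = set(self._tips)
        missing = [n for n in wanted if n not in have]
        if missing and on_missing != "drop":
            raise KeyError(f"species not in tree: {missing[:5]}"
                           f"{'...' if len(missing) > 5 else ''}")
        keep = [n for n in wanted if n in have]
        if not keep:
            raise ValueError("no requested species present in tree")
        if set(keep) == have:
            return Phylogeny(self._tree.clone(depth=1))
        orig_depths = self.tip_depths()
        sub = self._tree.extract_tree_with_taxa_labels(keep)
        sub.suppress_unifurcations()
        pruned = Phylogeny(sub)
        # extraction re-roots at the retained tips' MRCA; restore the shared
        # root stem so root-to-tip depths (hence covariances) are preserved
        ref = pruned.tips[0]
        deficit = orig_depths[ref] - pruned.tip_depths()[ref]
        if deficit > 1e-12:
            old_root = sub.seed_node
            new_root = dendropy.Node()
            new_root.add_child(old_root)
            old_root.edge.length = deficit
            sub.seed_node = new_root
            pruned = Phylogeny(sub)
        return pruned


# Functional aliases matching the operation-level API ------------------

def read_newick(text: str, missing_length: str = "error") -> Phylogeny:
    return Phylogeny.from_newick(text, missing_length=missing_length)


def phylo_covariance(tree: Phylogeny, lam: float = 1.0,
                     normalize: bool = False) -> PhyloCovariance:
    if tree.n_tips < 2:
        raise ValueError("need at least 2 tips for a covariance matrix")
    return tree.covariance(lam=lam, normalize=normalize)


def prune_and_match(tree: Phylogeny, names: list[str],
                    on_missing: str = "error") -> Phylogeny:
    return tree.prune(names, on_missing=on_missing)
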