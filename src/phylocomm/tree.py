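"""Phylogenies: newick I/O, cophenetic distances, and the Brownian-motion VCV.

A :class:`Phylogeny` wraps a rooted ``dendropy.Tree`` with branch lengths and
exposes the two matrix views every downstream statistic consumes:

* the cophenetic (patristic) distance matrix — total branch length on the
  path between two tips, and
* the phylogenetic variance–covariance matrix (VCV) — shared root-to-MRCA
  path length between two tips, the tip covariance implied by Brownian
  motion on the tree.

The newick dialect accepted here is deliberately strict: plain (unquoted)
labels, decimal branch lengths on every non-root edge, polytomies allowed.
Quoted labels and bracket comments are rejected loudly rather than
half-supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .distances import DistanceMatrix

__all__ = ["NewickParseError", "Phylogeny", "parse_newick"]


class NewickParseError(ValueError):
    """Raised for malformed newick input, naming the offending token."""


@dataclass
class Phylogeny:
    """A rooted tree with nonnegative branch lengths over uniquely labelled tips."""

    tree: dendropy.Tree
    tip_labels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        labels = []
        n_positive = 0
        for node in self.tree.preorder_node_iter():
            is_root = node.parent_node is None
            length = node.edge.length
            if length is None:
                if not is_root:
                    name = node.taxon.label if node.taxon else "<internal>"
                    raise NewickParseError(f"missing branch length on edge to {name!r}")
                node.edge.length = 0.0
                length = 0.0
            if length < 0:
                name = node.taxon.label if node.taxon else "<internal>"
                raise NewickParseError(f"negative branch length {length} on edge to {name!r}")
            if length > 0:
                n_positive += 1
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise NewickParseError("tip with empty label")
                labels.append(node.taxon.label)
        if len(set(labels)) != len(labels):
            dups = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickParseError(f"duplicate tip labels: {dups}")
        if n_positive == 0:
            raise NewickParseError("all branch lengths are zero")
        self.tip_labels = tuple(labels)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def to_newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
        )

    def _node_depths(self) -> dict:
        depths = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            base = 0.0 if parent is None else depths[parent]
            depths[node] = base + (node.edge.length or 0.0)
        return depths

    def cophenetic_distances(self) -> DistanceMatrix:
        """Patristic distance between every pair of tips (kind ``phylogenetic``)."""
        if self.n_tips < 2:
            raise ValueError("cophenetic distances need at least 2 tips")
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = self.tip_labels
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        return DistanceMatrix(labels=labels, values=d, kind="phylogenetic")

    def vcv(self) -> "PhyloVCV":
        """Brownian-motion variance–covariance matrix of the tips.

        ``V[i, j]`` is the depth (root-to-node path length) of the most recent
        common ancestor of tips *i* and *j*; the diagonal holds root-to-tip
        path lengths.
        """
        labels = self.tip_labels
        index = {lab: k for k, lab in enumerate(labels)}
        n = len(labels)
        depths = self._node_depths()
        V = np.zeros((n, n))
        # postorder: at each internal node, tips from distinct child subtrees
        # coalesce exactly there
        tipsets: dict = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                k = index[node.taxon.label]
                tipsets[node] = [k]
                V[k, k] = depths[node]
            else:
                children = node.child_nodes()
                groups = [tipsets.pop(c) for c in children]
                depth = depths[node]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        for i in groups[a]:
                            for j in groups[b]:
                                V[i, j] = V[j, i] = depth
                merged = [k for g in groups for k in g]
                tipsets[node] = merged
        return PhyloVCV(labels=labels, values=V)


@dataclass(frozen=True)
class PhyloVCV:
    """Tip covariance matrix under Brownian motion: shared root-to-MRCA path lengths."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1] or V.shape[0] != len(self.labels):
            raise ValueError("VCV must be square and match its labels")
        if not np.allclose(V, V.T):
            raise ValueError("VCV must be symmetric")
        diag = np.diag(V)
        if np.any(diag < 0):
            raise ValueError("VCV diagonal must be nonnegative")
        if np.any(V > np.minimum.outer(diag, diag) + 1e-9 * max(diag.max(), 1.0)):
            raise ValueError("shared path length cannot exceed either tip depth")
        object.__setattr__(self, "values", V)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels) -> "PhyloVCV":
        idx = [self.labels.index(l) for l in labels]
        return PhyloVCV(labels=tuple(labels), values=self.values[np.ix_(idx, idx)])


def parse_newick(text: str) -> Phylogeny:
    """Parse a strict-dialect newick string into a :class:`Phylogeny`.

    Raises :class:`NewickParseError` on unbalanced parentheses, a missing
    terminal ``;``, quoted labels or comments, duplicate tips, or negative
    branch lengths.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty newick string")
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("newick string must be terminated by ';'")
    if "'" in stripped or '"' in stripped:
        raise NewickParseError("quoted labels are not supported")
    if "[" in stripped or "]" in stripped:
        raise NewickParseError("newick comments are not supported")
    try:
        tree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"malformed newick: {exc}") from exc
    return Phylogeny(tree=tree)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(phy: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(phy.to_newick() + "\n")
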