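"""Phylogenies and the Brownian-motion covariance they imply.

A phylogenetic comparative analysis needs the expected trait covariance
between species under neutral drift: for Brownian motion on a rooted tree,
``cov(i, j)`` is the path length from the root to the most recent common
ancestor of tips ``i`` and ``j``, and ``var(i)`` is the root-to-tip depth of
``i``.  This module reads and prunes trees (via :mod:`dendropy`) and builds
that covariance matrix, optionally rescaled to unit diagonal so that the
phylogenetic variance component is expressed on the same scale as the other
variance components of the mixed model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._util import normalize_species_name

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "NewickParseError",
    "MissingSpeciesError",
    "read_newick",
    "write_newick",
    "prune_to_species",
    "bm_covariance",
]

logger = logging.getLogger(__name__)


class NewickParseError(ValueError):
    """The newick string violates the format or a tree invariant."""


class MissingSpeciesError(KeyError):
    """Species requested from a tree that does not contain them."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "species not found in tree: " + ", ".join(self.missing)
        )


@dataclass(frozen=True)
class Phylogeny:
    """A rooted tree with labeled tips and nonnegative branch lengths.

    Wraps a :class:`dendropy.Tree`; tip order is the order tips appear in the
    newick source and is the canonical ordering used by downstream matrices.
    """

    tree: dendropy.Tree
    tip_labels: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        labels = tuple(
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        )
        if not labels or any(not lbl for lbl in labels):
            raise NewickParseError("every tip must carry a nonempty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickParseError(f"duplicate tip labels: {', '.join(dupes)}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise NewickParseError(
                    f"negative branch length {edge.length} on edge to "
                    f"{_edge_label(edge)}"
                )
        object.__setattr__(self, "tip_labels", labels)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        out = {}
        for leaf in self.tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return out

    def label_index(self) -> dict[str, str]:
        """Map of normalized tip label -> original tip label."""
        return {normalize_species_name(l): l for l in self.tip_labels}


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian-motion covariance among the tips of a tree.

    ``matrix[i, j]`` is the shared root-to-MRCA path length of
    ``labels[i]`` and ``labels[j]``; when ``normalized`` the matrix has been
    rescaled elementwise by ``sqrt(depth_i * depth_j)`` so the diagonal is 1
    (a correlation matrix for equal-rate Brownian motion).
    """

    labels: tuple[str, ...]
    matrix: np.ndarray
    normalized: bool

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    def subset(self, labels) -> "PhyloCovariance":
        """Row/column restriction to ``labels``, preserving their order."""
        pos = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in pos]
        if missing:
            raise MissingSpeciesError(missing)
        idx = np.array([pos[l] for l in labels])
        return PhyloCovariance(
            labels=tuple(labels),
            matrix=self.matrix[np.ix_(idx, idx)],
            normalized=self.normalized,
        )

    def to_tsv(self, path) -> None:
        header = "\t".join(self.labels)
        np.savetxt(path, self.matrix, delimiter="\t", header=header, comments="")


def _edge_label(edge) -> str:
    node = edge.head_node
    if node is not None and node.taxon is not None:
        return node.taxon.label
    return "<internal node>"


def read_newick(text: str) -> Phylogeny:
    """Parse a single rooted newick tree.

    Internal node labels and bootstrap values are tolerated and ignored.
    Edges without branch lengths are assigned length 1 (logged as a warning).
    Duplicate tip labels, negative branch lengths and malformed syntax raise
    :class:`NewickParseError` naming the offending token.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise NewickParseError(f"duplicate tip labels: {e}") from e
    except Exception as e:  # dendropy raises several reader error classes
        raise NewickParseError(f"malformed newick: {e}") from e

    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            if edge.length is None:
                edge.length = 0.0
            continue
        if edge.length is None:
            edge.length = 1.0
            n_missing += 1
    if n_missing:
        logger.warning(
            "newick had %d edges without branch lengths; defaulted to 1",
            n_missing,
        )
    return Phylogeny(tree=tree)


def write_newick(phy: Phylogeny) -> str:
    """Serialize with branch lengths at full precision (round-trip safe)."""
    return phy.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    ).strip()


def prune_to_species(phy: Phylogeny, keep) -> Phylogeny:
    """Restrict a tree to the tip set ``keep``.

    Root-to-tip path lengths of retained tips are unchanged; unary internal
    nodes created by the pruning are collapsed with their branch lengths
    summed.  Raises :class:`MissingSpeciesError` listing any requested species
    absent from the tree (the caller decides whether to drop those species or
    abort).
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep must contain at least one species")
    present = set(phy.tip_labels)
    missing = keep - present
    if missing:
        raise MissingSpeciesError(missing)
    if keep == present:
        return phy
    sub = phy.tree.extract_tree_with_taxa_labels(labels=sorted(keep))
    return Phylogeny(tree=sub)


def bm_covariance(phy: Phylogeny, normalize: bool = True) -> PhyloCovariance:
    """Brownian-motion covariance matrix of the tips of ``phy``.

    With ``normalize`` (default), the matrix is divided elementwise by
    ``sqrt(depth_i * depth_j)``, giving unit diagonal; this requires every tip
    to have strictly positive depth.
    """
    labels = phy.tip_labels
    n = len(labels)
    pos = {l: i for i, l in enumerate(labels)}

    depth = {}
    root = phy.tree.seed_node
    depth[root] = root.edge.length or 0.0
    for node in phy.tree.preorder_node_iter():
        if node is root:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    cov = np.zeros((n, n))
    tipsets: dict = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            i = pos[node.taxon.label]
            tipsets[node] = [i]
            cov[i, i] = depth[node]
            continue
        groups = [tipsets.pop(c) for c in node.child_nodes()]
        d = depth[node]
        # tips in different child subtrees share exactly the root->node path
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                ii = np.asarray(groups[gi])
                jj = np.asarray(groups[gj])
                cov[np.ix_(ii, jj)] = d
                cov[np.ix_(jj, ii)] = d
        tipsets[node] = [i for g in groups for i in g]

    if normalize:
        diag = np.diag(cov)
        if np.any(diag <= 0):
            bad = [labels[i] for i in np.flatnonzero(diag <= 0)]
            raise ValueError(
                "cannot normalize: zero-depth tips " + ", ".join(bad)
            )
        scale = np.sqrt(diag)
        cov = cov / np.outer(scale, scale)
        np.fill_diagonal(cov, 1.0)

    return PhyloCovariance(labels=labels, matrix=cov, normalized=normalize)
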