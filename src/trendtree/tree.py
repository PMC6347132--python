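"""Rooted phylogenies with branch lengths, element ages, and clade bookkeeping.

A :class:`Phylogeny` stores a rooted (possibly non-ultrametric, possibly
multifurcating) tree as flat preorder arrays.  Every element (tip or internal
node) except the root indexes the branch directly above it; per-branch
quantities such as evolutionary rates are keyed on this index.  Ages are
measured from the root (root = 0, most recent tip = tree height), so extinct
tips have age < tree height.

Newick I/O is delegated to dendropy; this module only adds the array view and
validation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "CladeSelection",
    "TreeFormatError",
    "InvalidSelectionError",
    "read_newick",
    "write_newick",
    "read_trait_csv",
    "write_trait_csv",
    "validate_trait",
]


class TreeFormatError(ValueError):
    """Raised for malformed Newick input (missing lengths, duplicate labels)."""


class InvalidSelectionError(ValueError):
    """Raised when a clade selection is not a valid internal node / disjoint pair."""


class Phylogeny:
    """Array-backed rooted phylogeny.

    Parameters
    ----------
    parent : array of int
        Parent element index per element; -1 for the root.  Elements are in
        preorder (parents before children), root at index 0.
    edge_length : array of float
        Length of the branch above each element; ``nan`` for the root.
    labels : sequence of str
        Unique label per element.
    is_tip : array of bool
        True for leaves.
    """

    def __init__(self, parent, edge_length, labels, is_tip):
        self.parent = np.asarray(parent, dtype=np.intp)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.labels = list(labels)
        self.is_tip = np.asarray(is_tip, dtype=bool)
        n = self.parent.size
        if not (self.edge_length.size == len(self.labels) == self.is_tip.size == n):
            raise ValueError("inconsistent array lengths")
        if self.parent[0] != -1 or np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("elements must be in preorder with root first")
        if np.any(~np.isfinite(self.edge_length[1:])) or np.any(self.edge_length[1:] <= 0):
            raise TreeFormatError("all non-root branch lengths must be positive and finite")
        if len(set(self.labels)) != n:
            raise TreeFormatError("duplicate element labels")
        # ages by preorder accumulation: age(child) = age(parent) + branch length
        age = np.zeros(n)
        for i in range(1, n):
            age[i] = age[self.parent[i]] + self.edge_length[i]
        self.age = age
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    # ------------------------------------------------------------------ sizes
    @property
    def n_elements(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def n_nodes(self) -> int:
        """Number of internal nodes (root included)."""
        return self.n_elements - self.n_tips

    @property
    def n_branches(self) -> int:
        return self.n_elements - 1

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def node_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def tree_height(self) -> float:
        return float(self.age[self.is_tip].max())

    @property
    def tip_ages(self) -> pd.Series:
        return pd.Series(self.age[self.is_tip], index=self.tip_labels, name="age")

    def index_of(self, label: str) -> int:
        return self._index[label]

    def element_ages(self) -> pd.Series:
        """Root distance of every element, keyed by label (root maps to 0)."""
        return pd.Series(self.age, index=self.labels, name="age")

    # --------------------------------------------------------------- topology
    def children(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.parent == i)

    def subtree_mask(self, i: int) -> np.ndarray:
        """Boolean mask of elements in the subtree rooted at ``i`` (inclusive)."""
        mask = np.zeros(self.n_elements, dtype=bool)
        mask[i] = True
        for j in range(i + 1, self.n_elements):
            if mask[self.parent[j]]:
                mask[j] = True
        return mask

    def path_matrix(self) -> np.ndarray:
        """Design matrix of root-to-element paths, shape (elements, branches).

        Column ``j`` corresponds to the branch above element ``j + 1``; the
        entry is that branch's length if it lies on the root path of the row
        element, else 0.  Row sums therefore equal element ages.
        """
        n = self.n_elements
        A = np.zeros((n, n - 1))
        for i in range(1, n):
            A[i] = A[self.parent[i]]
            A[i, i - 1] = self.edge_length[i]
        return A

    def path_indicator(self) -> np.ndarray:
        """0/1 version of :meth:`path_matrix` (branch membership only)."""
        with np.errstate(invalid="ignore"):
            A = self.path_matrix()
        return (A > 0).astype(float)

    # ------------------------------------------------------------------ clade
    def clade(self, node: str | int) -> "CladeSelection":
        """Select the clade subtended by an internal node.

        The focal node itself belongs to the selection (its branch carries the
        rate "into" the clade).  Clade height is the span from the focal node
        to its deepest member tip; ``h_ratio`` is tree height over that span.
        """
        i = node if isinstance(node, (int, np.integer)) else self.index_of(node)
        if self.is_tip[i]:
            raise InvalidSelectionError(f"element {self.labels[i]!r} is a tip, not an internal node")
        mask = self.subtree_mask(i)
        tip_idx = np.flatnonzero(mask & self.is_tip)
        if tip_idx.size < 2:
            raise InvalidSelectionError("clade must contain at least two tips")
        clade_height = float(self.age[tip_idx].max() - self.age[i])
        if clade_height <= 0:
            raise InvalidSelectionError("clade has zero height")
        return CladeSelection(
            node=self.labels[i],
            node_index=int(i),
            element_indices=np.flatnonzero(mask),
            tip_indices=tip_idx,
            tip_labels=[self.labels[j] for j in tip_idx],
            clade_height=clade_height,
            h_ratio=self.tree_height / clade_height,
        )

    # --------------------------------------------------------------------- IO
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        root = tree.seed_node
        order = []
        stack = [root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(reversed(nd.child_nodes()))
        idx = {id(nd): k for k, nd in enumerate(order)}
        parent, length, labels, is_tip = [], [], [], []
        auto = 1
        seen = set()
        for k, nd in enumerate(order):
            leaf = nd.is_leaf()
            if leaf:
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeFormatError(f"unlabeled tip at preorder position {k}")
                lab = nd.taxon.label
            else:
                lab = nd.label or (nd.taxon.label if nd.taxon else None)
                if not lab:
                    lab = f"N{auto}"
                    auto += 1
            if lab in seen:
                raise TreeFormatError(f"duplicate label {lab!r}")
            seen.add(lab)
            if k == 0:
                parent.append(-1)
                length.append(np.nan)
            else:
                parent.append(idx[id(nd.parent_node)])
                if nd.edge.length is None:
                    raise TreeFormatError(f"missing branch length above {lab!r}")
                length.append(float(nd.edge.length))
            labels.append(lab)
            is_tip.append(leaf)
        return cls(parent, length, labels, is_tip)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = {}
        for i in range(self.n_elements):
            nd = tree.seed_node if i == 0 else dendropy.Node()
            if self.is_tip[i]:
                nd.taxon = taxa.new_taxon(label=self.labels[i])
            else:
                nd.label = self.labels[i]
            if i > 0:
                nodes[self.parent[i]].add_child(nd)
                nd.edge.length = float(self.edge_length[i])
            nodes[i] = nd
        return tree

    def to_newick(self) -> str:
        return (
            self.to_dendropy().as_string(
                schema="newick",
                suppress_rooting=True,
                suppress_internal_node_labels=False,
                unquoted_underscores=True,
            ).strip()
        )


@dataclass
class CladeSelection:
    """A focal internal node and the elements it subtends."""

    node: str
    node_index: int
    element_indices: np.ndarray
    tip_indices: np.ndarray
    tip_labels: list[str] = field(repr=False)
    clade_height: float = 0.0
    h_ratio: float = 1.0

    @property
    def n_tips(self) -> int:
        return int(self.tip_indices.size)

    def overlaps(self, other: "CladeSelection") -> bool:
        return bool(np.intersect1d(self.element_indices, other.element_indices).size)


# ---------------------------------------------------------------------- I/O


def read_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick string (branch lengths required) to a Phylogeny."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeFormatError(f"could not parse Newick: {exc}") from exc
    if tree.seed_node.num_child_nodes() == 0:
        raise TreeFormatError("empty tree")
    return Phylogeny.from_dendropy(tree)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


def validate_trait(tree: Phylogeny, y: pd.Series) -> pd.Series:
    """Check a tip-keyed trait against a tree and return it in tip order."""
    y = pd.Series(y, dtype=float)
    tips = tree.tip_labels
    missing = set(tips) - set(y.index)
    extra = set(y.index) - set(tips)
    if missing or extra:
        raise ValueError(
            f"trait keys do not match tree tips (missing: {sorted(missing)[:5]}, "
            f"extra: {sorted(extra)[:5]})"
        )
    y = y.reindex(tips)
    if not np.all(np.isfinite(y.to_numpy())):
        raise ValueError("trait values must be finite")
    return y


def read_trait_csv(path_or_buf) -> pd.Series:
    """Read a 'tip,value' CSV into a tip-keyed Series."""
    df = pd.read_csv(path_or_buf)
    if df.shape[1] < 2:
        raise ValueError("trait CSV must have columns 'tip,value'")
    return pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str), name="value")


def write_trait_csv(y: pd.Series, path_or_buf=None) -> str | None:
    df = pd.DataFrame({"tip": y.index, "value": y.to_numpy()})
    if path_or_buf is None:
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()
    df.to_csv(path_or_buf, index=False)
    return None
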