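"""Gene trees, patristic distances and the branch-length diversity statistic.

Trees are *consumed*, never inferred: each homologous group comes with a
maximum-likelihood gene tree in Newick format whose branch lengths are in
substitutions per site.  Two quantities are derived from each tree:

* the patristic distance matrix, ``d(i, j)`` = sum of branch lengths on the
  unique path between leaves *i* and *j* (sequence divergence, not time);
* the phylogenetic diversity ``D = sum_i l_i`` over all branches.

Both are invariant to the position of the root.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .core_io import DataFormatError

__all__ = ["GeneTree", "DistanceMatrix", "parse_newick", "read_newick_file",
           "read_trees_dir", "patristic_distances", "tree_diversity"]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative zero-diagonal matrix over labelled objects."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError(
                f"shape {self.values.shape} does not match {n} labels")
        if not np.isfinite(self.values).all():
            raise ValueError("distance matrix contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("distance matrix contains negative values")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        # enforce exact symmetry / zero diagonal after the tolerance check
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy condensed) order."""
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(lbl) for lbl in labels]
        if len(idx) != len(self.labels) or len(set(idx)) != len(idx):
            raise ValueError("reorder labels must be a permutation")
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(list(df.index), df.to_numpy())


class GeneTree:
    """A rooted branch-length-bearing tree over gene ids.

    Wraps a :class:`dendropy.Tree`; construction validates that leaf labels
    are unique and that every non-root edge carries a non-negative length
    (zero-length branches are allowed, as maximum-likelihood inference
    commonly produces them).
    """

    def __init__(self, tree: dendropy.Tree):
        leaves = [leaf for leaf in tree.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
        if any(lbl is None for lbl in labels):
            raise DataFormatError("tree has an unlabelled leaf")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise DataFormatError(f"duplicate leaf labels: {dup}")
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            if node.edge.length is None:
                name = (node.taxon.label if node.taxon
                        else f"internal node above {self._clade_label(node)}")
                raise DataFormatError(f"missing branch length on {name}")
            if node.edge.length < 0:
                raise DataFormatError(
                    f"negative branch length {node.edge.length}")
        self._tree = tree
        self._leaf_labels = labels

    @staticmethod
    def _clade_label(node) -> str:
        leaves = [lf.taxon.label for lf in node.leaf_iter() if lf.taxon]
        return "{" + ",".join(sorted(leaves)) + "}"

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return list(self._leaf_labels)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    def edges(self) -> list[tuple[object, object, float]]:
        """(parent, child, length) triples for all non-root edges."""
        out = []
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            out.append((node.parent_node, node, float(node.edge.length)))
        return out

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick",
                                    suppress_rooting=True).strip()


def parse_newick(text: str) -> GeneTree:
    """Parse a Newick string into a validated :class:`GeneTree`.

    Underscores in labels are preserved literally (gene ids frequently
    contain them).
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise DataFormatError(f"malformed Newick: {exc}") from None
    return GeneTree(tree)


def read_newick_file(path: str | Path) -> GeneTree:
    try:
        return parse_newick(Path(path).read_text())
    except DataFormatError as exc:
        raise DataFormatError(str(exc), path=path) from None


def read_trees_dir(path: str | Path, suffix: str = ".nwk"
                   ) -> dict[str, GeneTree]:
    """Read one tree per homologous group; file stem is the group id."""
    out = {}
    for p in sorted(Path(path).glob(f"*{suffix}")):
        out[p.stem] = read_newick_file(p)
    return out


def patristic_distances(tree: GeneTree) -> DistanceMatrix:
    """Pairwise path-length (patristic) distances between leaves."""
    if tree.n_leaves < 2:
        raise ValueError("patristic distances require at least 2 leaves")
    pdm = tree.tree.phylogenetic_distance_matrix()
    labels = tree.leaf_labels
    taxa = {lf.taxon.label: lf.taxon for lf in tree.tree.leaf_node_iter()}
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def tree_diversity(tree: GeneTree) -> float:
    """Phylogenetic diversity D = sum of all branch lengths."""
    return float(sum(length for _, _, length in tree.edges()))
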