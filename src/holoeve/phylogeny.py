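"""Rooted species trees and the patristic distances they supply.

The Ornstein-Uhlenbeck covariance used by the expression-evolution model only
needs tip-to-tip (patristic) distances, so :class:`Phylogeny` is a thin
validated wrapper around a :class:`dendropy.Tree` that caches the distance
matrix and enforces the invariants the downstream likelihoods rely on:
unique tip labels, at least two tips, and non-negative branch lengths on
every non-root edge.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

__all__ = ["Phylogeny", "TreeValidationError", "three_taxon_tree"]

#: Newick for the default three-species design: two sister species A and B
#: (patristic distance 2) and an outgroup C, all tips at distance 2 from
#: the root.
THREE_TAXON_NEWICK = "((A:1,B:1):1,C:2);"


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates the package's tree invariants."""


class Phylogeny:
    """A rooted, branch-length-bearing species tree.

    Parameters
    ----------
    tree:
        A ``dendropy.Tree``. Every edge except the root edge must carry a
        non-negative branch length, and tip labels must be unique.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._tips = tuple(
            leaf.taxon.label for leaf in tree.leaf_node_iter()
        )
        self._index = {t: i for i, t in enumerate(self._tips)}
        self._dist = self._patristic_matrix()

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        """Parse a newick string into a validated :class:`Phylogeny`."""
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", rooting="force-rooted"
            )
        except Exception as exc:  # dendropy raises several parser types
            raise TreeValidationError(f"malformed newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path, "r", encoding="utf-8", newline=None) as fh:
            text = fh.read()
        return cls.from_newick(text)

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        leaves = list(self._tree.leaf_node_iter())
        if len(leaves) < 2:
            raise TreeValidationError("tree must have at least 2 tips")
        labels = []
        for leaf in leaves:
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeValidationError("tree has an unlabeled tip")
            labels.append(leaf.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeValidationError(
                f"duplicate tip labels: {sorted(dupes)}"
            )
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            bl = node.edge.length
            if bl is None:
                name = node.taxon.label if node.taxon else "<internal>"
                raise TreeValidationError(
                    f"missing branch length on edge leading to {name!r}"
                )
            if bl < 0:
                name = node.taxon.label if node.taxon else "<internal>"
                raise TreeValidationError(
                    f"negative branch length ({bl}) on edge to {name!r}"
                )

    def _patristic_matrix(self) -> np.ndarray:
        pdm = self._tree.phylogenetic_distance_matrix()
        n = len(self._tips)
        dist = np.zeros((n, n))
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        for i, a in enumerate(self._tips):
            for j, b in enumerate(self._tips):
                if i < j:
                    d = pdm.patristic_distance(taxa[a], taxa[b])
                    dist[i, j] = dist[j, i] = d
        return dist

    # ------------------------------------------------------------------
    @property
    def tips(self) -> tuple[str, ...]:
        """Tip (species) labels in a fixed traversal order."""
        return self._tips

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def distance(self, a: str, b: str) -> float:
        """Patristic distance between two tips (0 for a tip with itself)."""
        return float(self._dist[self._index[a], self._index[b]])

    def distance_matrix(self, order: list[str] | None = None) -> np.ndarray:
        """Patristic distance matrix, optionally reordered to ``order``."""
        if order is None:
            return self._dist.copy()
        missing = [s for s in order if s not in self._index]
        if missing:
            raise TreeValidationError(
                f"species not on tree: {missing}; tips are {list(self._tips)}"
            )
        idx = [self._index[s] for s in order]
        return self._dist[np.ix_(idx, idx)]

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Phylogeny({len(self._tips)} tips: {', '.join(self._tips)})"


def three_taxon_tree() -> Phylogeny:
    """The preset ((A:1,B:1):1,C:2) design tree (all tips at depth 2)."""
    return Phylogeny.from_newick(THREE_TAXON_NEWICK)
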