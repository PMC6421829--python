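"""Rooted phylogenetic tree over zOTU tips, for Faith's PD and UniFrac.

A thin layer over :mod:`dendropy` that enforces the contracts the
phylogenetic statistics need — branch lengths on every non-root edge,
unique tip labels — and exposes the tree as an edge incidence structure
(edge lengths + which zOTU columns descend from each edge) so that PD and
UniFrac reduce to array operations.

Conventions: the Newick outermost node is taken as the root (bifurcating or
polytomous roots both accepted, never re-rooted); a length attached to the
root itself is ignored — only edges internal to the tip-spanning tree
contribute to PD/UniFrac; zero-length branches are legal and contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

__all__ = ["PhyloTree", "EdgeStructure"]


@dataclass
class EdgeStructure:
    """Edge lengths and edge->zOTU incidence for a fixed zOTU ordering.

    ``incidence[e, j]`` is True when zOTU ``j`` descends from edge ``e``.
    Tips present in the tree but absent from the ordering simply never set a
    bit, so pruning to the observed community happens implicitly.
    """

    lengths: np.ndarray  # (n_edges,)
    incidence: np.ndarray  # (n_edges, n_otus) bool

    @property
    def n_edges(self) -> int:
        return self.lengths.shape[0]


class PhyloTree:
    """Rooted tree with branch lengths; tips are zOTU identifiers."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._edge_cache: dict[tuple[str, ...], EdgeStructure] = {}

    # -- construction --------------------------------------------------
    @classmethod
    def from_newick(cls, source: str | Path) -> "PhyloTree":
        """Read from a Newick file path or a literal Newick string."""
        text = None
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("(")
        ):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parser errors
            raise ValueError(f"could not parse Newick input: {exc}") from exc
        tree.is_rooted = True
        return cls(tree)

    def _validate(self) -> None:
        labels = [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip label(s): {dups}")
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                where = (
                    node.taxon.label if node.taxon is not None else "an internal node"
                )
                raise ValueError(
                    f"missing branch length on the edge above {where}; "
                    "PD and UniFrac are undefined without branch lengths"
                )
            if node.edge.length < 0:
                raise ValueError("negative branch length")

    # -- queries -------------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_edges(self) -> int:
        root = self._tree.seed_node
        return sum(1 for n in self._tree.preorder_node_iter() if n is not root)

    @property
    def total_length(self) -> float:
        """Sum of all non-root branch lengths."""
        root = self._tree.seed_node
        return float(
            sum(n.edge.length for n in self._tree.preorder_node_iter() if n is not root)
        )

    def clade_tips(self, min_size: int, max_size: int) -> list[str] | None:
        """Tip labels of some internal clade with size in [min_size, max_size],
        preferring the smallest admissible clade (used by the synthetic
        generator to designate an RNA-enriched group)."""
        best: list[str] | None = None
        root = self._tree.seed_node
        for node in self._tree.preorder_internal_node_iter():
            if node is root:
                continue
            tips = [l.taxon.label for l in node.leaf_iter()]
            if min_size <= len(tips) <= max_size:
                if best is None or len(tips) < len(best):
                    best = tips
        return best

    # -- edge structure ------------------------------------------------
    def edge_structure(self, otu_ids: Sequence[str], strict: bool = True) -> EdgeStructure:
        """Edge lengths and incidence matrix over the given zOTU ordering.

        With ``strict`` (default) every requested zOTU must be a tip of the
        tree; the first missing one is named in the error.
        """
        key = tuple(otu_ids)
        cached = self._edge_cache.get(key)
        if cached is not None:
            return cached
        col = {label: j for j, label in enumerate(otu_ids)}
        tips = set(self.tip_labels)
        if strict:
            for label in otu_ids:
                if label not in tips:
                    raise KeyError(f"zOTU {label!r} is not a tip of the tree")
        root = self._tree.seed_node
        lengths: list[float] = []
        rows: list[np.ndarray] = []
        # postorder: each node's descendant-tip bitset is the union of its
        # children's; leaves set their own column bit.
        below: dict[int, np.ndarray] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                mask = np.zeros(len(otu_ids), dtype=bool)
                j = col.get(node.taxon.label)
                if j is not None:
                    mask[j] = True
            else:
                mask = np.zeros(len(otu_ids), dtype=bool)
                for child in node.child_nodes():
                    mask |= below[id(child)]
            below[id(node)] = mask
            if node is not root:
                lengths.append(float(node.edge.length))
                rows.append(mask)
        structure = EdgeStructure(
            lengths=np.asarray(lengths, dtype=float),
            incidence=np.asarray(rows, dtype=bool),
        )
        if len(self._edge_cache) > 8:  # bounded cache
            self._edge_cache.clear()
        self._edge_cache[key] = structure
        return structure

    def brownian_tip_values(
        self, rng: np.random.Generator, rate: float = 1.0
    ) -> dict[str, float]:
        """Simulate a Brownian trait along the tree; returns tip values.

        Each edge adds a Normal(0, rate * length) increment, so values are
        correlated in proportion to shared ancestry — the mechanism the
        synthetic generator uses to give environmental responses
        phylogenetic signal.
        """
        values: dict[int, float] = {id(self._tree.seed_node): 0.0}
        out: dict[str, float] = {}
        for node in self._tree.preorder_node_iter():
            if node is not self._tree.seed_node:
                parent = values[id(node.parent_node)]
                step = rng.normal(0.0, np.sqrt(rate * max(node.edge.length, 0.0)))
                values[id(node)] = parent + step
            if node.is_leaf():
                out[node.taxon.label] = values[id(node)]
        return out

    # -- output --------------------------------------------------------
    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".12g",
        ).strip() + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick(), encoding="utf-8")
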