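"""The four community dissimilarity measures, from first principles.

* weighted Bray-Curtis:    sum|x_i - y_i| / sum(x_i + y_i)
* unweighted Bray-Curtis:  the binary (Sorensen) form (A + B - 2J)/(A + B),
  A and B the species counts of the two samples, J the shared species
* weighted UniFrac:        normalized form, sum_b l_b |p_b - q_b| /
  sum_b l_b (p_b + q_b), with p_b, q_b the fractions of each sample's reads
  descending from branch b
* unweighted UniFrac:      sum_b l_b |1(p_b>0) - 1(q_b>0)| /
  sum_b l_b 1(p_b>0 or q_b>0)

UniFrac works on within-sample proportions, so multiplying one sample's
counts by a constant changes nothing; the unweighted variants depend only
on presence/absence, which is what makes them sensitive to the rare
community.  No rarefaction happens here — repeated rarefaction is the
caller's job.
"""

from __future__ import annotations

import numpy as np

from .tables import CountTable, DistanceMatrix
from .tree import PhyloTree

__all__ = ["MEASURES", "bray_curtis", "unifrac", "distance_matrix"]

MEASURES = ("bray_weighted", "bray_unweighted", "unifrac_weighted", "unifrac_unweighted")


def bray_curtis(x, y, weighted: bool = True) -> float:
    """Bray-Curtis dissimilarity between two count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors differ in length")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two empty samples")
    if weighted:
        return float(np.abs(x - y).sum() / (x + y).sum())
    px, py = x > 0, y > 0
    a, b = int(px.sum()), int(py.sum())
    j = int((px & py).sum())
    return float((a + b - 2 * j) / (a + b))


def _edge_proportions(counts: np.ndarray, tree: PhyloTree, otu_ids) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample branch proportions: row s, edge b -> fraction of sample s's
    reads descending from b.  Returns (proportions, edge lengths)."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("UniFrac undefined for an empty sample")
    tips = set(tree.tip_labels)
    present = counts.sum(axis=0) > 0
    missing = [o for o, p in zip(otu_ids, present) if p and o not in tips]
    if missing:
        raise KeyError(f"zOTU(s) with counts missing from the tree: {missing[:5]}")
    structure = tree.edge_structure(list(otu_ids), strict=False)
    prop = counts / totals[:, None]
    edge_prop = prop @ structure.incidence.T.astype(float)
    return edge_prop, structure.lengths


def unifrac(x, y, tree: PhyloTree, otu_ids=None, weighted: bool = True) -> float:
    """UniFrac dissimilarity between two samples on a rooted tree.

    Accepts pandas Series (index = zOTU ids) or arrays plus ``otu_ids``.
    """
    import pandas as pd

    if isinstance(x, pd.Series):
        otu_ids = list(x.index.astype(str))
        x, y = x.to_numpy(), np.asarray(y)
    if otu_ids is None:
        raise ValueError("otu_ids required with bare arrays")
    P, lengths = _edge_proportions(np.vstack([x, y]), tree, otu_ids)
    return _unifrac_from_props(P[0], P[1], lengths, weighted)


def _unifrac_from_props(p, q, lengths, weighted: bool) -> float:
    if weighted:
        denom = (lengths * (p + q)).sum()
        if denom == 0:
            raise ValueError("no shared tree mass between samples and tree")
        return float((lengths * np.abs(p - q)).sum() / denom)
    pp, qq = p > 0, q > 0
    denom = lengths[pp | qq].sum()
    if denom == 0:
        raise ValueError("no branches covered by either sample")
    return float(lengths[pp ^ qq].sum() / denom)


def distance_matrix(
    table: CountTable, measure: str, tree: PhyloTree | None = None
) -> DistanceMatrix:
    """All pairwise dissimilarities for one of the four measures."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    if measure.startswith("unifrac") and tree is None:
        raise ValueError(f"measure {measure!r} requires a phylogenetic tree")
    values = pairwise_dissimilarity(table.counts, measure, tree, table.otu_ids)
    return DistanceMatrix(list(table.sample_ids), values, measure)


def pairwise_dissimilarity(
    counts: np.ndarray, measure: str, tree: PhyloTree | None, otu_ids
) -> np.ndarray:
    """Vectorized pairwise dissimilarity on a raw count matrix."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    if measure.startswith("unifrac") and tree is None:
        raise ValueError(f"measure {measure!r} requires a phylogenetic tree")
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    D = np.zeros((n, n))
    if measure == "bray_weighted":
        for i in range(n):
            diff = np.abs(counts[i] - counts[i + 1:]).sum(axis=1)
            tot = (counts[i] + counts[i + 1:]).sum(axis=1)
            D[i, i + 1:] = diff / tot
    elif measure == "bray_unweighted":
        pres = counts > 0
        a = pres.sum(axis=1)
        J = pres.astype(float) @ pres.T.astype(float)
        with np.errstate(invalid="ignore"):
            full = (a[:, None] + a[None, :] - 2 * J) / (a[:, None] + a[None, :])
        iu = np.triu_indices(n, 1)
        D[iu] = full[iu]
    else:
        P, lengths = _edge_proportions(counts, tree, otu_ids)
        if measure == "unifrac_weighted":
            for i in range(n):
                num = (lengths * np.abs(P[i] - P[i + 1:])).sum(axis=1)
                den = (lengths * (P[i] + P[i + 1:])).sum(axis=1)
                D[i, i + 1:] = num / den
        else:
            pres = P > 0
            for i in range(n):
                num = ((pres[i] ^ pres[i + 1:]) * lengths).sum(axis=1)
                den = ((pres[i] | pres[i + 1:]) * lengths).sum(axis=1)
                D[i, i + 1:] = num / den
    return D + D.T
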