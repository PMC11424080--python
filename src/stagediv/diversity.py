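"""Diversity of temporal expression patterns vs phylogenetic diversity.

Each homologous group contributes one point: its phylogenetic diversity
(sum of gene-tree branch lengths) and its expression-pattern diversity,
obtained by Ward hierarchical clustering of the members' standardized
stage profiles and summing the branch lengths of the resulting dendrogram
(leaves at height 0, each edge spanning the height difference between a
cluster and its parent merge).

Across groups the relationship is summarized by a Spearman rank
correlation, a linear-vs-quadratic least-squares comparison (residual sums
of squares; the quadratic is nested so SSE_quad <= SSE_lin always), and a
within-group-size stratification that separates the effect of gene
addition from phylogenetic diversification.

Ward linkage here is the squared-Euclidean-consistent variant (Lance-
Williams update on d^2, merge heights reported on the distance scale,
i.e. the `ward.D2` convention); the classic variant that applies the same
update to unsquared dissimilarities is available as ``variant="d"``.
Agglomeration is O(n^3) with deterministic tie-breaking by smallest leaf
index, which is ample for gene-family-sized inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .homology import HomologousGroupSet
from .phylo import GeneTree, tree_diversity
from .preprocess import StageProfileMatrix

__all__ = ["Dendrogram", "DiversityPair", "SpearmanResult", "ward_dendrogram",
           "dendrogram_diversity", "diversity_correlation",
           "compare_linear_quadratic", "stratify_by_size",
           "group_diversity_analysis"]


@dataclass
class Dendrogram:
    """Agglomeration result in scipy linkage convention.

    ``merges`` has one row per merge: (cluster_a, cluster_b, height, size)
    where leaves are clusters 0..n-1 and merge *m* creates cluster n+m.
    Heights are non-decreasing (Ward linkage is monotone).
    """

    labels: list[str]
    merges: np.ndarray

    def __post_init__(self):
        self.labels = list(self.labels)
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.labels)
        if self.merges.shape != (n - 1, 4):
            raise ValueError(
                f"expected {n - 1} merges of 4 fields, got {self.merges.shape}")
        h = self.merges[:, 2]
        if (h < -1e-12).any():
            raise ValueError("negative merge height")
        if (np.diff(h) < -1e-9).any():
            raise ValueError("merge heights are not non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible linkage matrix (e.g. for plotting)."""
        return self.merges.copy()


@dataclass
class DiversityPair:
    group_id: str
    group_size: int
    phylo_diversity: float
    expr_diversity: float

    def __post_init__(self):
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")
        for v in (self.phylo_diversity, self.expr_diversity):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"diversity must be finite and >= 0, got {v}")


@dataclass
class SpearmanResult:
    n: int
    rho: float | None
    p: float | None
    skipped_reason: str | None = None


def ward_dendrogram(profiles: StageProfileMatrix | np.ndarray,
                    gene_ids: Sequence[str] | None = None,
                    variant: str = "d2") -> Dendrogram:
    """Agglomerative Ward clustering of standardized stage profiles.

    ``variant="d2"`` (default) runs the Lance-Williams recurrence on
    squared Euclidean distances and reports heights on the distance scale;
    ``variant="d"`` runs the same recurrence on unsquared distances.
    Ties are broken by the smallest leaf index contained in a cluster.
    """
    if isinstance(profiles, StageProfileMatrix):
        if not profiles.standardized:
            raise ValueError("profiles must be standardized")
        genes = list(gene_ids) if gene_ids is not None else profiles.gene_ids
        x = profiles.rows(genes).to_numpy()
        labels = genes
    else:
        x = np.asarray(profiles, dtype=float)
        labels = (list(gene_ids) if gene_ids is not None
                  else [str(i) for i in range(len(x))])
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 genes to cluster")
    if variant not in ("d2", "d"):
        raise ValueError(f"unknown Ward variant {variant!r}")

    d = squareform(pdist(x, metric="euclidean"))
    work = d ** 2 if variant == "d2" else d.copy()
    np.fill_diagonal(work, np.inf)

    # active cluster bookkeeping: scipy-style ids, sizes, smallest leaf index
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    rep = {i: i for i in range(n)}  # smallest contained leaf index
    index_of = {cid: k for k, cid in enumerate(ids)}  # row in `work`
    active = ids.copy()
    merges = []
    next_id = n
    for step in range(n - 1):
        # find minimal pair, ties broken by (rep_i, rep_j) with rep_i < rep_j
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                ci, cj = active[ai], active[aj]
                val = work[index_of[ci], index_of[cj]]
                lo, hi = sorted((rep[ci], rep[cj]))
                key = (val, lo, hi)
                if best is None or key < best[0]:
                    best = (key, ci, cj)
        (_val, _lo, _hi), ci, cj = best
        dij = work[index_of[ci], index_of[cj]]
        height = float(np.sqrt(max(dij, 0.0))) if variant == "d2" else float(dij)
        a, b = sorted((ci, cj))
        merges.append((a, b, height, sizes[ci] + sizes[cj]))

        # Lance-Williams Ward update into ci's slot
        ni, nj = sizes[ci], sizes[cj]
        ii, jj = index_of[ci], index_of[cj]
        for ck in active:
            if ck in (ci, cj):
                continue
            kk = index_of[ck]
            nk = sizes[ck]
            new = ((ni + nk) * work[kk, ii] + (nj + nk) * work[kk, jj]
                   - nk * dij) / (ni + nj + nk)
            work[kk, ii] = work[ii, kk] = new
        work[jj, :] = work[:, jj] = np.inf
        sizes[next_id] = ni + nj
        rep[next_id] = min(rep[ci], rep[cj])
        index_of[next_id] = ii
        active.remove(ci)
        active.remove(cj)
        active.append(next_id)
        next_id += 1

    m = np.asarray(merges, dtype=float)
    # Ward is monotone; clip any tiny numerical inversions
    m[:, 2] = np.maximum.accumulate(np.maximum(m[:, 2], 0.0))
    return Dendrogram(labels, m)


def dendrogram_diversity(dend: Dendrogram) -> float:
    """Total branch length of a dendrogram, leaves at height 0.

    Each cluster contributes an edge of length (parent merge height - its
    own height); summing over all edges gives the expression-pattern
    analogue of phylogenetic diversity.
    """
    n = dend.n_leaves
    height = {i: 0.0 for i in range(n)}
    total = 0.0
    for m, (a, b, h, _size) in enumerate(dend.merges):
        total += (h - height[int(a)]) + (h - height[int(b)])
        height[n + m] = h
    return float(total)


def diversity_correlation(x: Sequence[float], y: Sequence[float]
                          ) -> SpearmanResult:
    """Spearman rank correlation (mid-ranks for ties, t-approximation p)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(x.size, None, None, "zero_rank_variance")
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(x.size, float(rho), float(p))


def compare_linear_quadratic(x: Sequence[float], y: Sequence[float]
                             ) -> tuple[float, float]:
    """Residual sums of squares of OLS fits y ~ x and y ~ x + x^2."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct x values")

    def sse(design: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return float(resid @ resid)

    ones = np.ones_like(x)
    sse_lin = sse(np.column_stack([ones, x]))
    sse_quad = sse(np.column_stack([ones, x, x ** 2]))
    return sse_lin, min(sse_quad, sse_lin)


def stratify_by_size(pairs: Sequence[DiversityPair],
                     min_groups_per_size: int = 5) -> pd.DataFrame:
    """Per-group-size Spearman correlations of phylo vs expression diversity.

    Only sizes represented by at least ``min_groups_per_size`` groups are
    reported (columns: size, n, rho, p).
    """
    if min_groups_per_size < 3:
        raise ValueError("min_groups_per_size must be >= 3")
    by_size: dict[int, list[DiversityPair]] = {}
    for p in pairs:
        by_size.setdefault(p.group_size, []).append(p)
    rows = []
    for size in sorted(by_size):
        members = by_size[size]
        if len(members) < min_groups_per_size:
            continue
        res = diversity_correlation([m.phylo_diversity for m in members],
                                    [m.expr_diversity for m in members])
        rows.append((size, res.n, res.rho, res.p))
    return pd.DataFrame(rows, columns=["size", "n", "rho", "p"])


def group_diversity_analysis(groupset: HomologousGroupSet,
                             profiles: StageProfileMatrix,
                             trees: Mapping[str, GeneTree],
                             variant: str = "d2",
                             ) -> tuple[list[DiversityPair], pd.DataFrame]:
    """Phylogenetic and expression diversity for every usable group.

    Groups reduced below 2 usable genes by zero-variance profile drops are
    skipped; the second return value lists them with reasons.
    """
    available = set(profiles.gene_ids)
    pairs: list[DiversityPair] = []
    skipped = []
    for gid, members in zip(groupset.group_ids(), groupset.groups):
        if gid not in trees:
            raise KeyError(f"no tree for group {gid}")
        usable = [m for m in members if m in available]
        if len(usable) < 2:
            skipped.append((gid, len(members), "too_few_usable_genes"))
            continue
        dend = ward_dendrogram(profiles, usable, variant=variant)
        pairs.append(DiversityPair(
            group_id=gid, group_size=len(members),
            phylo_diversity=tree_diversity(trees[gid]),
            expr_diversity=dendrogram_diversity(dend)))
    skipped_df = pd.DataFrame(skipped,
                              columns=["group_id", "size", "reason"])
    return pairs, skipped_df
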