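"""Phylogenetic vs expression-pattern divergence within homologous groups.

For each homologous group the patristic distance matrix of its gene tree
is correlated, via a Mantel permutation test, with the matrix of Euclidean
distances between the genes' standardized stage profiles.  Across groups,
the distribution of Mantel coefficients is then tested for a positive
shift from zero with a one-sample t-test, and the fraction of groups with
r > 0 is reported.

The Mantel statistic is the Pearson correlation over the n(n-1)/2 distinct
pairs; significance comes from jointly permuting rows and columns of one
matrix, p = (#{r_perm >= r_obs} + 1) / (n_permutations + 1) for the
default one-sided "greater" alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .homology import HomologousGroupSet
from .phylo import DistanceMatrix, GeneTree, patristic_distances
from .preprocess import StageProfileMatrix

__all__ = ["MantelResult", "ShiftTestResult", "expression_distance_matrix",
           "mantel_test", "coefficient_shift_test", "positive_fraction",
           "group_mantel_analysis"]


@dataclass
class MantelResult:
    group_id: str | None
    n_members: int
    r: float | None
    p: float | None
    n_permutations: int
    skipped_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skipped_reason is not None


@dataclass
class ShiftTestResult:
    n: int
    mean_r: float
    t_statistic: float
    p: float
    alternative: str


def expression_distance_matrix(profiles: StageProfileMatrix,
                               gene_ids: Sequence[str] | None = None
                               ) -> DistanceMatrix:
    """Pairwise Euclidean distances between standardized stage profiles."""
    if not profiles.standardized:
        raise ValueError("profiles must be standardized")
    genes = list(gene_ids) if gene_ids is not None else profiles.gene_ids
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    x = profiles.rows(genes).to_numpy()
    from scipy.spatial.distance import pdist, squareform
    return DistanceMatrix(genes, squareform(pdist(x, metric="euclidean")))


def _pearson_condensed(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def mantel_test(d_phylo: DistanceMatrix, d_expr: DistanceMatrix,
                n_permutations: int = 999, seed=None,
                alternative: str = "greater",
                group_id: str | None = None) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    Both matrices must carry the same labels in the same order.  Groups
    too small for a meaningful test (n < 3) or with a zero-variance
    triangle are skipped with a reason rather than raising.
    """
    if d_phylo.labels != d_expr.labels:
        raise ValueError("distance matrices have mismatched labels")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = len(d_phylo)
    if n < 3:
        return MantelResult(group_id, n, None, None, n_permutations,
                            skipped_reason="too_small")
    x = d_phylo.condensed()
    y = d_expr.condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return MantelResult(group_id, n, None, None, n_permutations,
                            skipped_reason="zero_variance")
    r_obs = _pearson_condensed(x, y)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    ymat = d_expr.values
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_perm = _pearson_condensed(x, ymat[np.ix_(perm, perm)][iu])
        if alternative == "greater":
            count += r_perm >= r_obs
        elif alternative == "less":
            count += r_perm <= r_obs
        else:
            count += abs(r_perm) >= abs(r_obs)
    p = (count + 1) / (n_permutations + 1)
    return MantelResult(group_id, n, r_obs, p, n_permutations)


def coefficient_shift_test(rs: Sequence[float],
                           alternative: str = "greater") -> ShiftTestResult:
    """One-sample t-test of the mean Mantel coefficient against zero."""
    rs = np.asarray(list(rs), dtype=float)
    if rs.size < 2:
        raise ValueError("need at least 2 coefficients")
    if not np.isfinite(rs).all():
        raise ValueError("non-finite coefficients")
    if rs.std(ddof=1) == 0:
        raise ValueError("degenerate: zero variance among coefficients")
    res = stats.ttest_1samp(rs, popmean=0.0, alternative=alternative)
    return ShiftTestResult(n=rs.size, mean_r=float(rs.mean()),
                           t_statistic=float(res.statistic),
                           p=float(res.pvalue), alternative=alternative)


def positive_fraction(rs: Sequence[float]) -> float:
    """Fraction of coefficients strictly greater than zero."""
    rs = np.asarray(list(rs), dtype=float)
    if rs.size == 0:
        raise ValueError("empty coefficient list")
    return float((rs > 0).sum() / rs.size)


def group_mantel_analysis(groupset: HomologousGroupSet,
                          profiles: StageProfileMatrix,
                          trees: Mapping[str, GeneTree],
                          n_permutations: int = 999, seed: int = 0,
                          alternative: str = "greater",
                          min_group_size: int = 3,
                          ) -> tuple[pd.DataFrame, dict]:
    """Run the Mantel test in every homologous group and summarize.

    Parameters
    ----------
    groupset:
        The homologous groups; ``trees`` must contain one tree per group
        keyed by the ids from :meth:`HomologousGroupSet.group_ids`.
    profiles:
        Standardized stage profiles; genes dropped there (zero variance)
        are excluded from their group's test, and groups left with fewer
        than ``min_group_size`` usable genes are skipped.
    seed:
        Parent seed; each group receives an independent child stream so
        results do not depend on group iteration order.

    Returns
    -------
    (per_group, summary):
        ``per_group`` has one row per group (group_id, n, r, p,
        skipped_reason); ``summary`` carries the shift t-test and positive
        fractions computed both over tested groups and over all groups.
    """
    available = set(profiles.gene_ids)
    results: list[MantelResult] = []
    children = np.random.SeedSequence(seed).spawn(len(groupset.groups))
    for gid, members, child in zip(groupset.group_ids(), groupset.groups,
                                   children):
        if gid not in trees:
            raise KeyError(f"no tree for group {gid}")
        usable = [m for m in members if m in available]
        if len(usable) < max(min_group_size, 3):
            results.append(MantelResult(gid, len(usable), None, None,
                                        n_permutations, "too_small"))
            continue
        d_phy = patristic_distances(trees[gid]).reorder(usable)
        d_exp = expression_distance_matrix(profiles, usable)
        res = mantel_test(d_phy, d_exp, n_permutations=n_permutations,
                          seed=child, alternative=alternative, group_id=gid)
        results.append(res)
    per_group = pd.DataFrame(
        [(r.group_id, r.n_members, r.r, r.p, r.skipped_reason or "")
         for r in results],
        columns=["group_id", "n", "r", "p", "skipped_reason"])
    rs = [r.r for r in results if not r.skipped]
    summary: dict = {"n_groups": len(results), "n_tested": len(rs)}
    if len(rs) >= 2:
        shift = coefficient_shift_test(rs, alternative=alternative)
        summary.update(mean_r=shift.mean_r, t_statistic=shift.t_statistic,
                       p=shift.p, alternative=shift.alternative,
                       positive_fraction=positive_fraction(rs),
                       positive_fraction_all=(
                           sum(r > 0 for r in rs) / len(results)))
        summary["shift_test"] = shift
    return per_group, summary
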