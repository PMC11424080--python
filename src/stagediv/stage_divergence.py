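"""Whole-transcriptome divergence between life stages.

Samples are compared by Manhattan distance on raw TPM (high-dimensional
data where the magnitude of transcriptional change matters).  Divergence
by developmental stage and host plant is assessed with PERMANOVA:

* one-factor: the direct sum-of-squares partition
  ``SS_total = (1/n) sum_{i<j} d_ij^2``,
  ``SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2``, pseudo-F =
  ``(SS_between/(k-1)) / (SS_within/(n-k))``, with significance from
  free permutation of sample labels;
* two-factor: sequential (type-I) sums of squares via the Gower-centered
  inner-product matrix and hat-matrix projections, permuting raw sample
  identities.

Pairwise stage contrasts run a one-factor PERMANOVA per stage pair and
additionally report the Manhattan distance between the two per-stage mean
(centroid) TPM vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import ExpressionMatrix
from .phylo import DistanceMatrix

__all__ = ["PermanovaResult", "PermanovaTable", "PairwiseStageResult",
           "manhattan_distances", "permanova_one_factor",
           "permanova_two_factor", "pairwise_stage_tests",
           "adjacent_and_adult_pairs"]


@dataclass
class PermanovaResult:
    term: str
    df: int
    ss: float
    pseudo_f: float | None
    r2: float | None
    p: float | None
    n_permutations: int | None


@dataclass
class PermanovaTable:
    rows: list[PermanovaResult]

    def term(self, name: str) -> PermanovaResult:
        for row in self.rows:
            if row.term == name:
                return row
        raise KeyError(name)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.term, r.df, r.ss, r.pseudo_f, r.r2, r.p) for r in self.rows],
            columns=["term", "df", "SS", "pseudo_F", "R2", "p"])


@dataclass
class PairwiseStageResult:
    stage_a: str
    stage_b: str
    n_a: int
    n_b: int
    centroid_distance: float
    between_group_ss: float
    pseudo_f: float | None
    p: float | None


def manhattan_distances(matrix: ExpressionMatrix) -> DistanceMatrix:
    """Manhattan (L1) distances between samples over all genes."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(matrix.values.to_numpy().T, metric="cityblock"))
    return DistanceMatrix(matrix.sample_ids, d)


def _group_indices(labels: Sequence[str]) -> dict[str, np.ndarray]:
    labels = np.asarray(labels)
    return {lvl: np.flatnonzero(labels == lvl)
            for lvl in pd.unique(labels)}


def _ss_decomposition(d2: np.ndarray, groups: dict[str, np.ndarray]
                      ) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for idx in groups.values():
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2 * len(idx))
    return ss_total, ss_within


def permanova_one_factor(dist: DistanceMatrix, labels: Sequence[str],
                         n_permutations: int = 999, seed=None
                         ) -> PermanovaTable:
    """One-factor PERMANOVA on a distance matrix.

    Returns a table with rows for the factor, the residual and the total.
    If some group has zero within-group dispersion overall (SS_within = 0)
    the pseudo-F is reported as +inf and the permutation p-value is still
    valid.  p = (#{F_perm >= F_obs} + 1) / (n_permutations + 1).
    """
    labels = list(labels)
    n = len(dist)
    if len(labels) != n:
        raise ValueError("labels length does not match distance matrix")
    groups = _group_indices(labels)
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(idx) < 1 for idx in groups.values()):
        raise ValueError("every group needs at least 1 sample")
    if n <= k:
        raise ValueError("need more samples than groups")
    d2 = dist.values ** 2
    ss_total, ss_within = _ss_decomposition(d2, groups)
    ss_between = ss_total - ss_within
    df_b, df_w = k - 1, n - k

    def f_stat(ss_w: float) -> float:
        if ss_w <= 0:
            return np.inf
        return ((ss_total - ss_w) / df_b) / (ss_w / df_w)

    f_obs = f_stat(ss_within)
    rng = np.random.default_rng(seed)
    lbl_arr = np.asarray(labels)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        _, ss_w = _ss_decomposition(d2, _group_indices(lbl_arr[perm]))
        count += f_stat(ss_w) >= f_obs
    p = (count + 1) / (n_permutations + 1)
    r2 = ss_between / ss_total if ss_total > 0 else None
    rows = [
        PermanovaResult("factor", df_b, ss_between, f_obs, r2, p,
                        n_permutations),
        PermanovaResult("Residual", df_w, ss_within, None,
                        (ss_within / ss_total) if ss_total > 0 else None,
                        None, None),
        PermanovaResult("Total", n - 1, ss_total, None, 1.0, None, None),
    ]
    return PermanovaTable(rows)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _hat(design: np.ndarray) -> np.ndarray:
    return design @ np.linalg.pinv(design)


def _dummies(labels: Sequence[str]) -> np.ndarray:
    return pd.get_dummies(pd.Series(list(labels)), dtype=float).to_numpy()


def permanova_two_factor(dist: DistanceMatrix, factor_a: Sequence[str],
                         factor_b: Sequence[str],
                         names: tuple[str, str] = ("A", "B"),
                         n_permutations: int = 999, seed=None
                         ) -> PermanovaTable:
    """Two-factor additive PERMANOVA with sequential (type-I) SS.

    Terms are fitted in the order given: SS(A), then SS(B adjusted for A),
    via traces of hat-matrix projections of the Gower-centered matrix.
    Significance permutes raw sample identities; each term's pseudo-F uses
    the residual mean square of the full additive model.
    """
    fa = list(factor_a)
    fb = list(factor_b)
    n = len(dist)
    if len(fa) != n or len(fb) != n:
        raise ValueError("factor length does not match distance matrix")
    ka = len(set(fa))
    kb = len(set(fb))
    if ka < 2:
        raise ValueError(f"factor {names[0]!r} is constant")
    if kb < 2:
        raise ValueError(f"factor {names[1]!r} is constant")
    df_a, df_b = ka - 1, kb - 1
    df_resid = n - 1 - df_a - df_b
    if df_resid <= 0:
        raise ValueError("not enough samples for the additive model")

    g = _gower_center(dist.values ** 2)
    ones = np.ones((n, 1))
    xa = np.hstack([ones, _dummies(fa)])
    xab = np.hstack([ones, _dummies(fa), _dummies(fb)])
    h_a = _hat(xa)
    h_ab = _hat(xab)

    def seq_ss(gmat: np.ndarray) -> tuple[float, float, float]:
        ss_a = float(np.trace(h_a @ gmat))
        ss_model = float(np.trace(h_ab @ gmat))
        ss_total = float(np.trace(gmat))
        return ss_a, ss_model - ss_a, ss_total - ss_model

    ss_a, ss_b, ss_resid = seq_ss(g)
    ss_total = float(np.trace(g))
    ms_resid = ss_resid / df_resid
    f_a = (ss_a / df_a) / ms_resid if ms_resid > 0 else np.inf
    f_b = (ss_b / df_b) / ms_resid if ms_resid > 0 else np.inf

    rng = np.random.default_rng(seed)
    count_a = count_b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        pa, pb, presid = seq_ss(gp)
        pms = presid / df_resid
        pf_a = (pa / df_a) / pms if pms > 0 else np.inf
        pf_b = (pb / df_b) / pms if pms > 0 else np.inf
        count_a += pf_a >= f_a
        count_b += pf_b >= f_b
    p_a = (count_a + 1) / (n_permutations + 1)
    p_b = (count_b + 1) / (n_permutations + 1)

    rows = [
        PermanovaResult(names[0], df_a, ss_a, f_a, ss_a / ss_total, p_a,
                        n_permutations),
        PermanovaResult(names[1], df_b, ss_b, f_b, ss_b / ss_total, p_b,
                        n_permutations),
        PermanovaResult("Residual", df_resid, ss_resid, None,
                        ss_resid / ss_total, None, None),
        PermanovaResult("Total", n - 1, ss_total, None, 1.0, None, None),
    ]
    return PermanovaTable(rows)


def adjacent_and_adult_pairs(stage_order: Sequence[str],
                             n_larval: int = 2) -> list[tuple[str, str]]:
    """Adjacent-stage pairs plus each larval stage against the final stage."""
    stages = list(stage_order)
    pairs = list(zip(stages[:-1], stages[1:]))
    adult = stages[-1]
    for larval in stages[:n_larval]:
        if (larval, adult) not in pairs:
            pairs.append((larval, adult))
    return pairs


def pairwise_stage_tests(matrix: ExpressionMatrix,
                         pairs: Sequence[tuple[str, str]] | None = None,
                         n_permutations: int = 999, seed: int = 0
                         ) -> list[PairwiseStageResult]:
    """One-factor PERMANOVA and centroid L1 distance per stage pair.

    ``centroid_distance`` is the Manhattan distance between the two
    per-stage mean TPM vectors.  Each pair gets an independent seeded
    stream so results do not depend on pair order.
    """
    if pairs is None:
        pairs = adjacent_and_adult_pairs(matrix.stage_order)
    known = set(matrix.stage_order)
    for a, b in pairs:
        for s in (a, b):
            if s not in known:
                raise ValueError(f"unknown stage label {s!r}")
    results = []
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    for (a, b), child in zip(pairs, children):
        ids_a = matrix.samples_for_stage(a)
        ids_b = matrix.samples_for_stage(b)
        sub = matrix.subset_samples(ids_a + ids_b)
        dist = manhattan_distances(sub)
        table = permanova_one_factor(dist, list(sub.stages),
                                     n_permutations=n_permutations,
                                     seed=child)
        mean_a = matrix.values[ids_a].mean(axis=1).to_numpy()
        mean_b = matrix.values[ids_b].mean(axis=1).to_numpy()
        factor = table.term("factor")
        results.append(PairwiseStageResult(
            stage_a=a, stage_b=b, n_a=len(ids_a), n_b=len(ids_b),
            centroid_distance=float(np.abs(mean_a - mean_b).sum()),
            between_group_ss=factor.ss, pseudo_f=factor.pseudo_f,
            p=factor.p))
    return results


def pairwise_results_frame(results: Sequence[PairwiseStageResult]
                           ) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.stage_a, r.stage_b, r.n_a, r.n_b, r.centroid_distance,
          r.between_group_ss, r.pseudo_f, r.p) for r in results],
        columns=["stage_a", "stage_b", "n_a", "n_b",
                 "centroid_L1_distance", "between_group_SS", "pseudo_F", "p"])
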