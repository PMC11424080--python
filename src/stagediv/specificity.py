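"""Stage-specificity (tau) and its comparison between duplicates and singletons.

The specificity index tau summarizes how concentrated a gene's expression
is in one developmental stage:

    tau = sum_i (1 - x_i) / (N - 1),   x_i = v_i / max(v)

where N is the number of stages.  tau = 0 for perfectly uniform expression
and tau = 1 for expression confined to a single stage.  It is computed here
on log-transformed stage-median expression (pseudocount >= 1 keeps values
non-negative, as tau requires).

Duplicate genes (members of homologous groups) and singletons are compared
with a two-sample Kolmogorov-Smirnov test on their tau distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .homology import HomologousGroupSet
from .preprocess import StageProfileMatrix

__all__ = ["KSResult", "SpecificityComparison", "tau", "build_tau_table",
           "ks_two_sample", "compare_specificity"]


@dataclass
class KSResult:
    D: float
    p: float
    n_a: int
    n_b: int

    def __post_init__(self):
        if not 0.0 <= self.D <= 1.0:
            raise ValueError(f"KS statistic must be in [0, 1], got {self.D}")


@dataclass
class SpecificityComparison:
    ks: KSResult
    mean_tau_duplicate: float
    mean_tau_singleton: float
    n_duplicate: int
    n_singleton: int


def tau(expression) -> float:
    """Stage-specificity index of a non-negative expression vector.

    Raises ``ValueError("no_expression")`` for an all-zero vector, for
    which tau is undefined; callers exclude such genes with that reason.
    """
    v = np.asarray(expression, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("expression must be a vector of length >= 2")
    if not np.isfinite(v).all():
        raise ValueError("non-finite expression values")
    if (v < 0).any():
        raise ValueError("negative expression values")
    vmax = v.max()
    if vmax == 0:
        raise ValueError("no_expression")
    x = v / vmax
    return float((1.0 - x).sum() / (v.size - 1))


def build_tau_table(profiles: StageProfileMatrix,
                    groupset: HomologousGroupSet
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene tau with duplicate/singleton class labels.

    ``profiles`` must be *unstandardized* log stage medians (tau needs
    non-negative values on their original scale).  Genes with no
    expression in any stage are excluded and returned separately.
    """
    if profiles.standardized:
        raise ValueError("tau is computed on unstandardized log profiles")
    duplicates = groupset.duplicate_genes
    universe = groupset.universe
    rows = []
    excluded: list[str] = []
    for gene_id, profile in profiles.values.iterrows():
        if gene_id not in universe:
            continue
        try:
            t = tau(profile.to_numpy())
        except ValueError as exc:
            if str(exc) == "no_expression":
                excluded.append(gene_id)
                continue
            raise
        cls = "duplicate" if gene_id in duplicates else "singleton"
        rows.append((gene_id, t, cls))
    return (pd.DataFrame(rows, columns=["gene_id", "tau", "class"]),
            excluded)


def ks_two_sample(a, b) -> KSResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs; p comes
    from the asymptotic Kolmogorov distribution with effective sample size
    n_a * n_b / (n_a + n_b).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    # guard against underflow: a p-value is strictly positive
    p = max(float(res.pvalue), np.finfo(float).tiny)
    return KSResult(D=float(res.statistic), p=p, n_a=a.size, n_b=b.size)


def compare_specificity(tau_table: pd.DataFrame) -> SpecificityComparison:
    """KS comparison of tau between duplicate and singleton genes."""
    dup = tau_table.loc[tau_table["class"] == "duplicate", "tau"].to_numpy()
    sing = tau_table.loc[tau_table["class"] == "singleton", "tau"].to_numpy()
    if dup.size == 0 or sing.size == 0:
        raise ValueError("both classes (duplicate, singleton) must be "
                         "non-empty")
    ks = ks_two_sample(dup, sing)
    return SpecificityComparison(
        ks=ks, mean_tau_duplicate=float(dup.mean()),
        mean_tau_singleton=float(sing.mean()),
        n_duplicate=dup.size, n_singleton=sing.size)


def ecdf_table(tau_table: pd.DataFrame) -> pd.DataFrame:
    """Empirical CDF of tau per class, for plotting."""
    frames = []
    for cls, sub in tau_table.groupby("class", sort=True):
        vals = np.sort(sub["tau"].to_numpy())
        frames.append(pd.DataFrame({
            "class": cls, "tau": vals,
            "ecdf": np.arange(1, vals.size + 1) / vals.size}))
    return pd.concat(frames, ignore_index=True)
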