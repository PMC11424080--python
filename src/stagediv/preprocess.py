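"""From raw TPM to the per-stage expression profiles downstream statistics use.

The pipeline's profile of a gene is the median log TPM per developmental
stage (hosts and replicates pooled), optionally standardized to mean 0 and
sample standard deviation 1 across stages so that distances between
profiles reflect temporal *shape* rather than expression magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix

__all__ = ["StageProfileMatrix", "log_transform", "stage_median_profiles",
           "standardize_profiles"]


@dataclass
class StageProfileMatrix:
    """Gene x stage profile matrix.

    ``values`` is indexed by gene id with one column per stage, in stage
    order.  When ``standardized`` is true every row has mean 0 and sample
    standard deviation (denominator S-1) 1 across stages, and ``dropped``
    lists genes excluded for zero across-stage variance.
    """

    values: pd.DataFrame
    standardized: bool = False
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.standardized and len(self.values):
            arr = self.values.to_numpy()
            if not (np.allclose(arr.mean(axis=1), 0.0, atol=1e-9)
                    and np.allclose(arr.std(axis=1, ddof=1), 1.0, atol=1e-9)):
                raise ValueError(
                    "standardized profiles must have row mean 0 and sd 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_stages(self) -> int:
        return self.values.shape[1]

    def rows(self, gene_ids) -> pd.DataFrame:
        return self.values.loc[list(gene_ids)]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def read_profiles_tsv(path, standardized: bool = False) -> StageProfileMatrix:
    """Read a gene x stage profile table written by ``to_tsv``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return StageProfileMatrix(df.astype(float), standardized=standardized)


def log_transform(matrix: ExpressionMatrix,
                  pseudocount: float = 1.0) -> ExpressionMatrix:
    """Replace each TPM value x by ln(x + pseudocount).

    The pseudocount (default 1, so TPM 0 maps to exactly 0) keeps genes
    silent in some stages — e.g. during the non-feeding pupal stage — on a
    finite scale.  Strictly monotone, so it preserves within-sample ranks.
    """
    if matrix.transformed:
        raise ValueError("matrix is already log-transformed")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    arr = matrix.values.to_numpy()
    if (arr < 0).any():
        raise ValueError("negative expression values")
    out = pd.DataFrame(np.log(arr + pseudocount), index=matrix.values.index,
                       columns=matrix.values.columns)
    return matrix.with_values(out, transformed=True)


def stage_median_profiles(matrix: ExpressionMatrix) -> StageProfileMatrix:
    """Median expression per gene per stage, pooling hosts and replicates.

    Expects a log-transformed matrix.  The median over an even number of
    samples is the mean of the two middle values.
    """
    if not matrix.transformed:
        raise ValueError("expected a log-transformed matrix; "
                         "apply log_transform first")
    cols = {}
    for stage in matrix.stage_order:
        ids = matrix.samples_for_stage(stage)
        if not ids:
            raise ValueError(f"stage {stage!r} has no samples")
        cols[stage] = matrix.values[ids].median(axis=1)
    values = pd.DataFrame(cols, columns=list(matrix.stage_order))
    values.index = matrix.values.index
    return StageProfileMatrix(values, standardized=False)


def standardize_profiles(profiles: StageProfileMatrix) -> StageProfileMatrix:
    """Mean-center and scale each gene's profile to unit variance.

    z_s = (m_s - mean(m)) / sd(m) with sd using denominator S-1.  Rows with
    zero across-stage variance carry no temporal signal and cannot be
    scaled; they are dropped and reported in ``dropped``.
    """
    if profiles.standardized:
        raise ValueError("profiles are already standardized")
    if profiles.n_stages < 2:
        raise ValueError("standardization requires at least 2 stages")
    arr = profiles.values.to_numpy()
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [g for g, k in zip(profiles.gene_ids, keep) if not k]
    kept = arr[keep]
    z = (kept - kept.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    values = pd.DataFrame(z, index=profiles.values.index[keep],
                          columns=profiles.values.columns)
    return StageProfileMatrix(values, standardized=True, dropped=dropped)
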