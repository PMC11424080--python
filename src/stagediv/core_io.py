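"""Data model and table I/O for the stage-divergence pipeline.

The pipeline consumes four kinds of plain-text inputs:

* a gene x sample expression matrix of TPM values (tab-separated, first
  column gene id), or per-sample pseudo-alignment abundance tables with
  ``target_id``/``tpm`` columns from which the matrix is assembled;
* a sample metadata table mapping each sample id to a developmental
  stage, a host plant and a replicate number;
* a six-column tabular protein-alignment hit table
  (query, target, pident, aln_length, target_length, evalue);
* Newick gene trees with branch lengths (handled in :mod:`stagediv.phylo`).

All readers validate eagerly and raise :class:`DataFormatError` naming the
offending file (and line where applicable) rather than silently coercing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("stagediv")

__all__ = [
    "DataFormatError",
    "SampleMetadata",
    "HomologyHit",
    "ExpressionMatrix",
    "PipelineConfig",
    "read_metadata_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "write_metadata_tsv",
    "read_abundance_tables",
    "read_hits_tab",
    "write_hits_tab",
    "write_provenance",
]


class DataFormatError(ValueError):
    """Malformed input; carries file path and line number when known."""

    def __init__(self, message: str, path: str | Path | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}"
            if line is not None:
                loc += f":{line}"
            loc += "]"
        super().__init__(message + loc)
        self.path = str(path) if path is not None else None
        self.line = line


@dataclass(frozen=True)
class SampleMetadata:
    """One sequenced individual: id, developmental stage, host plant, replicate."""

    sample_id: str
    stage: str
    host: str
    replicate: int

    def __post_init__(self):
        if self.replicate < 1:
            raise DataFormatError(
                f"replicate must be a positive integer, got {self.replicate} "
                f"for sample {self.sample_id!r}")


@dataclass(frozen=True)
class HomologyHit:
    """One row of an all-vs-all protein alignment table."""

    query: str
    target: str
    pident: float
    aln_length: int
    target_length: int
    evalue: float

    def __post_init__(self):
        if not 0.0 <= self.pident <= 100.0:
            raise DataFormatError(
                f"pident must be in [0, 100], got {self.pident} "
                f"({self.query} vs {self.target})")
        if self.aln_length <= 0:
            raise DataFormatError(
                f"aln_length must be positive, got {self.aln_length}")
        if self.target_length <= 0:
            raise DataFormatError(
                f"target_length must be positive, got {self.target_length}")
        if self.evalue < 0:
            raise DataFormatError(f"evalue must be >= 0, got {self.evalue}")


class ExpressionMatrix:
    """Gene x sample TPM matrix with per-sample metadata.

    Parameters
    ----------
    values:
        DataFrame indexed by gene id with one column per sample id.
        Non-negative TPM unless ``transformed`` is true.
    samples:
        One :class:`SampleMetadata` per column of ``values``.
    stage_order:
        Explicit total order of developmental stages.  Never inferred
        from string sort.
    transformed:
        Whether values are log-transformed (see
        :func:`stagediv.preprocess.log_transform`).
    """

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleMetadata],
                 stage_order: Sequence[str], transformed: bool = False):
        values = values.astype(float)
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate gene ids: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate sample ids: {dups}")
        if values.isna().any().any():
            bad = values.columns[values.isna().any()].tolist()
            raise DataFormatError(f"missing values in samples {bad}")
        by_id = {s.sample_id: s for s in samples}
        if len(by_id) != len(samples):
            raise DataFormatError("duplicate sample ids in metadata")
        missing = [c for c in values.columns if c not in by_id]
        if missing:
            raise DataFormatError(
                f"samples missing from metadata: {missing}")
        stage_order = list(stage_order)
        if len(set(stage_order)) != len(stage_order):
            raise DataFormatError(f"stage order has duplicates: {stage_order}")
        unknown = sorted({s.stage for s in samples} - set(stage_order))
        if unknown:
            raise DataFormatError(
                f"stages not in declared stage order: {unknown}")
        if not transformed and (values.to_numpy() < 0).any():
            raise DataFormatError("negative TPM values in untransformed matrix")
        # keep metadata in column order; normalize axis names
        values = values.rename_axis(index="gene_id", columns=None)
        self.values = values
        self.samples = [by_id[c] for c in values.columns]
        self.stage_order = stage_order
        self.transformed = bool(transformed)

    # -- basic accessors ---------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def stages(self) -> pd.Series:
        """Stage label per sample, aligned with columns."""
        return pd.Series([s.stage for s in self.samples],
                         index=self.values.columns, name="stage")

    @property
    def hosts(self) -> pd.Series:
        return pd.Series([s.host for s in self.samples],
                         index=self.values.columns, name="host")

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(s) for s in self.samples]
        ).set_index("sample_id")

    def samples_for_stage(self, stage: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.stage == stage]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = set(sample_ids)
        samples = [s for s in self.samples if s.sample_id in keep]
        return ExpressionMatrix(self.values[[s.sample_id for s in samples]],
                                samples, self.stage_order, self.transformed)

    def with_values(self, values: pd.DataFrame,
                    transformed: bool) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.samples, self.stage_order,
                                transformed)


# ---------------------------------------------------------------------------
# configuration

#: Developmental stages of the default (monarch-like) study design, ordered.
DEFAULT_STAGE_ORDER = (
    "third_instar", "fifth_instar", "early_pupa", "late_pupa", "adult")


@dataclass
class PipelineConfig:
    """Tunable thresholds and run parameters for the whole pipeline."""

    # homology filtering (strict preset; see stagediv.homology for presets)
    min_pident: float = 30.0
    min_target_coverage: float = 0.90
    max_evalue: float = 1e-10
    # preprocessing
    pseudocount: float = 1.0
    # permutation tests
    n_permutations: int = 999
    seed: int = 0
    # analysis scoping
    min_group_size_mantel: int = 3
    min_groups_per_size: int = 5
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER

    def __post_init__(self):
        if not 0.0 <= self.min_pident <= 100.0:
            raise ValueError("min_pident must be in [0, 100]")
        if not 0.0 <= self.min_target_coverage <= 1.0:
            raise ValueError("min_target_coverage must be in [0, 1]")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.min_group_size_mantel < 3:
            raise ValueError("min_group_size_mantel must be >= 3")
        if self.min_groups_per_size < 3:
            raise ValueError("min_groups_per_size must be >= 3")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stage_order" in data:
            data["stage_order"] = tuple(data["stage_order"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_order"] = list(d["stage_order"])
        return d


# ---------------------------------------------------------------------------
# readers / writers

def read_metadata_tsv(path: str | Path,
                      stage_order: Sequence[str] | None = None
                      ) -> tuple[list[SampleMetadata], list[str]]:
    """Read a sample metadata table.

    Columns (tab-separated, with header): sample_id, stage, host, replicate.
    ``stage_order`` must normally be declared explicitly; if omitted, the
    order of first appearance in the file is used (never a string sort).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "stage", "host", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(
            f"metadata missing columns {sorted(missing)}", path=path)
    samples = []
    for i, row in df.iterrows():
        try:
            rep = int(row["replicate"])
        except ValueError:
            raise DataFormatError(
                f"non-integer replicate {row['replicate']!r}",
                path=path, line=i + 2) from None
        samples.append(SampleMetadata(row["sample_id"], row["stage"],
                                      row["host"], rep))
    if stage_order is None:
        stage_order = list(dict.fromkeys(s.stage for s in samples))
        logger.info("stage order taken from first appearance: %s", stage_order)
    return samples, list(stage_order)


def read_expression_tsv(path: str | Path, metadata_path: str | Path,
                        stage_order: Sequence[str] | None = None
                        ) -> ExpressionMatrix:
    """Read a gene x sample TPM matrix plus its metadata table.

    First column of the matrix is the gene id; remaining columns are sample
    ids, all of which must appear in the metadata.
    """
    samples, stage_order = read_metadata_tsv(metadata_path, stage_order)
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise DataFormatError(
                f"non-numeric cell in column {col!r}: {bad.iloc[0]!r} "
                f"(gene {bad.index[0]!r})", path=path)
    known = {s.sample_id for s in samples}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise DataFormatError(
            f"samples absent from metadata: {unknown}", path=path)
    try:
        return ExpressionMatrix(df, samples, stage_order, transformed=False)
    except DataFormatError as exc:
        raise DataFormatError(str(exc), path=path) from None


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path,
                         metadata_path: str | Path | None = None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    if metadata_path is not None:
        write_metadata_tsv(matrix.samples, metadata_path)


def write_metadata_tsv(samples: Sequence[SampleMetadata],
                       path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in samples]).to_csv(
        path, sep="\t", index=False)


def read_abundance_tables(sample_to_path: Mapping[str, str | Path],
                          samples: Sequence[SampleMetadata],
                          stage_order: Sequence[str],
                          ) -> ExpressionMatrix:
    """Assemble a TPM matrix from per-sample abundance tables.

    Each table is tab-separated with a header containing at least
    ``target_id`` and ``tpm`` (the pseudo-alignment output dialect).  The
    gene universe is the union of target ids across samples; a gene absent
    from one sample gets TPM 0 there, and the number of such fills is
    logged as a warning.
    """
    by_id = {s.sample_id: s for s in samples}
    missing_meta = sorted(set(sample_to_path) - set(by_id))
    if missing_meta:
        raise DataFormatError(
            f"samples absent from metadata: {missing_meta}")
    columns: dict[str, pd.Series] = {}
    for sample_id, path in sample_to_path.items():
        df = pd.read_csv(path, sep="\t")
        for col in ("target_id", "tpm"):
            if col not in df.columns:
                raise DataFormatError(
                    f"abundance table lacks {col!r} column", path=path)
        if df["target_id"].duplicated().any():
            dup = df["target_id"][df["target_id"].duplicated()].iloc[0]
            raise DataFormatError(
                f"duplicate target_id {dup!r}", path=path)
        columns[sample_id] = df.set_index("target_id")["tpm"].astype(float)
    union = sorted(set().union(*(s.index for s in columns.values())))
    mat = pd.DataFrame(index=pd.Index(union, name="gene_id"))
    n_filled = 0
    for sample_id, series in columns.items():
        aligned = series.reindex(union)
        n_filled += int(aligned.isna().sum())
        mat[sample_id] = aligned.fillna(0.0)
    if n_filled:
        logger.warning("filled %d absent gene/sample entries with TPM 0",
                       n_filled)
    used = [by_id[c] for c in mat.columns]
    return ExpressionMatrix(mat, used, stage_order, transformed=False)


def collapse_transcripts(matrix: ExpressionMatrix,
                         transcript_to_gene: Mapping[str, str]
                         ) -> ExpressionMatrix:
    """Sum transcript-level TPM rows into gene-level rows.

    Optional: by default each target id is one analysis unit.  The mapping
    must cover every row; TPM is additive over transcripts of a gene, so
    rows are summed.  Requires an untransformed matrix.
    """
    if matrix.transformed:
        raise ValueError("collapse must happen before log transformation")
    missing = [g for g in matrix.gene_ids if g not in transcript_to_gene]
    if missing:
        raise DataFormatError(
            f"transcripts absent from mapping: {missing[:5]}"
            + ("..." if len(missing) > 5 else ""))
    genes = pd.Index([transcript_to_gene[t] for t in matrix.gene_ids])
    collapsed = matrix.values.groupby(genes, sort=True).sum()
    return ExpressionMatrix(collapsed, matrix.samples, matrix.stage_order,
                            transformed=False)


_HITS_COLUMNS = ("query", "target", "pident", "aln_length",
                 "target_length", "evalue")


def read_hits_tab(path: str | Path) -> list[HomologyHit]:
    """Read a six-column hit table (header optional, auto-detected).

    Column order: query, target, pident, aln_length, target_length, evalue.
    Self-hits are retained at this layer; filtering happens in
    :func:`stagediv.homology.filter_hits`.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise DataFormatError(
                    f"expected 6 tab-separated columns, got {len(fields)}",
                    path=path, line=lineno)
            if lineno == 1:
                try:
                    float(fields[2])
                except ValueError:
                    continue  # header row
            try:
                hits.append(HomologyHit(
                    query=fields[0], target=fields[1],
                    pident=float(fields[2]), aln_length=int(fields[3]),
                    target_length=int(fields[4]), evalue=float(fields[5])))
            except ValueError as exc:
                raise DataFormatError(
                    f"unparsable value: {exc}", path=path, line=lineno
                ) from None
    return hits


def write_hits_tab(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HITS_COLUMNS) + "\n")
        for h in hits:
            fh.write(f"{h.query}\t{h.target}\t{h.pident:.10g}\t"
                     f"{h.aln_length}\t{h.target_length}\t{h.evalue:.10g}\n")


# ---------------------------------------------------------------------------
# provenance

def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path: str | Path, config: PipelineConfig,
                     inputs: Mapping[str, str | Path] | None = None,
                     extra: Mapping[str, object] | None = None) -> None:
    """Write a JSON record of config values, seed and input digests."""
    record: dict[str, object] = {
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in (inputs or {}).items()},
    }
    if extra:
        record.update(extra)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
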