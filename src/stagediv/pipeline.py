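"""End-to-end orchestration: from input tables to all result TSVs.

This is the library backbone of the ``stagediv all`` command; each step is
also exposed as its own CLI subcommand.  Every run writes deterministic
TSV outputs given the same inputs, config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import (core_io, divergence, diversity, homology, phylo, preprocess,
               specificity, stage_divergence)
from .core_io import ExpressionMatrix, PipelineConfig


@dataclass
class PipelineResults:
    groupset: homology.HomologousGroupSet
    mantel_per_group: pd.DataFrame
    mantel_summary: dict
    diversity_pairs: list
    diversity_summary: dict
    specificity_comparison: specificity.SpecificityComparison
    permanova: stage_divergence.PermanovaTable
    pairwise_stages: list


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(expression_path: str | Path, metadata_path: str | Path,
                 hits_path: str | Path, trees_dir: str | Path,
                 outdir: str | Path, config: PipelineConfig,
                 preset: str = "lenient") -> PipelineResults:
    """Run every analysis stage and write result tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix = core_io.read_expression_tsv(
        expression_path, metadata_path,
        stage_order=config.stage_order if config.stage_order else None)

    # homology groups
    hits = core_io.read_hits_tab(hits_path)
    thr = homology.PRESETS[preset]
    edges = homology.filter_hits(hits, thr.min_pident,
                                 thr.min_target_coverage, thr.max_evalue)
    groupset = homology.build_groups(edges, matrix.gene_ids, thresholds=thr)
    _fmt(groupset.as_frame(), outdir / "groups.tsv")
    _fmt(groupset.size_histogram(), outdir / "group_size_histogram.tsv")

    # profiles
    logged = preprocess.log_transform(matrix, config.pseudocount)
    medians = preprocess.stage_median_profiles(logged)
    std = preprocess.standardize_profiles(medians)
    medians.to_tsv(outdir / "stage_profiles.tsv")
    std.to_tsv(outdir / "stage_profiles_standardized.tsv")
    pd.DataFrame({"gene_id": std.dropped}).to_csv(
        outdir / "excluded_zero_variance.tsv", sep="\t", index=False)

    # trees keyed to group ids by matching leaf sets
    trees_by_file = phylo.read_trees_dir(trees_dir)
    trees = _match_trees_to_groups(groupset, trees_by_file)

    # phylogenetic vs expression divergence
    per_group, summary = divergence.group_mantel_analysis(
        groupset, std, trees, n_permutations=config.n_permutations,
        seed=config.seed, min_group_size=config.min_group_size_mantel)
    _fmt(per_group, outdir / "mantel_per_group.tsv")
    _summary_tsv(summary, outdir / "mantel_summary.tsv")
    tested = per_group[per_group["skipped_reason"] == ""]
    ecdf = tested.sort_values("r").reset_index(drop=True)
    ecdf["ecdf"] = (ecdf.index + 1) / len(ecdf) if len(ecdf) else []
    _fmt(ecdf[["group_id", "r", "ecdf"]], outdir / "mantel_r_ecdf.tsv")

    # diversity scaling
    pairs, skipped = diversity.group_diversity_analysis(groupset, std, trees)
    pairs_df = pd.DataFrame(
        [(p.group_id, p.group_size, p.phylo_diversity, p.expr_diversity)
         for p in pairs],
        columns=["group_id", "size", "phylo_diversity", "expr_diversity"])
    _fmt(pairs_df, outdir / "diversity_pairs.tsv")
    div_summary: dict = {"n_groups": len(pairs)}
    if len(pairs) >= 3:
        corr = diversity.diversity_correlation(
            pairs_df["phylo_diversity"], pairs_df["expr_diversity"])
        sse_lin, sse_quad = diversity.compare_linear_quadratic(
            pairs_df["phylo_diversity"], pairs_df["expr_diversity"])
        div_summary.update(rho=corr.rho, p=corr.p, sse_linear=sse_lin,
                           sse_quadratic=sse_quad)
        _fmt(diversity.stratify_by_size(pairs, config.min_groups_per_size),
             outdir / "diversity_by_size.tsv")
    _summary_tsv(div_summary, outdir / "diversity_summary.tsv")

    # stage specificity
    tau_table, excluded = specificity.build_tau_table(medians, groupset)
    comp = specificity.compare_specificity(tau_table)
    _fmt(tau_table, outdir / "tau.tsv")
    _fmt(specificity.ecdf_table(tau_table), outdir / "tau_ecdf.tsv")
    _summary_tsv({
        "ks_D": comp.ks.D, "ks_p": comp.ks.p,
        "n_duplicate": comp.n_duplicate, "n_singleton": comp.n_singleton,
        "mean_tau_duplicate": comp.mean_tau_duplicate,
        "mean_tau_singleton": comp.mean_tau_singleton,
        "n_excluded_no_expression": len(excluded),
    }, outdir / "tau_summary.tsv")

    # whole-transcriptome stage divergence (raw TPM)
    dist = stage_divergence.manhattan_distances(matrix)
    dist.to_tsv(outdir / "sample_manhattan_distances.tsv")
    table = stage_divergence.permanova_two_factor(
        dist, list(matrix.stages), list(matrix.hosts),
        names=("stage", "host"), n_permutations=config.n_permutations,
        seed=config.seed)
    _fmt(table.as_frame(), outdir / "permanova.tsv")
    pairwise = stage_divergence.pairwise_stage_tests(
        matrix, n_permutations=config.n_permutations, seed=config.seed)
    _fmt(stage_divergence.pairwise_results_frame(pairwise),
         outdir / "pairwise_stages.tsv")

    core_io.write_provenance(
        outdir / "provenance.json", config,
        inputs={"expression": expression_path, "metadata": metadata_path,
                "hits": hits_path})

    return PipelineResults(
        groupset=groupset, mantel_per_group=per_group,
        mantel_summary=summary, diversity_pairs=pairs,
        diversity_summary=div_summary, specificity_comparison=comp,
        permanova=table, pairwise_stages=pairwise)


def _match_trees_to_groups(groupset: homology.HomologousGroupSet,
                           trees_by_file: dict[str, phylo.GeneTree]
                           ) -> dict[str, phylo.GeneTree]:
    """Key trees by pipeline group id via exact leaf-set match.

    Tree files are named by the id they were generated under, which need
    not match the ids assigned after group assembly; the leaf set is the
    stable join key.
    """
    by_leafset = {frozenset(t.leaf_labels): t for t in trees_by_file.values()}
    out = {}
    for gid, members in zip(groupset.group_ids(), groupset.groups):
        tree = by_leafset.get(frozenset(members))
        if tree is None:
            raise KeyError(
                f"no tree with leaf set matching group {gid} ({members})")
        out[gid] = tree
    return out


def _summary_tsv(summary: dict, path: Path) -> None:
    rows = [(k, v) for k, v in summary.items()
            if isinstance(v, (int, float, str))]
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")
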