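"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the study design the pipeline targets: five
developmental stages x two host plants x five replicates, a set of
homologous gene groups whose members' temporal expression profiles diverge
with sequence divergence, and a pool of broadly expressed singletons.

Mechanism, per homologous group:

1. a pure-birth (Yule) gene tree with exponential waiting times gives the
   group's topology and branch lengths;
2. each member's log-expression profile evolves along the tree by Brownian
   motion — per stage, child = parent + Normal(0, sigma^2 * branch length)
   — so expression distance grows with patristic distance, the structure
   the Mantel analysis presupposes;
3. duplicate genes additionally receive a one-hot boost on a random stage
   (stage-specificity signal); singletons get flat profiles;
4. observed TPM per replicate is exp(profile + noise), and a hit table is
   derived from patristic distances through fixed monotone maps (synthetic
   conventions, not biology) chosen so default homology thresholds recover
   the true partition.

All randomness flows from a single seeded generator; regenerating with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import phylo
from .core_io import (ExpressionMatrix, HomologyHit, SampleMetadata,
                      write_expression_tsv, write_hits_tab,
                      write_metadata_tsv)
from .phylo import GeneTree

__all__ = ["SimulationConfig", "SyntheticBundle", "simulate_gene_tree",
           "evolve_profiles", "make_expression_matrix", "make_hits",
           "generate_dataset"]

DEFAULT_STAGES = ("third_instar", "fifth_instar", "early_pupa",
                  "late_pupa", "adult")
DEFAULT_HOSTS = ("incarnata", "curassavica")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults reproduce the design the pipeline targets: 100 homologous
    groups of 3-8 genes, 300 singletons, 5 stages x 2 hosts x 5
    replicates, Brownian rate sigma^2 = 0.5 per unit branch length,
    stage-boost 1.0 (log scale) for duplicates and replicate noise sd 0.3.
    """

    seed: int
    n_groups: int = 100
    min_group_size: int = 3
    max_group_size: int = 8
    n_singletons: int = 300
    stages: tuple[str, ...] = DEFAULT_STAGES
    hosts: tuple[str, ...] = DEFAULT_HOSTS
    replicates_per_cell: int = 5
    bm_rate: float = 0.5                 # sigma^2 per unit branch length
    birth_rate: float = 1.0              # Yule split rate
    root_profile_sd: float = 1.0         # per-stage sd of group root profiles
    duplicate_specificity_boost: float = 1.0
    replicate_noise_sd: float = 0.3
    host_effect_sd: float = 0.0          # no host effect by default
    base_log_expression: float = 3.0     # log TPM scale; exp(3) ~ 20 TPM
    pident_decay: float = 0.2

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("bm_rate", "root_profile_sd",
                     "duplicate_specificity_boost", "replicate_noise_sd",
                     "host_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if self.pident_decay <= 0:
            raise ValueError("pident_decay must be > 0")
        if self.min_group_size < 2 or self.max_group_size < self.min_group_size:
            raise ValueError("group sizes must satisfy 2 <= min <= max")
        if len(self.stages) < 2:
            raise ValueError("need at least 2 stages")

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def n_samples(self) -> int:
        return len(self.stages) * len(self.hosts) * self.replicates_per_cell

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["hosts"] = list(d["hosts"])
        return d


@dataclass
class SyntheticBundle:
    """In-memory handles plus file paths of one generated dataset."""

    config: SimulationConfig
    outdir: Path
    expression: ExpressionMatrix
    trees: dict[str, GeneTree]
    true_groups: dict[str, tuple[str, ...]]
    singletons: tuple[str, ...]
    true_profiles: pd.DataFrame          # gene x stage, log scale, post-boost
    true_patristic: pd.DataFrame         # group_id, gene_a, gene_b, distance
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def duplicate_genes(self) -> frozenset[str]:
        return frozenset(g for grp in self.true_groups.values() for g in grp)


# ---------------------------------------------------------------------------
# tree simulation


class _Lineage:
    __slots__ = ("birth", "children", "length", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.children: list["_Lineage"] = []
        self.length: float | None = None
        self.label: str | None = None


def _to_newick(node: _Lineage) -> str:
    if node.children:
        inner = ",".join(_to_newick(c) for c in node.children)
        body = f"({inner})"
    else:
        body = node.label
    if node.length is None:  # root
        return f"{body};"
    return f"{body}:{node.length:.9f}"


def simulate_gene_tree(n_leaves: int, birth_rate: float, seed,
                       labels: Sequence[str] | None = None) -> GeneTree:
    """Pure-birth (Yule) gene tree with exponential waiting times.

    Starting from a root split into two lineages at time 0, a uniformly
    random extant lineage splits after an Exponential(k * birth_rate)
    wait with k current lineages until ``n_leaves`` is reached; one final
    wait sets the leaf tips, so the tree is ultrametric with 2n - 2
    branches whose lengths are elapsed times.
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if labels is None:
        labels = [f"g{i + 1}" for i in range(n_leaves)]
    labels = list(labels)
    if len(labels) != n_leaves:
        raise ValueError("labels length must equal n_leaves")

    root = _Lineage(0.0)
    tips = [_Lineage(0.0), _Lineage(0.0)]
    root.children = list(tips)
    t = 0.0
    while len(tips) < n_leaves:
        k = len(tips)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        parent = tips.pop(idx)
        parent.length = t - parent.birth
        kids = [_Lineage(t), _Lineage(t)]
        parent.children = kids
        tips.extend(kids)
    t_end = t + rng.exponential(1.0 / (n_leaves * birth_rate))
    for leaf, label in zip(tips, labels):
        leaf.length = t_end - leaf.birth
        leaf.label = label
    return phylo.parse_newick(_to_newick(root))


def evolve_profiles(tree: GeneTree, bm_rate: float,
                    root_profile: np.ndarray, seed
                    ) -> dict[str, np.ndarray]:
    """Brownian motion of a stage profile along a gene tree.

    Each stage dimension evolves independently; along a branch of length l
    the child value is parent + Normal(0, bm_rate * l).  Returns the leaf
    profiles keyed by leaf label.
    """
    if bm_rate < 0:
        raise ValueError("bm_rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    root_profile = np.asarray(root_profile, dtype=float)
    s = root_profile.size
    values = {id(tree.tree.seed_node): root_profile.copy()}
    out: dict[str, np.ndarray] = {}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            current = values[id(node)]
        else:
            parent = values[id(node.parent_node)]
            sd = np.sqrt(bm_rate * float(node.edge.length))
            current = parent + rng.normal(0.0, 1.0, s) * sd
            values[id(node)] = current
        if node.is_leaf():
            out[node.taxon.label] = current.copy()
    return out


# ---------------------------------------------------------------------------
# expression and hits


def _sample_design(config: SimulationConfig) -> list[SampleMetadata]:
    samples = []
    for stage in config.stages:
        for host in config.hosts:
            for rep in range(1, config.replicates_per_cell + 1):
                samples.append(SampleMetadata(
                    sample_id=f"{stage}_{host}_r{rep}",
                    stage=stage, host=host, replicate=rep))
    return samples


def make_expression_matrix(profiles: Mapping[str, np.ndarray],
                           config: SimulationConfig, rng,
                           duplicate_genes: frozenset[str] | set[str],
                           ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Replicate-level TPM from per-gene log-scale stage profiles.

    Duplicate genes first receive an additive one-hot boost of size
    ``duplicate_specificity_boost`` on a uniformly chosen stage.  Observed
    TPM(g, sample in stage s) = exp(profile_gs + host effect + noise) with
    noise ~ Normal(0, replicate_noise_sd^2) per replicate.  Also returns
    the post-boost true profiles (the simulation's ground truth).
    """
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    samples = _sample_design(config)
    gene_ids = list(profiles)
    s = config.n_stages
    stage_index = {stage: i for i, stage in enumerate(config.stages)}

    true = np.vstack([np.asarray(profiles[g], dtype=float)
                      for g in gene_ids])
    for gi, g in enumerate(gene_ids):
        if g in duplicate_genes and config.duplicate_specificity_boost > 0:
            true[gi, int(rng.integers(s))] += config.duplicate_specificity_boost

    host_shift = {h: 0.0 for h in config.hosts}
    if config.host_effect_sd > 0:
        for h in config.hosts:
            host_shift[h] = float(rng.normal(0.0, config.host_effect_sd))

    log_tpm = np.empty((len(gene_ids), len(samples)))
    for si, smp in enumerate(samples):
        log_tpm[:, si] = true[:, stage_index[smp.stage]] + host_shift[smp.host]
    noise = rng.normal(0.0, 1.0, log_tpm.shape) * config.replicate_noise_sd
    tpm = np.exp(log_tpm + noise)

    values = pd.DataFrame(tpm, index=pd.Index(gene_ids, name="gene_id"),
                          columns=[smp.sample_id for smp in samples])
    matrix = ExpressionMatrix(values, samples, config.stages,
                              transformed=False)
    true_df = pd.DataFrame(true, index=pd.Index(gene_ids, name="gene_id"),
                           columns=list(config.stages))
    return matrix, true_df


def make_hits(trees: Mapping[str, GeneTree], pident_decay: float, rng,
              target_lengths: Mapping[str, int]) -> list[HomologyHit]:
    """Hit table derived from within-group patristic distances.

    For a pair at patristic distance d:
    pident = 20 + 80 exp(-decay d), full target coverage, and
    evalue = 10^(-50 exp(-decay d)).  Both hit directions are written; no
    between-group or singleton hits are emitted.  These maps are synthetic
    conventions chosen so the default thresholds recover the partition.
    """
    if pident_decay <= 0:
        raise ValueError("pident_decay must be > 0")
    hits: list[HomologyHit] = []
    for gid in sorted(trees):
        dm = phylo.patristic_distances(trees[gid])
        labels = dm.labels
        for i in range(len(labels)):
            for j in range(len(labels)):
                if i == j:
                    continue
                d = dm.values[i, j]
                decay = float(np.exp(-pident_decay * d))
                query, target = labels[i], labels[j]
                tlen = int(target_lengths[target])
                hits.append(HomologyHit(
                    query=query, target=target,
                    pident=20.0 + 80.0 * decay,
                    aln_length=tlen, target_length=tlen,
                    evalue=float(10.0 ** (-50.0 * decay))))
    return hits


# ---------------------------------------------------------------------------
# orchestration


def generate_dataset(config: SimulationConfig,
                     outdir: str | Path) -> SyntheticBundle:
    """Generate and write a complete synthetic dataset.

    Writes expression.tsv, metadata.tsv, hits.tsv, one Newick per group
    under trees/, and ground-truth tables under truth/.  Byte-identical
    across repeated calls with the same config.
    """
    outdir = Path(outdir)
    (outdir / "trees").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    sizes = rng.integers(config.min_group_size, config.max_group_size + 1,
                         config.n_groups)
    trees: dict[str, GeneTree] = {}
    profiles: dict[str, np.ndarray] = {}
    true_groups: dict[str, tuple[str, ...]] = {}
    patristic_rows = []
    for g in range(config.n_groups):
        gid = f"G{g + 1:04d}"
        members = [f"{gid}_{m + 1}" for m in range(int(sizes[g]))]
        tree = simulate_gene_tree(len(members), config.birth_rate, rng,
                                  labels=members)
        trees[gid] = tree
        true_groups[gid] = tuple(tree.leaf_labels)
        root = (config.base_log_expression
                + rng.normal(0.0, 1.0, config.n_stages)
                * config.root_profile_sd)
        profiles.update(evolve_profiles(tree, config.bm_rate, root, rng))
        dm = phylo.patristic_distances(tree)
        for i in range(len(dm.labels)):
            for j in range(i + 1, len(dm.labels)):
                patristic_rows.append((gid, dm.labels[i], dm.labels[j],
                                       dm.values[i, j]))

    singletons = tuple(f"S{i + 1:04d}" for i in range(config.n_singletons))
    for s in singletons:
        offset = float(rng.normal(0.0, 1.0)) * config.root_profile_sd
        profiles[s] = np.full(config.n_stages,
                              config.base_log_expression + offset)

    duplicate_genes = frozenset(m for grp in true_groups.values()
                                for m in grp)
    expression, true_df = make_expression_matrix(
        profiles, config, rng, duplicate_genes)

    target_lengths = {g: int(rng.integers(150, 601))
                      for g in sorted(duplicate_genes)}
    hits = make_hits(trees, config.pident_decay, rng, target_lengths)

    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "hits": outdir / "hits.tsv",
        "trees": outdir / "trees",
        "truth_groups": outdir / "truth" / "groups.tsv",
        "truth_profiles": outdir / "truth" / "profiles.tsv",
        "truth_patristic": outdir / "truth" / "patristic.tsv",
    }
    write_expression_tsv(expression, paths["expression"])
    write_metadata_tsv(expression.samples, paths["metadata"])
    write_hits_tab(hits, paths["hits"])
    for gid, tree in trees.items():
        (outdir / "trees" / f"{gid}.nwk").write_text(tree.as_newick() + "\n")

    member_rows = [(m, gid) for gid in sorted(true_groups)
                   for m in true_groups[gid]]
    member_rows += [(s, "singleton") for s in singletons]
    pd.DataFrame(member_rows, columns=["gene_id", "group_id"]).to_csv(
        paths["truth_groups"], sep="\t", index=False)
    true_df.to_csv(paths["truth_profiles"], sep="\t", index_label="gene_id")
    true_patristic = pd.DataFrame(
        patristic_rows,
        columns=["group_id", "gene_a", "gene_b", "distance"])
    true_patristic.to_csv(paths["truth_patristic"], sep="\t", index=False)

    return SyntheticBundle(
        config=config, outdir=outdir, expression=expression, trees=trees,
        true_groups=true_groups, singletons=singletons,
        true_profiles=true_df, true_patristic=true_patristic, paths=paths)
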