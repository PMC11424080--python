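"""Homologous-group assembly from all-vs-all protein alignment hits.

A pair of genes is called homologous when their alignment passes identity,
target-coverage and E-value thresholds; passing pairs form an undirected
graph whose connected components (size >= 2) are the homologous groups
("duplicate genes").  Genes in no passing pair are singletons.

Two named threshold presets are provided:

* ``strict``  — pident >= 30, target coverage >= 0.90, E <= 1e-10
* ``lenient`` — pident >= 20, target coverage >= 0.70, E <= 1e-5

All boundary comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .core_io import HomologyHit

__all__ = ["Thresholds", "PRESETS", "HomologousGroupSet", "filter_hits",
           "build_groups"]


@dataclass(frozen=True)
class Thresholds:
    min_pident: float
    min_target_coverage: float
    max_evalue: float

    def __post_init__(self):
        if not 0.0 <= self.min_pident <= 100.0:
            raise ValueError("min_pident must be in [0, 100]")
        if not 0.0 <= self.min_target_coverage <= 1.0:
            raise ValueError("min_target_coverage must be in [0, 1]")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")


PRESETS: dict[str, Thresholds] = {
    "strict": Thresholds(30.0, 0.90, 1e-10),
    "lenient": Thresholds(20.0, 0.70, 1e-5),
}


@dataclass
class HomologousGroupSet:
    """Partition of the gene universe into groups (>= 2 members) and singletons.

    Groups are ordered deterministically by their smallest member id and
    each group's members are sorted.
    """

    groups: list[tuple[str, ...]]
    singletons: frozenset[str]
    thresholds: Thresholds | None = None

    def __post_init__(self):
        seen: set[str] = set()
        for g in self.groups:
            if len(g) < 2:
                raise ValueError(f"group {g} has fewer than 2 members")
            if seen & set(g):
                raise ValueError("groups are not pairwise disjoint")
            seen |= set(g)
        if seen & self.singletons:
            raise ValueError("gene assigned to both a group and singletons")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set(self.singletons)
        for g in self.groups:
            out |= set(g)
        return frozenset(out)

    @property
    def duplicate_genes(self) -> frozenset[str]:
        return frozenset(m for g in self.groups for m in g)

    def group_ids(self) -> list[str]:
        return [f"HG{i + 1:04d}" for i in range(len(self.groups))]

    def as_frame(self) -> pd.DataFrame:
        """Gene-to-group membership table (group_id or 'singleton')."""
        rows = []
        for gid, members in zip(self.group_ids(), self.groups):
            rows += [(m, gid) for m in members]
        rows += [(s, "singleton") for s in sorted(self.singletons)]
        return pd.DataFrame(rows, columns=["gene_id", "group_id"])

    def size_histogram(self) -> pd.DataFrame:
        sizes = pd.Series([len(g) for g in self.groups], dtype=int)
        hist = sizes.value_counts().sort_index()
        return hist.rename_axis("group_size").reset_index(name="n_groups")


def filter_hits(hits: Iterable[HomologyHit], min_pident: float,
                min_target_coverage: float, max_evalue: float
                ) -> set[frozenset[str]]:
    """Threshold hits into undirected gene-pair edges.

    An edge (q, t) is retained iff q != t, pident >= min_pident,
    aln_length / target_length >= min_target_coverage and
    evalue <= max_evalue.  Reciprocal and duplicate hits collapse to one
    undirected edge.
    """
    Thresholds(min_pident, min_target_coverage, max_evalue)  # validate
    edges: set[frozenset[str]] = set()
    for h in hits:
        if h.target_length == 0:
            raise ValueError(
                f"target_length is 0 for {h.query} vs {h.target}")
        if h.query == h.target:
            continue
        if (h.pident >= min_pident
                and h.aln_length / h.target_length >= min_target_coverage
                and h.evalue <= max_evalue):
            edges.add(frozenset((h.query, h.target)))
    return edges


def build_groups(edges: Iterable[frozenset[str] | tuple[str, str]],
                 universe: Iterable[str],
                 thresholds: Thresholds | None = None) -> HomologousGroupSet:
    """Merge edges into homologous groups by connected components.

    Every edge endpoint must belong to ``universe``; genes touched by no
    edge become singletons.
    """
    universe = set(universe)
    g = nx.Graph()
    for e in edges:
        pair = tuple(e)
        if len(pair) != 2:
            raise ValueError(f"edge {pair} is not a 2-element pair")
        a, b = pair
        if a not in universe or b not in universe:
            missing = [x for x in (a, b) if x not in universe]
            raise ValueError(f"edge endpoint(s) outside universe: {missing}")
        g.add_edge(a, b)
    groups = [tuple(sorted(c)) for c in nx.connected_components(g)]
    groups.sort(key=lambda members: members[0])
    in_group = {m for grp in groups for m in grp}
    return HomologousGroupSet(groups=groups,
                              singletons=frozenset(universe - in_group),
                              thresholds=thresholds)


def groupset_from_frame(df: pd.DataFrame) -> HomologousGroupSet:
    """Rebuild a group set from a membership table written by `as_frame`."""
    singles = frozenset(df.loc[df["group_id"] == "singleton", "gene_id"])
    grouped = df[df["group_id"] != "singleton"]
    groups = [tuple(sorted(sub["gene_id"]))
              for _, sub in grouped.groupby("group_id", sort=True)]
    groups.sort(key=lambda members: members[0])
    return HomologousGroupSet(groups=groups, singletons=singles)
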