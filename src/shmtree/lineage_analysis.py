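"""Lineage statistics, branch-of-interest detection and logo matrices.

Repertoire-level summaries cover four per-lineage statistics: depth (edge
count of the longest root-to-tip path), dominant isotype (>50 % of nodes,
else mixed), clonal expansion (maximum node size) and lineage size (node
count).  Single-node lineages have zero depth — their ancestry is
unobserved — and are excluded from the summaries.

A *branch of interest* is a connected set of closely related nodes:
a connected component of the subgraph keeping only edges whose normalized
edit distance is at most ``w_max`` (default 0.1), retained when it is deep
(depth >= 2) and large (>= 5 nodes).  Qualifying branches can be rendered
as nucleotide or amino-acid position-frequency matrices for logo plots.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import pandas as pd
from Bio.Seq import Seq

from .clonotype_shm import (CloneNode, HEAVY_CDR_REGIONS,
                            LIGHT_CDR_REGIONS)
from .inheritance_tree import LineageTree

DEFAULT_W_MAX = 0.1
DEFAULT_D_MIN = 2
DEFAULT_S_MIN = 5
DEFAULT_DEPTH_MIN = 2


@dataclass
class LineageStats:
    lineage_id: str
    depth: int
    dominant_isotype: str
    expansion: int
    size: int


@dataclass
class Branch:
    """A connected subtree of closely related nodes."""

    tree_name: str
    node_names: list[str]
    branch_depth: int
    branch_size: int


@dataclass
class PositionFrequencyMatrix:
    """Per-position symbol frequencies (rows: positions, columns: symbols);
    every row sums to 1 over the observed symbols."""

    alphabet: str  # "nt" | "aa"
    frequencies: pd.DataFrame

    @property
    def length(self) -> int:
        return len(self.frequencies)


def _real_nodes(tree: LineageTree) -> list[CloneNode]:
    """Tree nodes minus any dummy root (size 0 by construction)."""
    return [n for n in tree.nodes.values() if not n.is_dummy]


def tree_depth(tree: LineageTree) -> int:
    """Edge count along the longest root-to-tip path."""
    depth = {tree.root: 0}
    best = 0
    for e in tree.edges:  # edges are emitted in attachment order
        depth[e.child] = depth[e.parent] + 1
        best = max(best, depth[e.child])
    return best


def dominant_isotype(tree: LineageTree) -> str:
    """Isotype held by a strict majority (>50 %) of non-dummy nodes,
    else "mixed"."""
    counts = Counter(n.node_isotype for n in _real_nodes(tree))
    total = sum(counts.values())
    for isotype, n in counts.most_common(1):
        if n * 2 > total:
            return isotype
    return "mixed"


def expansion_level(tree: LineageTree) -> int:
    """Clonal expansion: the maximum node size within the lineage."""
    return max(n.size for n in _real_nodes(tree))


def lineage_stats(tree: LineageTree) -> LineageStats:
    nodes = _real_nodes(tree)
    return LineageStats(lineage_id=tree.lineage_id or tree.tree_name,
                        depth=tree_depth(tree),
                        dominant_isotype=dominant_isotype(tree),
                        expansion=expansion_level(tree),
                        size=len(nodes))


def find_branches(tree: LineageTree, w_max: float = DEFAULT_W_MAX,
                  d_min: int = DEFAULT_D_MIN,
                  s_min: int = DEFAULT_S_MIN) -> list[Branch]:
    """Detect branches of interest.

    Keep edges with weight <= ``w_max``; each connected component of the
    resulting subgraph is a candidate branch, returned when its internal
    longest path has >= ``d_min`` edges and it has >= ``s_min`` nodes.
    """
    g = nx.DiGraph()
    g.add_nodes_from(tree.nodes)
    g.add_edges_from((e.parent, e.child) for e in tree.edges
                     if e.weight <= w_max)
    branches = []
    for comp in nx.weakly_connected_components(g):
        if len(comp) < s_min:
            continue
        sub = g.subgraph(comp)
        depth = nx.dag_longest_path_length(sub)
        if depth >= d_min:
            order = [n for n in tree.node_order() if n in comp]
            branches.append(Branch(tree_name=tree.tree_name,
                                   node_names=order,
                                   branch_depth=depth,
                                   branch_size=len(comp)))
    branches.sort(key=lambda b: b.node_names)
    return branches


def _aa_sequence(node: CloneNode) -> str:
    """Translate the node's CDRs region by region (each CDR in its own
    frame) and concatenate; stop codons render as '*'."""
    if not node.cdr_seqs:
        raise ValueError(f"node {node.node_name} carries no per-region CDR "
                         "sequences; amino-acid logos unavailable")
    parts = []
    for region in HEAVY_CDR_REGIONS + LIGHT_CDR_REGIONS:
        nt = node.cdr_seqs.get(region)
        if nt:
            trimmed = nt[:len(nt) - len(nt) % 3]
            parts.append(str(Seq(trimmed).translate()))
    return "".join(parts)


def logo_matrix(branch: Branch, nodes: dict[str, CloneNode],
                level: str = "nt") -> PositionFrequencyMatrix:
    """Size-weighted position-frequency matrix over a branch's node
    sequences (nucleotide clonotype sequences, or translated CDRs).

    Branches whose sequences differ in length (indels) cannot be stacked
    into a matrix and raise ``ValueError``.
    """
    if level not in ("nt", "aa"):
        raise ValueError(f"unknown logo level: {level!r}")
    pool = [nodes[name] for name in branch.node_names
            if not nodes[name].is_dummy]
    seqs = [(n.clonotype_seq if level == "nt" else _aa_sequence(n),
             max(n.size, 1)) for n in pool]
    if len({len(s) for s, _ in seqs}) != 1:
        raise ValueError(f"branch in {branch.tree_name} contains sequences "
                         "of unequal length (indels); no logo matrix")
    length = len(seqs[0][0])
    counts: list[Counter] = [Counter() for _ in range(length)]
    for seq, weight in seqs:
        for pos, sym in enumerate(seq):
            counts[pos][sym] += weight
    symbols = sorted({sym for c in counts for sym in c})
    rows = []
    for c in counts:
        total = sum(c.values())
        rows.append({sym: c.get(sym, 0) / total for sym in symbols})
    df = pd.DataFrame(rows, columns=symbols)
    df.index.name = "position"
    return PositionFrequencyMatrix(alphabet=level, frequencies=df)


@dataclass
class RepertoireSummary:
    """Distribution tables over multi-node lineages plus deep-lineage
    flags (depth >= depth_min)."""

    per_lineage: pd.DataFrame
    distributions: dict[str, pd.Series]
    n_deep: int


def summarize_repertoire(stats: Iterable[LineageStats],
                         depth_min: int = DEFAULT_DEPTH_MIN
                         ) -> RepertoireSummary:
    """Summarize lineage statistics over lineages with depth > 0
    (single-node lineages are excluded from downstream analysis)."""
    rows = [s for s in stats if s.depth > 0]
    df = pd.DataFrame(
        [{"lineage_id": s.lineage_id, "depth": s.depth,
          "dominant_isotype": s.dominant_isotype, "expansion": s.expansion,
          "size": s.size, "deep": s.depth >= depth_min} for s in rows],
        columns=["lineage_id", "depth", "dominant_isotype", "expansion",
                 "size", "deep"])
    dists = {col: df[col].value_counts().sort_index()
             for col in ("depth", "dominant_isotype", "expansion", "size")}
    return RepertoireSummary(per_lineage=df, distributions=dists,
                             n_deep=int(df["deep"].sum()) if len(df) else 0)
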