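"""SHM-ordered inheritance tree construction.

The central model: affinity maturation proceeds under constant antigenic
selection, so observed CDR mutations are treated as advantageous and
inherited — reversions are not expected.  A lineage tree therefore has two
defining properties: (i) SHM rates never decrease from root to tip, and
(ii) every child carries all of its parent's CDR mutations.

Construction: the clonotype with the lowest SHM rate roots the tree (ties
prefer unswitched IgM/IgD isotypes; remaining ties produce a consensus
"dummy" root with 'D' at disagreeing positions).  Remaining clonotypes are
visited in ascending SHM order and each attaches to the already-placed
candidate parent with the smallest Levenshtein distance among those whose
mutation set it fully inherits; the root always remains a candidate so the
tree stays connected, and edges attached through that fallback are
flagged.  Edge weights are the Levenshtein distance normalized by the
parent sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import edlib

from .airr_io import UNSWITCHED_ISOTYPES
from .clonotype_shm import CloneNode, MutationSet


class Edge(NamedTuple):
    parent: str
    child: str
    weight: float
    fallback: bool = False


@dataclass
class LineageTree:
    """Rooted directed tree over clonotype nodes with normalized
    edit-distance edge weights."""

    tree_name: str
    nodes: dict[str, CloneNode]
    edges: list[Edge]
    root: str
    lineage_id: str = ""
    sample: str = ""

    def node_order(self) -> list[str]:
        """Root first, then children in attachment order."""
        rest = [e.child for e in self.edges]
        return [self.root] + rest

    def children(self, name: str) -> list[str]:
        return [e.child for e in self.edges if e.parent == name]

    def parent(self, name: str) -> Optional[str]:
        for e in self.edges:
            if e.child == name:
                return e.parent
        return None

    def to_networkx(self):
        import networkx as nx
        g = nx.DiGraph()
        for name, node in self.nodes.items():
            g.add_node(name, size=node.size, shm_rate=node.shm_rate,
                       isotype=node.node_isotype)
        for e in self.edges:
            g.add_edge(e.parent, e.child, weight=e.weight,
                       fallback=e.fallback)
        return g


def levenshtein(a: str, b: str) -> int:
    """Levenshtein edit distance; the placeholder base 'D' of a dummy root
    mismatches every real nucleotide."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW")["editDistance"]


def edge_weight(parent_seq: str, child_seq: str) -> float:
    """Normalized pairwise edit distance: Levenshtein distance divided by
    the parent node sequence length."""
    if not parent_seq:
        raise ValueError("edge weight undefined for an empty parent sequence")
    return levenshtein(parent_seq, child_seq) / len(parent_seq)


def inherits(parent_mut: MutationSet, child_mut: MutationSet) -> bool:
    """True iff the child carries every parental CDR mutation (identity on
    region, position and observed base)."""
    return parent_mut <= child_mut


def make_dummy_root(candidates: Iterable[str]) -> str:
    """Positionwise consensus of equal-length candidate sequences, with
    'D' at every disagreeing position (e.g. AGC + CGC -> DGC)."""
    seqs = list(candidates)
    if len(seqs) < 2:
        raise ValueError("a dummy root requires at least two candidates")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("dummy-root candidates must have equal length")
    return "".join(col[0] if len(set(col)) == 1 else "D"
                   for col in zip(*seqs))


def select_root(nodes: list[CloneNode]) -> tuple[CloneNode, bool]:
    """Pick the root: the unique lowest-SHM clonotype; among ties prefer
    unswitched (IgM/IgD) isotypes; if ties remain, build a dummy root
    whose sequence is the tied candidates' consensus, whose SHM is the
    tied minimum and whose mutation set is the intersection of theirs
    (so every candidate is a valid child)."""
    if not nodes:
        raise ValueError("cannot select a root from an empty lineage")
    min_shm = min(n.shm_rate for n in nodes)
    tied = [n for n in nodes if n.shm_rate == min_shm]
    if len(tied) == 1:
        return tied[0], False
    unswitched = [n for n in tied if n.node_isotype in UNSWITCHED_ISOTYPES]
    if len(unswitched) == 1:
        return unswitched[0], False
    pool = unswitched if unswitched else tied
    seq = make_dummy_root(n.clonotype_seq for n in pool)
    mut = frozenset.intersection(*(frozenset(n.cdr_mutations) for n in pool))
    dummy = CloneNode(node_name="R", clonotype_seq=seq, size=0,
                      isotype_counts={}, node_isotype="dummy",
                      shm_rate=min_shm, cdr_mutations=mut, is_dummy=True)
    return dummy, True


def build_tree(nodes: list[CloneNode], tree_name: str = "",
               lineage_id: str = "", sample: str = "") -> LineageTree:
    """Build the SHM-ordered inheritance tree over a lineage's clonotypes.

    Nodes are renamed on the way in: the root becomes "R" and the
    remaining clonotypes "1", "2", ... in ascending SHM order (ties broken
    lexicographically by sequence), so node numbering follows divergence.
    Deterministic for any input order of ``nodes``.
    """
    root, is_dummy = select_root(nodes)
    pending = sorted((n for n in nodes if is_dummy or n is not root),
                     key=lambda n: (n.shm_rate, n.clonotype_seq))
    root.node_name = "R"
    placed: list[CloneNode] = [root]  # kept in descending SHM order
    tree_nodes = {"R": root}
    edges: list[Edge] = []
    for i, child in enumerate(pending, start=1):
        child.node_name = str(i)
        candidates = [p for p in placed
                      if inherits(p.cdr_mutations, child.cdr_mutations)]
        if root not in candidates:  # universal-root fallback
            candidates.append(root)
        best = min(candidates,
                   key=lambda p: (levenshtein(p.clonotype_seq,
                                              child.clonotype_seq),
                                  -p.shm_rate, p.clonotype_seq))
        fallback = (best is root
                    and not inherits(root.cdr_mutations,
                                     child.cdr_mutations))
        edges.append(Edge(best.node_name, child.node_name,
                          edge_weight(best.clonotype_seq,
                                      child.clonotype_seq), fallback))
        # insert keeping descending SHM order
        at = next((j for j, p in enumerate(placed)
                   if p.shm_rate < child.shm_rate), len(placed))
        placed.insert(at, child)
        tree_nodes[child.node_name] = child
    return LineageTree(tree_name=tree_name, nodes=tree_nodes, edges=edges,
                       root="R", lineage_id=lineage_id, sample=sample)
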