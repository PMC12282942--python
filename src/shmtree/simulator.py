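"""Germinal-centre lineage simulator for benchmarking tree reconstruction.

Generates ground-truth lineage trees under a simple affinity-maturation
model: growth starts from a random germline sequence of length L; each
node produces Poisson(lambda_c) children; each child acquires a
zero-truncated Poisson(lambda_m) count of new substitutions at previously
unmutated positions, with 10 % of positions designated hotspots carrying
3x mutation weight; all parental mutations are inherited (no reversions,
so a mutated position is frozen thereafter); growth stops once the node
count reaches N or any node has mutated 95 % of its positions.

Children are drawn generation by generation (breadth-first), and a child
whose sequence would duplicate an existing node is redrawn a bounded
number of times so that node sequences stay pairwise distinct — a
zero-mutation child would collapse into its parent's clonotype during
reconstruction and make ground-truth comparison ill-defined.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .clonotype_shm import CloneNode

_ALPHABET = np.array(list("ACGT"))

#: Simulated mutations live in a single nominal CDR region.
SIM_REGION = "cdrh3"


@dataclass
class SimParams:
    """Simulation parameters; the defaults are the smallest cell of the
    benchmark grid (L=100, N=100, lambda_c=2, lambda_m=1)."""

    L: int = 100
    N: int = 100
    lambda_c: float = 2.0
    lambda_m: float = 1.0
    hotspot_frac: float = 0.10
    hotspot_mult: float = 3.0
    stop_frac: float = 0.95
    seed: int = 0
    max_dup_retries: int = 30

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("sequence length L must be >= 1")
        if self.N < 1:
            raise ValueError("node cap N must be >= 1")
        if self.lambda_c <= 0 or self.lambda_m <= 0:
            raise ValueError("Poisson means must be positive")
        if not (0 < self.hotspot_frac < 1 and 0 < self.stop_frac < 1):
            raise ValueError("hotspot_frac and stop_frac must lie in (0,1)")


@dataclass
class SimTree:
    """Ground-truth simulated lineage: germline, hotspots, per-node
    mutation sets and the true parent-child edges."""

    germline: str
    hotspots: frozenset
    nodes: dict[int, frozenset]  # node_id -> {(position, base), ...}
    edges: list[tuple[int, int]]
    root_id: int = 0

    def sequence(self, node_id: int) -> str:
        seq = list(self.germline)
        for pos, base in self.nodes[node_id]:
            seq[pos] = base
        return "".join(seq)

    def edge_labels(self) -> set[tuple[str, str]]:
        """True directed edges labelled by node sequence."""
        return {(self.sequence(p), self.sequence(c)) for p, c in self.edges}

    def __len__(self) -> int:
        return len(self.nodes)


def simulate_germline(L: int, rng: np.random.Generator) -> str:
    """Uniform i.i.d. germline sequence over {A,C,G,T}."""
    if L < 1:
        raise ValueError("sequence length L must be >= 1")
    return "".join(rng.choice(_ALPHABET, size=L))


def _truncated_poisson(rng: np.random.Generator, lam: float) -> int:
    """Poisson redrawn until >= 1 (each child carries a new mutation)."""
    while True:
        k = int(rng.poisson(lam))
        if k >= 1:
            return k


def _draw_child(rng: np.random.Generator, germline: str,
                parent_mut: frozenset, weights: np.ndarray,
                lam_m: float) -> Optional[frozenset]:
    taken = {pos for pos, _ in parent_mut}
    free = np.array([i for i in range(len(germline)) if i not in taken])
    if free.size == 0:
        return None
    m = min(_truncated_poisson(rng, lam_m), free.size)
    w = weights[free]
    positions = rng.choice(free, size=m, replace=False, p=w / w.sum())
    new = set(parent_mut)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != germline[pos]]
        new.add((int(pos), alternatives[rng.integers(3)]))
    return frozenset(new)


def simulate_tree(params: SimParams) -> SimTree:
    """Grow one ground-truth lineage tree; deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    germline = simulate_germline(params.L, rng)
    n_hot = max(1, round(params.hotspot_frac * params.L))
    hotspots = frozenset(int(i) for i in
                         rng.choice(params.L, size=n_hot, replace=False))
    weights = np.where(np.isin(np.arange(params.L), sorted(hotspots)),
                       params.hotspot_mult, 1.0)

    nodes: dict[int, frozenset] = {0: frozenset()}
    seqs = {germline}
    edges: list[tuple[int, int]] = []
    queue: deque[int] = deque([0])
    stopped = params.N == 1
    while queue and not stopped:
        parent = queue.popleft()
        n_children = int(rng.poisson(params.lambda_c))
        for _ in range(n_children):
            child_mut = None
            for _ in range(params.max_dup_retries):
                cand = _draw_child(rng, germline, nodes[parent], weights,
                                   params.lambda_m)
                if cand is None:
                    break
                seq = _apply(germline, cand)
                if seq not in seqs:
                    child_mut, child_seq = cand, seq
                    break
            if child_mut is None:
                continue  # saturated or persistent duplicate: skip child
            node_id = len(nodes)
            nodes[node_id] = child_mut
            seqs.add(child_seq)
            edges.append((parent, node_id))
            queue.append(node_id)
            if (len(nodes) >= params.N
                    or len(child_mut) / params.L >= params.stop_frac):
                stopped = True
                break
    return SimTree(germline=germline, hotspots=hotspots, nodes=nodes,
                   edges=edges)


def _apply(germline: str, mutations: frozenset) -> str:
    seq = list(germline)
    for pos, base in mutations:
        seq[pos] = base
    return "".join(seq)


def sim_to_lineage(sim: SimTree) -> list[CloneNode]:
    """Adapter: one clonotype node per simulated node, with the whole
    sequence treated as a single CDR region, SHM = mutation fraction."""
    L = len(sim.germline)
    out = []
    for node_id, mut in sim.nodes.items():
        out.append(CloneNode(
            node_name=f"s{node_id}",
            clonotype_seq=sim.sequence(node_id),
            size=1,
            isotype_counts={},
            node_isotype="unknown",
            shm_rate=len(mut) / L,
            cdr_mutations=frozenset((SIM_REGION, pos, base)
                                    for pos, base in mut),
        ))
    return out


def write_sim_tree(sim: SimTree, fasta_path: str | Path,
                   edges_path: str | Path) -> None:
    """Write node sequences (germline first) as FASTA and the true edges
    as a two-column TSV."""
    with open(fasta_path, "w") as fh:
        for node_id in sim.nodes:
            fh.write(f">node{node_id}\n{sim.sequence(node_id)}\n")
    with open(edges_path, "w") as fh:
        fh.write("parent_id\tchild_id\n")
        for p, c in sim.edges:
            fh.write(f"node{p}\tnode{c}\n")
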