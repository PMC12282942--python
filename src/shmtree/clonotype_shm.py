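"""Clonotype nodes, somatic-hypermutation rates and CDR mutation sets.

A *clonotype* is a unique receptor sequence identity inside one lineage:
either the full V-region nucleotide sequence, or the concatenation of all
CDR nucleotide sequences ("full CDR").  Cells sharing a clonotype collapse
into one :class:`CloneNode`.  The SHM rate of a chain is the fraction of
mutated positions between its V-region alignment and the inferred germline;
CDR mutations are called positionwise against the germline inside each CDR
and identified by (region, position, observed base), so a different base at
the same site counts as a distinct mutation event.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

from .airr_io import Cell, ReceptorRecord
from .grouping import Lineage

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
_GAP_CHARS = ".-"

#: (region, 0-based position within the gapped region slice, observed base)
Mutation = tuple[str, int, str]
MutationSet = frozenset

HEAVY_CDR_REGIONS = ("cdrh1", "cdrh2", "cdrh3")
LIGHT_CDR_REGIONS = ("cdrl1", "cdrl2", "cdrl3")


class Member(NamedTuple):
    """Provenance of one cell/sequence collapsed into a clone node."""

    sequence_id: str
    cell_id: str
    isotype: str


@dataclass
class CloneNode:
    """A unique clonotype: sequence, abundance, isotype mix, SHM rate and
    the set of CDR mutations relative to the germline."""

    node_name: str
    clonotype_seq: str
    size: int
    isotype_counts: dict[str, int]
    node_isotype: str
    shm_rate: float
    cdr_mutations: MutationSet
    members: list[Member] = field(default_factory=list)
    cdr_seqs: dict[str, str] = field(default_factory=dict)
    is_dummy: bool = False

    @property
    def member_ids(self) -> list[str]:
        return [m.cell_id for m in self.members]


def compute_chain_shm(seq_align: str, germ_align: str) -> float:
    """Mutation fraction between a gapped V-region alignment and its
    germline counterpart.

    A position is comparable iff both characters are A/C/G/T; gaps, dots
    and ambiguity codes contribute to neither numerator nor denominator.
    Returns 0.0 when nothing is comparable.
    """
    if len(seq_align) != len(germ_align):
        raise ValueError("sequence and germline alignments differ in length")
    comparable = mismatches = 0
    for s, g in zip(seq_align.upper(), germ_align.upper()):
        if s in _BASES and g in _BASES:
            comparable += 1
            if s != g:
                mismatches += 1
    return mismatches / comparable if comparable else 0.0


def combine_shm(h: float, l: Optional[float], method: str = "mean") -> float:
    """Combine heavy- and light-chain SHM into one rate: ``heavy`` (hSHM
    alone), ``max``, or ``mean`` (the default elsewhere in the package)."""
    if method == "heavy":
        return h
    if l is None:
        raise ValueError(f"combine_shm method {method!r} requires a "
                         "light-chain SHM rate")
    if method == "max":
        return max(h, l)
    if method == "mean":
        return (h + l) / 2.0
    raise ValueError(f"unknown SHM combination method: {method!r}")


def degap(aligned: str) -> str:
    return "".join(c for c in aligned if c not in _GAP_CHARS)


def _alignment_index_map(aligned: str) -> list[int]:
    """Alignment coordinate of each ungapped position."""
    return [i for i, c in enumerate(aligned) if c not in _GAP_CHARS]


def _chain_cdr_mutations(rec: ReceptorRecord,
                         regions: tuple[str, str, str]) -> set[Mutation]:
    """Call mutations inside CDR1/2/3 of one chain.

    Each CDR field is located inside the ungapped sequence alignment and
    mapped back into alignment coordinates; positions are 0-based within
    the gapped CDR slice so heavy/light concatenation cannot shift them.
    """
    ungapped = degap(rec.sequence_alignment)
    idx_map = _alignment_index_map(rec.sequence_alignment)
    muts: set[Mutation] = set()
    for region, cdr in zip(regions, (rec.cdr1, rec.cdr2, rec.cdr3)):
        start = ungapped.find(cdr)
        if not cdr or start < 0:
            raise ValueError(
                f"CDR field for {region} not locatable inside the sequence "
                f"alignment of {rec.sequence_id}")
        a_start = idx_map[start]
        a_end = idx_map[start + len(cdr) - 1] + 1
        seq_slice = rec.sequence_alignment[a_start:a_end].upper()
        germ_slice = rec.germline_alignment[a_start:a_end].upper()
        for pos, (s, g) in enumerate(zip(seq_slice, germ_slice)):
            if s in _BASES and g in _BASES and s != g:
                muts.add((region, pos, s))
    return muts


def call_cdr_mutations(cell: Cell) -> MutationSet:
    """All CDR mutations of a cell (heavy chain, plus light if present)."""
    muts = _chain_cdr_mutations(cell.heavy, HEAVY_CDR_REGIONS)
    if cell.light is not None:
        muts |= _chain_cdr_mutations(cell.light, LIGHT_CDR_REGIONS)
    return frozenset(muts)


def _member_shm(cell: Cell, method: str) -> float:
    h = compute_chain_shm(cell.heavy.sequence_alignment,
                          cell.heavy.germline_alignment)
    if cell.light is None:
        # heavy-only input: hSHM is the only available rate
        return h
    l = compute_chain_shm(cell.light.sequence_alignment,
                          cell.light.germline_alignment)
    return combine_shm(h, l, method)


def clonotype_sequence(cell: Cell, definition: str) -> str:
    """The clonotype identity string of a cell under a node definition:
    ``vregion`` (ungapped V-region, heavy then light) or ``fullcdr``
    (concatenated CDR1+2+3 nucleotides, heavy then light)."""
    if definition == "vregion":
        seq = degap(cell.heavy.sequence_alignment)
        if cell.light is not None:
            seq += degap(cell.light.sequence_alignment)
        return seq
    if definition == "fullcdr":
        h = cell.heavy
        seq = h.cdr1 + h.cdr2 + h.cdr3
        if cell.light is not None:
            l = cell.light
            seq += l.cdr1 + l.cdr2 + l.cdr3
        return seq
    raise ValueError(f"unknown clonotype definition: {definition!r}")


def _majority_isotype(counts: Counter) -> str:
    total = sum(counts.values())
    for isotype, n in counts.most_common():
        if n * 2 > total:
            return isotype
        break
    return "mixed"


def _cdr_seq_map(cell: Cell) -> dict[str, str]:
    seqs = dict(zip(HEAVY_CDR_REGIONS,
                    (cell.heavy.cdr1, cell.heavy.cdr2, cell.heavy.cdr3)))
    if cell.light is not None:
        seqs.update(zip(LIGHT_CDR_REGIONS,
                        (cell.light.cdr1, cell.light.cdr2, cell.light.cdr3)))
    return seqs


def build_clonotypes(lineage: Lineage, definition: str = "vregion",
                     shm_method: str = "mean") -> list[CloneNode]:
    """Collapse lineage members into clonotype nodes.

    Node size is the member count; node SHM is the mean of member-level
    combined SHM rates (always computed on the V-region alignment,
    whichever clonotype definition is in force); node isotype is the
    strict-majority (>50 %) member isotype, else ``mixed``.  Cells whose
    CDR fields cannot be located in their alignment are dropped with a
    warning.
    """
    if not lineage.members:
        raise ValueError(f"lineage {lineage.lineage_id} is empty")
    groups: dict[str, list[tuple[Cell, float, MutationSet]]] = defaultdict(list)
    for cell in lineage.members:
        try:
            muts = call_cdr_mutations(cell)
        except ValueError as exc:
            logger.warning("dropping cell %s: %s", cell.cell_id, exc)
            continue
        seq = clonotype_sequence(cell, definition)
        groups[seq].append((cell, _member_shm(cell, shm_method), muts))

    nodes = []
    for i, seq in enumerate(sorted(groups)):
        entries = groups[seq]
        counts = Counter(cell.isotype for cell, _, _ in entries)
        members = sorted(
            Member(cell.heavy.sequence_id, cell.cell_id, cell.isotype)
            for cell, _, _ in entries)
        # a clonotype's CDRs are shared; take mutations/CDRs of the
        # lexicographically-first member for determinism
        first = min(entries, key=lambda e: e[0].heavy.sequence_id)
        nodes.append(CloneNode(
            node_name=f"c{i + 1}",
            clonotype_seq=seq,
            size=len(entries),
            isotype_counts=dict(counts),
            node_isotype=_majority_isotype(counts),
            shm_rate=sum(shm for _, shm, _ in entries) / len(entries),
            cdr_mutations=first[2],
            members=members,
            cdr_seqs=_cdr_seq_map(first[0]),
        ))
    return nodes
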