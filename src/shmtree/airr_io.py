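"""Reading, validation and filtering of AIRR rearrangement TSV files.

The AIRR Rearrangement schema (MiAIRR) is the community-standard
tab-separated format for annotated adaptive immune receptor sequences,
produced by annotators such as IgBLAST.  This module parses such files
into :class:`ReceptorRecord`/:class:`Cell` objects, pairs heavy and light
chains into cells for single-cell data, and writes the cell-to-node
mapping table for built lineage trees.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

#: Columns that must be present in an input rearrangement TSV.
REQUIRED_COLUMNS = (
    "sequence_id",
    "sequence",
    "productive",
    "locus",
    "v_call",
    "j_call",
    "sequence_alignment",
    "germline_alignment",
    "fwr1", "fwr1_aa",
    "cdr1", "cdr1_aa",
    "fwr2", "fwr2_aa",
    "cdr2", "cdr2_aa",
    "fwr3", "fwr3_aa",
    "cdr3", "cdr3_aa",
    "fwr4", "fwr4_aa",
)

#: Optional columns carried through when present.
OPTIONAL_COLUMNS = ("cell_id", "c_call")

ALLOWED_LOCI = frozenset({"IGH", "IGK", "IGL"})

_PRODUCTIVE_TRUE = frozenset({"T", "TRUE", "true"})
_PRODUCTIVE_FALSE = frozenset({"F", "FALSE", "false"})

#: Heavy-chain constant-region gene prefix -> isotype label.
_ISOTYPE_PREFIXES = (
    ("IGHM", "IgM"),
    ("IGHD", "IgD"),
    ("IGHG", "IgG"),
    ("IGHA", "IgA"),
    ("IGHE", "IgE"),
)

UNSWITCHED_ISOTYPES = frozenset({"IgM", "IgD"})


@dataclass
class ReceptorRecord:
    """One annotated BCR chain (a single AIRR rearrangement row)."""

    sequence_id: str
    locus: str
    v_call: str
    j_call: str
    productive: bool
    sequence: str
    sequence_alignment: str
    germline_alignment: str
    fwr1: str
    fwr2: str
    fwr3: str
    fwr4: str
    cdr1: str
    cdr2: str
    cdr3: str
    fwr1_aa: str = ""
    fwr2_aa: str = ""
    fwr3_aa: str = ""
    fwr4_aa: str = ""
    cdr1_aa: str = ""
    cdr2_aa: str = ""
    cdr3_aa: str = ""
    cell_id: Optional[str] = None
    c_call: Optional[str] = None


@dataclass
class Cell:
    """A B cell: one heavy chain and, in single-cell mode, one light chain."""

    cell_id: str
    heavy: ReceptorRecord
    light: Optional[ReceptorRecord] = None
    isotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.isotype == "unknown":
            self.isotype = isotype_from_c_call(self.heavy.c_call)


@dataclass
class Repertoire:
    """A collection of cells from one sample, in single-cell or bulk mode."""

    cells: list[Cell]
    mode: str  # "single_cell" | "bulk"
    sample_name: str = "sample"

    def __len__(self) -> int:
        return len(self.cells)


def isotype_from_c_call(c_call: Optional[str]) -> str:
    """Derive the isotype label (IgM/IgD/IgG/IgA/IgE) from a heavy-chain
    constant-region gene call; records without a recognizable call are
    ``unknown`` and treated as class-switched downstream."""
    if not c_call:
        return "unknown"
    for prefix, label in _ISOTYPE_PREFIXES:
        if c_call.upper().startswith(prefix):
            return label
    return "unknown"


def derive_cell_id(sequence_id: str) -> str:
    """Cell barcode fallback: the sequence_id up to its last underscore
    (10x-style ``<barcode>_contig_N`` naming)."""
    head, sep, _ = sequence_id.rpartition("_")
    return head if sep else sequence_id


def _parse_row(row: dict) -> Optional[ReceptorRecord]:
    prod_raw = row["productive"].strip()
    if prod_raw in _PRODUCTIVE_TRUE:
        productive = True
    elif prod_raw in _PRODUCTIVE_FALSE:
        productive = False
    else:
        logger.warning(
            "row %s rejected: unparsable productive value %r",
            row["sequence_id"], prod_raw)
        return None
    if len(row["sequence_alignment"]) != len(row["germline_alignment"]):
        logger.warning(
            "row %s rejected: sequence_alignment and germline_alignment "
            "lengths differ", row["sequence_id"])
        return None
    return ReceptorRecord(
        sequence_id=row["sequence_id"],
        locus=row["locus"],
        v_call=row["v_call"],
        j_call=row["j_call"],
        productive=productive,
        sequence=row["sequence"],
        sequence_alignment=row["sequence_alignment"],
        germline_alignment=row["germline_alignment"],
        fwr1=row["fwr1"], fwr2=row["fwr2"], fwr3=row["fwr3"], fwr4=row["fwr4"],
        cdr1=row["cdr1"], cdr2=row["cdr2"], cdr3=row["cdr3"],
        fwr1_aa=row["fwr1_aa"], fwr2_aa=row["fwr2_aa"],
        fwr3_aa=row["fwr3_aa"], fwr4_aa=row["fwr4_aa"],
        cdr1_aa=row["cdr1_aa"], cdr2_aa=row["cdr2_aa"], cdr3_aa=row["cdr3_aa"],
        cell_id=row.get("cell_id") or None,
        c_call=row.get("c_call") or None,
    )


def read_records(path: str | Path) -> list[ReceptorRecord]:
    """Parse an AIRR rearrangement TSV into receptor records.

    Raises ``ValueError`` naming the first missing required column.  Rows
    with unparsable ``productive`` values or unequal alignment lengths are
    rejected with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"required AIRR column missing: {col!r}")
    records = []
    for row in df.to_dict(orient="records"):
        rec = _parse_row(row)
        if rec is not None:
            records.append(rec)
    return records


def pair_cells(records: Iterable[ReceptorRecord]) -> list[Cell]:
    """Pair heavy and light chains into cells by cell barcode.

    Only cells with exactly one productive heavy (IGH) and exactly one
    productive light (IGK/IGL) chain are kept; ambiguous or incomplete
    cells are dropped with a logged count.
    """
    by_cell: dict[str, list[ReceptorRecord]] = defaultdict(list)
    for rec in records:
        cid = rec.cell_id or derive_cell_id(rec.sequence_id)
        by_cell[cid].append(rec)
    cells, n_dropped = [], 0
    for cid, recs in by_cell.items():
        heavies = [r for r in recs if r.productive and r.locus == "IGH"]
        lights = [r for r in recs
                  if r.productive and r.locus in ("IGK", "IGL")]
        if len(heavies) == 1 and len(lights) == 1:
            cells.append(Cell(cell_id=cid, heavy=heavies[0], light=lights[0]))
        else:
            n_dropped += 1
    if n_dropped:
        logger.warning("pair_cells: dropped %d cells without exactly one "
                       "productive heavy and one productive light chain",
                       n_dropped)
    return cells


def read_airr(path: str | Path, mode: str = "single_cell",
              sample_name: Optional[str] = None) -> Repertoire:
    """Read an AIRR rearrangement TSV into a :class:`Repertoire`.

    In bulk mode every IGH row becomes its own cell; in single-cell mode
    chains are paired by barcode via :func:`pair_cells`.
    """
    if mode not in ("single_cell", "bulk"):
        raise ValueError(f"unknown mode: {mode!r}")
    records = read_records(path)
    if sample_name is None:
        sample_name = Path(path).stem
    if mode == "bulk":
        n_light = sum(r.locus != "IGH" for r in records)
        if n_light:
            logger.warning("bulk mode: ignoring %d non-IGH rows", n_light)
        cells = [Cell(cell_id=r.cell_id or r.sequence_id, heavy=r)
                 for r in records if r.locus == "IGH"]
    else:
        cells = pair_cells(records)
    return Repertoire(cells=cells, mode=mode, sample_name=sample_name)


def _record_ok(rec: ReceptorRecord) -> bool:
    return (rec.productive and rec.locus in ALLOWED_LOCI
            and bool(rec.cdr1) and bool(rec.cdr2) and bool(rec.cdr3))


def filter_functional(repertoire: Repertoire) -> Repertoire:
    """Keep only cells whose chains are productive, on a recognized locus,
    and have non-empty CDR1/2/3.  Idempotent; never raises."""
    kept = []
    for cell in repertoire.cells:
        if not _record_ok(cell.heavy):
            continue
        if repertoire.mode == "single_cell":
            if cell.light is None or not _record_ok(cell.light):
                continue
        kept.append(cell)
    n_dropped = len(repertoire.cells) - len(kept)
    if n_dropped:
        logger.info("filter_functional: dropped %d of %d cells",
                    n_dropped, len(repertoire.cells))
    return replace(repertoire, cells=kept)


def write_airr(records: Iterable[ReceptorRecord], path: str | Path) -> None:
    """Write receptor records back to an AIRR rearrangement TSV with the
    required columns in canonical order (round-trips :func:`read_records`)."""
    rows = []
    has_cell = has_c = False
    for rec in records:
        row = {col: getattr(rec, col) for col in REQUIRED_COLUMNS
               if col != "productive"}
        row["productive"] = "T" if rec.productive else "F"
        if rec.cell_id is not None:
            row["cell_id"] = rec.cell_id
            has_cell = True
        if rec.c_call is not None:
            row["c_call"] = rec.c_call
            has_c = True
        rows.append(row)
    cols = list(REQUIRED_COLUMNS)
    if has_cell:
        cols.append("cell_id")
    if has_c:
        cols.append("c_call")
    df = pd.DataFrame(rows, columns=cols).fillna("")
    df.to_csv(path, sep="\t", index=False)


NODE_TABLE_COLUMNS = (
    "sequence_id", "cell_id", "sample", "lineage_id", "tree_name",
    "node_name", "node_size", "isotype", "shm_rate", "parent_node",
    "edge_weight",
)


def write_node_table(trees, path: str | Path) -> None:
    """Write the cell-to-node mapping CSV for a collection of built lineage
    trees: one row per member cell/sequence of every clonotype node."""
    rows = []
    for tree in trees:
        parent_of = {e.child: (e.parent, e.weight) for e in tree.edges}
        for name in tree.node_order():
            node = tree.nodes[name]
            parent, weight = parent_of.get(name, ("", ""))
            for member in node.members:
                rows.append({
                    "sequence_id": member.sequence_id,
                    "cell_id": member.cell_id,
                    "sample": tree.sample,
                    "lineage_id": tree.lineage_id,
                    "tree_name": tree.tree_name,
                    "node_name": name,
                    "node_size": node.size,
                    "isotype": member.isotype,
                    "shm_rate": node.shm_rate,
                    "parent_node": parent,
                    "edge_weight": weight,
                })
    pd.DataFrame(rows, columns=NODE_TABLE_COLUMNS).to_csv(path, index=False)
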