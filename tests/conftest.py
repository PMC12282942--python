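"""Shared fixtures: hand-built AIRR rearrangement rows with a known
germline, so mutation sets and SHM rates are derivable by inspection."""

from __future__ import annotations

import pandas as pd
import pytest
from Bio.Seq import Seq

# Germline V-region segments (all CDR lengths divisible by 3 so the
# amino-acid fields are well defined).
HEAVY_SEGMENTS = {
    "fwr1": "TCTGGCGGA",
    "cdr1": "TGGTAC",
    "fwr2": "GGCCTTACC",
    "cdr2": "AGCATC",
    "fwr3": "ACCGTAGCA",
    "cdr3": "TGCGCAAGA",
    "fwr4": "TGGGGCCAA",
}
LIGHT_SEGMENTS = {
    "fwr1": "GACATCCAG",
    "cdr1": "CAGAGC",
    "fwr2": "TTAGCCTGG",
    "cdr2": "GCTGCA",
    "fwr3": "GGGACAGAT",
    "cdr3": "CAACAGTAT",
    "fwr4": "TTCGGCGGA",
}
SEGMENT_ORDER = ("fwr1", "cdr1", "fwr2", "cdr2", "fwr3", "cdr3", "fwr4")


def airr_row(sequence_id: str, locus: str = "IGH",
             v_call: str = "IGHV4-4*02", j_call: str = "IGHJ4*02",
             c_call: str = "IGHG1", productive: str = "T",
             mutations: dict | None = None,
             cell_id: str | None = None) -> dict:
    """One AIRR TSV row from the germline plus point substitutions.

    ``mutations`` maps a segment name ("cdr3", "fwr1", ...) to
    {position_within_segment: new_base}.
    """
    segments = dict(HEAVY_SEGMENTS if locus == "IGH" else LIGHT_SEGMENTS)
    germline = "".join(segments[s] for s in SEGMENT_ORDER)
    for seg, subs in (mutations or {}).items():
        chars = list(segments[seg])
        for pos, base in subs.items():
            chars[pos] = base
        segments[seg] = "".join(chars)
    sequence = "".join(segments[s] for s in SEGMENT_ORDER)
    row = {
        "sequence_id": sequence_id,
        "sequence": sequence,
        "productive": productive,
        "locus": locus,
        "v_call": v_call,
        "j_call": j_call,
        "sequence_alignment": sequence,
        "germline_alignment": germline,
    }
    for seg in SEGMENT_ORDER:
        row[seg] = segments[seg]
        row[f"{seg}_aa"] = str(Seq(segments[seg]).translate())
    if cell_id is not None:
        row["cell_id"] = cell_id
    row["c_call"] = c_call
    return row


def light_row(sequence_id: str, cell_id: str, mutations: dict | None = None,
              v_call: str = "IGKV1D-39*01", productive: str = "T") -> dict:
    return airr_row(sequence_id, locus="IGK", v_call=v_call,
                    j_call="IGKJ1*01", c_call="", productive=productive,
                    mutations=mutations, cell_id=cell_id)


def write_airr_tsv(rows: list[dict], path) -> str:
    cols = list(rows[0]) if rows else [
        "sequence_id", "sequence", "productive", "locus", "v_call",
        "j_call", "sequence_alignment", "germline_alignment",
        "fwr1", "fwr1_aa", "cdr1", "cdr1_aa", "fwr2", "fwr2_aa",
        "cdr2", "cdr2_aa", "fwr3", "fwr3_aa", "cdr3", "cdr3_aa",
        "fwr4", "fwr4_aa"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return str(path)


@pytest.fixture
def bulk_tsv(tmp_path):
    """Bulk repertoire: one lineage of three heavy chains accumulating
    CDR3 mutations (germline-identical, +1, +2), plus one unproductive
    row and one separate naive lineage with a different V gene."""
    rows = [
        airr_row("seq1", c_call="IGHM"),
        airr_row("seq2", mutations={"cdr3": {2: "T"}}),
        airr_row("seq3", mutations={"cdr3": {2: "T", 4: "A"}}),
        airr_row("seq4", productive="F"),
        airr_row("seq5", v_call="IGHV1-2*02", c_call="IGHM"),
    ]
    return write_airr_tsv(rows, tmp_path / "bulk.tsv")


@pytest.fixture
def paired_tsv(tmp_path):
    """Single-cell repertoire: three paired cells of one lineage with
    increasing heavy-chain CDR3 mutation loads."""
    rows = []
    for i, muts in enumerate(({}, {"cdr3": {2: "T"}},
                              {"cdr3": {2: "T", 4: "A"}}), start=1):
        cid = f"cell{i}"
        rows.append(airr_row(f"{cid}_contig_1", cell_id=cid,
                             mutations=muts,
                             c_call="IGHM" if i == 1 else "IGHG1"))
        rows.append(light_row(f"{cid}_contig_2", cell_id=cid))
    return write_airr_tsv(rows, tmp_path / "paired.tsv")
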