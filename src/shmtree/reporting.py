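"""End-to-end repertoire analysis: configuration, pipeline and exports.

Runs the full chain — read, filter, group, collapse to clonotypes, build
SHM-ordered inheritance trees — and writes the output folder: per-lineage
tree files (Graphviz DOT plus machine-readable JSON), the cell-to-node
mapping CSV, branch logo matrices as TSV, and the lineage-statistics
summary.  Figure rendering (PNG logos/summary) is optional and gated on
matplotlib being available.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import airr_io, grouping, lineage_analysis
from .clonotype_shm import CloneNode, build_clonotypes
from .inheritance_tree import LineageTree, build_tree
from .lineage_analysis import (DEFAULT_D_MIN, DEFAULT_DEPTH_MIN,
                               DEFAULT_S_MIN, DEFAULT_W_MAX, find_branches,
                               lineage_stats, logo_matrix,
                               summarize_repertoire)

logger = logging.getLogger(__name__)

_ISOTYPE_LETTER = {"IgA": "A", "IgD": "D", "IgE": "E", "IgG": "G",
                   "IgM": "M", "unknown": "U"}

#: Node shape by isotype: triangle for unswitched IgM/IgD, circle for IgG,
#: rectangle for IgA.
_ISOTYPE_SHAPE = {"IgM": "triangle", "IgD": "triangle", "IgG": "circle",
                  "IgA": "box", "dummy": "diamond"}


@dataclass
class RunConfig:
    """Pipeline configuration with the package defaults."""

    input_path: str
    output_dir: str
    mode: str = "single_cell"            # single_cell | bulk
    grouping: str = "strict"             # strict | loose
    clonotype: str = "vregion"           # vregion | fullcdr
    shm: str = "mean"                    # heavy | max | mean
    depth_min: int = DEFAULT_DEPTH_MIN
    w_max: float = DEFAULT_W_MAX
    d_min: int = DEFAULT_D_MIN
    s_min: int = DEFAULT_S_MIN
    sample_name: Optional[str] = None
    emit_all_trees: bool = False
    render: bool = False
    seed: int = 0


def isotype_count_string(isotype_counts: dict[str, int]) -> str:
    """Isotype annotation of a node, e.g. ``G2`` (two IgG cells) or
    ``A1G1`` (one IgA plus one IgG); letters in alphabetical order with
    explicit counts."""
    parts = sorted((_ISOTYPE_LETTER.get(iso, "U"), n)
                   for iso, n in isotype_counts.items() if n)
    return "".join(f"{letter}{n}" for letter, n in parts)


def format_shm(shm: float) -> str:
    """SHM rate in scientific notation with 3 decimals (e.g. 4.594e-02)."""
    return f"{shm:.3e}"


def annotate_node_label(node: CloneNode) -> str:
    """Full node annotation: name, isotype-count string, SHM rate."""
    iso = "dummy" if node.is_dummy else isotype_count_string(
        node.isotype_counts)
    return f"{node.node_name} | {iso} | {format_shm(node.shm_rate)}"


def make_tree_name(sample: str, key: grouping.LineageKey) -> str:
    """Tree naming convention: sample, VH gene, VL gene, then CDR lengths
    in the order CDRH1, CDRL1, CDRH2, CDRL2, CDRH3, CDRL3."""
    parts = [sample, key.v_heavy]
    h = key.cdr_lengths[:3]
    if key.v_light is not None:
        l = key.cdr_lengths[3:]
        parts.append(key.v_light)
        lengths = [h[0], l[0], h[1], l[1], h[2], l[2]]
    else:
        lengths = list(h)
    return "_".join(parts + [str(n) for n in lengths])


def tree_to_dot(tree: LineageTree) -> str:
    """Graphviz DOT rendering: shape by isotype, node area proportional
    to size, edges labelled with the normalized edit distance to three
    significant digits."""
    lines = [f'digraph "{tree.tree_name}" {{', "  rankdir=TB;"]
    for name in tree.node_order():
        node = tree.nodes[name]
        shape = _ISOTYPE_SHAPE.get(node.node_isotype, "ellipse")
        width = 0.5 * math.sqrt(max(node.size, 1))
        lines.append(
            f'  "{name}" [label="{annotate_node_label(node)}", '
            f'shape={shape}, width={width:.2f}, fixedsize=false];')
    for e in tree.edges:
        style = ', style=dashed' if e.fallback else ""
        lines.append(f'  "{e.parent}" -> "{e.child}" '
                     f'[label="{e.weight:.3g}"{style}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def tree_to_json(tree: LineageTree) -> dict:
    """Machine-readable twin of the DOT output."""
    return {
        "tree_name": tree.tree_name,
        "lineage_id": tree.lineage_id,
        "sample": tree.sample,
        "root": tree.root,
        "nodes": [{
            "name": name,
            "size": n.size,
            "isotype": n.node_isotype,
            "isotype_counts": n.isotype_counts,
            "shm_rate": n.shm_rate,
            "is_dummy": n.is_dummy,
            "clonotype_seq": n.clonotype_seq,
            "members": [m._asdict() for m in n.members],
        } for name, n in ((name, tree.nodes[name])
                          for name in tree.node_order())],
        "edges": [{"parent": e.parent, "child": e.child,
                   "weight": e.weight, "fallback": e.fallback}
                  for e in tree.edges],
    }


def build_repertoire_trees(config: RunConfig) -> list[LineageTree]:
    """Read, filter, group and build one tree per lineage."""
    rep = airr_io.read_airr(config.input_path, mode=config.mode,
                            sample_name=config.sample_name)
    rep = airr_io.filter_functional(rep)
    lineages = grouping.group_lineages(rep, criteria=config.grouping)
    trees = []
    for lineage in lineages:
        try:
            nodes = build_clonotypes(lineage, definition=config.clonotype,
                                     shm_method=config.shm)
            if not nodes:
                continue
            tree = build_tree(nodes,
                              tree_name=make_tree_name(rep.sample_name,
                                                       lineage.key),
                              lineage_id=lineage.lineage_id,
                              sample=rep.sample_name)
        except ValueError as exc:
            logger.warning("skipping lineage %s: %s",
                           lineage.lineage_id, exc)
            continue
        trees.append(tree)
    return trees


def run_repertoire(config: RunConfig) -> dict:
    """Run the full pipeline and write the output folder.

    Returns a small manifest of what was written.  Deterministic for a
    fixed input and configuration.
    """
    out = Path(config.output_dir)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    (out / "logos").mkdir(exist_ok=True)
    trees = build_repertoire_trees(config)
    if not trees:
        logger.warning("empty repertoire after filtering; writing empty "
                       "outputs")

    airr_io.write_node_table(trees, out / "node_table.csv")

    stats = [lineage_stats(t) for t in trees]
    summary = summarize_repertoire(stats, depth_min=config.depth_min)
    summary.per_lineage.to_csv(out / "lineage_stats.tsv", sep="\t",
                               index=False)
    dist_rows = [{"statistic": stat, "value": str(idx), "n_lineages": int(n)}
                 for stat, series in summary.distributions.items()
                 for idx, n in series.items()]
    pd.DataFrame(dist_rows,
                 columns=["statistic", "value", "n_lineages"]).to_csv(
        out / "summary_distributions.tsv", sep="\t", index=False)

    n_tree_files = n_logos = 0
    for tree in trees:
        depth = lineage_analysis.tree_depth(tree)
        if depth < config.depth_min and not config.emit_all_trees:
            continue
        (out / "trees" / f"{tree.tree_name}.dot").write_text(
            tree_to_dot(tree))
        (out / "trees" / f"{tree.tree_name}.json").write_text(
            json.dumps(tree_to_json(tree), indent=1))
        n_tree_files += 1
        for b_idx, branch in enumerate(
                find_branches(tree, w_max=config.w_max,
                              d_min=config.d_min, s_min=config.s_min),
                start=1):
            for level in ("nt", "aa"):
                try:
                    pfm = logo_matrix(branch, tree.nodes, level=level)
                except ValueError as exc:
                    logger.warning("no %s logo for branch %d of %s: %s",
                                   level, b_idx, tree.tree_name, exc)
                    continue
                logo_path = (out / "logos" /
                             f"{tree.tree_name}_branch{b_idx}_{level}.tsv")
                pfm.frequencies.to_csv(logo_path, sep="\t")
                n_logos += 1
                if config.render:
                    _render_logo(pfm, logo_path.with_suffix(".png"))
    if config.render:
        _render_summary(summary, out / "summary.png")
    return {"n_lineages": len(trees), "n_tree_files": n_tree_files,
            "n_logos": n_logos, "n_deep": summary.n_deep,
            "output_dir": str(out)}


def _render_logo(pfm, path) -> None:  # pragma: no cover - optional plots
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    ax = pfm.frequencies.plot.bar(stacked=True, figsize=(10, 2.5),
                                  width=0.9, legend=True)
    ax.set_xlabel("position")
    ax.set_ylabel("frequency")
    ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(ax.figure)


def _render_summary(summary, path) -> None:  # pragma: no cover
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, (stat, series) in zip(axes.ravel(),
                                  summary.distributions.items()):
        series.plot.bar(ax=ax)
        ax.set_title(stat)
        ax.set_ylabel("lineages")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
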