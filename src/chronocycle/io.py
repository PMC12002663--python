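"""Lineage-tree import/export (CSV and Newick) and deterministic fixtures."""

from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd

from .lineage import CellRecord, LineageTree, SimulationRun

__all__ = [
    "tree_to_frame",
    "tree_from_frame",
    "export_tree",
    "import_tree_csv",
    "tree_to_newick",
    "make_fixtures",
]


def tree_to_frame(tree: LineageTree) -> pd.DataFrame:
    """Attribute table with one row per cell."""
    rows = []
    for rec in sorted(tree.cells(), key=lambda r: r.cell_id):
        rows.append({
            "cell_id": rec.cell_id,
            "parent_id": -1 if rec.parent_id is None else rec.parent_id,
            "lineage_id": rec.lineage_id,
            "birth_time": rec.birth_time,
            "division_time": np.nan if rec.division_time is None else rec.division_time,
            "IMT": np.nan if rec.IMT is None else rec.IMT,
            "generation": rec.generation,
            "censored": rec.censored,
        })
    return pd.DataFrame(rows)


def tree_from_frame(df: pd.DataFrame) -> LineageTree:
    tree = LineageTree()
    for row in df.sort_values("cell_id").itertuples():
        rec = CellRecord(
            cell_id=int(row.cell_id),
            lineage_id=int(row.lineage_id),
            parent_id=None if row.parent_id < 0 else int(row.parent_id),
            birth_time=float(row.birth_time),
            generation=int(row.generation),
            birth_state=np.empty(0),
            division_time=None if pd.isna(row.division_time) else float(row.division_time),
            censored=bool(row.censored),
        )
        tree.add_cell(rec)
    return tree


def _newick_node(tree: LineageTree, cid: int) -> str:
    rec = tree.record(cid)
    label = str(cid) + ("*" if rec.censored else "")
    length = rec.IMT
    if length is None:  # censored: time observed until the stop
        length = 0.0
    kids = sorted(tree.children(cid))
    if kids:
        inner = ",".join(_newick_node(tree, k) for k in kids)
        return f"({inner}){label}:{length:.6g}"
    return f"{label}:{length:.6g}"


def tree_to_newick(tree: LineageTree) -> str:
    """One Newick record per lineage; IMT as branch length, censored leaves
    flagged with a ``*`` suffix."""
    return "\n".join(_newick_node(tree, r) + ";" for r in sorted(tree.roots()))


def export_tree(tree_or_run, path, format: str = "csv"):
    tree = tree_or_run.tree if isinstance(tree_or_run, SimulationRun) else tree_or_run
    if format == "csv":
        tree_to_frame(tree).to_csv(path, index=False)
    elif format == "newick":
        with open(path, "w") as fh:
            fh.write(tree_to_newick(tree) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'newick'")


def import_tree_csv(path) -> LineageTree:
    return tree_from_frame(pd.read_csv(path))


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------


def _hand_tree(imts: dict, censored=()) -> LineageTree:
    """Complete binary tree from a dict {cell_id: IMT}; ids are 1-based in
    breadth-first order (1 -> 2,3 -> 4..7 -> ...)."""
    tree = LineageTree()
    ids = sorted(imts)
    birth = {1: 0.0}
    for cid in ids:
        if cid not in birth:  # parent never divided: cell does not exist
            continue
        parent = None if cid == 1 else cid // 2
        gen = int(np.log2(cid))
        b = birth[cid]
        rec = CellRecord(cell_id=cid, lineage_id=0, parent_id=parent,
                         birth_time=b, generation=gen,
                         birth_state=np.empty(0))
        if cid not in censored:
            rec.division_time = b + imts[cid]
            rec.censored = False
            birth[2 * cid] = rec.division_time
            birth[2 * cid + 1] = rec.division_time
        tree.add_cell(rec)
    return tree


def make_fixtures(seed: int = 0) -> dict:
    """Deterministic test inputs with documented expected values.

    * ``tree3`` — a complete 3-generation pedigree (cells 1..15; the seven
      inner cells 1..7 divided, the eight leaves are censored).  Counting
      only pairs in which both members have a defined cycle time (divided,
      non-root), it contains 6 mother-daughter, 3 sister, 4 cousin and
      4 grandmother pairs.
    * ``tree_partial`` — same shape but only cells 1, 2, 3 divided:
      2 mother-daughter pairs, 1 sister pair, 0 cousins.
    * ``tone`` — cos(2*pi*t/24) sampled at 0.1 h over 240 h: dominant
      frequency 1/24 h^-1, amplitude 1.
    * ``exp_counts`` — 100*2^(t/20) on t = 0,10,...,100: growth rate
      ln2/20 per hour with a perfect log-linear fit.
    """
    rng = np.random.default_rng(seed)
    imts = {i: float(v) for i, v in
            zip(range(1, 16), 10 + 10 * rng.random(15))}
    tree3 = _hand_tree(imts, censored=tuple(range(8, 16)))
    tree_partial = _hand_tree(imts, censored=tuple(range(4, 16)))
    t = np.arange(0.0, 240.0, 0.1)
    tone = (t, np.cos(2 * np.pi * t / 24.0))
    tt = np.arange(0.0, 101.0, 10.0)
    exp_counts = (tt, 100.0 * 2 ** (tt / 20.0))
    return {
        "tree3": tree3,
        "tree3_expected_pairs": {"mother_daughter": 6, "sister": 3,
                                 "cousin": 4, "grandmother": 4},
        "tree_partial": tree_partial,
        "tree_partial_expected_pairs": {"mother_daughter": 2, "sister": 1,
                                        "cousin": 0},
        "tone": tone,
        "tone_expected": {"frequency": 1.0 / 24.0, "amplitude": 1.0},
        "exp_counts": exp_counts,
        "exp_counts_expected": {"lam": np.log(2) / 20.0, "r_squared": 1.0},
    }
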