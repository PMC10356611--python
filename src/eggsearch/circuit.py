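"""Recurrent-motif queries over a connectome synapse table.

The input is a directed, weighted cell-to-cell connection list (pre cell,
post cell, synapse count) with per-cell class and hemisphere labels, the
shape produced by neuPrint-style connectome exports.  Queries follow the
conventions used for dense fly connectome analysis: duplicate rows for the
same (pre, post) pair are summed before a synapse-count threshold (ten by
default) is applied; reciprocal pairs are cells connected strongly in both
directions; and the recurrent motif of interest is a *single-intermediary
cross-hemisphere loop* — one cell that receives from and projects back to
a seed cell class on both sides of the brain, every edge meeting the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MotifResult",
    "aggregate_table",
    "filter_edges",
    "reciprocal_pairs",
    "single_intermediary_loops",
]

_COLUMNS = [
    "pre_id",
    "post_id",
    "pre_class",
    "post_class",
    "pre_side",
    "post_side",
    "n_synapses",
]


@dataclass(frozen=True)
class MotifResult:
    """One single-intermediary loop: the cell, its class/side and evidence."""

    intermediary_id: str
    intermediary_class: str
    intermediary_side: str
    supporting_edges: pd.DataFrame
    seeds_received_from: frozenset
    seeds_projected_to: frozenset


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"synapse table missing columns: {missing}")
    if (table["n_synapses"] < 1).any():
        raise ValueError("n_synapses must be >= 1")
    for role in ("pre", "post"):
        grp = table.groupby(f"{role}_id")[[f"{role}_class", f"{role}_side"]].nunique()
        bad = grp[(grp > 1).any(axis=1)]
        if len(bad):
            raise ValueError(
                f"cells with inconsistent class/side labels: {list(bad.index)[:5]}"
            )


def aggregate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Sum synapse counts over duplicate (pre, post) rows."""
    _check_table(table)
    return (
        table.groupby(
            ["pre_id", "post_id", "pre_class", "post_class", "pre_side", "post_side"],
            as_index=False,
        )["n_synapses"]
        .sum()
    )


def filter_edges(table: pd.DataFrame, min_synapses: int = 10) -> pd.DataFrame:
    """Edges with at least ``min_synapses`` after duplicate aggregation."""
    agg = aggregate_table(table)
    return agg[agg["n_synapses"] >= min_synapses].reset_index(drop=True)


def reciprocal_pairs(
    edges: pd.DataFrame, class_filter: str | None = None
) -> list[tuple[str, str]]:
    """Unordered cell pairs connected in both directions.

    ``class_filter`` optionally keeps only pairs in which at least one
    member belongs to the given class.  ``edges`` should already be
    thresholded (see :func:`filter_edges`).
    """
    pairs = set(zip(edges["pre_id"], edges["post_id"]))
    classes = dict(zip(edges["pre_id"], edges["pre_class"]))
    classes.update(zip(edges["post_id"], edges["post_class"]))
    out = set()
    for a, b in pairs:
        if a < b and (b, a) in pairs:
            if class_filter is None or class_filter in (classes[a], classes[b]):
                out.add((a, b))
    return sorted(out)


def single_intermediary_loops(
    edges: pd.DataFrame,
    seed_class: str,
    require_both_directions: bool = True,
) -> list[MotifResult]:
    """Cells that interconnect a seed class across hemispheres by themselves.

    A cell ``x`` (of any non-seed class) qualifies when thresholded edges
    exist from a left-side seed cell into ``x`` and from ``x`` onto a
    right-side seed cell, *and* from a right-side seed cell into ``x`` and
    from ``x`` onto a left-side seed cell — i.e. ``x`` alone carries
    seed-class signals across the midline in both directions.  The
    intermediary may receive from and project to different individual
    seed cells.  With ``require_both_directions=False`` a single
    cross-hemisphere chain (seed_L -> x -> seed_R, or the mirror image)
    suffices.

    Raises ``ValueError`` when the seed class is absent from the table.
    """
    seeds_pre = edges["pre_class"] == seed_class
    seeds_post = edges["post_class"] == seed_class
    if not (seeds_pre.any() or seeds_post.any()):
        raise ValueError(f"seed class {seed_class!r} absent from the edge table")

    info: dict[str, tuple[str, str]] = {}
    for role in ("pre", "post"):
        for cid, cls, side in zip(
            edges[f"{role}_id"], edges[f"{role}_class"], edges[f"{role}_side"]
        ):
            info[str(cid)] = (str(cls), str(side))

    inputs: dict[str, set[tuple[str, str]]] = {}
    outputs: dict[str, set[tuple[str, str]]] = {}
    for _, row in edges.iterrows():
        pre, post = str(row["pre_id"]), str(row["post_id"])
        if row["pre_class"] == seed_class and row["post_class"] != seed_class:
            inputs.setdefault(post, set()).add((pre, str(row["pre_side"])))
        if row["post_class"] == seed_class and row["pre_class"] != seed_class:
            outputs.setdefault(pre, set()).add((post, str(row["post_side"])))

    results = []
    for x in sorted(set(inputs) & set(outputs)):
        in_sides = {s for _, s in inputs[x]}
        out_sides = {s for _, s in outputs[x]}
        lr = ("L" in in_sides and "R" in out_sides)
        rl = ("R" in in_sides and "L" in out_sides)
        ok = (lr and rl) if require_both_directions else (lr or rl)
        if not ok:
            continue
        seed_ids = {c for c, _ in inputs[x]} | {c for c, _ in outputs[x]}
        support = edges[
            ((edges["pre_id"] == x) & edges["post_id"].isin(seed_ids))
            | ((edges["post_id"] == x) & edges["pre_id"].isin(seed_ids))
        ].reset_index(drop=True)
        cls, side = info[x]
        results.append(
            MotifResult(
                intermediary_id=x,
                intermediary_class=cls,
                intermediary_side=side,
                supporting_edges=support,
                seeds_received_from=frozenset(c for c, _ in inputs[x]),
                seeds_projected_to=frozenset(c for c, _ in outputs[x]),
            )
        )
    return results
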