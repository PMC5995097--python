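"""Per-branch morphology at the segment, path and subtree levels.

A branch can be characterised at three nested scales:

* **segment** -- the values measured directly on the branch itself.
  Surface area and volume treat the segment as a cylinder of basal
  diameter D and length L: SA = pi*D*L, V = pi*(D/2)^2*L.
* **path** -- the branch plus the longest continuous chain of distal
  branches: at every node the chain follows the child whose own path
  length is maximal.  Length, mass, surface area and volume are summed
  along that chain; the diameter stays the branch's own basal diameter.
* **subtree** -- the branch plus *all* distal branches; additive
  quantities are summed over the whole subtree, diameter again stays
  the branch's own.

Path selection maximises cumulative length only (ties broken by larger
child diameter, then lexicographically smallest branch id, so repeated
runs are identical); mass, surface area and volume are then summed along
that length-maximal chain.  A missing mass anywhere in a chain or
subtree makes the aggregate mass missing (NaN) rather than silently
zero-filled.

Twigs are excluded from every level by default, matching the main
analysis; ``include_twigs=True`` keeps them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .architecture import BranchRecord, TreeArchitecture

__all__ = [
    "LEVELS",
    "METRIC_NAMES",
    "BranchMetrics",
    "segment_geometry",
    "path_metrics",
    "subtree_metrics",
    "tree_metrics",
    "metrics_table",
]

logger = logging.getLogger(__name__)

LEVELS = ("segment", "path", "subtree")
#: additive quantities summed along paths / over subtrees
METRIC_NAMES = ("length", "mass", "surface_area", "volume")


@dataclass(frozen=True)
class BranchMetrics:
    """Morphological values for one branch at one classification level.

    ``diameter`` is always the branch's own measured basal diameter;
    ``mass`` is NaN when any contributing record lacks a measurement.
    """

    branch_id: str
    level: str
    diameter: float
    length: float
    mass: float
    surface_area: float
    volume: float


def segment_geometry(record: BranchRecord) -> BranchMetrics:
    """Cylinder geometry of a single segment: SA = pi*D*L, V = pi*(D/2)^2*L."""
    d, ln = record.diameter, record.length
    return BranchMetrics(
        branch_id=record.branch_id,
        level="segment",
        diameter=d,
        length=ln,
        mass=math.nan if record.mass is None else record.mass,
        surface_area=math.pi * d * ln,
        volume=math.pi * (d / 2.0) ** 2 * ln,
    )


def _working_ids(tree: TreeArchitecture, include_twigs: bool) -> list[str]:
    """Branch ids retained for analysis, in preorder.

    Excluding a twig excludes its (rare) descendants too, so the retained
    set is always a connected rooted subtree.
    """
    keep: list[str] = []
    dropped = 0
    stack = [tree.root_id]
    while stack:
        b = stack.pop()
        rec = tree.record(b)
        if rec.is_twig and not include_twigs and not rec.is_root:
            dropped += 1 + len(tree.descendant_ids(b))
            continue
        keep.append(b)
        stack.extend(tree.children(b))
    if dropped:
        logger.info("tree %s: excluded %d twig record(s) from aggregates",
                    tree.tree_id, dropped)
    return keep


def _postorder(tree: TreeArchitecture, keep: set[str]) -> list[str]:
    order: list[str] = []
    stack: list[tuple[str, bool]] = [(tree.root_id, False)]
    while stack:
        b, expanded = stack.pop()
        if b not in keep:
            continue
        if expanded:
            order.append(b)
        else:
            stack.append((b, True))
            stack.extend((c, False) for c in tree.children(b))
    return order


def _segment_frame(tree: TreeArchitecture, keep: Sequence[str]) -> pd.DataFrame:
    rows = [segment_geometry(tree.record(b)) for b in keep]
    return pd.DataFrame({
        "branch_id": [m.branch_id for m in rows],
        "diameter": [m.diameter for m in rows],
        "length": [m.length for m in rows],
        "mass": [m.mass for m in rows],
        "surface_area": [m.surface_area for m in rows],
        "volume": [m.volume for m in rows],
    }).set_index("branch_id")


def path_metrics(tree: TreeArchitecture, include_twigs: bool = False) -> pd.DataFrame:
    """Path-level metrics for every retained branch (index = branch_id)."""
    keep = _working_ids(tree, include_twigs)
    seg = _segment_frame(tree, keep)
    return _path_from_segments(tree, seg)


def _path_from_segments(tree: TreeArchitecture, seg: pd.DataFrame) -> pd.DataFrame:
    keep = set(seg.index)
    path = {m: {} for m in METRIC_NAMES}
    # post-order so every child is resolved before its parent
    for b in _postorder(tree, keep):
        kids = [c for c in tree.children(b) if c in keep]
        if kids:
            # longest path; ties -> larger diameter, then smallest id
            chosen = sorted(
                kids,
                key=lambda c: (-path["length"][c], -seg.at[c, "diameter"], c),
            )[0]
            for m in METRIC_NAMES:
                path[m][b] = seg.at[b, m] + path[m][chosen]
        else:
            for m in METRIC_NAMES:
                path[m][b] = seg.at[b, m]
    out = pd.DataFrame({"diameter": seg["diameter"]})
    for m in METRIC_NAMES:
        out[m] = pd.Series(path[m])
    return out[["diameter", *METRIC_NAMES]]


def subtree_metrics(tree: TreeArchitecture, include_twigs: bool = False) -> pd.DataFrame:
    """Subtree-level metrics for every retained branch (index = branch_id)."""
    keep = _working_ids(tree, include_twigs)
    seg = _segment_frame(tree, keep)
    return _subtree_from_segments(tree, seg)


def _subtree_from_segments(tree: TreeArchitecture, seg: pd.DataFrame) -> pd.DataFrame:
    keep = set(seg.index)
    sub = {m: {} for m in METRIC_NAMES}
    for b in _postorder(tree, keep):
        kids = [c for c in tree.children(b) if c in keep]
        for m in METRIC_NAMES:
            # plain sum so a NaN (missing mass) propagates
            sub[m][b] = seg.at[b, m] + sum(sub[m][c] for c in kids)
    out = pd.DataFrame({"diameter": seg["diameter"]})
    for m in METRIC_NAMES:
        out[m] = pd.Series(sub[m])
    return out[["diameter", *METRIC_NAMES]]


def tree_metrics(tree: TreeArchitecture,
                 levels: Iterable[str] = LEVELS,
                 include_twigs: bool = False) -> pd.DataFrame:
    """Long-format metrics for one tree: one row per (branch, level)."""
    levels = list(levels)
    unknown = set(levels) - set(LEVELS)
    if unknown:
        raise ValueError(f"unknown level(s) {sorted(unknown)}; choose from {LEVELS}")
    keep = _working_ids(tree, include_twigs)
    seg = _segment_frame(tree, keep)
    frames = {"segment": seg,
              "path": _path_from_segments(tree, seg),
              "subtree": _subtree_from_segments(tree, seg)}
    chunks = []
    for level in levels:
        f = frames[level].copy()
        f.insert(0, "level", level)
        chunks.append(f.reset_index())
    out = pd.concat(chunks, ignore_index=True)
    root = tree.root
    out.insert(0, "tree_id", tree.tree_id)
    out.insert(1, "species", root.species)
    out.insert(2, "rootstock", root.rootstock)
    return out


def metrics_table(trees: Iterable[TreeArchitecture] | TreeArchitecture,
                  levels: Iterable[str] = LEVELS,
                  include_twigs: bool = False) -> pd.DataFrame:
    """Concatenated long-format metrics over a collection of trees."""
    if isinstance(trees, TreeArchitecture):
        trees = [trees]
    frames = [tree_metrics(t, levels=levels, include_twigs=include_twigs)
              for t in trees]
    return pd.concat(frames, ignore_index=True)
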