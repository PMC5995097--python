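"""Shared fixtures: small hand-built trees and random architectures."""

from __future__ import annotations

import numpy as np
import pytest

from allomtree import BranchRecord, TreeArchitecture


def make_record(branch_id, parent_id, diameter=2.0, length=10.0, mass=5.0,
                tree_id="t1", **kwargs):
    return BranchRecord(tree_id=tree_id, branch_id=branch_id,
                        parent_id=parent_id, diameter=diameter, length=length,
                        mass=mass, **kwargs)


def random_tree(seed: int, n: int = 50, tree_id: str = "rand") -> TreeArchitecture:
    """Random rooted topology with continuous measurements (ties measure-zero)."""
    rng = np.random.default_rng(seed)
    recs = [make_record("b000", None, diameter=float(rng.uniform(5, 10)),
                        length=float(rng.uniform(50, 150)),
                        mass=float(rng.uniform(100, 1000)), tree_id=tree_id)]
    for i in range(1, n):
        parent = recs[int(rng.integers(0, i))].branch_id
        recs.append(make_record(
            f"b{i:03d}", parent, diameter=float(rng.uniform(0.5, 5)),
            length=float(rng.uniform(1, 100)), mass=float(rng.uniform(1, 100)),
            tree_id=tree_id))
    return TreeArchitecture.from_records(recs)


@pytest.fixture
def small_tree() -> TreeArchitecture:
    """Root (L=10, M=100) with terminal children A (L=8, M=40), B (L=5, M=10)."""
    return TreeArchitecture.from_records([
        make_record("root", None, diameter=4.0, length=10.0, mass=100.0),
        make_record("A", "root", diameter=3.0, length=8.0, mass=40.0),
        make_record("B", "root", diameter=2.0, length=5.0, mass=10.0),
    ])


@pytest.fixture
def chain_tree() -> TreeArchitecture:
    """root -> A -> A1 chain (lengths 10, 8, 4) with side child B (L=5)."""
    return TreeArchitecture.from_records([
        make_record("root", None, diameter=4.0, length=10.0),
        make_record("A", "root", diameter=3.0, length=8.0),
        make_record("A1", "A", diameter=2.0, length=4.0),
        make_record("B", "root", diameter=2.5, length=5.0),
    ])


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept free of the traversal code they check)
# ---------------------------------------------------------------------------

def descendants_by_parent_walk(tree: TreeArchitecture, branch_id: str) -> set[str]:
    """All strict descendants of a branch, found by walking each record's
    parent chain upward -- no use of the tree's child index."""
    parents = {r.branch_id: r.parent_id for r in tree}
    out = set()
    for b, p in parents.items():
        cur = p
        while cur is not None:
            if cur == branch_id:
                out.add(b)
                break
            cur = parents[cur]
    return out


def chains_to_tips(tree: TreeArchitecture, branch_id: str) -> list[list[str]]:
    """Every branch-to-tip chain starting at ``branch_id`` (exhaustive)."""
    kids = tree.children(branch_id)
    if not kids:
        return [[branch_id]]
    return [[branch_id] + tail for k in kids for tail in chains_to_tips(tree, k)]
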