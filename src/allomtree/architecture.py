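"""Branch-table ingest and rooted tree architecture.

An orchard tree is recorded in the field as a flat table with one row per
branch: the branch's identity, its parent branch, the basal diameter of the
segment, the node-to-node segment length, and (for a subset of stems) the
oven-dry mass.  This module turns such a table into a validated rooted
topology (:class:`TreeArchitecture`) that the morphology and regression
layers traverse, and serialises topologies back out as Newick text.

Canonical units are centimetres (diameter, length) and grams (mass); the
:class:`TableSchema` carries multiplicative conversion factors for tables
recorded in other units.

Twigs -- stems supporting only buds or short fruit-bearing spurs, under
2 cm basal diameter -- are flagged at ingest.  Twig status is partly
observational (it depends on what the stem bears, not only on its
geometry), so it is read from a column when the table has one and
otherwise defaults to a configurable constant rather than being inferred.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

__all__ = [
    "BranchRecord",
    "TreeArchitecture",
    "TableSchema",
    "SchemaError",
    "TopologyError",
    "ValidationError",
    "read_branch_table",
    "write_branch_table",
    "export_topology",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing or the schema config is malformed."""


class TopologyError(ValueError):
    """The parent/child relation does not form a single rooted tree."""


class ValidationError(ValueError):
    """One or more rows violate the per-record measurement invariants."""


@dataclass(frozen=True)
class BranchRecord:
    """One measured branch.

    Parameters
    ----------
    tree_id : str
        Identifier of the individual tree.
    branch_id : str
        Identifier of this branch, unique within the tree.
    parent_id : str or None
        Identifier of the parent branch; ``None`` marks the trunk base
        (the root of the architecture).
    diameter : float
        Basal diameter of the segment, cm; strictly positive.
    length : float
        Node-to-node segment length, cm; non-negative.
    mass : float or None
        Oven-dry biomass, g; non-negative, ``None`` when not measured.
    is_twig : bool
        Whether the stem is a twig (buds/spurs only, < 2 cm basal
        diameter); twigs are excluded from the main analysis by default.
    species, rootstock, individual : str or None
        Grouping labels carried through to the fitted allometries.
    """

    tree_id: str
    branch_id: str
    parent_id: str | None
    diameter: float
    length: float
    mass: float | None = None
    is_twig: bool = False
    species: str | None = None
    rootstock: str | None = None
    individual: str | None = None

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise ValidationError(
                f"branch {self.branch_id!r}: diameter must be > 0, got {self.diameter}"
            )
        if not (self.length >= 0):
            raise ValidationError(
                f"branch {self.branch_id!r}: length must be >= 0, got {self.length}"
            )
        if self.mass is not None and not (self.mass >= 0):
            raise ValidationError(
                f"branch {self.branch_id!r}: mass must be >= 0 or missing, got {self.mass}"
            )

    @property
    def is_root(self) -> bool:
        return self.parent_id is None


class TreeArchitecture:
    """Validated rooted branching topology of one individual.

    Guarantees exactly one root record, every ``parent_id`` resolving to an
    existing branch, and an acyclic, connected parent/child relation.
    Construct via :meth:`from_records`; iteration yields records in
    insertion order.
    """

    def __init__(self, tree_id: str, records: Mapping[str, BranchRecord],
                 root_id: str, children: Mapping[str, tuple[str, ...]]):
        self.tree_id = tree_id
        self._records = dict(records)
        self._root_id = root_id
        self._children = {k: tuple(v) for k, v in children.items()}

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[BranchRecord],
                     tree_id: str | None = None) -> "TreeArchitecture":
        recs = list(records)
        if not recs:
            raise TopologyError("cannot build a tree from zero records")
        tid = tree_id if tree_id is not None else recs[0].tree_id

        by_id: dict[str, BranchRecord] = {}
        for r in recs:
            if r.branch_id in by_id:
                raise ValidationError(
                    f"tree {tid!r}: duplicate branch_id {r.branch_id!r}"
                )
            by_id[r.branch_id] = r

        roots = [r.branch_id for r in recs if r.parent_id is None]
        if len(roots) != 1:
            raise TopologyError(
                f"tree {tid!r}: expected exactly one root, found {len(roots)}"
                f" ({roots[:5]!r})"
            )
        root_id = roots[0]

        graph = nx.DiGraph()
        graph.add_nodes_from(by_id)
        for r in recs:
            if r.parent_id is None:
                continue
            if r.parent_id == r.branch_id:
                raise TopologyError(
                    f"tree {tid!r}: branch {r.branch_id!r} is its own parent"
                )
            if r.parent_id not in by_id:
                raise TopologyError(
                    f"tree {tid!r}: branch {r.branch_id!r} references unknown"
                    f" parent {r.parent_id!r}"
                )
            graph.add_edge(r.parent_id, r.branch_id)
        if not nx.is_arborescence(graph):
            cyclic = [n for c in nx.simple_cycles(graph) for n in c]
            detail = f"cycle through {cyclic[:5]!r}" if cyclic else "disconnected topology"
            raise TopologyError(f"tree {tid!r}: {detail}")

        children: dict[str, list[str]] = {bid: [] for bid in by_id}
        for r in recs:
            if r.parent_id is not None:
                children[r.parent_id].append(r.branch_id)
        return cls(tid, by_id, root_id, {k: tuple(v) for k, v in children.items()})

    # -- access -------------------------------------------------------

    @property
    def root_id(self) -> str:
        return self._root_id

    @property
    def root(self) -> BranchRecord:
        return self._records[self._root_id]

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, branch_id: str) -> bool:
        return branch_id in self._records

    def record(self, branch_id: str) -> BranchRecord:
        return self._records[branch_id]

    def children(self, branch_id: str) -> tuple[str, ...]:
        return self._children.get(branch_id, ())

    def branch_ids(self) -> tuple[str, ...]:
        return tuple(self._records)

    def terminal_ids(self) -> tuple[str, ...]:
        return tuple(b for b in self._records if not self._children.get(b))

    def depth_map(self) -> dict[str, int]:
        """Edge-count depth of every branch from the root (root = 0)."""
        depth = {self._root_id: 0}
        stack = [self._root_id]
        while stack:
            b = stack.pop()
            for c in self._children.get(b, ()):
                depth[c] = depth[b] + 1
                stack.append(c)
        return depth

    def descendant_ids(self, branch_id: str) -> tuple[str, ...]:
        """All branches strictly distal to ``branch_id`` (preorder)."""
        out: list[str] = []
        stack = list(self._children.get(branch_id, ()))
        while stack:
            b = stack.pop()
            out.append(b)
            stack.extend(self._children.get(b, ()))
        return tuple(out)

    def parent_child_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (p, c) for p, kids in self._children.items() for c in kids
        )

    def replace_records(self, new_records: Iterable[BranchRecord]) -> "TreeArchitecture":
        """Re-validate and rebuild from a modified record set."""
        return TreeArchitecture.from_records(new_records, tree_id=self.tree_id)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

@dataclass
class TableSchema:
    """Column mapping, unit conversions and twig policy for a branch table.

    Unit factors are multiplicative conversions into the canonical units
    (cm for diameter and length, g for mass): a table measured in metres
    would set ``length_unit=100``.
    """

    tree_id: str = "tree_id"
    branch_id: str = "branch_id"
    parent_id: str = "parent_id"
    diameter: str = "diameter"
    length: str = "length"
    mass: str | None = "mass"
    twig: str | None = None
    species: str | None = "species"
    rootstock: str | None = None
    diameter_unit: float = 1.0
    length_unit: float = 1.0
    mass_unit: float = 1.0
    root_markers: Sequence[str] = ("", "NA", "ROOT")
    default_twig: bool = False
    delimiter: str = ","

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TableSchema":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["root_markers"] = list(self.root_markers)
        return d


def _parse_parent(value, markers: set[str]) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    return None if text in markers else text


def _parse_mass(value, factor: float) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value) * factor


_TRUTHY = {"1", "true", "t", "yes", "y"}


def _parse_twig(value, default: bool) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return default
    if isinstance(value, (bool,)):
        return bool(value)
    return str(value).strip().lower() in _TRUTHY


def read_branch_table(path: str | Path,
                      schema: TableSchema | None = None) -> list[TreeArchitecture]:
    """Read a delimited branch table into one :class:`TreeArchitecture` per tree.

    Rows failing the per-record invariants are reported with their 1-based
    data row numbers in a single :class:`ValidationError`; topology defects
    raise :class:`TopologyError` naming the offending branch ids.
    """
    schema = schema or TableSchema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=schema.delimiter, dtype=str)

    required = [schema.tree_id, schema.branch_id, schema.parent_id,
                schema.diameter, schema.length]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    optional = {
        "mass": schema.mass if schema.mass in df.columns else None,
        "twig": schema.twig if schema.twig in df.columns else None,
        "species": schema.species if schema.species in df.columns else None,
        "rootstock": schema.rootstock if schema.rootstock in df.columns else None,
    }
    markers = {str(m) for m in schema.root_markers}

    records_by_tree: dict[str, list[BranchRecord]] = {}
    row_errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            rec = BranchRecord(
                tree_id=str(row[schema.tree_id]).strip(),
                branch_id=str(row[schema.branch_id]).strip(),
                parent_id=_parse_parent(row[schema.parent_id], markers),
                diameter=float(row[schema.diameter]) * schema.diameter_unit,
                length=float(row[schema.length]) * schema.length_unit,
                mass=_parse_mass(
                    row[optional["mass"]] if optional["mass"] else None,
                    schema.mass_unit),
                is_twig=_parse_twig(
                    row[optional["twig"]] if optional["twig"] else None,
                    schema.default_twig),
                species=row[optional["species"]] if optional["species"] else None,
                rootstock=row[optional["rootstock"]] if optional["rootstock"] else None,
            )
        except (ValidationError, ValueError, TypeError) as exc:
            row_errors.append(f"row {i}: {exc}")
            continue
        records_by_tree.setdefault(rec.tree_id, []).append(rec)
    if row_errors:
        raise ValidationError(
            f"{path.name}: {len(row_errors)} invalid row(s):\n  " + "\n  ".join(row_errors)
        )

    trees = [TreeArchitecture.from_records(recs, tree_id=tid)
             for tid, recs in records_by_tree.items()]
    logger.info("%s: read %d rows into %d tree(s); %d twig record(s) flagged",
                path.name, len(df), len(trees),
                sum(r.is_twig for t in trees for r in t))
    return trees


def write_branch_table(trees: Iterable[TreeArchitecture] | TreeArchitecture,
                       path: str | Path,
                       schema: TableSchema | None = None) -> pd.DataFrame:
    """Write trees back out in the same delimited schema the ingest reads."""
    schema = schema or TableSchema()
    if isinstance(trees, TreeArchitecture):
        trees = [trees]
    rows = []
    for tree in trees:
        for r in tree:
            rows.append({
                schema.tree_id: r.tree_id,
                schema.branch_id: r.branch_id,
                schema.parent_id: r.parent_id if r.parent_id is not None
                else (schema.root_markers[1] if len(schema.root_markers) > 1 else ""),
                schema.diameter: r.diameter / schema.diameter_unit,
                schema.length: r.length / schema.length_unit,
                (schema.mass or "mass"): (None if r.mass is None
                                          else r.mass / schema.mass_unit),
                (schema.twig or "is_twig"): r.is_twig,
                (schema.species or "species"): r.species,
            })
    df = pd.DataFrame(rows)
    df.to_csv(path, sep=schema.delimiter, index=False)
    return df


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

_NEWICK_UNSAFE = set("(),:;[]' \t\n")


def _newick_label(branch_id: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in branch_id):
        return "'" + branch_id.replace("'", "''") + "'"
    return branch_id


def export_topology(tree: TreeArchitecture) -> str:
    """Serialise a tree as Newick with branch ids as labels and segment
    lengths (cm) as branch lengths.  Children are emitted in sorted id
    order so the output is deterministic."""

    def render(branch_id: str) -> str:
        rec = tree.record(branch_id)
        label = f"{_newick_label(branch_id)}:{rec.length:.6g}"
        kids = sorted(tree.children(branch_id))
        if not kids:
            return label
        return "(" + ",".join(render(k) for k in kids) + ")" + label

    return render(tree.root_id) + ";"
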