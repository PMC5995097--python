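"""Self-similar branching-tree generator with known allometric exponents.

Generates full n-ary branching architectures in which every branch at
depth i has diameter ``root_diameter * beta**i`` and length
``root_length * gamma**i`` before noise.  The segment-level
length~diameter exponent of such a network is exactly

    a_true = ln(gamma) / ln(beta)

so every stage of the pipeline can be validated against a closed form
without field data.  Measurement noise is multiplicative lognormal on
diameter and length independently (allometric residuals are
scale-proportional, which keeps log-log residuals homoscedastic --
exactly the error structure RMA assumes); segment mass is wood density
times cylinder volume of the *noised* dimensions, times its own
lognormal factor.

The :func:`wbe_geometry` preset uses beta = n^(-1/2) (area-preserving
branching) and gamma = n^(-1/3), the geometry in which segment mass
scales as diameter^(8/3) exactly when noiseless.

Two pruning operators idealise orchard management cuts:
*branch-removing* deletes whole subtrees at eligible depths with a
given probability, and *length-reducing* shortens every terminal
segment (and proportionally its mass) by a fixed fraction.  Both are
idealisations of qualitative cut types, not a mechanistic regrowth
model.

Randomness comes from one ``numpy`` generator seeded from
``SynthConfig.seed``; draws occur in a documented order (per-branch
D, L, mass noise in breadth-first id order, then subtree-removal
uniforms in sorted id order), so every fixture is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
import numpy as np
import yaml

from .architecture import BranchRecord, TreeArchitecture, TableSchema, write_branch_table

__all__ = ["SynthConfig", "generate", "wbe_geometry", "prune", "write_synthetic"]


@dataclass
class SynthConfig:
    """Parameters of the self-similar generator.

    Defaults describe a realistic orchard-scale architecture: a
    bifurcating tree with area-preserving diameter scaling
    (beta = 2^-1/2) and the matching gamma = 2^-1/3 length ratio, a
    10 cm trunk base, 100 cm trunk segment, and wood density
    0.6 g/cm^3 (typical for temperate fruitwood).
    """

    n_children: int = 2
    levels: int = 6
    root_diameter: float = 10.0  # cm
    root_length: float = 100.0   # cm
    beta: float = 2.0 ** -0.5    # diameter ratio per level, in (0, 1)
    gamma: float = 2.0 ** (-1.0 / 3.0)  # length ratio per level, in (0, 1)
    noise_sigma: float = 0.0     # sd of ln-scale multiplicative noise
    wood_density: float = 0.6    # g/cm^3
    prune_fraction: float = 0.0  # P(remove subtree) at depth >= prune_min_depth
    tip_trim: float = 0.0        # fraction removed from terminal lengths
    prune_min_depth: int = 1
    seed: int = 0
    tree_id: str = "synth-1"
    species: str = "synthetic"

    def validate(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        for name in ("beta", "gamma"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not (0.0 <= self.prune_fraction < 1.0):
            raise ValueError("prune_fraction must be in [0, 1)")
        if not (0.0 <= self.tip_trim < 1.0):
            raise ValueError("tip_trim must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.root_diameter <= 0 or self.root_length <= 0:
            raise ValueError("root dimensions must be positive")
        if self.wood_density <= 0:
            raise ValueError("wood_density must be positive")

    @property
    def a_true(self) -> float:
        """Closed-form segment-level length~diameter exponent."""
        return math.log(self.gamma) / math.log(self.beta)


def _branch_ids(n_children: int, levels: int, root: str = "R"):
    """Breadth-first (id, parent, depth) triples of a full n-ary tree."""
    yield root, None, 0
    frontier = [root]
    for depth in range(1, levels):
        nxt = []
        for parent in frontier:
            for k in range(n_children):
                bid = f"{parent}.{k}"
                yield bid, parent, depth
                nxt.append(bid)
        frontier = nxt


def generate(config: SynthConfig) -> tuple[TreeArchitecture, dict]:
    """Generate one architecture; returns (tree, truth record).

    The truth record carries the generator parameters and the
    closed-form segment L~D exponent ``a_true`` plus the implied
    noiseless segment M~D exponent ``2 + a_true`` (mass ~ D^2 L).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    records: list[BranchRecord] = []
    for bid, parent, depth in _branch_ids(config.n_children, config.levels):
        d0 = config.root_diameter * config.beta ** depth
        l0 = config.root_length * config.gamma ** depth
        if config.noise_sigma > 0:
            fd, fl, fm = np.exp(rng.normal(0.0, config.noise_sigma, size=3))
        else:
            fd = fl = fm = 1.0
        d = d0 * fd
        ln = l0 * fl
        mass = config.wood_density * math.pi * (d / 2.0) ** 2 * ln * fm
        records.append(BranchRecord(
            tree_id=config.tree_id, branch_id=bid, parent_id=parent,
            diameter=d, length=ln, mass=mass, species=config.species,
        ))
    tree = TreeArchitecture.from_records(records, tree_id=config.tree_id)

    removed_fraction = 0.0
    if config.prune_fraction > 0 or config.tip_trim > 0:
        tree, removed_fraction = prune(
            tree, prune_fraction=config.prune_fraction,
            tip_trim=config.tip_trim,
            prune_min_depth=config.prune_min_depth, rng=rng)

    truth = {
        **asdict(config),
        "a_true": config.a_true,
        "a_true_mass_diameter": 2.0 + config.a_true,
        "n_branches": len(tree),
        "removed_mass_fraction": removed_fraction,
    }
    return tree, truth


def wbe_geometry(n_children: int = 2, levels: int = 8, *,
                 root_diameter: float = 10.0, root_length: float = 100.0,
                 wood_density: float = 0.6, noise_sigma: float = 0.0,
                 seed: int = 0, tree_id: str = "wbe-synth",
                 **kwargs) -> tuple[TreeArchitecture, dict]:
    """Area-preserving preset: beta = n^(-1/2), gamma = n^(-1/3).

    Noiseless trees from this preset have segment L ~ D^(2/3) and
    M ~ D^(8/3) exactly.
    """
    config = SynthConfig(
        n_children=n_children, levels=levels,
        root_diameter=root_diameter, root_length=root_length,
        beta=float(n_children) ** -0.5, gamma=float(n_children) ** (-1.0 / 3.0),
        noise_sigma=noise_sigma, wood_density=wood_density,
        seed=seed, tree_id=tree_id, **kwargs)
    return generate(config)


def _total_mass(tree: TreeArchitecture) -> float:
    total = 0.0
    for r in tree:
        if r.mass is None:
            raise ValueError("pruning bookkeeping requires mass on every record")
        total += r.mass
    return total


def prune(tree: TreeArchitecture, prune_fraction: float = 0.0,
          tip_trim: float = 0.0, prune_min_depth: int = 1,
          seed: int | None = None,
          rng: np.random.Generator | None = None) -> tuple[TreeArchitecture, float]:
    """Apply branch-removing and length-reducing cuts.

    Branch-removing: every surviving non-root branch at depth >=
    ``prune_min_depth`` loses its whole subtree with probability
    ``prune_fraction`` (the root is never removed).  Length-reducing:
    terminal segments of the remaining tree have length and mass
    multiplied by ``1 - tip_trim`` (surface area and volume, computed
    downstream from length, scale along).  Returns the new tree and the
    fraction of total branch mass removed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not (0.0 <= prune_fraction < 1.0) or not (0.0 <= tip_trim < 1.0):
        raise ValueError("prune_fraction and tip_trim must be in [0, 1)")

    total = _total_mass(tree)
    depth = tree.depth_map()
    removed: set[str] = set()
    # sorted ids so the uniform draws hit branches in a reproducible order
    for bid in sorted(tree.branch_ids()):
        if bid == tree.root_id or depth[bid] < prune_min_depth or bid in removed:
            continue
        if rng.uniform() < prune_fraction:
            removed.add(bid)
            removed.update(tree.descendant_ids(bid))

    kept = [tree.record(b) for b in tree.branch_ids() if b not in removed]
    kept_ids = {r.branch_id for r in kept}
    terminal_after = {
        r.branch_id for r in kept
        if not any(c in kept_ids for c in tree.children(r.branch_id))
    }
    factor = 1.0 - tip_trim
    new_records = []
    for r in kept:
        if tip_trim > 0 and r.branch_id in terminal_after:
            r = BranchRecord(
                tree_id=r.tree_id, branch_id=r.branch_id, parent_id=r.parent_id,
                diameter=r.diameter, length=r.length * factor,
                mass=None if r.mass is None else r.mass * factor,
                is_twig=r.is_twig, species=r.species,
                rootstock=r.rootstock, individual=r.individual)
        new_records.append(r)

    pruned = TreeArchitecture.from_records(new_records, tree_id=tree.tree_id)
    removed_fraction = (total - _total_mass(pruned)) / total if total > 0 else 0.0
    return pruned, removed_fraction


def write_synthetic(config: SynthConfig, table_path: str | Path,
                    truth_path: str | Path | None = None,
                    schema: TableSchema | None = None) -> tuple[TreeArchitecture, dict]:
    """Generate a tree and write it in the ingest's delimited schema,
    plus an optional YAML sidecar of the true generator parameters."""
    tree, truth = generate(config)
    write_branch_table(tree, table_path, schema=schema)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=True)
    return tree, truth
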