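"""End-to-end orchestration: ingest -> morphology -> fits -> model comparison.

A :class:`RunConfig` names the inputs (branch tables on disk, or
synthetic generator configurations), the variable pairs, classification
levels and grouping to fit, and an output directory.  :func:`run`
validates everything up front (fail-fast), executes the stages, and
writes a report bundle:

* ``allometry.csv``      -- exponent table (a, CI, b, CI, r^2, n) per
  (pair, level, group), failures included as explicit rows;
* ``model_comparison.csv`` -- each successful fit against the FS range
  and/or WBE point, with its classification status and, for FS rows,
  the direction of exponent movement across levels;
* ``aicc.csv``           -- linear vs quadratic AICc per cell;
* ``predictions.csv``    -- the theoretical prediction table;
* ``manifest.json``      -- everything needed to replay the run;
* ``report.md``          -- human-readable tables rounded to 2 decimals.

Machine-readable CSVs keep full precision.  Re-running an identical
config reproduces every table byte for byte, and :func:`replay`
re-executes a run from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .architecture import TableSchema, TreeArchitecture, read_branch_table
from .morphology import LEVELS, metrics_table
from .regression import (AllometryFit, aicc_compare, fit_grid, fits_to_frame,
                         InsufficientDataError)
from .synthetic import SynthConfig, generate
from .theory import FS_PAIRS, WBE_PAIRS, classify_fit, fs_range, prediction_table, \
    tendency, wbe_prediction

__all__ = ["RunConfig", "DEFAULT_PAIRS", "run", "replay"]

logger = logging.getLogger(__name__)

#: the nine variable pairs of the full analysis
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("length", "diameter"),
    ("surface_area", "volume"),
    ("diameter", "volume"),
    ("length", "volume"),
    ("diameter", "surface_area"),
    ("length", "surface_area"),
    ("mass", "diameter"),
    ("length", "mass"),
    ("mass", "volume"),
)

_VALID_GROUPINGS = ("species", "individual", "rootstock", "pooled")
_VALID_METRICS = ("length", "diameter", "mass", "surface_area", "volume")


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    inputs: Sequence[str] = ()
    synth: Sequence[SynthConfig] = ()
    schema: TableSchema = field(default_factory=TableSchema)
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS
    levels: Sequence[str] = LEVELS
    grouping: str = "species"
    include_twigs: bool = False
    confidence: float = 0.95
    outdir: str = "allomtree-run"
    seed: int = 0

    def validate(self) -> None:
        if not self.inputs and not self.synth:
            raise ValueError("RunConfig needs input table(s) or synth config(s)")
        for lv in self.levels:
            if lv not in LEVELS:
                raise ValueError(f"unknown level {lv!r}; choose from {LEVELS}")
        for y, x in self.pairs:
            for name in (y, x):
                if name not in _VALID_METRICS:
                    raise ValueError(f"unknown metric {name!r} in pair ({y},{x})")
        if self.grouping not in _VALID_GROUPINGS:
            raise ValueError(f"unknown grouping {self.grouping!r}; choose from "
                             f"{_VALID_GROUPINGS}")
        if not (0.0 < self.confidence < 1.0):
            raise ValueError("confidence must be in (0, 1)")

    def to_manifest(self) -> dict:
        return {
            "version": __version__,
            "inputs": list(self.inputs),
            "synth": [dataclasses.asdict(c) for c in self.synth],
            "schema": self.schema.to_dict(),
            "pairs": [list(p) for p in self.pairs],
            "levels": list(self.levels),
            "grouping": self.grouping,
            "include_twigs": self.include_twigs,
            "confidence": self.confidence,
            "seed": self.seed,
        }

    @classmethod
    def from_manifest(cls, manifest: dict, outdir: str) -> "RunConfig":
        return cls(
            inputs=manifest["inputs"],
            synth=[SynthConfig(**c) for c in manifest["synth"]],
            schema=TableSchema(**manifest["schema"]),
            pairs=[tuple(p) for p in manifest["pairs"]],
            levels=manifest["levels"],
            grouping=manifest["grouping"],
            include_twigs=manifest["include_twigs"],
            confidence=manifest["confidence"],
            outdir=outdir,
            seed=manifest["seed"],
        )


def _load_trees(config: RunConfig) -> list[TreeArchitecture]:
    trees: list[TreeArchitecture] = []
    for path in config.inputs:
        trees.extend(read_branch_table(path, schema=config.schema))
    for synth in config.synth:
        tree, _ = generate(synth)
        trees.append(tree)
    return trees


def _comparison_frame(fits: list, pairs, levels) -> pd.DataFrame:
    """Fit-vs-prediction rows with classification status and FS tendency."""
    ok = [f for f in fits if f.ok]
    by_cell = {(f.y_variable, f.x_variable, f.level, f.group): f for f in ok}
    groups = sorted({f.group for f in ok})
    level_order = [lv for lv in LEVELS if lv in levels]

    rows = []
    for pair in pairs:
        preds = []
        if tuple(pair) in FS_PAIRS:
            preds.append(fs_range(tuple(pair)))
        if tuple(pair) in WBE_PAIRS:
            preds.append(wbe_prediction(tuple(pair)))
        for pred in preds:
            for group in groups:
                seq = [by_cell[(pair[0], pair[1], lv, group)]
                       for lv in level_order
                       if (pair[0], pair[1], lv, group) in by_cell]
                direction = ""
                if pred.model == "FS" and len(seq) >= 2:
                    direction = tendency(seq, pred)["direction"]
                for f in seq:
                    rows.append({
                        "y": f.y_variable, "x": f.x_variable,
                        "level": f.level, "group": f.group,
                        "a_hat": f.a_hat, "a_lo": f.a_ci[0], "a_hi": f.a_ci[1],
                        "model": pred.model,
                        "predicted": (f"[{float(pred.range[0]):g}, "
                                      f"{float(pred.range[1]):g}]"
                                      if pred.model == "FS"
                                      else f"{float(pred.point_value):g}"),
                        "reconstructed": pred.reconstructed,
                        "status": classify_fit(f, pred)["status"],
                        "tendency": direction,
                    })
    return pd.DataFrame(rows, columns=[
        "y", "x", "level", "group", "a_hat", "a_lo", "a_hi", "model",
        "predicted", "reconstructed", "status", "tendency"])


def _aicc_frame(metrics: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    group_col = {"species": "species", "individual": "tree_id",
                 "rootstock": "rootstock", "pooled": None}[config.grouping]
    rows = []
    for level in config.levels:
        at_level = metrics[metrics["level"] == level]
        groups = ([("all", at_level)] if group_col is None
                  else [(str(k), g) for k, g in at_level.groupby(group_col, dropna=False)])
        for gname, gdf in groups:
            for y, x in config.pairs:
                try:
                    res = aicc_compare(gdf[x], gdf[y])
                    rows.append({"y": y, "x": x, "level": level, "group": gname,
                                 "n": res["n"], "aicc_linear": res["aicc_linear"],
                                 "aicc_quadratic": res["aicc_quadratic"],
                                 "preferred": res["preferred"], "reason": ""})
                except InsufficientDataError as exc:
                    rows.append({"y": y, "x": x, "level": level, "group": gname,
                                 "n": int(len(gdf)), "aicc_linear": float("nan"),
                                 "aicc_quadratic": float("nan"),
                                 "preferred": "", "reason": str(exc)})
    return pd.DataFrame(rows)


def _report_md(allometry: pd.DataFrame, comparison: pd.DataFrame) -> str:
    shown = allometry[allometry["status"] == "ok"].copy()
    for col in ("a_hat", "a_lo", "a_hi", "b_hat", "b_lo", "b_hi"):
        shown[col] = shown[col].round(2)
    shown["r_squared"] = shown["r_squared"].round(3)
    lines = ["# Allometry report", "", "## Estimated exponents", "",
             shown.to_string(index=False), ""]
    if len(comparison):
        lines += ["## Model comparison", "",
                  comparison.assign(
                      a_hat=comparison["a_hat"].round(2),
                      a_lo=comparison["a_lo"].round(2),
                      a_hi=comparison["a_hi"].round(2),
                  ).to_string(index=False), ""]
    lines += ["---",
              "CI-overlap interpretations use raw 95% intervals; no"
              " multiple-comparison correction is applied.", ""]
    return "\n".join(lines)


def run(config: RunConfig) -> dict:
    """Execute a full run and write the report bundle into ``config.outdir``.

    Returns the in-memory tables: ``{"allometry", "comparison", "aicc",
    "predictions", "metrics", "manifest"}``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        trees = _load_trees(config)
    except Exception as exc:
        raise RuntimeError(f"stage ingest failed: {exc}") from exc
    if not trees:
        raise RuntimeError("stage ingest failed: no trees loaded")

    try:
        metrics = metrics_table(trees, levels=config.levels,
                                include_twigs=config.include_twigs)
    except Exception as exc:
        raise RuntimeError(f"stage morphology failed: {exc}") from exc

    try:
        fits = fit_grid(metrics, pairs=config.pairs, levels=config.levels,
                        grouping=config.grouping, confidence=config.confidence)
        allometry = fits_to_frame(fits)
        comparison = _comparison_frame(fits, config.pairs, config.levels)
        aicc = _aicc_frame(metrics, config)
    except Exception as exc:
        raise RuntimeError(f"stage fitting failed: {exc}") from exc

    predictions = prediction_table()
    manifest = config.to_manifest()
    manifest["n_trees"] = len(trees)
    manifest["n_records"] = int(sum(len(t) for t in trees))
    manifest["n_failed_fits"] = int((allometry["status"] == "failed").sum())
    manifest["n_dropped_pairs"] = int(sum(f.n_dropped for f in fits if f.ok))

    allometry.to_csv(outdir / "allometry.csv", index=False)
    comparison.to_csv(outdir / "model_comparison.csv", index=False)
    aicc.to_csv(outdir / "aicc.csv", index=False)
    predictions.to_csv(outdir / "predictions.csv", index=False)
    metrics.to_csv(outdir / "metrics.csv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (outdir / "report.md").write_text(_report_md(allometry, comparison))
    logger.info("run complete: %d tree(s), %d fit row(s), %d failure(s)",
                len(trees), len(allometry), manifest["n_failed_fits"])

    return {"allometry": allometry, "comparison": comparison, "aicc": aicc,
            "predictions": predictions, "metrics": metrics, "manifest": manifest,
            "fits": fits}


def replay(manifest_path: str | Path, outdir: str | Path) -> dict:
    """Re-execute a run from its manifest alone."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = RunConfig.from_manifest(manifest, outdir=str(outdir))
    return run(config)
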