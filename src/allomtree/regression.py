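"""Power-law allometry estimation by reduced (standardized) major axis.

An allometric relationship y = b*x^a is linear in log-log space,
log10 y = a*log10 x + log10 b.  Because both coordinates are measured
with error, the slope is estimated by reduced major axis (RMA, also
called standardized major axis, SMA) regression rather than OLS:

    a_hat = sign(r) * sd(log10 y) / sd(log10 x)

with r the Pearson correlation of the log pair.  The 95% CI follows the
standard SMA construction

    Q    = F(0.95; 1, n-2) * (1 - r^2) / (n - 2)
    a_ci = a_hat * (sqrt(Q + 1) -/+ sqrt(Q))

ordered low < high (so the factor ordering mirrors for negative
slopes).  The intercept CI is the approximation obtained by
re-evaluating the intercept at the slope CI endpoints.

Base-10 logarithms are used throughout, so the reported multiplier
b_hat is a log10 intercept.  Pairs with a missing or non-positive value
in either coordinate are dropped pairwise (the log transform forces
positivity) and the drop count is logged.

``aicc_compare`` checks whether a quadratic in log-log space beats the
straight line by small-sample-corrected AIC; ``fit_grid`` sweeps
(variable pair, classification level, group) combinations over a
morphology metrics table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AllometryFit",
    "FitFailure",
    "InsufficientDataError",
    "DegenerateDataError",
    "rma_fit",
    "fit_grid",
    "fits_to_frame",
    "aicc_compare",
    "ci_overlap",
]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Fewer valid pairs than the estimator requires."""


class DegenerateDataError(ValueError):
    """Zero variance in a log coordinate, or exactly zero correlation."""


@dataclass(frozen=True)
class AllometryFit:
    """One estimated allometry y = b*x^a.

    ``a_hat`` is the log-log slope (allometric exponent), ``b_hat`` the
    log10 intercept (log10 of the multiplier); CIs are 95% two-sided by
    default.
    """

    y_variable: str
    x_variable: str
    level: str
    group: str
    n: int
    a_hat: float
    a_ci: tuple[float, float]
    b_hat: float
    b_ci: tuple[float, float]
    r_squared: float
    n_dropped: int = 0

    @property
    def ok(self) -> bool:
        return True


@dataclass(frozen=True)
class FitFailure:
    """Explicit record of a (pair, level, group) cell that could not be fit."""

    y_variable: str
    x_variable: str
    level: str
    group: str
    n: int
    reason: str

    @property
    def ok(self) -> bool:
        return False


def _clean_log_pairs(x, y) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    valid = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    dropped = int(x.size - valid.sum())
    return np.log10(x[valid]), np.log10(y[valid]), dropped


def rma_fit(x, y, confidence: float = 0.95, *,
            y_variable: str = "y", x_variable: str = "x",
            level: str = "", group: str = "") -> AllometryFit:
    """Fit y = b*x^a by reduced major axis on log10-transformed data.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 valid (positive, finite) pairs.
    DegenerateDataError
        Zero variance in either log coordinate, or r exactly 0 (the
        slope's sign is undefined).
    """
    u, v, dropped = _clean_log_pairs(x, y)
    n = u.size
    if dropped:
        logger.info("rma_fit(%s~%s): dropped %d non-positive/missing pair(s)",
                    y_variable, x_variable, dropped)
    if n < 3:
        raise InsufficientDataError(
            f"need >= 3 valid pairs, have {n} (dropped {dropped})")
    su = u.std(ddof=1)
    sv = v.std(ddof=1)
    if su == 0 or sv == 0:
        raise DegenerateDataError("zero variance in a log coordinate")
    r = float(np.corrcoef(u, v)[0, 1])
    if r == 0:
        raise DegenerateDataError("correlation exactly zero; slope sign undefined")

    a_hat = math.copysign(sv / su, r)
    b_hat = v.mean() - a_hat * u.mean()
    r2 = r * r

    q = stats.f.ppf(confidence, 1, n - 2) * (1.0 - r2) / (n - 2)
    lo = a_hat * (math.sqrt(q + 1.0) - math.sqrt(q))
    hi = a_hat * (math.sqrt(q + 1.0) + math.sqrt(q))
    a_lo, a_hi = (lo, hi) if lo <= hi else (hi, lo)
    # intercept re-evaluated at the slope CI endpoints (approximation)
    b_ends = sorted((v.mean() - a_lo * u.mean(), v.mean() - a_hi * u.mean()))

    return AllometryFit(
        y_variable=y_variable, x_variable=x_variable, level=level, group=group,
        n=int(n), a_hat=float(a_hat), a_ci=(float(a_lo), float(a_hi)),
        b_hat=float(b_hat), b_ci=(float(b_ends[0]), float(b_ends[1])),
        r_squared=float(r2), n_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Grid sweeps over a metrics table
# ---------------------------------------------------------------------------

_GROUPINGS = {"species": "species", "individual": "tree_id",
              "rootstock": "rootstock", "pooled": None}


def fit_grid(metrics: pd.DataFrame,
             pairs: Sequence[tuple[str, str]],
             levels: Sequence[str],
             grouping: str = "species",
             confidence: float = 0.95) -> list[AllometryFit | FitFailure]:
    """One RMA fit per (pair, level, group) cell of a long metrics table.

    ``metrics`` is the long format produced by
    :func:`allomtree.morphology.metrics_table`.  Cells that cannot be fit
    are returned as :class:`FitFailure` records, never dropped silently.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; choose from "
                         f"{sorted(_GROUPINGS)}")
    known_levels = set(metrics["level"].unique())
    metric_cols = set(metrics.columns)
    for lv in levels:
        if lv not in ("segment", "path", "subtree"):
            raise ValueError(f"unknown level {lv!r}")
    for y, x in pairs:
        for name in (y, x):
            if name not in metric_cols:
                raise ValueError(f"unknown metric {name!r} in pair ({y},{x})")

    group_col = _GROUPINGS[grouping]
    results: list[AllometryFit | FitFailure] = []
    for level in levels:
        at_level = metrics[metrics["level"] == level]
        if level not in known_levels:
            at_level = at_level.iloc[0:0]
        if group_col is None:
            groups = [("all", at_level)]
        else:
            groups = [(str(k), g) for k, g in at_level.groupby(group_col, dropna=False)]
        for gname, gdf in groups:
            for y, x in pairs:
                try:
                    results.append(rma_fit(
                        gdf[x], gdf[y], confidence=confidence,
                        y_variable=y, x_variable=x, level=level, group=gname))
                except (InsufficientDataError, DegenerateDataError, KeyError) as exc:
                    results.append(FitFailure(
                        y_variable=y, x_variable=x, level=level, group=gname,
                        n=int(len(gdf)), reason=str(exc)))
    return results


def fits_to_frame(fits: Iterable[AllometryFit | FitFailure]) -> pd.DataFrame:
    """Tabulate fits and failures in a Table-2-shaped report frame."""
    rows = []
    for f in fits:
        if f.ok:
            rows.append({
                "y": f.y_variable, "x": f.x_variable, "level": f.level,
                "group": f.group, "n": f.n, "a_hat": f.a_hat,
                "a_lo": f.a_ci[0], "a_hi": f.a_ci[1], "b_hat": f.b_hat,
                "b_lo": f.b_ci[0], "b_hi": f.b_ci[1],
                "r_squared": f.r_squared, "status": "ok", "reason": "",
            })
        else:
            rows.append({
                "y": f.y_variable, "x": f.x_variable, "level": f.level,
                "group": f.group, "n": f.n, "a_hat": math.nan,
                "a_lo": math.nan, "a_hi": math.nan, "b_hat": math.nan,
                "b_lo": math.nan, "b_hi": math.nan, "r_squared": math.nan,
                "status": "failed", "reason": f.reason,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Linear vs quadratic comparison in log-log space
# ---------------------------------------------------------------------------

def _gaussian_aicc(rss: float, n: int, k: int) -> float:
    """AICc of an OLS fit with Gaussian errors; k counts coefficients + variance."""
    sigma2 = rss / n
    ll = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    aic = 2.0 * k - 2.0 * ll
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_compare(x, y) -> dict:
    """Compare a straight line against a quadratic in log-log space by AICc.

    Returns ``{"aicc_linear", "aicc_quadratic", "preferred", "n"}``.
    ``preferred`` is "linear" on ties (within 1e-9) and whenever the
    linear residual variance is numerically zero -- the Gaussian
    likelihood diverges there and parsimony decides.
    """
    u, v, _ = _clean_log_pairs(x, y)
    n = u.size
    # quadratic has 3 coefficients + variance = 4; need n - k - 1 > 0 with margin
    if n < 6:
        raise InsufficientDataError(f"need >= 6 valid pairs for AICc, have {n}")

    rss = {}
    for degree in (1, 2):
        coeffs = np.polynomial.polynomial.polyfit(u, v, degree)
        resid = v - np.polynomial.polynomial.polyval(u, coeffs)
        rss[degree] = float(resid @ resid)

    scale = max(float(v @ v), 1.0)
    if rss[1] <= 1e-20 * scale:  # perfect straight line: likelihoods diverge
        return {"aicc_linear": -math.inf, "aicc_quadratic": -math.inf,
                "preferred": "linear", "n": int(n)}

    aicc_lin = _gaussian_aicc(rss[1], n, k=3)
    aicc_quad = _gaussian_aicc(rss[2], n, k=4)
    preferred = "linear" if aicc_lin <= aicc_quad + 1e-9 else "quadratic"
    return {"aicc_linear": aicc_lin, "aicc_quadratic": aicc_quad,
            "preferred": preferred, "n": int(n)}


def ci_overlap(fit1: AllometryFit, fit2: AllometryFit) -> dict:
    """Whether two slope CIs intersect as closed intervals.

    Overlapping 95% CIs are read as statistically indistinguishable
    exponents; no multiplicity correction is applied.
    """
    lo1, hi1 = fit1.a_ci
    lo2, hi2 = fit2.a_ci
    return {"overlaps": bool(lo1 <= hi2 and lo2 <= hi1)}
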