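"""Theoretical allometric exponent predictions: Flow Similarity and WBE.

Flow Similarity (FS) parameterises branch allometry by a single exponent
alpha_F, the length~diameter exponent, and derives the other pairwise
exponents from cylinder geometry:

    L  ~ D^alpha_F
    SA ~ V^((alpha_F+1)/(alpha_F+2))
    D  ~ V^(1/(alpha_F+2))
    L  ~ V^(alpha_F/(alpha_F+2))
    D  ~ SA^(1/(alpha_F+1))
    L  ~ SA^(alpha_F/(alpha_F+1))

Two physical regimes pin alpha_F: *flow similarity* (area-preserving
branching that keeps water flow rate and velocity constant) gives
alpha_F = 2, and *elastic similarity* (branches sized to the buckling
limit under their own weight) gives alpha_F = 2/3.  FS therefore
predicts, for each variable pair, a *range* of exponents between the
flow and elastic endpoints.

The West-Brown-Enquist (WBE) fractal branching model predicts single
exponents instead; for branch-level data the anchored value is
mass ~ diameter^(8/3).  The companion points length ~ diameter^(2/3)
and length ~ mass^(1/4) follow from the standard WBE derivation
(M ~ D^(8/3) and L ~ M^(1/4) compose to L ~ D^(2/3)); they are carried
with ``reconstructed=True`` so reports can flag them.

All predictions are exact :class:`fractions.Fraction` values internally
and only become floats at comparison time.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence  # noqa: F401

import pandas as pd

from .regression import AllometryFit

__all__ = [
    "ALPHA_FLOW",
    "ALPHA_ELASTIC",
    "FS_PAIRS",
    "WBE_PAIRS",
    "ExponentPrediction",
    "fs_exponent",
    "fs_range",
    "wbe_prediction",
    "classify_fit",
    "tendency",
    "prediction_table",
]

#: alpha_F at the flow-similarity (area-preserving) endpoint
ALPHA_FLOW = Fraction(2)
#: alpha_F at the elastic-similarity (buckling-limit) endpoint
ALPHA_ELASTIC = Fraction(2, 3)

_FS_EXPRESSIONS: dict[tuple[str, str], Callable[[Fraction], Fraction]] = {
    ("length", "diameter"): lambda a: a,
    ("surface_area", "volume"): lambda a: (a + 1) / (a + 2),
    ("diameter", "volume"): lambda a: 1 / (a + 2),
    ("length", "volume"): lambda a: a / (a + 2),
    ("diameter", "surface_area"): lambda a: 1 / (a + 1),
    ("length", "surface_area"): lambda a: a / (a + 1),
}
FS_PAIRS: tuple[tuple[str, str], ...] = tuple(_FS_EXPRESSIONS)

_WBE_POINTS: dict[tuple[str, str], tuple[Fraction, bool]] = {
    # (point exponent, reconstructed-from-derivation flag)
    ("mass", "diameter"): (Fraction(8, 3), False),
    ("length", "diameter"): (Fraction(2, 3), True),
    ("length", "mass"): (Fraction(1, 4), True),
}
WBE_PAIRS: tuple[tuple[str, str], ...] = tuple(_WBE_POINTS)


@dataclass(frozen=True)
class ExponentPrediction:
    """A theoretical exponent (WBE point) or endpoint range (FS) for one pair."""

    model: str  # "FS" | "WBE"
    y_variable: str
    x_variable: str
    flow_value: Fraction | None = None
    elastic_value: Fraction | None = None
    range: tuple[Fraction, Fraction] | None = None
    point_value: Fraction | None = None
    reconstructed: bool = False


def _check_pair(pair: tuple[str, str], table: dict, model: str) -> tuple[str, str]:
    pair = (str(pair[0]), str(pair[1]))
    if pair not in table:
        raise ValueError(
            f"no {model} prediction for pair {pair!r}; supported: {sorted(table)}")
    return pair


def fs_exponent(pair: tuple[str, str], alpha_f) -> Fraction:
    """Evaluate the FS expression for ``pair`` at a given alpha_F (> 0)."""
    pair = _check_pair(pair, _FS_EXPRESSIONS, "FS")
    alpha = Fraction(alpha_f)
    if alpha <= 0:
        raise ValueError(f"alpha_f must be > 0, got {alpha_f}")
    return _FS_EXPRESSIONS[pair](alpha)


def fs_range(pair: tuple[str, str]) -> ExponentPrediction:
    """FS prediction: exponent range between the flow and elastic endpoints."""
    pair = _check_pair(pair, _FS_EXPRESSIONS, "FS")
    flow = fs_exponent(pair, ALPHA_FLOW)
    elastic = fs_exponent(pair, ALPHA_ELASTIC)
    return ExponentPrediction(
        model="FS", y_variable=pair[0], x_variable=pair[1],
        flow_value=flow, elastic_value=elastic,
        range=(min(flow, elastic), max(flow, elastic)),
    )


def wbe_prediction(pair: tuple[str, str]) -> ExponentPrediction:
    """WBE point prediction for a supported pair."""
    pair = _check_pair(pair, _WBE_POINTS, "WBE")
    point, reconstructed = _WBE_POINTS[pair]
    return ExponentPrediction(
        model="WBE", y_variable=pair[0], x_variable=pair[1],
        point_value=point, reconstructed=reconstructed,
    )


#: slack on closed-interval comparisons; a perfect fit (r^2 = 1) has a
#: zero-width CI whose endpoints carry only floating-point error
_BOUNDARY_TOL = 1e-9


def classify_fit(fit: AllometryFit, prediction: ExponentPrediction) -> dict:
    """Place a fitted exponent CI against a theoretical prediction.

    FS range: ``within_range`` when the whole CI lies inside the closed
    range, ``overlaps_range`` when they merely intersect, else
    ``outside_range``.  WBE point: ``consistent_with_point`` when the
    point lies inside the closed CI, else ``inconsistent_with_point``.
    Boundary comparisons allow 1e-9 of slack so degenerate CIs from
    numerically perfect fits compare as the closed intervals they are.
    """
    lo, hi = fit.a_ci
    tol = _BOUNDARY_TOL
    if prediction.model == "FS":
        rmin, rmax = (float(prediction.range[0]), float(prediction.range[1]))
        if rmin - tol <= lo and hi <= rmax + tol:
            status = "within_range"
        elif lo <= rmax + tol and rmin - tol <= hi:
            status = "overlaps_range"
        else:
            status = "outside_range"
    elif prediction.model == "WBE":
        point = float(prediction.point_value)
        status = ("consistent_with_point" if lo - tol <= point <= hi + tol
                  else "inconsistent_with_point")
    else:
        raise ValueError(f"unknown model {prediction.model!r}")
    return {"status": status}


def tendency(fits: Sequence[AllometryFit],
             prediction: ExponentPrediction) -> dict:
    """Direction of exponent movement across ordered classification levels.

    ``toward_flow`` (``toward_elastic``) when the distance of a_hat to
    the flow (elastic) endpoint is monotonically non-increasing with at
    least one strict decrease; a constant sequence, or one qualifying
    for both endpoints, is ``mixed``.
    """
    if len(fits) < 2:
        raise ValueError("need fits at >= 2 levels to assess a tendency")
    if prediction.model != "FS":
        raise ValueError("tendency is defined against an FS prediction")
    a = [f.a_hat for f in fits]

    def moves_toward(target: float) -> bool:
        d = [abs(v - target) for v in a]
        non_increasing = all(d[i + 1] <= d[i] for i in range(len(d) - 1))
        return non_increasing and d[-1] < d[0]

    to_flow = moves_toward(float(prediction.flow_value))
    to_elastic = moves_toward(float(prediction.elastic_value))
    if to_flow and not to_elastic:
        direction = "toward_flow"
    elif to_elastic and not to_flow:
        direction = "toward_elastic"
    else:
        direction = "mixed"
    return {"direction": direction}


def prediction_table() -> pd.DataFrame:
    """All FS ranges and WBE points as a tidy table with exact fractions.

    ``flow``, ``elastic`` and ``point`` columns hold the exact
    :class:`~fractions.Fraction` values; ``*_float`` columns their float
    renderings for plotting and comparison.
    """
    rows = []
    for pair in FS_PAIRS:
        p = fs_range(pair)
        rows.append({
            "model": "FS", "y": p.y_variable, "x": p.x_variable,
            "flow": p.flow_value, "elastic": p.elastic_value,
            "range_min": p.range[0], "range_max": p.range[1],
            "point": None, "reconstructed": False,
            "flow_float": float(p.flow_value),
            "elastic_float": float(p.elastic_value),
            "point_float": None,
        })
    for pair in WBE_PAIRS:
        p = wbe_prediction(pair)
        rows.append({
            "model": "WBE", "y": p.y_variable, "x": p.x_variable,
            "flow": None, "elastic": None, "range_min": None, "range_max": None,
            "point": p.point_value, "reconstructed": p.reconstructed,
            "flow_float": None, "elastic_float": None,
            "point_float": float(p.point_value),
        })
    return pd.DataFrame(rows)
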