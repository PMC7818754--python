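"""Barcode-rank cell calling: knee/inflection thresholds and efficiencies.

The per-CID total-count distribution is displayed as a transposed log-log
empirical cumulative density ("barcode-rank") curve.  A cubic regression
spline with 20 degrees of freedom is fit to log-total vs. log-rank; the knee
is the point minimizing the signed curvature y''/(1+y'^2)^(3/2) and the
inflection the point minimizing the first derivative.  CIDs above the
inflection point count as recovered cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate


@dataclass
class RankCurve:
    """Unique descending totals with average rank for ties, in natural logs."""

    totals: np.ndarray  # unique, strictly decreasing
    ranks: np.ndarray  # average rank of each total, strictly increasing
    log_rank: np.ndarray = field(init=False)
    log_total: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not (np.diff(self.totals) < 0).all():
            raise ValueError("curve totals must be strictly decreasing")
        if not (np.diff(self.ranks) > 0).all():
            raise ValueError("curve ranks must be strictly increasing")
        self.log_rank = np.log(self.ranks)
        self.log_total = np.log(self.totals)


@dataclass
class ThresholdPoints:
    knee_rank: float
    knee_total: float
    inflection_rank: float
    inflection_total: float
    no_transition: bool = False
    spline: object | None = None

    def __post_init__(self) -> None:
        if self.knee_total < self.inflection_total:
            import warnings

            warnings.warn(
                "knee total below inflection total: atypical curve geometry",
                RuntimeWarning,
            )


def build_rank_curve(totals) -> RankCurve:
    """Collapse per-CID totals into a rank curve with tie-averaged ranks."""
    totals = np.asarray(totals, dtype=float)
    if len(totals) < 100:
        raise ValueError("need at least 100 CIDs to build a rank curve")
    if np.ptp(totals) == 0:
        raise ValueError("degenerate curve: all totals equal")
    order = np.sort(totals)[::-1]
    uniq, start, counts = np.unique(-order, return_index=True, return_counts=True)
    uniq = -uniq  # ascending on negated -> descending totals
    avg_rank = start + (counts + 1) / 2.0  # ranks are 1-based
    keep = uniq > 0
    return RankCurve(totals=uniq[keep], ranks=avg_rank[keep])


def _fit_spline(x: np.ndarray, y: np.ndarray, df: int):
    # regression spline: df = (number of interior knots) + 4 for cubic
    n_interior = max(1, min(df - 4, len(x) - 5))
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    knots = np.quantile(x, qs)
    knots = knots[(knots > x[0]) & (knots < x[-1])]
    knots = np.unique(knots)
    return interpolate.LSQUnivariateSpline(x, y, t=knots, k=3)


def knee_inflection(
    curve: RankCurve,
    lower_bound: float = 100.0,
    df: int = 20,
    grid_points: int = 10_000,
    curvature_tol: float = 0.01,
) -> ThresholdPoints:
    """Locate the knee and inflection of the barcode-rank curve.

    The spline is fit over curve points with total >= ``lower_bound`` (in
    practice the minimum total of classified CIDs, or a floor excluding the
    deep ambient tail).  Derivatives are evaluated on a uniform log-rank grid
    of ``grid_points`` points; argmins are mapped back to the nearest curve
    point.  A curve whose minimum signed curvature never drops below
    ``-curvature_tol`` (a single power-law regime, no cell/ambient
    transition) is flagged and both thresholds are placed at the curve
    boundary.
    """
    mask = curve.totals >= lower_bound
    if mask.sum() < 20:
        raise ValueError(
            f"need >= 20 curve points above lower_bound={lower_bound}, "
            f"got {int(mask.sum())}"
        )
    x = curve.log_rank[mask]
    y = curve.log_total[mask]
    spl = _fit_spline(x, y, df)
    grid = np.linspace(x[0], x[-1], grid_points)
    d1 = spl.derivative(1)(grid)
    d2 = spl.derivative(2)(grid)
    curvature = d2 / (1.0 + d1**2) ** 1.5

    def _at(idx: int) -> tuple[float, float]:
        j = int(np.argmin(np.abs(x - grid[idx])))
        sub = np.where(mask)[0][j]
        return float(curve.ranks[sub]), float(curve.totals[sub])

    if curvature.min() > -curvature_tol:
        rank, total = _at(grid_points - 1)
        return ThresholdPoints(
            knee_rank=rank,
            knee_total=total,
            inflection_rank=rank,
            inflection_total=total,
            no_transition=True,
            spline=spl,
        )
    infl_idx = int(np.argmin(d1))
    # the knee is the bend at the top of the cliff: search at or above the
    # steepest point so spline ripple below it cannot masquerade as the knee
    knee_idx = int(np.argmin(curvature[: infl_idx + 1]))
    knee_rank, knee_total = _at(knee_idx)
    infl_rank, infl_total = _at(infl_idx)
    return ThresholdPoints(
        knee_rank=knee_rank,
        knee_total=knee_total,
        inflection_rank=infl_rank,
        inflection_total=infl_total,
        spline=spl,
    )


def efficiency_metrics(
    points: ThresholdPoints, totals, n_loaded: int
) -> dict[str, float]:
    """Cell capture efficiency and library pool efficiency.

    Capture = number of CIDs with totals strictly above the inflection total,
    divided by cells loaded.  Pool = fraction of all counts falling in those
    CIDs.
    """
    if n_loaded <= 0:
        raise ValueError("n_loaded must be positive")
    totals = np.asarray(totals, dtype=float)
    above = totals > points.inflection_total
    return {
        "n_cells_called": int(above.sum()),
        "capture_efficiency": float(above.sum() / n_loaded),
        "pool_efficiency": float(totals[above].sum() / totals.sum()),
    }


def theoretical_capture(model: str, value: float) -> float:
    """Theoretical capture rate under a loading model.

    ``"sub_poisson"`` and ``"poisson_occupancy"`` pass through the stated
    occupancy fraction; ``"well_poisson"`` returns the single-cell well
    fraction lambda * exp(-lambda) of Poisson loading at mean ``value``.
    """
    if model in ("sub_poisson", "poisson_occupancy"):
        if not 0.0 <= value <= 1.0:
            raise ValueError("occupancy fraction must be in [0, 1]")
        return float(value)
    if model == "well_poisson":
        if value <= 0:
            raise ValueError("Poisson mean must be > 0")
        return float(value * np.exp(-value))
    raise ValueError(f"unknown loading model {model!r}")
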