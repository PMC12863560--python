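"""Behavioral-economic demand curves derived from dose-response data.

Conceiving each unit dose as a price — on a fixed-ratio FR schedule the
unit price of drug is C = FR / dose responses per mg/kg — the same
self-administration data yield a demand curve: consumption
Q = mean infusions × dose (mg/kg) against price C.  Demand is fitted with
the exponential model of Hursh & Silberberg:

    log10 Q = log10 Q0 + k · (exp(−α · Q0 · C) − 1)

``Q0`` is consumption at zero price (demand intensity), ``α`` the demand
elasticity (how fast consumption collapses as standardized price rises)
and ``k`` a scaling constant reflecting the consumption range, shared
across curves that are to be compared.  The essential value

    EV = 1 / (100 · α · k^1.5)

is a k-robust index of how strongly consumption is defended against
price; higher means less elastic demand.

``k`` is not identifiable per subject on a six-point curve, so it is
calibrated once per cohort (:func:`calibrate_k`): the value minimizing
the pooled residual sum of squares when every subject keeps its own
(Q0, α) but k is common.  The Hursh range convention
``k = log10(Qmax/Qmin) + 0.5`` is available as an alternative policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .cohort import CohortTable, VariableTable

__all__ = [
    "DemandCurve",
    "DemandParams",
    "ExponentialDemand",
    "ExponentialDemandResults",
    "build_demand_curve",
    "fit_demand",
    "calibrate_k",
    "range_k",
    "essential_value",
    "fit_cohort_demand",
]


@dataclass(frozen=True)
class DemandCurve:
    """(price, consumption) pairs for one subject, sorted by price."""

    prices: np.ndarray        # C = FR/dose, responses per mg/kg, > 0
    consumptions: np.ndarray  # Q = mean infusions * dose, mg/kg, > 0

    def __post_init__(self):
        p = np.asarray(self.prices, dtype=float)
        q = np.asarray(self.consumptions, dtype=float)
        if p.shape != q.shape or p.ndim != 1:
            raise ValueError("prices and consumptions must be aligned 1-D arrays")
        keep = q > 0
        p, q = p[keep], q[keep]
        if p.size == 0 or np.any(p <= 0):
            raise ValueError("need strictly positive prices with nonzero consumption")
        if len(np.unique(p)) != p.size:
            raise ValueError("prices must be distinct")
        order = np.argsort(p)
        object.__setattr__(self, "prices", p[order])
        object.__setattr__(self, "consumptions", q[order])

    @property
    def n_points(self) -> int:
        return int(self.prices.size)


@dataclass(frozen=True)
class DemandParams:
    """Exponential-demand point estimates for one curve."""

    q0: float      # consumption at zero price, mg/kg
    alpha: float   # demand elasticity
    k: float       # consumption-range scaling constant (log10 units)
    evalue: float  # 1 / (100 * alpha * k**1.5)
    r2: float      # on log10 consumption

    def __post_init__(self):
        if not (self.q0 > 0 and self.alpha > 0 and self.k > 0):
            raise ValueError("q0, alpha and k must be positive")


def essential_value(alpha: float, k: float) -> float:
    """EV = 1 / (100 · α · k^1.5); decreasing in both arguments."""
    alpha, k = float(alpha), float(k)
    if alpha <= 0 or k <= 0:
        raise ValueError("alpha and k must be positive")
    return 1.0 / (100.0 * alpha * k**1.5)


def build_demand_curve(doses, responses, fixed_ratio: int = 5) -> DemandCurve:
    """Price/consumption pairs from one subject's mean responses per dose.

    Zero doses are excluded (their price is infinite), as are zero-
    consumption points (log-undefined).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    keep = doses > 0
    if not keep.any():
        raise ValueError("no nonzero doses")
    d, r = doses[keep], responses[keep]
    return DemandCurve(prices=fixed_ratio / d, consumptions=r * d)


def _fit_q0_alpha(prices, log_q, k, n_scan: int = 7):
    """Least squares over (log10 Q0, log10 α) at fixed k; coarse α scan
    for initialization, best SSE wins."""

    def residuals(p):
        lq0, la = p
        return lq0 + k * (np.exp(-(10.0**la) * (10.0**lq0) * prices) - 1.0) - log_q

    lq0_init = float(log_q.max())
    best = None
    for la0 in np.linspace(-4.5, -1.0, n_scan):
        try:
            sol = least_squares(residuals, [lq0_init, la0],
                                xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("demand fit failed to converge")
    return best.x, 2.0 * best.cost


class ExponentialDemand:
    """Exponential demand model for one curve at a fixed k."""

    def __init__(self, curve: DemandCurve, k: float):
        if curve.n_points < 3:
            raise ValueError("need >= 3 demand points")
        if k <= 0:
            raise ValueError("k must be positive")
        self.curve = curve
        self.k = float(k)
        self.log_q = np.log10(curve.consumptions)

    def fit(self) -> "ExponentialDemandResults":
        (lq0, la), sse = _fit_q0_alpha(self.curve.prices, self.log_q, self.k)
        return ExponentialDemandResults(self, 10.0**lq0, 10.0**la, sse)


class ExponentialDemandResults:
    def __init__(self, model: ExponentialDemand, q0: float, alpha: float, sse: float):
        self.model = model
        sst = float(np.sum((model.log_q - model.log_q.mean()) ** 2))
        self.residual_ss = float(sse)
        self.params = DemandParams(
            q0=float(q0),
            alpha=float(alpha),
            k=model.k,
            evalue=essential_value(alpha, model.k),
            r2=float(1.0 - sse / sst) if sst > 0 else 1.0,
        )

    def predict(self, prices) -> np.ndarray:
        p = self.params
        logq = np.log10(p.q0) + p.k * (
            np.exp(-p.alpha * p.q0 * np.asarray(prices, dtype=float)) - 1.0
        )
        return 10.0**logq

    def summary(self) -> str:
        p = self.params
        return (
            "Exponential demand fit\n"
            f"  n points   {self.model.curve.n_points}\n"
            f"  Q0         {p.q0:.4f} mg/kg\n"
            f"  alpha      {p.alpha:.6g}\n"
            f"  k (fixed)  {p.k:.4f}\n"
            f"  eValue     {p.evalue:.6f}\n"
            f"  R^2        {p.r2:.4f}\n"
        )


def fit_demand(curve: DemandCurve, k: float) -> DemandParams:
    """Fit one demand curve at a fixed scaling constant k."""
    return ExponentialDemand(curve, k).fit().params


def range_k(curves) -> float:
    """Hursh range convention: log10(max Q / min Q) over all curves + 0.5."""
    q = np.concatenate([c.consumptions for c in curves])
    if q.max() == q.min():
        raise ValueError("degenerate constant-consumption cohort")
    return float(np.log10(q.max() / q.min()) + 0.5)


def calibrate_k(curves, bounds=(0.5, 8.0)) -> float:
    """Shared k minimizing pooled SSE with per-curve (Q0, α).

    The pooled objective is smooth and single-troughed in practice; a
    bounded scalar minimization suffices.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("need >= 2 curves to calibrate k")
    q = np.concatenate([c.consumptions for c in curves])
    if q.max() == q.min():
        raise ValueError("degenerate constant-consumption cohort")

    def pooled_sse(k):
        total = 0.0
        for c in curves:
            _, sse = _fit_q0_alpha(c.prices, np.log10(c.consumptions), k, n_scan=5)
            total += sse
        return total

    res = minimize_scalar(pooled_sse, bounds=bounds, method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


def fit_cohort_demand(cohort: CohortTable, k_policy="shared"):
    """Demand parameters for every cohort subject under one shared k.

    Parameters
    ----------
    cohort : CohortTable
    k_policy : {"shared", "range"} or positive float
        "shared" calibrates k by pooled SSE (:func:`calibrate_k`),
        "range" uses the Hursh range convention, a float fixes k.

    Returns
    -------
    (VariableTable, float)
        Table with columns ``q0, alpha, evalue, r2`` and the k used.
    """
    curves = [
        build_demand_curve(cohort.doses, cohort.row(s), cohort.fixed_ratio)
        for s in cohort.subjects
    ]
    if k_policy == "shared":
        k = calibrate_k(curves)
    elif k_policy == "range":
        k = range_k(curves)
    else:
        k = float(k_policy)
        if k <= 0:
            raise ValueError("fixed k must be positive")
    rows = []
    for c in curves:
        p = fit_demand(c, k)
        rows.append([p.q0, p.alpha, p.evalue, p.r2])
    table = VariableTable(cohort.subjects, ["q0", "alpha", "evalue", "r2"],
                          np.asarray(rows))
    return table, k
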