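"""Gaussian parameterization of the inverted-U dose-response curve.

Drug self-administration rates rise and then fall with unit dose.  On
log-log axes that inverted U is well described by a Gaussian:

    log10(response) = A · exp(−0.5 · ((log10(dose) − x0) / b)²)

with three free parameters: ``A`` the peak log10 response, ``x0`` the
log10 dose at the peak, and ``b`` the width in log10-dose units.  The
reported curve-structure variables are the antilogged peak response
(amplitude, infusions), the antilogged peak dose (mean dose,
mg/kg/infusion), the width, and the analytic area under the Gaussian,
amplitude · width · √(2π).

The model class follows the statsmodels convention: build a
:class:`GaussianDoseResponse` from one subject's data, call
:meth:`~GaussianDoseResponse.fit`, and read estimates off the returned
:class:`GaussianDoseResponseResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .cohort import CohortTable, VariableTable

__all__ = [
    "IUDRParams",
    "GaussianDoseResponse",
    "GaussianDoseResponseResults",
    "IUDRFitError",
    "fit_iudr",
    "compute_auc",
    "fit_cohort_iudr",
]

SQRT_2PI = np.sqrt(2.0 * np.pi)

#: width bounds, log10-dose units; the lower bound guards against the
#: degenerate spike solution on sparse grids
WIDTH_BOUNDS = (1e-3, 10.0)


class IUDRFitError(RuntimeError):
    """Nonlinear fit could not be performed; carries diagnostics."""


@dataclass(frozen=True)
class IUDRParams:
    """Point estimates for one subject's inverted-U curve."""

    amplitude: float      # peak response, infusions (> 0)
    mean_dose: float      # dose at the peak, mg/kg/infusion (> 0)
    width: float          # Gaussian width, log10-dose units (> 0)
    auc: float            # amplitude * width * sqrt(2*pi)
    r2: float             # 1 - SSE/SST on log10 responses
    residual_ss: float    # SSE in log10-response space

    def __post_init__(self):
        if not (self.amplitude > 0 and self.mean_dose > 0 and self.width > 0):
            raise ValueError("amplitude, mean_dose and width must be positive")


def compute_auc(amplitude, width=None) -> float:
    """Area under the fitted Gaussian curve over the full log-dose axis.

    Accepts either an :class:`IUDRParams` or ``(amplitude, width)``.  Equal
    to ``amplitude * width * sqrt(2*pi)``, the closed-form integral of
    ``amplitude * exp(-0.5*((x - x0)/width)**2)`` over x ∈ (−∞, ∞).
    """
    if width is None:
        amplitude, width = amplitude.amplitude, amplitude.width
    amplitude, width = float(amplitude), float(width)
    if amplitude <= 0 or width <= 0:
        raise ValueError("amplitude and width must be positive")
    return amplitude * width * SQRT_2PI


class GaussianDoseResponse:
    """Log-log Gaussian dose-response model for a single subject.

    Parameters
    ----------
    doses : array-like
        Unit doses in mg/kg/infusion.  Zero doses are excluded from the
        fit (their log is undefined); they may still be present in the
        input and are simply dropped with the matching responses.
    responses : array-like
        Mean infusion counts aligned with ``doses``.  Zero responses are
        excluded with a warning.
    """

    def __init__(self, doses, responses):
        doses = np.asarray(doses, dtype=float)
        responses = np.asarray(responses, dtype=float)
        if doses.shape != responses.shape:
            raise ValueError("doses and responses must align")
        usable = doses > 0
        if np.any(responses[usable] == 0):
            warnings.warn("zero-response points excluded from Gaussian fit")
            usable &= responses > 0
        self.doses = doses[usable]
        self.responses = responses[usable]
        self.log_doses = np.log10(self.doses)
        self.log_responses = np.log10(self.responses)
        if self.doses.size < 4:
            raise IUDRFitError(
                f"need >= 4 positive (dose, response) points, got {self.doses.size}"
            )

    # -- fitting ----------------------------------------------------------

    def _residuals(self, params, x, y):
        A, x0, b = params
        return A * np.exp(-0.5 * ((x - x0) / b) ** 2) - y

    def fit(self, restarts: int = 5, seed: int = 0) -> "GaussianDoseResponseResults":
        """Unweighted nonlinear least squares in log10-response space.

        Starts from the data-driven initialization (peak log response,
        log dose at the peak, half the log-dose span) plus ``restarts``
        jittered restarts; the lowest-SSE solution wins.
        """
        x, y = self.log_doses, self.log_responses
        A0 = float(y.max())
        x00 = float(x[np.argmax(y)])
        b0 = float((x.max() - x.min()) / 2) or 0.5
        starts = [(A0, x00, b0)]
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            starts.append((
                A0 * rng.uniform(0.7, 1.3),
                x00 + rng.uniform(-0.5, 0.5),
                b0 * rng.uniform(0.4, 2.0),
            ))
        best = None
        lo = [-np.inf, -np.inf, WIDTH_BOUNDS[0]]
        hi = [np.inf, np.inf, WIDTH_BOUNDS[1]]
        for p0 in starts:
            p0 = (p0[0], p0[1], float(np.clip(p0[2], *WIDTH_BOUNDS)))
            try:
                sol = least_squares(self._residuals, p0, args=(x, y),
                                    bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.all(np.isfinite(best.x)):
            raise IUDRFitError("Gaussian fit failed to converge from any start")
        return GaussianDoseResponseResults(self, best.x, 2.0 * best.cost)


class GaussianDoseResponseResults:
    """Fitted log-log Gaussian curve for one subject."""

    def __init__(self, model: GaussianDoseResponse, log_params, sse: float):
        self.model = model
        self.log_amplitude, self.log_mean_dose, self.width = map(float, log_params)
        sst = float(np.sum((model.log_responses - model.log_responses.mean()) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else 1.0
        self.params = IUDRParams(
            amplitude=10.0 ** self.log_amplitude,
            mean_dose=10.0 ** self.log_mean_dose,
            width=self.width,
            auc=compute_auc(10.0 ** self.log_amplitude, self.width),
            r2=float(r2),
            residual_ss=float(sse),
        )

    def predict(self, doses) -> np.ndarray:
        """Model-implied mean responses (infusions) at the given doses."""
        x = np.log10(np.asarray(doses, dtype=float))
        logy = self.log_amplitude * np.exp(
            -0.5 * ((x - self.log_mean_dose) / self.width) ** 2
        )
        return 10.0 ** logy

    def summary(self) -> str:
        p = self.params
        return (
            "Gaussian dose-response fit\n"
            f"  n points      {self.model.doses.size}\n"
            f"  amplitude     {p.amplitude:.5f} infusions\n"
            f"  mean dose     {p.mean_dose:.6f} mg/kg/infusion\n"
            f"  width         {p.width:.4f} log10-dose units\n"
            f"  AUC           {p.auc:.5f}\n"
            f"  R^2 (log10)   {p.r2:.4f}\n"
        )


def fit_iudr(doses, responses, restarts: int = 5, seed: int = 0) -> IUDRParams:
    """Fit one subject's curve and return the point estimates."""
    return GaussianDoseResponse(doses, responses).fit(restarts, seed).params


def fit_cohort_iudr(cohort: CohortTable, restarts: int = 5,
                    seed: int = 0) -> VariableTable:
    """Fit every subject in a cohort.

    Returns a :class:`~qscan.cohort.VariableTable` with columns
    ``amplitude, mean, width, auc, r2``.  Subjects whose fit fails are kept
    in the table with NaN values and listed in the ``fit_failures``
    attribute rather than silently dropped.
    """
    rows, failures = [], {}
    for s in cohort.subjects:
        try:
            p = fit_iudr(cohort.doses, cohort.row(s), restarts, seed)
            rows.append([p.amplitude, p.mean_dose, p.width, p.auc, p.r2])
        except IUDRFitError as err:
            failures[s] = str(err)
            rows.append([np.nan] * 5)
    table = VariableTable(cohort.subjects,
                          ["amplitude", "mean", "width", "auc", "r2"],
                          np.asarray(rows))
    table.fit_failures = failures
    return table
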