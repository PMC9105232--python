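"""Regression fitting for the four stem/bark model families.

The linear DBH model is fitted by ordinary least squares; the rational
height model and the two-predictor power models by nonlinear least
squares on the original response scale (the published goodness-of-fit
numbers are squared-response-unit MSEs, so minimising a transformed
criterion would not reproduce them).  Nonlinear fits are initialised
from exact linearisations — ``D0^2/H`` is quadratic in ``D0`` for the
height model, and the power law is linear in log-log space — so
noiseless data is recovered to machine precision.

Standard errors come from the asymptotic Jacobian-based covariance
``s^2 (J'J)^{-1}`` with ``s^2 = SSE/(n-k)``; p-values are two-sided
Wald t-tests with ``n-k`` degrees of freedom.  MSE is reported with the
residual-degrees-of-freedom denominator ``n-k`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .geometry import DomainError
from .models import (
    FitStatistics,
    LinearModelCoefficients,
    PowerModelCoefficients,
    RationalHeightCoefficients,
)

__all__ = [
    "RESPONSE_KINDS",
    "FitError",
    "ObservationTable",
    "FittedModel",
    "fit_linear",
    "fit_rational_height",
    "fit_power_two_predictor",
    "goodness_of_fit",
]

#: response kinds and whether they need the height-above-ground predictor
RESPONSE_KINDS: Mapping[str, bool] = {
    "height_m": False,
    "dbh_mm": False,
    "thickness_mm": True,
    "radius_cm": True,
}

_CSV_COLUMNS = ["tree_id", "species", "d0_mm", "hg_cm", "response", "response_kind"]


class FitError(RuntimeError):
    """A model fit could not be computed or did not converge."""


@dataclass(frozen=True)
class ObservationTable:
    """Long-format observations for one response kind.

    ``data`` columns: ``tree_id``, ``species``, ``d0_mm``, ``response``
    and, for the two-predictor kinds, ``hg_cm``.
    """

    data: pd.DataFrame
    response_kind: str

    def __post_init__(self) -> None:
        if self.response_kind not in RESPONSE_KINDS:
            raise ValueError(
                f"unknown response_kind {self.response_kind!r}; "
                f"expected one of {sorted(RESPONSE_KINDS)}"
            )
        needed = {"tree_id", "species", "d0_mm", "response"}
        if RESPONSE_KINDS[self.response_kind]:
            needed.add("hg_cm")
        missing = needed - set(self.data.columns)
        if missing:
            raise ValueError(f"observation table lacks columns {sorted(missing)}")
        if self.data["response"].isna().any():
            raise ValueError("observation table has missing responses")
        if (self.data["d0_mm"] <= 0).any():
            raise DomainError("all d0_mm must be > 0")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def two_predictor(self) -> bool:
        return RESPONSE_KINDS[self.response_kind]

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        if "hg_cm" not in out.columns:
            out["hg_cm"] = np.nan
        out["response_kind"] = self.response_kind
        # %.17g guarantees value-exact round trips through text
        out[_CSV_COLUMNS].to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationTable":
        df = pd.read_csv(path, float_precision="round_trip")
        kinds = df["response_kind"].unique()
        if len(kinds) != 1:
            raise ValueError(f"expected a single response_kind per file, got {kinds}")
        kind = str(kinds[0])
        df = df.drop(columns=["response_kind"])
        if not RESPONSE_KINDS.get(kind, False):
            df = df.drop(columns=["hg_cm"], errors="ignore")
        return cls(df, kind)


@dataclass(frozen=True)
class FittedModel:
    """Estimated coefficients with uncertainty and convergence diagnostics."""

    model_form: str  # linear_dbh | rational_height | power_two_predictor
    coefficients: Mapping[str, float]
    se: Mapping[str, float]
    p_values: Mapping[str, float]
    fit: FitStatistics
    converged: bool = True
    n_iterations: int = 0
    gradient_norm: float = 0.0
    response_unit: str | None = None

    def to_coefficients(self):
        """Convert to the corresponding prediction-coefficient object."""
        c = self.coefficients
        if self.model_form == "linear_dbh":
            return LinearModelCoefficients(
                c["b0"], c["b1"], se_b0=self.se["b0"], se_b1=self.se["b1"], fit=self.fit
            )
        if self.model_form == "rational_height":
            return RationalHeightCoefficients(
                c["b0"], c["b1"], c["b2"], se=dict(self.se), fit=self.fit
            )
        if self.model_form == "power_two_predictor":
            return PowerModelCoefficients(
                c["b0"],
                c["b1"],
                c["b2"],
                response_unit=self.response_unit or "mm",
                se=dict(self.se),
                fit=self.fit,
            )
        raise ValueError(f"unknown model_form {self.model_form!r}")


def goodness_of_fit(
    observed: Sequence[float], predicted: Sequence[float], n_params: int
) -> FitStatistics:
    """R² and MSE of a fit; MSE uses the ``n - n_params`` denominator.

    R² is reported as computed (it can be negative for fits worse than
    the mean); no clamping is applied.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"shape mismatch: {obs.shape} vs {pred.shape}")
    n = obs.size
    if n <= n_params:
        raise ValueError(f"need n > n_params, got n={n}, n_params={n_params}")
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise DomainError("zero total variance in observed values")
    return FitStatistics(r_squared=1.0 - sse / sst, mse=sse / (n - n_params), n=n)


def _wald_p(coefs: np.ndarray, se: np.ndarray, df: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(coefs / se)
    return 2.0 * stats.t.sf(t, df)


def fit_linear(data: ObservationTable) -> FittedModel:
    """Ordinary least squares for ``DBH = b0 + b1 * D0``."""
    if data.response_kind != "dbh_mm":
        raise ValueError(f"fit_linear expects dbh_mm data, got {data.response_kind}")
    if len(data) < 3:
        raise FitError(f"need at least 3 rows, got {len(data)}")
    d0 = data.data["d0_mm"].to_numpy(float)
    y = data.data["response"].to_numpy(float)
    if np.ptp(d0) == 0:
        raise FitError("d0 values are all identical; the slope is not identifiable")

    res = sm.OLS(y, sm.add_constant(d0)).fit()
    names = ("b0", "b1")
    coefs = dict(zip(names, map(float, res.params)))
    se = dict(zip(names, map(float, res.bse)))
    p = dict(zip(names, map(float, res.pvalues)))
    fit = goodness_of_fit(y, res.fittedvalues, 2)
    fit = FitStatistics(fit.r_squared, fit.mse, n=len(y), p_values=p)
    return FittedModel(
        "linear_dbh", coefs, se, p, fit, converged=True, n_iterations=0, gradient_norm=0.0
    )


def _nls(
    residual,
    p0: np.ndarray,
    names: tuple[str, ...],
    y: np.ndarray,
    model_form: str,
    response_unit: str | None = None,
    bounds=(-np.inf, np.inf),
) -> FittedModel:
    """Shared nonlinear least-squares driver with asymptotic inference.

    Convergence demands a relative SSE change below 1e-12 (scipy's
    ``ftol``) within the evaluation budget; anything else raises
    :class:`FitError` with the solver trace attached.
    """
    sol = optimize.least_squares(
        residual,
        p0,
        method="trf" if np.any(np.isfinite(bounds)) else "lm",
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-14,
        max_nfev=200 * (len(p0) + 1),
        bounds=bounds,
    )
    if sol.status <= 0:
        raise FitError(
            f"nonlinear fit of {model_form} did not converge: {sol.message} "
            f"(nfev={sol.nfev}, cost={sol.cost:.6g})"
        )
    n, k = y.size, len(p0)
    sse = 2.0 * sol.cost
    s2 = sse / (n - k)
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError as exc:  # singular design
        raise FitError(f"singular Jacobian in {model_form} fit") from exc
    se_vals = np.sqrt(np.diag(cov))
    if np.any(~np.isfinite(se_vals)) or (sse > 0 and np.any(se_vals <= 0)):
        raise FitError(f"non-positive standard errors in {model_form} fit")
    p_vals = _wald_p(sol.x, se_vals, n - k)

    coefs = dict(zip(names, map(float, sol.x)))
    se = dict(zip(names, map(float, se_vals)))
    p = dict(zip(names, map(float, p_vals)))
    predicted = y + sol.fun  # residuals are model - y
    try:
        fit = goodness_of_fit(y, predicted, k)
    except DomainError:
        # constant response: R2 is 1 for an (essentially) exact fit,
        # undefined otherwise
        if sse <= 1e-20 * max(1.0, float(np.sum(y * y))):
            fit = FitStatistics(r_squared=1.0, mse=sse / (n - k), n=n)
        else:
            raise
    fit = FitStatistics(fit.r_squared, fit.mse, n=n, p_values=p)
    return FittedModel(
        model_form,
        coefs,
        se,
        p,
        fit,
        converged=True,
        n_iterations=int(sol.nfev),
        gradient_norm=float(np.linalg.norm(sol.grad, np.inf)),
        response_unit=response_unit,
    )


def fit_rational_height(data: ObservationTable) -> FittedModel:
    """Nonlinear least squares for ``H = D0^2/(b0 + b1*D0 + b2*D0^2)``.

    Initialised by the exact linearisation: regressing ``D0^2/H`` on
    ``(1, D0, D0^2)`` by OLS, which is itself the zero-residual optimum
    for noiseless data.
    """
    if data.response_kind != "height_m":
        raise ValueError(
            f"fit_rational_height expects height_m data, got {data.response_kind}"
        )
    if len(data) < 4:
        raise FitError(f"need at least 4 rows, got {len(data)}")
    d0 = data.data["d0_mm"].to_numpy(float)
    y = data.data["response"].to_numpy(float)
    if np.unique(d0).size < 2:
        raise FitError("need more than one distinct d0")
    if np.any(y <= 0):
        raise DomainError("heights must be > 0 m")

    X = np.column_stack([np.ones_like(d0), d0, d0 * d0])
    beta, *_ = np.linalg.lstsq(X, d0 * d0 / y, rcond=None)
    p0 = beta.copy()
    if p0[2] <= 0:  # keep the asymptote finite at the start point
        p0[2] = 1.0 / max(y.max(), 0.5)

    def residual(p):
        denom = p[0] + p[1] * d0 + p[2] * d0 * d0
        return d0 * d0 / denom - y

    return _nls(residual, p0, ("b0", "b1", "b2"), y, "rational_height")


def fit_power_two_predictor(data: ObservationTable) -> FittedModel:
    """Nonlinear least squares for ``y = b0 * D0^b1 * Hg^b2``.

    Fits on the original response scale (matching squared-response-unit
    MSE reporting); a log-log OLS fit provides the starting point only.
    """
    if not data.two_predictor:
        raise ValueError(
            f"fit_power_two_predictor expects thickness_mm or radius_cm data, "
            f"got {data.response_kind}"
        )
    if len(data) < 5:
        raise FitError(f"need at least 5 rows, got {len(data)}")
    d0 = data.data["d0_mm"].to_numpy(float)
    hg = data.data["hg_cm"].to_numpy(float)
    y = data.data["response"].to_numpy(float)
    if np.any(y <= 0):
        raise DomainError("all responses must be > 0 for the power model")
    if np.any(hg <= 0):
        raise DomainError("all hg_cm must be > 0 for the power model")
    if np.unique(d0).size < 2 or np.unique(hg).size < 2:
        raise FitError("both predictors must vary")

    X = np.column_stack([np.ones_like(d0), np.log(d0), np.log(hg)])
    beta, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    p0 = np.array([np.exp(beta[0]), beta[1], beta[2]])

    def residual(p):
        return p[0] * d0 ** p[1] * hg ** p[2] - y

    unit = "mm" if data.response_kind == "thickness_mm" else "cm"
    return _nls(
        residual, p0, ("b0", "b1", "b2"), y, "power_two_predictor", response_unit=unit
    )
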