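"""Hill-equation fitting of E/c curves and comparison against references.

The centrepiece is :class:`HillRegressor`, a scikit-learn style estimator
(``fit`` / ``predict`` / ``get_params``) for the three-parameter Hill
model on the common-log concentration scale,

    E = Emax / (1 + 10^(n * (logEC50 - log10 c))),

fitted by unweighted damped (Levenberg-Marquardt-type) least squares
with a fixed, data-derived initialisation so that fitting is fully
deterministic. ``fit_hill`` / ``fit_model`` are thin functional wrappers
used by the pipeline, and ``compare_to_reference`` checks a set of fits
against the packaged reference tables (the simulated Hill parameters of
the final model, and the ex vivo parameters kept for display only).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .curve_engine import ECCurve
from .receptor_core import HillParams

__all__ = [
    "HillRegressor",
    "HillFit",
    "ReferenceTable",
    "fit_hill",
    "fit_model",
    "compare_to_reference",
    "DEFAULT_TOLERANCES",
]

# Soft parameter bounds: generous enough never to bind on a well-formed
# sigmoid, tight enough to stop runaway fits on truncated curves.
EMAX_MAX = 120.0
N_MAX = 5.0

DEFAULT_TOLERANCES: dict[str, float] = {"Emax": 0.5, "logEC50": 0.05, "n": 0.03}


class DegenerateCurveError(ValueError):
    """The curve carries no concentration-dependence to fit."""


class HillRegressor(RegressorMixin, BaseEstimator):
    """Three-parameter Hill (log-logistic) regression.

    Parameters
    ----------
    max_nfev : int, optional
        Cap on residual evaluations passed to the optimiser.

    Attributes
    ----------
    Emax_ : float
        Fitted upper plateau (percent effect).
    logEC50_ : float
        Fitted common-log half-maximal organ-bath concentration.
    n_ : float
        Fitted Hill slope.
    se_ : ndarray of shape (3,)
        Asymptotic standard errors of (Emax, logEC50, n) from the
        residual-variance-scaled inverse Gauss-Newton Hessian.
    rss_ : float
        Residual sum of squares at the optimum.
    converged_ : bool
        Whether the optimiser reported success.
    bound_hits_ : list of str
        Names of parameters that ended on a soft bound (reported, not
        silently clipped).
    n_points_ : int
        Number of fitted points.

    Examples
    --------
    >>> import numpy as np
    >>> from atriasim.receptor_core import HillParams, hill_effect
    >>> lg = np.arange(-10, -2.0, 0.5)
    >>> y = hill_effect(HillParams(80, -6, 1), 10.0 ** lg)
    >>> HillRegressor().fit(lg, y).logEC50_
    -6.0...
    """

    def __init__(self, max_nfev: int = 10_000):
        self.max_nfev = max_nfev

    # ------------------------------------------------------------------
    def fit(self, X: ArrayLike, y: ArrayLike) -> "HillRegressor":
        """Fit to log10 organ-bath concentrations ``X`` and effects ``y``."""
        lg = np.asarray(X, dtype=float).reshape(-1)
        ef = np.asarray(y, dtype=float).reshape(-1)
        if lg.shape != ef.shape:
            raise ValueError("X and y must have equal length")
        if lg.size < 4:
            raise ValueError("need at least 4 points to fit 3 parameters")
        if not (np.all(np.isfinite(lg)) and np.all(np.isfinite(ef))):
            raise ValueError("inputs must be finite")
        if np.ptp(ef) == 0.0:
            raise DegenerateCurveError("flat curve: effects are all equal")

        def resid(p: NDArray[np.float64]) -> NDArray[np.float64]:
            emax, logec, n = p
            return emax / (1.0 + 10.0 ** (n * (logec - lg))) - ef

        # Fixed initialisation: plateau from the data, midpoint from the
        # log-linear half-max crossing, unit slope.
        emax0 = float(ef.max())
        logec0 = float(np.interp(emax0 / 2.0, ef, lg))
        x0 = np.array([emax0, logec0, 1.0])
        lo = np.array([1e-6, lg.min() - 10.0, 1e-3])
        hi = np.array([EMAX_MAX, lg.max() + 10.0, N_MAX])
        sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi),
                            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                            max_nfev=self.max_nfev)

        self.Emax_, self.logEC50_, self.n_ = map(float, sol.x)
        self.rss_ = float(2.0 * sol.cost)
        self.converged_ = bool(sol.success)
        self.n_points_ = int(lg.size)
        self.bound_hits_ = [
            name for name, v, l, h in zip(("Emax", "logEC50", "n"), sol.x, lo, hi)
            if np.isclose(v, l) or np.isclose(v, h)
        ]

        dof = max(lg.size - 3, 1)
        jtj = sol.jac.T @ sol.jac
        try:
            cov = self.rss_ / dof * np.linalg.inv(jtj)
            self.se_ = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            self.se_ = np.full(3, np.nan)
            self.converged_ = False
        return self

    def predict(self, X: ArrayLike) -> NDArray[np.float64]:
        """Predicted effects at log10 organ-bath concentrations ``X``."""
        check_is_fitted(self, "Emax_")
        lg = np.asarray(X, dtype=float).reshape(-1)
        return self.Emax_ / (1.0 + 10.0 ** (self.n_ * (self.logEC50_ - lg)))

    @property
    def params_(self) -> HillParams:
        check_is_fitted(self, "Emax_")
        return HillParams(self.Emax_, self.logEC50_, self.n_)


@dataclass(frozen=True)
class HillFit:
    """Point estimates, uncertainties and diagnostics of one Hill fit."""

    params: HillParams
    se: tuple[float, float, float]
    rss: float
    converged: bool
    n_points: int
    bound_hits: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"Emax": self.params.Emax, "logEC50": self.params.logEC50,
                "n": self.params.n}


def fit_hill(curve: ECCurve) -> HillFit:
    """Fit the Hill equation to one simulated (or synthetic-mean) curve."""
    reg = HillRegressor().fit(curve.log10_c_bath, curve.effect)
    return HillFit(params=reg.params_, se=tuple(reg.se_), rss=reg.rss_,
                   converged=reg.converged_, n_points=reg.n_points_,
                   bound_hits=tuple(reg.bound_hits_))


def fit_model(curves: list[ECCurve]) -> dict[tuple[str, str], HillFit]:
    """Fit every curve of one model; keys are (agonist, treatment)."""
    fits: dict[tuple[str, str], HillFit] = {}
    errors: dict[tuple[str, str], Exception] = {}
    for cv in curves:
        try:
            fits[cv.key] = fit_hill(cv)
        except ValueError as exc:  # collect, report together
            errors[cv.key] = exc
    if errors:
        detail = "; ".join(f"{k}: {v}" for k, v in errors.items())
        raise RuntimeError(f"fit failures for {len(errors)} curve(s): {detail}")
    return fits


# ----------------------------------------------------------------------
# Reference tables

@dataclass(frozen=True)
class ReferenceTable:
    """Printed Hill parameters keyed by (agonist, treatment, parameter)."""

    source: str
    entries: Mapping[tuple[str, str, str], tuple[float, float]]

    @classmethod
    def load(cls, source: str) -> "ReferenceTable":
        """Load a packaged table: ``table2_model4`` (simulated Hill
        parameters of the final model) or ``table1_exvivo`` (ex vivo
        parameters; for display, never asserted against)."""
        if source not in ("table2_model4", "table1_exvivo"):
            raise KeyError(f"unknown reference table {source!r}")
        with resources.files("atriasim.data").joinpath(f"{source}.csv").open() as fh:
            df = pd.read_csv(fh)
        entries = {(r.agonist, r.treatment, r.parameter): (r.value, r.error)
                   for r in df.itertuples()}
        return cls(source=source, entries=entries)


def compare_to_reference(fits: Mapping[tuple[str, str], HillFit],
                         ref: ReferenceTable,
                         tol: Mapping[str, float] = DEFAULT_TOLERANCES,
                         ) -> pd.DataFrame:
    """Per-parameter deltas between fits and a reference table.

    Returns a tidy frame with columns agonist, treatment, parameter,
    fitted, reference, ref_error, delta, tol, passed. Reference entries
    with no corresponding fit are listed with NaN fitted values (a gap,
    not a crash); pass/fail uses absolute deltas against ``tol``.
    """
    rows = []
    for (ag, tr, par), (val, err) in ref.entries.items():
        fit = fits.get((ag, tr))
        fitted = fit.as_dict()[par] if fit is not None else np.nan
        delta = fitted - val
        t = float(tol[par])
        rows.append((ag, tr, par, fitted, val, err, delta, t,
                     bool(np.isfinite(delta) and abs(delta) <= t)))
    return pd.DataFrame(rows, columns=["agonist", "treatment", "parameter",
                                       "fitted", "reference", "ref_error",
                                       "delta", "tol", "passed"])
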