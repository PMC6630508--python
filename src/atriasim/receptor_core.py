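"""Operational-model primitives for A1-adenosinergic effect calculations.

The negative inotropic response of the paced guinea pig left atrium is
modelled with the Black-Leff operational model of agonism, in its
single-agonist and two-agonist forms, plus two auxiliary relationships:
a "biasing" transform that mimics neglecting the effect of a pre-existing
(endogenous) agonist when reading out a concentration-response curve, and
the Hill equation used to summarise every simulated curve.

All effects are percent decreases of the initial contractile force, so
they live on a 0-100 scale and ``Em`` (the ceiling of the transducer
function) can never usefully exceed 100.

Everything here is a pure function of its arguments; scenario handling
and concentration bookkeeping live in :mod:`atriasim.scenarios` and
:mod:`atriasim.curve_engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "OperationalSystem",
    "DualAgonistInput",
    "HillParams",
    "effect_single",
    "effect_dual",
    "bias_transform",
    "hill_effect",
]


class ConfigurationError(ValueError):
    """A parameter set violates the model's invariants."""


class InputError(ValueError):
    """A concentration or effect argument is out of domain."""


def _require(cond: bool, msg: str, exc: type[ValueError] = ConfigurationError) -> None:
    if not cond:
        raise exc(msg)


@dataclass(frozen=True)
class OperationalSystem:
    """One receptor-system state of the operational model.

    Parameters
    ----------
    Em
        Upper asymptote of the transducer (signal-amplification) function,
        percent of initial contractile force; ``Em = 100`` means complete
        abolition of contraction is attainable.
    n_op
        Operational slope factor (dimensionless).
    K
        Agonist-receptor equilibrium dissociation constant, mol/L
        (inverse affinity).
    KE
        Inverse efficacy measure, mol/L.
    R0
        Concentration of operable receptors, mol/L.

    The transducer ratio ``tau = R0 / KE`` is always derived, never stored,
    so it cannot drift out of sync with its parents.
    """

    Em: float
    n_op: float
    K: float
    KE: float
    R0: float

    def __post_init__(self) -> None:
        _require(np.isfinite(self.Em) and 0.0 < self.Em <= 100.0,
                 f"Em must be in (0, 100], got {self.Em}")
        _require(np.isfinite(self.n_op) and self.n_op > 0.0,
                 f"n_op must be positive, got {self.n_op}")
        for name in ("K", "KE", "R0"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v > 0.0, f"{name} must be positive, got {v}")

    @property
    def tau(self) -> float:
        """Transducer ratio R0/KE (dimensionless efficacy measure)."""
        return self.R0 / self.KE


@dataclass(frozen=True)
class DualAgonistInput:
    """Concentrations and per-agonist parameters for two co-acting agonists.

    ``c_test`` is the near-receptor concentration of the exogenous agonist
    used to build the curve; ``c_bias`` is the surplus near-receptor
    concentration of the endogenous agonist that accumulated beforehand.
    """

    c_test: float
    K_test: float
    tau_test: float
    c_bias: float
    K_bias: float
    tau_bias: float

    def __post_init__(self) -> None:
        for name in ("c_test", "c_bias"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v >= 0.0,
                     f"{name} must be finite and >= 0, got {v}", InputError)
        for name in ("K_test", "K_bias", "tau_test", "tau_bias"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v > 0.0, f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class HillParams:
    """Hill-equation parameters on the organ-bath concentration scale."""

    Emax: float
    logEC50: float
    n: float

    def __post_init__(self) -> None:
        _require(np.isfinite(self.Emax) and self.Emax > 0.0,
                 f"Emax must be positive, got {self.Emax}")
        _require(np.isfinite(self.n) and self.n > 0.0,
                 f"n must be positive, got {self.n}")
        _require(np.isfinite(self.logEC50), "logEC50 must be finite")


def _validate_conc(c: ArrayLike, name: str = "c") -> NDArray[np.float64]:
    arr = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0.0):
        raise InputError(f"{name} must be finite and nonnegative")
    return arr


def effect_single(sys: OperationalSystem, c: ArrayLike) -> NDArray[np.float64] | float:
    """Effect of one agonist at near-receptor concentration ``c`` (mol/L).

    Evaluates ``E = Em * (tau*c)^n / ((K + c)^n + (tau*c)^n)``, the
    operational model for a single agonist. Strictly increasing in ``c``,
    zero at ``c = 0``, and bounded above by ``Em * tau^n / (1 + tau^n)``.
    """
    arr = _validate_conc(c)
    tau, n = sys.tau, sys.n_op
    num = np.power(tau * arr, n)
    den = np.power(sys.K + arr, n) + num
    out = sys.Em * num / den
    return out if out.ndim else float(out)


def effect_dual(sys: OperationalSystem, d: DualAgonistInput) -> float:
    """Combined effect of a test and a bias agonist acting on one receptor.

    Two-agonist operational model:

    ``E = Em * A^n / (B^n + A^n)`` with
    ``A = tau_t*c_t*K_b + tau_b*c_b*K_t`` and
    ``B = c_t*K_b + K_t*K_b + c_b*K_t``.

    With ``c_bias = 0`` this reduces exactly to :func:`effect_single`
    evaluated at ``c_test``; it is symmetric under swapping the two
    agonists' (c, K, tau) triples.
    """
    n = sys.n_op
    act = d.tau_test * d.c_test * d.K_bias + d.tau_bias * d.c_bias * d.K_test
    occ = d.c_test * d.K_bias + d.K_test * d.K_bias + d.c_bias * d.K_test
    num = act**n
    return float(sys.Em * num / (occ**n + num))


def bias_transform(E: ArrayLike, E_bias: float) -> NDArray[np.float64] | float:
    """Re-express an effect as if the bias agonist's contribution were ignored.

    ``E' = 100 - 100 * (100 - E) / (100 - E_bias)``

    where ``E`` is the combined (intermediate) effect and ``E_bias`` the
    effect of the bias concentration alone. On a 0-100 percent scale this
    maps the remaining response capacity ``[E_bias, 100)`` onto ``[0, 100)``:
    an observer who is unaware of the pre-existing agonist sees the curve
    start from zero but run against a silently reduced ceiling.
    """
    if not np.isfinite(E_bias) or not (0.0 <= E_bias < 100.0):
        raise InputError(f"E_bias must lie in [0, 100), got {E_bias}")
    arr = np.asarray(E, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr >= 100.0):
        raise InputError("E must be finite and < 100")
    if np.any(arr < E_bias - 1e-9):
        raise InputError(
            "E < E_bias: the combined effect cannot be below the bias-alone "
            "effect; the scenario is mis-built")
    out = 100.0 - 100.0 * (100.0 - arr) / (100.0 - E_bias)
    out = np.maximum(out, 0.0)  # clip float dust at E == E_bias
    return out if out.ndim else float(out)


def hill_effect(p: HillParams, c: ArrayLike) -> NDArray[np.float64] | float:
    """Hill equation ``E = Emax / (1 + 10^(n*(logEC50 - log10 c)))``.

    ``c`` is the organ-bath concentration in mol/L; must be positive.
    """
    arr = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0.0):
        raise InputError("c must be finite and positive (log scale)")
    out = p.Emax / (1.0 + 10.0 ** (p.n * (p.logEC50 - np.log10(arr))))
    return out if out.ndim else float(out)
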