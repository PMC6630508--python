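"""Simulation of E/c curves for any model configuration.

A "simple" curve (Co or X arm) is the single-agonist operational model
evaluated on near-receptor concentrations. A "complex" curve (NB or
X+NB arm) is built in two steps: the two-agonist model gives the joint
effect of the exogenous test agonist plus the accumulated endogenous
bias agonist, and the biasing transform then discards the bias agonist's
share, mimicking how such curves are read out when the surplus
endogenous agonist goes unnoticed. Effects are always paired with
organ-bath (undivided) concentrations, as in the wet-lab practice the
simulation imitates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .receptor_core import (
    DualAgonistInput,
    OperationalSystem,
    bias_transform,
    effect_dual,
    effect_single,
)
from .scenarios import (
    AGONIST_A,
    AGONIST_C,
    TREATMENTS,
    Agonist,
    ModelConfig,
    Treatment,
    bias_concentration,
    near_receptor_concentration,
    receptor_pool,
)

__all__ = ["ConcentrationGrid", "ECCurve", "simulate_curve", "simulate_model",
           "curves_to_frame", "frame_to_curves"]


@dataclass(frozen=True)
class ConcentrationGrid:
    """Inclusive log10-spaced organ-bath concentration grid (mol/L).

    The default spans 1e-10 to 10^-2.5 mol/L in half-log steps, the
    usual spacing of cumulative organ-bath dosing.
    """

    log10_start: float = -10.0
    log10_end: float = -2.5
    step: float = 0.5

    def __post_init__(self) -> None:
        if not self.log10_start < self.log10_end:
            raise ValueError("log10_start must be < log10_end")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def log10_c(self) -> NDArray[np.float64]:
        n = int(round((self.log10_end - self.log10_start) / self.step))
        return self.log10_start + self.step * np.arange(n + 1)

    @property
    def c(self) -> NDArray[np.float64]:
        return 10.0 ** self.log10_c


DEFAULT_GRID = ConcentrationGrid()


@dataclass(frozen=True)
class ECCurve:
    """One simulated concentration-effect curve."""

    agonist: str
    treatment: str
    model: str
    log10_c_bath: NDArray[np.float64]
    effect: NDArray[np.float64]
    biased: bool

    def __post_init__(self) -> None:
        lc = np.asarray(self.log10_c_bath, float)
        ef = np.asarray(self.effect, float)
        object.__setattr__(self, "log10_c_bath", lc)
        object.__setattr__(self, "effect", ef)
        if lc.shape != ef.shape:
            raise ValueError("log10_c_bath and effect must align")
        if np.any(ef < 0.0) or np.any(ef >= 100.0):
            raise ValueError("effects must lie in [0, 100)")
        if np.any(np.diff(ef) < -1e-9):
            raise ValueError("effects must be nondecreasing along the grid")

    @property
    def key(self) -> tuple[str, str]:
        return (self.agonist, self.treatment)


def _system(cfg: ModelConfig, agonist: Agonist, tr: Treatment) -> OperationalSystem:
    return OperationalSystem(Em=cfg.Em, n_op=cfg.n_op, K=agonist.K,
                             KE=agonist.KE, R0=receptor_pool(cfg, tr))


def simulate_curve(cfg: ModelConfig, agonist: Agonist, tr: Treatment,
                   grid: ConcentrationGrid = DEFAULT_GRID) -> ECCurve:
    """Simulate one E/c curve for a scenario (model x agonist x treatment)."""
    sys = _system(cfg, agonist, tr)
    c_bath = grid.c
    c_near = np.array([near_receptor_concentration(cfg, agonist, tr, cb)
                       for cb in c_bath])
    c_bias = bias_concentration(cfg, tr)
    if c_bias == 0.0:
        effect = np.asarray(effect_single(sys, c_near), float)
        biased = False
    else:
        # The bias agonist is a CPA-equivalent near-receptor surplus; both
        # agonists share K and KE, so tau_bias = tau_test in every arm.
        def dual(ct: float) -> float:
            d = DualAgonistInput(c_test=ct, K_test=agonist.K, tau_test=sys.tau,
                                 c_bias=c_bias, K_bias=AGONIST_C.K,
                                 tau_bias=sys.tau)
            return effect_dual(sys, d)

        e_bias = dual(0.0)
        effect = np.asarray(
            bias_transform(np.array([dual(ct) for ct in c_near]), e_bias),
            float)
        biased = True
    return ECCurve(agonist=agonist.name, treatment=tr.label, model=cfg.name,
                   log10_c_bath=grid.log10_c, effect=effect, biased=biased)


def simulate_model(cfg: ModelConfig,
                   grid: ConcentrationGrid = DEFAULT_GRID) -> list[ECCurve]:
    """Simulate all eight curves of a model: {C, A} x {Co, X, NB, X+NB}."""
    return [simulate_curve(cfg, ag, tr, grid)
            for ag in (AGONIST_C, AGONIST_A) for tr in TREATMENTS]


def curves_to_frame(curves: list[ECCurve]) -> pd.DataFrame:
    """Long-format table: one row per simulated point."""
    rows = []
    for cv in curves:
        for lc, ef in zip(cv.log10_c_bath, cv.effect):
            rows.append((cv.model, cv.agonist, cv.treatment, lc, ef, cv.biased))
    return pd.DataFrame(rows, columns=["model", "agonist", "treatment",
                                       "log10_c_bath", "effect", "biased"])


def frame_to_curves(df: pd.DataFrame) -> list[ECCurve]:
    """Inverse of :func:`curves_to_frame` (round-trips fits bit-identically
    when written with full precision)."""
    out = []
    for (model, agonist, treatment), g in df.groupby(
            ["model", "agonist", "treatment"], sort=False):
        g = g.sort_values("log10_c_bath")
        out.append(ECCurve(agonist=agonist, treatment=treatment, model=model,
                           log10_c_bath=g["log10_c_bath"].to_numpy(),
                           effect=g["effect"].to_numpy(),
                           biased=bool(g["biased"].iloc[0])))
    return out
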