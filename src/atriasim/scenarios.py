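"""Agonists, treatments and the six preset model configurations.

Two full A1-receptor agonists are modelled: agonist A stands for
adenosine (subject to inward transmembranous transport, so its
near-receptor concentration is lower than the organ-bath one) and
agonist C for CPA (N6-cyclopentyladenosine; enzyme-resistant, not
transported, near-receptor equals bath concentration).

Two agents modify the system: agent X (FSCPX-like irreversible receptor
antagonist, leaving 18% of receptors operable) and agent NB (NBTI-like
ENT1 transport inhibitor, which both weakens the transport of agonist A
and lets endogenous agonist A accumulate to a surplus concentration
``c_bias`` before the curve is taken).

Six model configurations encode increasingly refined assumptions about
how X and NB interact; Model 4 is the final one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

__all__ = [
    "Agonist",
    "Treatment",
    "ModelConfig",
    "AGONIST_A",
    "AGONIST_C",
    "TREATMENTS",
    "MODEL_NAMES",
    "model_preset",
    "load_config",
    "near_receptor_concentration",
    "receptor_pool",
    "bias_concentration",
]

# Shared pharmacological constants: both agonists are full agonists with
# identical affinity and efficacy; only transport distinguishes them.
K_SHARED = 3e-5     # mol/L
KE_SHARED = 1e-13   # mol/L
R0_NAIVE = 1e-10    # mol/L, untreated receptor pool
R0_X = 1.8e-11      # mol/L, 18% left operable after agent X
DIVISOR_NO_NB = 400.0  # intact transport: bath / 400 at the receptors
X_NB_RATIO = 14.8952   # c_bias(NB) / c_bias(X+NB), measured ex vivo


@dataclass(frozen=True)
class Agonist:
    name: str
    transported: bool
    K: float = K_SHARED
    KE: float = KE_SHARED


AGONIST_A = Agonist("A", transported=True)
AGONIST_C = Agonist("C", transported=False)

_AGONISTS = {"A": AGONIST_A, "C": AGONIST_C}


def get_agonist(name: str) -> Agonist:
    try:
        return _AGONISTS[name.upper()]
    except KeyError:
        raise KeyError(f"unknown agonist {name!r}; expected 'A' or 'C'") from None


@dataclass(frozen=True)
class Treatment:
    """One of the four treatment arms: Co, X, NB, X+NB."""

    label: str
    x_pretreated: bool
    nb_treated: bool

    def __post_init__(self) -> None:
        expected = {
            (False, False): "Co",
            (True, False): "X",
            (False, True): "NB",
            (True, True): "X+NB",
        }[(self.x_pretreated, self.nb_treated)]
        if self.label != expected:
            raise ValueError(
                f"treatment label {self.label!r} inconsistent with flags "
                f"(expected {expected!r})")


TREATMENTS: tuple[Treatment, ...] = (
    Treatment("Co", False, False),
    Treatment("X", True, False),
    Treatment("NB", False, True),
    Treatment("X+NB", True, True),
)

_TREATMENTS = {t.label: t for t in TREATMENTS}


def get_treatment(label: str) -> Treatment:
    key = label.upper().replace(" ", "").replace("XNB", "X+NB")
    key = {"CO": "Co"}.get(key, key)
    try:
        return _TREATMENTS[key]
    except KeyError:
        raise KeyError(
            f"unknown treatment {label!r}; expected one of "
            f"{sorted(_TREATMENTS)}") from None


@dataclass(frozen=True)
class ModelConfig:
    """Complete parameterisation of one in silico model.

    ``divisor_*`` are the transport divisors applied to agonist A's
    organ-bath concentration (agonist C is never divided); ``c_bias_*``
    are surplus near-receptor endogenous-agonist concentrations already
    expressed on the near-receptor scale, so no divisor applies to them.
    """

    name: str
    Em: float
    n_op: float = 0.75
    R0_naive: float = R0_NAIVE
    R0_x: float = R0_X
    c_bias_nb: float = 0.0
    c_bias_xnb: float = 0.0
    divisor_no_nb: float = DIVISOR_NO_NB
    divisor_nb: float = 1.0
    divisor_xnb: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.Em <= 100.0:
            raise ValueError(f"Em must be in (0, 100], got {self.Em}")
        for name in ("divisor_no_nb", "divisor_nb", "divisor_xnb"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        for name in ("c_bias_nb", "c_bias_xnb"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")

    def with_overrides(self, **kwargs: float) -> "ModelConfig":
        """Return a copy with fields replaced (presets stay immutable)."""
        return replace(self, **kwargs)


_PRESETS: dict[str, ModelConfig] = {
    # Models 1-2: NB stops transport entirely (divisor 1), one arbitrary
    # c_bias for both NB arms, no X-NB interaction.
    "model1": ModelConfig("model1", Em=100.0, c_bias_nb=2.5e-6,
                          c_bias_xnb=2.5e-6, divisor_nb=1.0, divisor_xnb=1.0),
    "model2": ModelConfig("model2", Em=99.0, c_bias_nb=2.5e-6,
                          c_bias_xnb=2.5e-6, divisor_nb=1.0, divisor_xnb=1.0),
    # Model 3: Em=90, measured c_bias, NB only slows transport (divisor 6).
    "model3": ModelConfig("model3", Em=90.0, c_bias_nb=1.002e-7,
                          c_bias_xnb=1.002e-7, divisor_nb=6.0, divisor_xnb=6.0),
    # Model 4 (final): distinct c_bias for X+NB — X blunts NB's
    # accumulation of the endogenous agonist.
    "model4": ModelConfig("model4", Em=90.0, c_bias_nb=1.002e-7,
                          c_bias_xnb=6.727e-9, divisor_nb=6.0, divisor_xnb=6.0),
    # Variant v1: like Model 4 but NB stops transport completely.
    "model4v1": ModelConfig("model4v1", Em=90.0, c_bias_nb=1.002e-7,
                            c_bias_xnb=6.727e-9, divisor_nb=1.0,
                            divisor_xnb=1.0),
    # Variant v2: X additionally blunts NB's effect on the exogenous
    # agonist, composed multiplicatively on the X+NB divisor.
    "model4v2": ModelConfig("model4v2", Em=90.0, c_bias_nb=1.002e-7,
                            c_bias_xnb=6.727e-9, divisor_nb=6.0,
                            divisor_xnb=6.0 * X_NB_RATIO),
}

MODEL_NAMES: tuple[str, ...] = tuple(_PRESETS)


def model_preset(name: str) -> ModelConfig:
    """Return the preset configuration for one of the six model names."""
    key = name.lower().replace("-", "").replace("_", "")
    try:
        return _PRESETS[key]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; expected one of {MODEL_NAMES}") from None


def load_config(path) -> ModelConfig:
    """Read a ModelConfig from a structured text file (YAML or JSON).

    The file holds a mapping of ModelConfig fields; ``base`` may name a
    preset whose fields serve as defaults for the remaining keys.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a key-value mapping")
    base_name = raw.pop("base", None)
    fields = {f.name for f in dataclasses.fields(ModelConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if base_name is not None:
        return model_preset(base_name).with_overrides(**raw)
    return ModelConfig(**raw)


def near_receptor_concentration(cfg: ModelConfig, agonist: Agonist,
                                tr: Treatment, c_bath: float) -> float:
    """Translate an organ-bath concentration to the near-receptor one.

    Agonist C is never divided. Agonist A is divided by 400 with intact
    transport (Co, X) and by the model's NB or X+NB divisor otherwise.
    """
    if c_bath < 0.0:
        raise ValueError("c_bath must be >= 0")
    if not agonist.transported:
        return c_bath
    if not tr.nb_treated:
        return c_bath / cfg.divisor_no_nb
    return c_bath / (cfg.divisor_xnb if tr.x_pretreated else cfg.divisor_nb)


def receptor_pool(cfg: ModelConfig, tr: Treatment) -> float:
    """Operable receptor concentration (mol/L) for a treatment arm."""
    return cfg.R0_x if tr.x_pretreated else cfg.R0_naive


def bias_concentration(cfg: ModelConfig, tr: Treatment) -> float:
    """Surplus near-receptor endogenous-agonist concentration (mol/L).

    Zero without NB; already near-receptor-scale, so never divided.
    """
    if not tr.nb_treated:
        return 0.0
    return cfg.c_bias_xnb if tr.x_pretreated else cfg.c_bias_nb
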