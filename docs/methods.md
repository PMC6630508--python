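# Methods

## Model and assumptions

The package simulates the direct negative inotropic response of the
isolated, paced guinea pig left atrium to A1 adenosine receptor full
agonists, on a percent-of-initial-contractile-force scale. Effects are
generated algebraically from the Black–Leff operational model of
agonism; no kinetics are modelled — every treatment is a static change
of parameters.

Two agonists share all receptor parameters (`K = 3e-5` mol/L,
`KE = 1e-13` mol/L) and differ in exactly one property: agonist A
(adenosine-like) is subject to inward transmembranous transport, so its
near-receptor concentration is an organ-bath concentration divided by a
transport divisor; agonist C (CPA-like) is enzyme-resistant and never
divided. Two agents perturb the system:

- **agent X** (irreversible antagonist): receptor pool reduced from
  `R0 = 1e-10` to `1.8e-11` mol/L (18% operable, a division by ≈5.556),
  i.e. the transducer ratio `tau = R0/KE` falls from 1000 to 180;
- **agent NB** (transport inhibitor): the divisor of agonist A drops
  from 400 to the model's NB divisor, and a surplus near-receptor
  concentration `c_bias` of endogenous agonist A appears *before* the
  curve is generated.

A simple (Co or X) curve is the single-agonist operational model on
near-receptor concentrations. A complex (NB or X+NB) curve is the
two-agonist operational model — test agonist plus bias agonist — passed
through the biasing transform `E' = 100 - 100(100-E)/(100-E_bias)`,
which models the standard (bias-unaware) evaluation of such curves:
the bias agonist's effect `E_bias` is silently subtracted from the
available response capacity. `E_bias` is recomputed for every
treatment arm and configuration rather than cached, so parameter
overrides can never stale it. The bias concentration is interpreted as
a CPA-equivalent near-receptor surplus and is therefore evaluated with
agonist-C parameters and never divided; since both agonists share K and
KE this is a labelling, not a numerical, choice.

Effects are always paired with organ-bath (undivided) concentrations,
mirroring wet-lab practice where near-receptor concentrations are
unknown.

## Preset configurations

| preset | Em | c_bias (NB) | c_bias (X+NB) | divisor (NB) | divisor (X+NB) |
|---|---|---|---|---|---|
| model1 | 100 | 2.5e-6 | 2.5e-6 | 1 | 1 |
| model2 | 99 | 2.5e-6 | 2.5e-6 | 1 | 1 |
| model3 | 90 | 1.002e-7 | 1.002e-7 | 6 | 6 |
| model4 | 90 | 1.002e-7 | 6.727e-9 | 6 | 6 |
| model4v1 | 90 | 1.002e-7 | 6.727e-9 | 1 | 1 |
| model4v2 | 90 | 1.002e-7 | 6.727e-9 | 6 | 89.3712 |

All presets share `n_op = 0.75`, the receptor pools above, and divisor
400 with intact transport. Model 4 is the final configuration: its two
`c_bias` values (ratio 14.8952, taken from ex vivo measurements) encode
an X–NB interaction confined to the *endogenous* agonist. Variant v2
composes its X+NB divisor multiplicatively (6 × 14.8952) because the
additional attenuation applies to the already NB-divided near-receptor
concentration. The `model1`/`model2` bias concentration (2.5e-6) is an
opaque constant of the simplest scenario; presets are frozen
dataclasses, and overrides create new configs.

## Concentration grid and Hill fitting

The default organ-bath grid spans log10 c from −10 to −2.5 in half-log
steps (16 points) — the printed range of the study, with the spacing
chosen as the standard cumulative-dosing half-log step. Fits are
grid-stable: halving the step moves every fitted parameter by <0.1%
(tested), so the unknown original spacing is immaterial at the
tolerances used. Fitting always uses the full simulated range; the
narrower ranges seen in display figures are treated as crops.

`HillRegressor` fits `E = Emax / (1 + 10^(n(logEC50 - log10 c)))` by
unweighted damped least squares (scipy's trust-region reflective solver
with tolerances 1e-14), with a fixed data-derived initialisation
(`Emax0` = max observed effect, `logEC50_0` = log-linear half-max
crossing, `n0 = 1`) so fits are deterministic and bit-reproducible.
Soft bounds `Emax <= 120`, `n <= 5` guard against runaway fits on
truncated curves; bound hits are reported, never silently clipped.
Standard errors are asymptotic (residual-variance-scaled inverse
Gauss–Newton Hessian). They depend on the grid density, so they are
reported but never compared against reference values; only point
estimates are treated as reproducible. Comparison tolerances against
the packaged simulated-reference table default to (Emax 0.5,
logEC50 0.05, n 0.03), absorbing the unknown grid spacing, and are
CLI-configurable.

## Synthetic replicate data

The original ex vivo recordings are unpublished, so the
`synthetic_data` module manufactures stand-ins: additive homoscedastic
Gaussian noise (default sd 3 percent-effect, roughly the scale of the
ex vivo SEMs) on any model curve, across a configurable number of
simulated atria (default 8), clipped to the physical [0, 100] scale
with clip events counted and a warning above 10% clipped. A per-point
sd schedule hook exists for sensitivity work; no heteroscedastic
structure is assumed because only SEMs, not variance structure, are
reported for the real data. Replicates are averaged before fitting by
default (matching the averaged presentation of the ex vivo curves);
fitting individual replicates is a mode switch. Everything is a pure
function of (inputs, seed); the package default seed is fixed.

What passing recovery tests show: the Hill-fitting stage is unbiased
relative to its RMSE and consistent as noise vanishes *under this noise
model*. They do not show robustness to drift, tachyphylaxis,
stimulation artifacts or per-animal variance structure of real atrial
preparations, none of which are emulated.

## Numerical choices and degenerate inputs

- Effects are validated to [0, 100): the operational model's output is
  strictly below `Em`, and `Em <= 100` because the contractile force
  cannot fall below zero.
- `bias_transform` *enforces* `E >= E_bias` (a violation signals a
  mis-built scenario) and rejects `E_bias >= 100` (degenerate
  denominator); at `E == E_bias` float dust is clamped to exactly 0.
- Flat curves raise a degenerate-input error in fitting; fewer than 4
  points are rejected (3 parameters).
- The two-agonist model reduces to the single-agonist one at
  `c_bias = 0` to machine precision, a tested identity.

## Known limitations

- Purely algebraic treatment rules: no washout kinetics for agent X, no
  time-resolved transport; agent X is a static 18% residual pool.
- The Em-dependent order reversal of the complex curves is reproduced
  (fitted Emax difference changes sign near Em ≈ 99.9), but the NB and
  X+NB curves can only coincide in their plateau region: the
  receptor-pool knockdown shifts the X+NB rising phase by
  ~0.56 log units at every Em, leaving an irreducible mid-curve gap of
  about 1–2 percent effect.
- Single receptor, full agonists only; no partial-agonist or
  multi-receptor extensions.
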