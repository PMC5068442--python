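"""The oxygen store/usage model of dive duration, with Q10 temperature rescaling.

An air-breathing diver can stay down roughly as long as its onboard oxygen
store lasts: ``t_D = TO2 / B``, where ``TO2 = a * M**b`` is the oxygen carried
(approximately linear in body mass, ``b = 1``) and ``B = c * M**d * exp(k*T)``
is the rate it is burned (allometric in mass with exponent ``d`` near 3/4 and
exponentially increasing with temperature).  Dividing gives

    t_D = (a / c) * M**(b - d) * exp(-k * T)

so on the log scale dive duration is affine in ``ln M`` and ``T``, with mass
slope ``b - d`` and temperature slope ``-k``.

Two temperature constants appear in the literature and are kept independent
here: the exponential rate coefficient ``k`` (per °C) and the Q10 (fold change
of a rate per 10 °C, ``Q10 = exp(10 k)``).  ``k = 0.12`` and ``Q10 = 2.5`` are
both conventional but mutually inconsistent (``exp(1.2) ≈ 3.32``,
``ln(2.5)/10 ≈ 0.0916``); this module stores both and never silently converts
one into the other.  Observed durations are normalized to a reference
temperature using the Q10: a rate rises with temperature, so a duration
measured colder than the reference is shortened when moved to it.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

__all__ = [
    "ScalingParams",
    "DivePrediction",
    "oxygen_store",
    "metabolic_rate",
    "predicted_dive_duration",
    "mass_exponent",
    "q10_rate_coefficient",
    "normalize_duration",
]


@dataclass(frozen=True)
class ScalingParams:
    """Parameters of the oxygen store/usage model.

    a : oxygen stored per gram of body mass (volume · g⁻¹), > 0
    b : mass exponent of oxygen storage (dimensionless), default 1
    c : metabolic normalization constant (volume · g⁻ᵈ · min⁻¹), > 0
    d : mass exponent of whole-organism metabolic rate, default 3/4
    k : exponential temperature coefficient of metabolic rate (°C⁻¹)
    Q10 : fold change of metabolic rate per 10 °C (> 1)
    T_ref : reference temperature for duration normalization (°C)
    """

    a: float = 1.0
    b: float = 1.0
    c: float = 1.0
    d: float = 0.75
    k: float = 0.12
    Q10: float = 2.5
    T_ref: float = 30.0

    def __post_init__(self):
        if self.a <= 0 or self.c <= 0:
            raise ValueError("a and c must be positive")
        if not (0 < self.d <= self.b):
            raise ValueError("require 0 < d <= b")
        if self.k < 0:
            raise ValueError("k must be nonnegative")
        if self.Q10 <= 1:
            raise ValueError("Q10 must exceed 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScalingParams":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class DivePrediction:
    """A predicted dive duration at a given mass and temperature."""

    mass_g: float
    temp_C: float
    duration_min: float


def _check_mass(mass_g: float) -> None:
    if mass_g <= 0:
        raise ValueError(f"body mass must be positive, got {mass_g}")


def oxygen_store(mass_g: float, params: ScalingParams = ScalingParams()) -> float:
    """Total oxygen carried on a dive: ``a * M**b`` (volume)."""
    _check_mass(mass_g)
    return params.a * mass_g ** params.b


def metabolic_rate(
    mass_g: float, temp_C: float, params: ScalingParams = ScalingParams()
) -> float:
    """Oxygen consumption rate: ``c * M**d * exp(k * T)`` (volume per minute)."""
    _check_mass(mass_g)
    return params.c * mass_g ** params.d * math.exp(params.k * temp_C)


def predicted_dive_duration(
    mass_g: float, temp_C: float, params: ScalingParams = ScalingParams()
) -> DivePrediction:
    """Dive duration as store over usage: ``(a/c) * M**(b-d) * exp(-k*T)`` minutes."""
    _check_mass(mass_g)
    duration = (
        params.a
        / params.c
        * mass_g ** (params.b - params.d)
        * math.exp(-params.k * temp_C)
    )
    return DivePrediction(mass_g=mass_g, temp_C=temp_C, duration_min=duration)


def mass_exponent(params: ScalingParams = ScalingParams()) -> float:
    """The predicted log-log slope of dive duration on body mass, ``b - d``."""
    return params.b - params.d


def q10_rate_coefficient(Q10: float) -> float:
    """Per-°C exponential rate coefficient equivalent to a given Q10: ``ln(Q10)/10``."""
    if Q10 <= 0:
        raise ValueError(f"Q10 must be positive, got {Q10}")
    return math.log(Q10) / 10.0


def normalize_duration(
    t_obs: float, T_obs: float, params: ScalingParams = ScalingParams()
) -> float:
    """Rescale an observed duration to the reference temperature.

    Duration is inversely proportional to metabolic rate, and the rate scales
    as ``Q10**(T/10)``; moving an observation from ``T_obs`` to ``T_ref``
    therefore multiplies it by ``Q10**((T_obs - T_ref)/10)``.  A duration
    measured 10 °C below a Q10=2.5 reference shrinks 2.5-fold.
    """
    if t_obs <= 0:
        raise ValueError(f"duration must be positive, got {t_obs}")
    return t_obs * params.Q10 ** ((T_obs - params.T_ref) / 10.0)
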