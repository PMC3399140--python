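"""Temperature-dependent exponential decomposition of salmon carcasses.

Carcass dry mass is assumed to decline exponentially, ``W(t) = W(0)·e^{kt}``
with a daily rate constant ``k ≤ 0`` (more negative = faster decay). A
compilation of published salmonid decomposition observations ships with the
package; an ordinary least-squares fit of ``k`` on temperature provides the
daily rate used to decay the carcass pool under any winter temperature
series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecayObservation",
    "DecayModel",
    "load_decay_observations",
    "read_decay_csv",
    "decay_rate_from_masses",
    "fit_decay_temperature_model",
    "predict_k",
    "apply_decay",
]


@dataclass(frozen=True)
class DecayObservation:
    """One published carcass-decomposition measurement."""

    species: str
    temperature: float  # °C
    k: float  # day⁻¹, negative for mass loss
    exposure: str  # "Air" | "Water"
    source: str


@dataclass(frozen=True)
class DecayModel:
    """Fitted linear map from temperature (°C) to daily decay rate k (day⁻¹)."""

    slope: float  # day⁻¹ °C⁻¹
    intercept: float  # day⁻¹
    r_squared: float
    n_obs: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")
        if self.n_obs < 2:
            raise ValueError(f"n_obs must be >= 2, got {self.n_obs}")

    def predict(self, temperature: float) -> float:
        return predict_k(self, temperature)


def read_decay_csv(path) -> list[DecayObservation]:
    """Read decay observations from the CSV interchange format."""
    frame = pd.read_csv(path)
    required = {"species", "temperature_C", "k_per_day", "exposure", "source"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"decay CSV missing columns: {', '.join(sorted(missing))}")
    return [
        DecayObservation(
            species=row.species,
            temperature=float(row.temperature_C),
            k=float(row.k_per_day),
            exposure=row.exposure,
            source=row.source,
        )
        for row in frame.itertuples(index=False)
    ]


def load_decay_observations() -> list[DecayObservation]:
    """The nine shipped salmonid decomposition observations (−0.5 to 16 °C)."""
    ref = resources.files("eaglewinter.data") / "decay_observations.csv"
    with resources.as_file(ref) as path:
        return read_decay_csv(path)


def decay_rate_from_masses(w0: float, wt: float, t: float) -> float:
    """Daily decay rate k = ln(wt/w0)/t from two dry-mass measurements.

    Mass loss gives a negative k, matching the sign convention of the
    shipped observation table.
    """
    if w0 <= 0 or wt <= 0:
        raise ValueError("masses must be positive")
    if t <= 0:
        raise ValueError("elapsed time must be positive")
    return math.log(wt / w0) / t


def fit_decay_temperature_model(
    obs: Sequence[DecayObservation] | Iterable[DecayObservation],
) -> DecayModel:
    """Ordinary least squares of decay rate k on temperature.

    Air and water exposures are pooled; no weighting or transformation is
    applied.
    """
    obs = list(obs)
    if len(obs) < 2:
        raise ValueError("need at least 2 observations to fit")
    temps = np.array([o.temperature for o in obs], dtype=float)
    ks = np.array([o.k for o in obs], dtype=float)
    if np.ptp(temps) == 0:
        raise ValueError("all temperatures identical: regression is singular")
    result = stats.linregress(temps, ks)
    r_squared = float(result.rvalue**2)
    if math.isnan(r_squared):  # constant k: the fit explains nothing
        r_squared = 0.0
    return DecayModel(
        slope=float(result.slope),
        intercept=float(result.intercept),
        r_squared=min(1.0, max(0.0, r_squared)),
        n_obs=len(obs),
    )


def predict_k(model: DecayModel, temperature: float) -> float:
    """Daily decay rate at a given temperature, clamped to ≤ 0.

    The fitted line crosses zero near −2 °C; without the clamp, colder
    temperatures would make carcasses gain mass, which is unphysical.
    """
    return min(0.0, model.slope * temperature + model.intercept)


def apply_decay(mass: float, k: float, days: float) -> float:
    """Exponential dry-mass decay: ``mass · e^{k·days}`` with k ≤ 0."""
    if mass < 0:
        raise ValueError("mass must be >= 0")
    if k > 0:
        raise ValueError("decay rate k must be <= 0")
    if days < 0:
        raise ValueError("elapsed days must be >= 0")
    return mass * math.exp(k * days)
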