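"""Seasonal temperature forcing and run scenarios.

The model year is a 250-day growing season; the remaining 115 calendar
days are excluded from the simulation clock entirely (physiology is
assumed dormant).  Water temperature over the season follows a sinusoid

    T(t) = T_mean + a * sin(2 * pi * (t + omega) / GS)

with t a real day-of-year in [0, GS).  The two shipped regimes describe a
cooler ("1980s") and a warmer ("2010s") decade of Wadden Sea conditions;
with omega = 187 the season opens at the annual temperature minimum and
peaks mid-season (t = 125.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "TemperatureRegime",
    "Scenario",
    "REGIME_NAMES",
    "get_regime",
    "seasonal_temperature",
    "regime_summary",
    "FEEDING_LEVELS",
]

#: The three reported constant feeding levels (low, moderate, high).
FEEDING_LEVELS = (0.5, 0.7, 1.0)


@dataclass(frozen=True)
class TemperatureRegime:
    """Parameters of one seasonal sinusoid."""

    name: str
    T_mean: float    # annual mean water temperature (deg C)
    a: float         # amplitude (deg C)
    omega: float     # phase shift (days)
    GS: int = 250    # growing-season length (days)

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.a}")
        if self.GS <= 0:
            raise ValueError(f"growing season must be positive, got {self.GS}")


def _load_regimes() -> dict[str, TemperatureRegime]:
    text = (resources.files("thermofish") / "regimes.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: TemperatureRegime(name=name, **entry)
            for name, entry in raw.items()}


_REGIMES = _load_regimes()
REGIME_NAMES = tuple(sorted(_REGIMES))


def get_regime(name_or_path: str | Path) -> TemperatureRegime:
    """Fetch a shipped regime by name ("1980s", "2010s") or load a custom
    single-regime YAML file (keys: T_mean, a, omega, optional GS)."""
    key = str(name_or_path)
    if key in _REGIMES:
        return _REGIMES[key]
    p = Path(name_or_path)
    if p.suffix in (".yaml", ".yml") and p.is_file():
        raw = yaml.safe_load(p.read_text())
        return TemperatureRegime(name=p.stem, **raw)
    raise KeyError(f"unknown regime {key!r}; shipped: {list(REGIME_NAMES)}")


@dataclass(frozen=True)
class Scenario:
    """One simulation configuration.

    The model is deterministic; ``seed`` is reserved for future stochastic
    extensions and does not affect the run."""

    species: str
    regime: TemperatureRegime
    R_l: float                       # feeding level in [0, 1]
    dt: float = 1.0                  # step size (days)
    seed: int = 0
    integrator: str = "euler"        # "euler" (reference) or "rk4"
    prefeeding_mode: str = "inert"   # "inert" or "maintenance_only"
    thermal_mass_basis: str = "total"  # mass the thermal sizes use

    def __post_init__(self) -> None:
        if not (0.0 <= self.R_l <= 1.0):
            raise ValueError(f"feeding level must be in [0, 1], got {self.R_l}")
        if not (0.0 < self.dt <= 1.0):
            raise ValueError(f"dt must be in (0, 1] days, got {self.dt}")
        if self.integrator not in ("euler", "rk4"):
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.prefeeding_mode not in ("inert", "maintenance_only"):
            raise ValueError(
                f"unknown prefeeding mode {self.prefeeding_mode!r}")


def seasonal_temperature(reg: TemperatureRegime, t: float) -> float:
    """Water temperature (deg C) at day-of-year ``t`` in [0, GS).

    Callers stepping across years wrap t themselves (t = age mod GS)."""
    if not (0.0 <= t < reg.GS):
        raise ValueError(
            f"day-of-year must lie in [0, {reg.GS}), got {t!r}")
    return reg.T_mean + reg.a * math.sin(2.0 * math.pi * (t + reg.omega) / reg.GS)


def regime_summary(reg: TemperatureRegime, threshold: float) -> int:
    """Number of integer days t in {0, ..., GS-1} with T(t) <= threshold.

    Diagnostic only — e.g. the duration of thermally favourable conditions
    for a given species.  Counts from the idealized sinusoid can differ by
    a few days from counts taken on the monthly field data the sinusoid
    summarizes."""
    return sum(1 for t in range(reg.GS)
               if seasonal_temperature(reg, float(t)) <= threshold)
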