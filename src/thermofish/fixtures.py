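"""Verification oracles and synthetic observation tables.

Everything here exists so the repository is testable without downloads:
an independent straight-line re-derivation of the thermal performance
factor (used as a cross-check oracle, sharing no code with
:mod:`thermofish.thermal_response`), a generator of fake survey-style
length-at-age tables, and a descriptive overlay report comparing
simulated growth envelopes with an observation table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .species_registry import ThermalScaling, load_species
from .environment import Scenario, get_regime
from . import simulate as sim

__all__ = [
    "brute_force_thermal",
    "make_fake_observations",
    "overlay_report",
    "OBSERVATION_COLUMNS",
]

OBSERVATION_COLUMNS = ("species", "age_years", "length_cm", "period", "source")


def brute_force_thermal(s: ThermalScaling, w: float, T: float) -> float:
    """Thermal factor computed formula-by-formula, for oracle tests only.

    Deliberately naive: every intermediate (T_opt, T_max, Q, V, W, Y, X)
    is spelled out and combined with plain power/exp calls, with none of
    the log-space rearrangement the production path uses."""
    import math
    t_opt = s.gamma_opt * w ** s.v_opt
    t_max = s.gamma_max * w ** s.v_max
    q = s.theta_coef * w ** s.theta_exp
    if T >= t_max:
        return 0.0
    big_v = (t_max - T) / (t_max - t_opt)
    big_w = (t_max - t_opt) * math.log(q)
    big_y = (t_max - t_opt + 2.0) * math.log(q)
    big_x = big_w ** 2 * (1.0 + (1.0 + 40.0 / big_y) ** 0.5) ** 2 * (1.0 / 400.0)
    return big_v ** big_x * math.exp(big_x * (1.0 - big_v))


def make_fake_observations(seed: int, species: str,
                           n: int = 60, spread: float = 0.08) -> pd.DataFrame:
    """Synthetic survey-style length-at-age table for one species.

    Lengths are drawn lognormally (relative sd ``spread``) around the
    simulated cooler-regime length-at-age curve at moderate feeding, at
    uniformly random ages within the simulated lifetime.  Deterministic
    per seed.  Columns follow :data:`OBSERVATION_COLUMNS`."""
    p = load_species(species)
    res = sim.run_individual(Scenario(species=species,
                                      regime=get_regime("1980s"), R_l=0.7))
    traj = res.trajectory
    rng = np.random.default_rng(seed)
    max_age = float(traj["age_years"].iloc[-1])
    ages = rng.uniform(0.0, min(max_age, p.max_lifespan_years), size=n)
    curve = np.interp(ages, traj["age_years"], traj["length_cm"])
    lengths = curve * rng.lognormal(mean=0.0, sigma=spread, size=n)
    return pd.DataFrame({
        "species": species,
        "age_years": ages,
        "length_cm": lengths,
        "period": "synthetic",
        "source": f"fake-survey-seed-{seed}",
    })


def overlay_report(trajectories: dict[float, pd.DataFrame],
                   obs: pd.DataFrame, species: str) -> pd.DataFrame:
    """Per-observation envelope check against feeding-level extremes.

    ``trajectories`` maps feeding level to a trajectory frame for
    ``species``; the envelope at each observed age is the interval spanned
    by the lowest and highest feeding-level curves.  Returns one row per
    observation with the envelope bounds and an ``inside`` flag; the
    ``inside`` column mean is the inside-envelope fraction.  Raises
    ``ValueError`` on a species mismatch.  Empty observations give an
    empty report."""
    if len(obs) and not (obs["species"] == species).all():
        bad = sorted(set(obs["species"]) - {species})
        raise ValueError(f"observation species mismatch: {bad}")
    if not trajectories:
        raise ValueError("need at least one trajectory")
    lo_level, hi_level = min(trajectories), max(trajectories)
    out = obs.copy()
    if not len(obs):
        out["envelope_low"] = pd.Series(dtype=float)
        out["envelope_high"] = pd.Series(dtype=float)
        out["inside"] = pd.Series(dtype=bool)
        return out
    ages = obs["age_years"].to_numpy(dtype=float)
    bounds = []
    for lvl in (lo_level, hi_level):
        t = trajectories[lvl]
        bounds.append(np.interp(ages, t["age_years"], t["length_cm"]))
    low = np.minimum(*bounds)
    high = np.maximum(*bounds)
    out["envelope_low"] = low
    out["envelope_high"] = high
    out["inside"] = (obs["length_cm"].to_numpy() >= low) & \
                    (obs["length_cm"].to_numpy() <= high)
    return out
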