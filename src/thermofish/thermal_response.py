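"""Size-dependent thermal performance curves.

Each physiological process (food intake, maintenance metabolism) carries a
unimodal temperature response factor r(w, T) in [0, 1] that multiplies the
process rate.  Both the optimum temperature T_opt(w) and the upper lethal
limit T_max(w) shrink as the fish grows (negative mass exponents), which is
what lets warming suppress large individuals while sparing small ones.

The factor is the classic dome-shaped consumption curve used in fish
bioenergetics:

    r(w, T) = V**X * exp(X * (1 - V))

with

    V = (T_max - T) / (T_max - T_opt)
    W = (T_max - T_opt) * ln Q
    Y = (T_max - T_opt + 2) * ln Q
    X = W**2 * (1 + sqrt(1 + 40 / Y))**2 / 400

and T_opt, T_max, Q power laws of total mass (see
:class:`~thermofish.species_registry.ThermalScaling`).  r equals 1 at
T = T_opt and 0 at T = T_max; above T_max the curve is clamped to 0
(lethal-limit semantics — V would be negative and V**X undefined for
fractional X).  Below the optimum the exponential term drives a smooth
decay toward 0 with no lower clamp.
"""

from __future__ import annotations

import math

from .species_registry import ThermalScaling

__all__ = [
    "thermal_optimum",
    "thermal_maximum",
    "thermal_q",
    "temperature_factor",
]


def _check_mass(w: float) -> None:
    if not (w > 0):
        raise ValueError(f"mass must be > 0 g, got {w!r}")


def thermal_optimum(s: ThermalScaling, w: float) -> float:
    """Optimum temperature (deg C) at total mass ``w`` (g)."""
    _check_mass(w)
    return s.gamma_opt * w ** s.v_opt


def thermal_maximum(s: ThermalScaling, w: float) -> float:
    """Upper lethal temperature (deg C) at total mass ``w`` (g)."""
    _check_mass(w)
    return s.gamma_max * w ** s.v_max


def thermal_q(s: ThermalScaling, w: float) -> float:
    """Q10-like steepness of the curve at total mass ``w`` (g); must be > 1."""
    _check_mass(w)
    q = s.theta_coef * w ** s.theta_exp
    if not (q > 1):
        raise ValueError(
            f"thermal steepness Q({w} g) = {q:.6g} must exceed 1 "
            f"(ln Q degenerate otherwise)")
    return q


def temperature_factor(s: ThermalScaling, w: float, T: float) -> float:
    """Thermal performance factor r(w, T) in [0, 1].

    Returns exactly 0 for T >= T_max(w).  Raises ``ValueError`` when the
    scaling is degenerate at this mass (T_max <= T_opt or Q <= 1).
    """
    t_opt = thermal_optimum(s, w)
    t_max = thermal_maximum(s, w)
    if not (t_max > t_opt):
        raise ValueError(
            f"T_max({w} g) = {t_max:.6g} must exceed T_opt({w} g) = "
            f"{t_opt:.6g}")
    ln_q = math.log(thermal_q(s, w))
    if T >= t_max:
        return 0.0
    span = t_max - t_opt
    v = (t_max - T) / span
    w_ = span * ln_q
    y_ = (span + 2.0) * ln_q
    x_ = w_ * w_ * (1.0 + math.sqrt(1.0 + 40.0 / y_)) ** 2 / 400.0
    # log-space evaluation keeps the V >> 1 (cold) tail stable
    log_r = x_ * (math.log(v) + 1.0 - v)
    return min(math.exp(log_r), 1.0)
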