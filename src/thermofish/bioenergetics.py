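"""Per-day physiology of one individual: rates, allocation and fecundity.

The individual carries two masses: structural mass ``x`` (bones, vital
organs — never catabolized) and reserve mass ``y`` (fat, muscle, gonads —
burned to cover maintenance deficits).  Body condition is the ratio y/x;
Fulton's index 100 * (x + y) / L**3 is also exposed for comparison with
field data.  Standardized mass m(x) = x * (1 + q_j) is the size measure
driving length and intake allometry: structure plus reserves filled to the
juvenile ceiling, excluding any adult gonad build-up.

Daily energy flow (all in g/day of biomass equivalents):

    intake       I = d1 * m**d2 * r_a * R_l
    acquired   E_a = k_e * I
    maintenance E_m = rho1 * (x + y)**rho2 * r_m
    balance    E_g = E_a - E_m

A surplus (E_g > 0) is split by the kappa-style allocation fraction f:
f * E_g builds structure, the rest builds reserves.  The quadratic rise of
f with condition means a starved fish first rebuilds its reserves before
resuming structural growth.  A deficit (E_g < 0) is paid entirely from
reserves; structure never shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .species_registry import SpeciesParams
from .thermal_response import temperature_factor

__all__ = [
    "IndividualState",
    "RateBundle",
    "standardized_mass",
    "body_length",
    "condition_ratio",
    "fulton_condition",
    "intake",
    "maintenance",
    "net_energy",
    "allocation_fraction",
    "state_derivatives",
    "fecundity",
]


@dataclass
class IndividualState:
    """State variables of one simulated fish."""

    x: float                 # structural mass (g), never decreases
    y: float                 # reserve mass (g), >= 0 while alive
    age_days: float = 0.0    # days since the start of the first growing season
    mature: bool = False     # flips permanently once length reaches L_m
    alive: bool = True

    def copy(self) -> "IndividualState":
        return IndividualState(self.x, self.y, self.age_days,
                               self.mature, self.alive)


@dataclass(frozen=True)
class RateBundle:
    """All per-day rates evaluated at one (state, temperature, feeding level)."""

    temperature: float       # deg C
    r_intake: float          # thermal factor on intake, [0, 1]
    r_maint: float           # thermal factor on maintenance, [0, 1]
    intake: float            # I, g/day
    acquired: float          # E_a = k_e * I, g/day
    maintenance: float       # E_m, g/day
    net_energy: float        # E_g = E_a - E_m, g/day
    alloc_fraction: float    # f, share of a surplus going to structure


def standardized_mass(p: SpeciesParams, st: IndividualState) -> float:
    """m(x) = x * (1 + q_j), g.  Uses q_j for adults too: gonadal reserves
    above the juvenile ceiling do not make a fish 'longer'."""
    return st.x * (1.0 + p.q_j)


def body_length(p: SpeciesParams, st: IndividualState) -> float:
    """L = lambda1 * m(x)**lambda2, cm.  Depends on structure only."""
    return p.lambda1 * standardized_mass(p, st) ** p.lambda2


def condition_ratio(st: IndividualState) -> float:
    """Model body condition y/x."""
    return st.y / st.x


def fulton_condition(p: SpeciesParams, st: IndividualState) -> float:
    """Fulton's condition index 100 * (x + y) / L**3 (g, cm)."""
    return 100.0 * (st.x + st.y) / body_length(p, st) ** 3


def _thermal_mass(p: SpeciesParams, st: IndividualState,
                  mass_basis: str) -> float:
    if mass_basis == "total":
        return st.x + st.y
    if mass_basis == "standardized":
        return standardized_mass(p, st)
    raise ValueError(f"unknown thermal mass basis {mass_basis!r}")


def intake(p: SpeciesParams, st: IndividualState, T: float, R_l: float,
           mass_basis: str = "total") -> float:
    """Food intake I = d1 * m**d2 * r_a * R_l, g/day.

    ``R_l`` is the feeding level in [0, 1]: 0 is starvation, 1 supports
    maximum growth.  The thermal factor r_a is evaluated at total mass by
    default (``mass_basis='total'``)."""
    if not (0.0 <= R_l <= 1.0):
        raise ValueError(f"feeding level must be in [0, 1], got {R_l!r}")
    r_a = temperature_factor(p.intake_thermal, _thermal_mass(p, st, mass_basis), T)
    return p.d1 * standardized_mass(p, st) ** p.d2 * r_a * R_l


def maintenance(p: SpeciesParams, st: IndividualState, T: float,
                mass_basis: str = "total") -> float:
    """Maintenance requirement E_m = rho1 * (x + y)**rho2 * r_m, g/day."""
    r_m = temperature_factor(p.maintenance_thermal,
                             _thermal_mass(p, st, mass_basis), T)
    return p.rho1 * (st.x + st.y) ** p.rho2 * r_m


def net_energy(p: SpeciesParams, st: IndividualState, T: float, R_l: float,
               mass_basis: str = "total") -> RateBundle:
    """Evaluate the full daily rate bundle at one state and temperature."""
    w = _thermal_mass(p, st, mass_basis)
    r_a = temperature_factor(p.intake_thermal, w, T)
    r_m = temperature_factor(p.maintenance_thermal, w, T)
    if not (0.0 <= R_l <= 1.0):
        raise ValueError(f"feeding level must be in [0, 1], got {R_l!r}")
    i = p.d1 * standardized_mass(p, st) ** p.d2 * r_a * R_l
    e_a = p.k_e * i
    e_m = p.rho1 * (st.x + st.y) ** p.rho2 * r_m
    return RateBundle(
        temperature=T,
        r_intake=r_a,
        r_maint=r_m,
        intake=i,
        acquired=e_a,
        maintenance=e_m,
        net_energy=e_a - e_m,
        alloc_fraction=allocation_fraction(p, st),
    )


def allocation_fraction(p: SpeciesParams, st: IndividualState) -> float:
    """Share f of an energy surplus allocated to structural mass.

    With q the stage-specific condition ceiling (q_j juvenile, q_a adult):

        f = (y/x)**2 / ((1 + q) * q**2)   while y/x < q
        f = 1 / (1 + q)                   at or above the ceiling

    The two branches meet continuously at y/x = q.  The quadratic branch
    prioritizes reserve recovery after starvation."""
    q = p.q_a if st.mature else p.q_j
    c = st.y / st.x
    if c < q:
        return (c * c) / ((1.0 + q) * q * q)
    return 1.0 / (1.0 + q)


def state_derivatives(p: SpeciesParams, st: IndividualState, T: float,
                      R_l: float, mass_basis: str = "total"
                      ) -> tuple[float, float]:
    """(dx/dt, dy/dt) in g/day.

    Growing (E_g > 0): dx = f * E_g, dy = (1 - f) * E_g (conservative
    split).  Starving (E_g <= 0): dx = 0, dy = E_g — the whole deficit is
    drawn from reserves."""
    e_g = net_energy(p, st, T, R_l, mass_basis).net_energy
    if e_g > 0.0:
        f = allocation_fraction(p, st)
        return f * e_g, (1.0 - f) * e_g
    return 0.0, e_g


def fecundity(p: SpeciesParams, st: IndividualState) -> float:
    """Potential egg number F = k_r * (y - q_j * x) / w_b.

    Non-zero only for adults (length above L_m) holding reserves above the
    juvenile ceiling; the surplus y - q_j * x is the gonad mass, converted
    to eggs of mass w_b with efficiency k_r.  Returned as a real number;
    spawning records floor it to an integer count."""
    if body_length(p, st) > p.L_m and st.y > p.q_j * st.x:
        return p.k_r * (st.y - p.q_j * st.x) / p.w_b
    return 0.0
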