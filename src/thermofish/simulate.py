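"""Life-cycle integration of one individual.

A run starts from egg mass, steps through contiguous 250-day growing
seasons with an explicit Euler scheme (daily step, the reference
configuration), spawns on the first day of every model year after the
first, and ends at starvation (reserves exhausted) or at the species'
maximum lifespan.  The model is fully deterministic.

Day ordering: on day 0 of model year n (n >= 2) the spawning event fires
before the feeding step; maturity is re-evaluated after every state
update.  An individual younger than the age at first feeding (A_f days)
is energetically inert by default — the egg and yolk-sac phase neither
feeds nor pays maintenance (``prefeeding_mode='maintenance_only'`` makes
it pay maintenance instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .species_registry import SpeciesParams, load_species
from .environment import Scenario, TemperatureRegime, seasonal_temperature
from . import bioenergetics as bio
from .bioenergetics import IndividualState, RateBundle

__all__ = [
    "SpawningRecord",
    "DeathInfo",
    "RunResult",
    "TRAJECTORY_COLUMNS",
    "initial_state",
    "step_day",
    "spawn_event",
    "run_individual",
    "lifetime_fecundity",
    "run_summary",
]

TRAJECTORY_COLUMNS = (
    "model_year", "day_in_year", "age_years", "temperature", "x", "y",
    "total_mass", "length_cm", "condition_yx", "fulton_k", "r_intake",
    "r_maint", "intake", "acquired", "maintenance", "net_energy",
    "net_energy_per_length", "mature",
)


@dataclass(frozen=True)
class SpawningRecord:
    """One annual spawning event.

    ``event_year_label`` is the age in completed 250-day years at the
    event: spawning at the start of model year n + 1 is labelled Year n."""

    event_year_label: int
    eggs: int
    gonad_mass_removed: float
    pre_state: IndividualState
    post_state: IndividualState


@dataclass(frozen=True)
class DeathInfo:
    cause: str         # "starvation" or "lifespan"
    age_years: float   # age_days / 250 at death


@dataclass
class RunResult:
    scenario: Scenario
    params: SpeciesParams
    trajectory: pd.DataFrame
    spawnings: list[SpawningRecord]
    death: DeathInfo

    @property
    def max_length(self) -> float:
        return float(self.trajectory["length_cm"].max())


def initial_state(p: SpeciesParams) -> IndividualState:
    """Newborn at egg mass w_b, split so that condition y/x equals the
    juvenile ceiling q_j exactly."""
    x0 = p.w_b / (1.0 + p.q_j)
    return IndividualState(x=x0, y=p.q_j * x0, age_days=0.0,
                           mature=False, alive=True)


def _rates(p: SpeciesParams, st: IndividualState, T: float, R_l: float,
           prefeeding_mode: str, mass_basis: str) -> RateBundle:
    """Rate bundle honouring the pre-feeding phase."""
    if st.age_days < p.A_f:
        if prefeeding_mode == "inert":
            return RateBundle(T, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                              bio.allocation_fraction(p, st))
        # maintenance_only: pays metabolic costs but cannot feed yet
        b = bio.net_energy(p, st, T, 0.0, mass_basis)
        return b
    return bio.net_energy(p, st, T, R_l, mass_basis)


def _euler_update(p: SpeciesParams, st: IndividualState, e_g: float,
                  dt: float) -> None:
    """Apply one Euler increment in place; truncates at y = 0 and kills."""
    if e_g > 0.0:
        f = bio.allocation_fraction(p, st)
        st.x += f * e_g * dt
        st.y += (1.0 - f) * e_g * dt
    else:
        new_y = st.y + e_g * dt
        if new_y <= 0.0:
            st.y = 0.0
            st.alive = False
        else:
            st.y = new_y


def step_day(p: SpeciesParams, st: IndividualState, reg: TemperatureRegime,
             R_l: float, dt: float = 1.0, *, prefeeding_mode: str = "inert",
             mass_basis: str = "total",
             integrator: str = "euler") -> IndividualState:
    """Advance the state by one step of size ``dt`` (days), in place.

    Temperature is sampled at the step start (t = age mod GS).  If the
    update would drive reserves below zero the step truncates at y = 0 and
    the individual dies.  Maturity (length >= L_m, irreversible) is
    re-evaluated after the update.  Returns ``st`` for convenience."""
    if not st.alive:
        raise RuntimeError("cannot step a dead individual")
    if not (0.0 < dt <= 1.0):
        raise ValueError(f"dt must be in (0, 1] days, got {dt!r}")
    t0 = st.age_days % reg.GS

    if st.age_days < p.A_f and prefeeding_mode == "inert":
        st.age_days += dt
        return st

    if integrator == "euler":
        T = seasonal_temperature(reg, t0)
        e_g = _rates(p, st, T, R_l, prefeeding_mode, mass_basis).net_energy
        _euler_update(p, st, e_g, dt)
    elif integrator == "rk4":
        _rk4_update(p, st, reg, t0, R_l, dt, prefeeding_mode, mass_basis)
    else:
        raise ValueError(f"unknown integrator {integrator!r}")

    st.age_days += dt
    if st.alive and not st.mature and bio.body_length(p, st) >= p.L_m:
        st.mature = True
    return st


def _rk4_update(p: SpeciesParams, st: IndividualState, reg, t0: float,
                R_l: float, dt: float, prefeeding_mode: str,
                mass_basis: str) -> None:
    """Classical fixed-step RK4 increment (convergence checks only).

    The allocation branch and the thermal curve are continuous, so RK4 is
    well defined within a step; maturity is held fixed over the step."""

    def deriv(x: float, y: float, t: float) -> tuple[float, float]:
        probe = IndividualState(x=x, y=max(y, 1e-300), age_days=st.age_days,
                                mature=st.mature, alive=True)
        T = seasonal_temperature(reg, t % reg.GS)
        e_g = _rates(p, probe, T, R_l, prefeeding_mode, mass_basis).net_energy
        if e_g > 0.0:
            f = bio.allocation_fraction(p, probe)
            return f * e_g, (1.0 - f) * e_g
        return 0.0, e_g

    x0, y0 = st.x, st.y
    k1 = deriv(x0, y0, t0)
    k2 = deriv(x0 + 0.5 * dt * k1[0], y0 + 0.5 * dt * k1[1], t0 + 0.5 * dt)
    k3 = deriv(x0 + 0.5 * dt * k2[0], y0 + 0.5 * dt * k2[1], t0 + 0.5 * dt)
    k4 = deriv(x0 + dt * k3[0], y0 + dt * k3[1], t0 + dt)
    dx = dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    dy = dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    st.x = x0 + max(dx, 0.0)
    new_y = y0 + dy
    if new_y <= 0.0:
        st.y = 0.0
        st.alive = False
    else:
        st.y = new_y


def spawn_event(p: SpeciesParams, st: IndividualState
                ) -> tuple[IndividualState, SpawningRecord | None]:
    """First-day-of-year spawning: a mature individual with reserves above
    the juvenile ceiling converts the whole gonad mass y - q_j * x into
    floor(k_r * (y - q_j x) / w_b) eggs and drops to y = q_j * x.

    Returns the (possibly unchanged) state and a record, or ``None`` when
    no spawning occurred.  The egg count carries the conversion efficiency
    k_r; the mass removed is the full gonad mass."""
    if st.mature and st.y > p.q_j * st.x:
        pre = st.copy()
        gonad = st.y - p.q_j * st.x
        eggs = math.floor(p.k_r * gonad / p.w_b)
        st.y = p.q_j * st.x
        label = int(round(st.age_days / 250.0))
        rec = SpawningRecord(event_year_label=label, eggs=eggs,
                             gonad_mass_removed=gonad, pre_state=pre,
                             post_state=st.copy())
        return st, rec
    return st, None


def run_individual(scn: Scenario) -> RunResult:
    """Integrate one individual's whole life under a scenario.

    Loops model years of ``GS`` daily blocks (substepped when dt < 1),
    spawning at each year start from year 2 on.  Trajectory rows record
    the day-start state and the rates in force on that day.  Deterministic:
    identical scenarios give bit-identical results."""
    p = scn.species if isinstance(scn.species, SpeciesParams) \
        else load_species(scn.species)
    reg = scn.regime
    steps_per_day = max(1, round(1.0 / scn.dt))
    dt = 1.0 / steps_per_day

    st = initial_state(p)
    rows: list[tuple] = []
    spawnings: list[SpawningRecord] = []
    death: DeathInfo | None = None

    for year in range(1, p.max_lifespan_years + 1):
        for day in range(reg.GS):
            if day == 0 and year > 1:
                st, rec = spawn_event(p, st)
                if rec is not None:
                    spawnings.append(rec)

            T = seasonal_temperature(reg, float(day))
            b = _rates(p, st, T, scn.R_l, scn.prefeeding_mode,
                       scn.thermal_mass_basis)
            length = bio.body_length(p, st)
            rows.append((
                year, day, st.age_days / 250.0, T, st.x, st.y,
                st.x + st.y, length, st.y / st.x,
                bio.fulton_condition(p, st), b.r_intake, b.r_maint,
                b.intake, b.acquired, b.maintenance, b.net_energy,
                b.net_energy / length, st.mature,
            ))

            for _ in range(steps_per_day):
                step_day(p, st, reg, scn.R_l, dt,
                         prefeeding_mode=scn.prefeeding_mode,
                         mass_basis=scn.thermal_mass_basis,
                         integrator=scn.integrator)
                if not st.alive:
                    break
            if not st.alive:
                death = DeathInfo("starvation", st.age_days / 250.0)
                break
        if death is not None:
            break
    if death is None:
        death = DeathInfo("lifespan", st.age_days / 250.0)

    traj = pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS))
    return RunResult(scenario=scn, params=p, trajectory=traj,
                     spawnings=spawnings, death=death)


def lifetime_fecundity(records: list[SpawningRecord]) -> pd.DataFrame:
    """Per-event and cumulative egg totals.

    Columns: ``event_year`` (label), ``eggs`` (that event), ``cumulative``
    (running total).  The grand total is the last cumulative value, or 0
    for an empty record list."""
    years = [r.event_year_label for r in records]
    eggs = [r.eggs for r in records]
    df = pd.DataFrame({"event_year": years, "eggs": eggs})
    df["cumulative"] = df["eggs"].cumsum()
    return df


def run_summary(res: RunResult) -> dict:
    """Compact JSON-ready summary of one run."""
    fec = lifetime_fecundity(res.spawnings)
    traj = res.trajectory
    year_end = traj.groupby("model_year")["length_cm"].last()
    return {
        "species": res.params.name,
        "regime": res.scenario.regime.name,
        "feeding_level": res.scenario.R_l,
        "max_length_cm": res.max_length,
        "death_cause": res.death.cause,
        "death_age_years": res.death.age_years,
        "n_spawning_events": len(res.spawnings),
        "lifetime_fecundity": int(fec["eggs"].sum()) if len(fec) else 0,
        "spawning_events": [
            {"year": r.event_year_label, "eggs": r.eggs} for r in res.spawnings
        ],
        "length_at_year_end_cm": {int(y): float(v)
                                  for y, v in year_end.items()},
    }
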