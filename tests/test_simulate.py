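import dataclasses

import numpy as np
import pandas as pd
import pytest

from thermofish import (
    IndividualState,
    Scenario,
    TemperatureRegime,
    body_length,
    get_regime,
    initial_state,
    lifetime_fecundity,
    load_species,
    run_individual,
    spawn_event,
    step_day,
    thermal_optimum,
)
SPECIES = ("cod", "herring", "rockling", "sprat", "mullet")
REGIMES = ("1980s", "2010s")
LEVELS = (0.5, 0.7, 1.0)


# -- initial state -------------------------------------------------------

def test_cod_initial_state_masses():
    st = initial_state(load_species("cod"))
    assert st.x == pytest.approx(0.000229411765, abs=1e-10)
    assert st.y == pytest.approx(0.000160588235, abs=1e-10)
    assert st.x + st.y == pytest.approx(0.00039)


@pytest.mark.parametrize("name", SPECIES)
def test_newborn_at_juvenile_ceiling(name, params):
    p = params[name]
    st = initial_state(p)
    assert st.y / st.x == pytest.approx(p.q_j, rel=1e-12)
    assert body_length(p, st) == pytest.approx(p.lambda1 * p.w_b ** p.lambda2)
    assert not st.mature and st.alive and st.age_days == 0.0


# -- daily stepping ------------------------------------------------------

def test_starvation_step_draws_reserves_only():
    p = load_species("herring")
    reg = get_regime("1980s")
    st = IndividualState(x=5.0, y=3.0, age_days=100.0)
    x0 = st.x
    step_day(p, st, reg, R_l=0.0)
    assert st.x == x0
    assert st.y < 3.0


def test_growth_step_conserves_energy():
    import thermofish.bioenergetics as bio
    from thermofish import seasonal_temperature
    p = load_species("herring")
    reg = get_regime("1980s")
    st = IndividualState(x=5.0, y=3.0, age_days=100.0)
    e_g = bio.net_energy(p, st, seasonal_temperature(reg, 100.0), 1.0).net_energy
    w0 = st.x + st.y
    step_day(p, st, reg, R_l=1.0)
    assert e_g > 0.0
    assert st.x + st.y - w0 == pytest.approx(e_g, rel=1e-12)


def test_step_truncates_at_zero_reserves_and_kills():
    p = load_species("herring")
    reg = get_regime("1980s")
    st = IndividualState(x=5.0, y=1e-6, age_days=100.0)
    step_day(p, st, reg, R_l=0.0)
    assert st.y == 0.0 and not st.alive


def test_dead_individual_cannot_step():
    p = load_species("herring")
    st = IndividualState(x=5.0, y=0.0, age_days=10.0, alive=False)
    with pytest.raises(RuntimeError):
        step_day(p, st, get_regime("1980s"), R_l=1.0)


def test_prefeeding_phase_is_inert():
    p = load_species("herring")       # A_f = 25 days
    reg = get_regime("1980s")
    st = initial_state(p)
    for _ in range(p.A_f):
        step_day(p, st, reg, R_l=1.0)
    assert (st.x, st.y) == (initial_state(p).x, initial_state(p).y)
    step_day(p, st, reg, R_l=1.0)     # first feeding day
    assert st.x + st.y > p.w_b


def test_maturity_flips_once_length_reached():
    p = load_species("sprat")         # L_m = 9 cm
    reg = get_regime("1980s")
    m_mat = (p.L_m / p.lambda1) ** (1.0 / p.lambda2)
    x = m_mat / (1.0 + p.q_j) * 1.001
    st = IndividualState(x=x, y=p.q_j * x, age_days=100.0)
    assert body_length(p, st) > p.L_m
    step_day(p, st, reg, R_l=1.0)
    assert st.mature


def test_condition_converges_to_juvenile_ceiling():
    """Under sustained surplus at near-optimal temperature, a depleted
    juvenile rebuilds condition monotonically toward q_j."""
    p = load_species("cod")        # L_m = 62 cm: stays juvenile throughout
    t_opt = thermal_optimum(p.intake_thermal, 20.0)
    flat = TemperatureRegime(name="flat", T_mean=t_opt, a=0.0, omega=0, GS=250)
    st = IndividualState(x=10.0, y=1.0, age_days=100.0)
    ratios = [st.y / st.x]
    for _ in range(400):
        step_day(p, st, flat, R_l=1.0)
        ratios.append(st.y / st.x)
    assert all(a <= b + 1e-12 for a, b in zip(ratios, ratios[1:]))
    assert ratios[-1] == pytest.approx(p.q_j, abs=1e-3)


# -- spawning ------------------------------------------------------------

def test_spawn_event_sprat_example():
    p = load_species("sprat")
    st = IndividualState(x=10.0, y=10.0, age_days=250.0, mature=True)
    st, rec = spawn_event(p, st)
    assert rec is not None
    assert rec.eggs == 1000
    assert rec.event_year_label == 1
    assert st.y == pytest.approx(9.0)
    assert rec.post_state.x == rec.pre_state.x
    assert rec.gonad_mass_removed == pytest.approx(1.0)


def test_immature_individual_does_not_spawn():
    p = load_species("sprat")
    st = IndividualState(x=10.0, y=10.0, age_days=250.0, mature=False)
    st2, rec = spawn_event(p, st)
    assert rec is None and st2.y == 10.0


def test_no_spawn_at_reserve_threshold():
    p = load_species("sprat")
    st = IndividualState(x=10.0, y=9.0, age_days=250.0, mature=True)
    _, rec = spawn_event(p, st)
    assert rec is None


def test_lifetime_fecundity_empty():
    df = lifetime_fecundity([])
    assert len(df) == 0 and int(df["eggs"].sum()) == 0


def test_lifetime_fecundity_accumulates(grid_runs):
    res = grid_runs("sprat", "1980s", 1.0)
    df = lifetime_fecundity(res.spawnings)
    assert list(df["cumulative"]) == list(np.cumsum(df["eggs"]))
    assert df["cumulative"].iloc[-1] == sum(r.eggs for r in res.spawnings)


# -- whole-life runs -----------------------------------------------------

def test_run_is_deterministic():
    scn = Scenario(species="rockling", regime=get_regime("2010s"), R_l=0.7)
    a, b = run_individual(scn), run_individual(scn)
    pd.testing.assert_frame_equal(a.trajectory, b.trajectory)
    assert a.death == b.death
    assert [r.eggs for r in a.spawnings] == [r.eggs for r in b.spawnings]


@pytest.mark.parametrize("name", SPECIES)
@pytest.mark.parametrize("regime", REGIMES)
def test_final_length_monotone_in_feeding_level(name, regime, grid_runs):
    lengths = [grid_runs(name, regime, rl).max_length for rl in LEVELS]
    assert lengths[0] <= lengths[1] <= lengths[2]


def test_length_never_decreases(grid_runs):
    for name in SPECIES:
        traj = grid_runs(name, "2010s", 1.0).trajectory
        assert (traj["length_cm"].diff().dropna() >= -1e-12).all()


def test_trajectory_consistency(grid_runs):
    traj = grid_runs("herring", "1980s", 0.7).trajectory
    assert (traj["total_mass"] == traj["x"] + traj["y"]).all()
    np.testing.assert_allclose(
        traj["net_energy_per_length"],
        traj["net_energy"] / traj["length_cm"], rtol=1e-12)
    np.testing.assert_allclose(
        traj["acquired"], 0.5 * traj["intake"], rtol=1e-12)


def test_cod_never_spawns(grid_runs):
    """Cod never reaches its 62 cm maturation length, hence zero spawning
    events in all six scenarios."""
    for regime in REGIMES:
        for rl in LEVELS:
            res = grid_runs("cod", regime, rl)
            assert res.spawnings == []
            assert not res.trajectory["mature"].any()


def test_rockling_summer_energy_deficit_with_autumn_recovery(grid_runs):
    """Under the warm regime rockling hit a negative energy balance
    mid-way through year 1 and recover once temperatures drop."""
    for rl in LEVELS:
        y1 = grid_runs("rockling", "2010s", rl).trajectory.query(
            "model_year == 1")
        mid = y1.query("60 <= day_in_year <= 190")
        autumn = y1.query("day_in_year > 190")
        assert (mid["net_energy"] < 0).any()
        assert (autumn["net_energy"] > 0).all()


def test_death_bookkeeping(grid_runs):
    starving = grid_runs("cod", "2010s", 0.5)
    assert starving.death.cause == "starvation"
    assert starving.trajectory["age_years"].iloc[-1] < \
        starving.params.max_lifespan_years
    old_age = grid_runs("sprat", "1980s", 1.0)
    assert old_age.death.cause == "lifespan"
    assert old_age.death.age_years == old_age.params.max_lifespan_years


@pytest.mark.parametrize("name, regime, rl", [
    ("herring", "2010s", 1.0),
    ("rockling", "1980s", 0.7),
    ("cod", "2010s", 0.5),
    ("mullet", "2010s", 1.0),
])
def test_integrator_convergence(name, regime, rl, grid_runs):
    """Daily Euler (the reference), dt = 0.1 Euler and daily RK4 agree on
    final length to within 1% for shipped scenarios."""
    ref = grid_runs(name, regime, rl)
    scn = ref.scenario
    fine = run_individual(dataclasses.replace(scn, dt=0.1))
    rk4 = run_individual(dataclasses.replace(scn, integrator="rk4"))
    assert fine.max_length == pytest.approx(ref.max_length, rel=0.01)
    assert rk4.max_length == pytest.approx(ref.max_length, rel=0.01)
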