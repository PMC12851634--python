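import pytest

from thermofish import Scenario, get_regime, load_species, run_individual

SPECIES = ("cod", "herring", "rockling", "sprat", "mullet")
REGIMES = ("1980s", "2010s")
LEVELS = (0.5, 0.7, 1.0)


@pytest.fixture(scope="session")
def params():
    """All shipped species records, keyed by name."""
    return {name: load_species(name) for name in SPECIES}


@pytest.fixture(scope="session")
def grid_runs():
    """Lazily cached full 5 x 2 x 3 scenario matrix of reference runs."""
    cache = {}

    def run(species, regime, r_l):
        key = (species, regime, r_l)
        if key not in cache:
            cache[key] = run_individual(
                Scenario(species=species, regime=get_regime(regime), R_l=r_l))
        return cache[key]

    return run
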