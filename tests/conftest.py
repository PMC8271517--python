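import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phredox as px

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def constants() -> px.Constants:
    return px.Constants()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def quinone_like_couple() -> px.RedoxCouple:
    """A 2e-/2H+ couple with the benzoquinone/hydroquinone H-count pattern
    and free-energy components chosen so U0 = 0.730 V."""
    ox = px.SpeciesState(
        "bq_ox",
        n_hydrogens=4,
        charge=0,
        energy_solvent_opt=-250.12,
        energy_gas=-249.80,
        thermal_correction_gas=0.12,
        dG_solvation=-0.32,
    )
    red = px.SpeciesState(
        "bq_red",
        n_hydrogens=6,
        charge=0,
        energy_solvent_opt=-237.68,
        energy_gas=-237.30,
        thermal_correction_gas=0.12,
        dG_solvation=-0.38,
    )
    return px.RedoxCouple(ox, red)


def random_ladder(
    rng: np.random.Generator, species_id: str, nh: int, max_count: int = 3
) -> px.PKaLadder:
    count = int(rng.integers(0, min(max_count, nh) + 1))
    return px.PKaLadder(
        species_id, tuple(sorted(rng.uniform(0.5, 13.5, size=count).tolist()))
    )
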