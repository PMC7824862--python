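from pathlib import Path

import pytest

from jumbophage import simulate as sim

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort (8 phages per subgroup) shared by fast tests."""
    cfg = sim.CohortConfig(
        n_phages={"1": 8, "2.1": 8, "2.2": 8, "3.1": 8, "3.2": 8}, seed=11
    )
    return sim.generate_cohort(cfg)
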