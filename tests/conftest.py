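import numpy as np
import pandas as pd
import pytest

from dicascade import analyses, synthetic
from dicascade.pglmm import MCMCSchedule


@pytest.fixture(scope="session")
def tiny_schedule():
    """Short chain for unit-level fits (1000 retained draws)."""
    return MCMCSchedule(4000, 1000, 3)


@pytest.fixture(scope="session")
def small_study():
    """A 30-species simulated study, prepared through the full pipeline."""
    config = synthetic.SimulationConfig(
        n_species=30, n_specimens_per_species=10, seed=7
    )
    sim = synthetic.simulate_dataset(config)
    specimens, summaries, log = analyses.prepare_specimens(sim.specimens)
    return sim, specimens, summaries, log


@pytest.fixture()
def specimen_fixture():
    """Hand-built specimen table with known exclusion counts.

    Ten specimens of one species: 2 with high wear, 1 zoo, the remaining
    7 complete wild adults of both sexes.
    """
    rows = []
    for i in range(10):
        wear = "high" if i < 2 else "acceptable"
        provenance = "zoo" if i == 2 else "wild"
        sex = "male" if i % 2 == 0 else "female"
        row = {
            "species": "A",
            "sex": sex,
            "wear": wear,
            "provenance": provenance,
        }
        for k in (1, 2, 3):
            row[f"m{k}_length"] = 10.0 + k + 0.1 * i
            row[f"m{k}_breadth_trigonid"] = 8.0 + 0.05 * i
            row[f"m{k}_breadth_talonid"] = 7.0 + 0.05 * i
        rows.append(row)
    return pd.DataFrame(rows)
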