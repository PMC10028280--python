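import pytest
from hypothesis import HealthCheck, settings

from clonetrack import germline, simulate

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def germline_db():
    return germline.generate_germline_db(seed=7)


@pytest.fixture(scope="session")
def small_cohort(germline_db):
    """Two patients, 60 clones each, treatment scenario: clones, realized
    counts, cells with 2% SHM, and the ground-truth rearrangement table."""
    cfg = simulate.treatment_scenario(
        n_patients=2, n_clones_per_patient=60, cell_scale=0.5
    )
    clones, counts = simulate.simulate_cohort(cfg, seed=11, germline=germline_db)
    cells = simulate.materialize_cells(clones, counts, shm_rate=0.02, seed=12)
    truth = simulate.cells_to_rearrangements(cells, clones)
    return clones, counts, cells, truth
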