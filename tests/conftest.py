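import numpy as np
import pandas as pd
import pytest

import selftraingp as sg


@pytest.fixture(scope="session")
def small_population() -> sg.SimulatedPopulation:
    """Desk-scale population with missing genotypes exercising every stage."""
    params = sg.SimulationParams(
        n_animals=150, n_markers=250, n_qtl=60, heritability=0.4,
        missing_rate=0.05, n_weeks_per_animal=10, n_cohorts=12,
        n_ysc_levels=5, n_par_age_levels=4, seed=11,
    )
    return sg.simulate_population(params)


@pytest.fixture(scope="session")
def qc_genotypes(small_population) -> sg.GenotypeMatrix:
    G, _ = sg.qc_pipeline(small_population.genotypes)
    return G


@pytest.fixture()
def tiny_matrix() -> sg.GenotypeMatrix:
    values = np.array([
        [0.0, 1.0, 2.0],
        [np.nan, 0.0, 2.0],
    ])
    return sg.GenotypeMatrix(["a1", "a2"], ["m1", "m2", "m3"], values)


def grouped_records(
    seed: int,
    n_cohorts: int = 40,
    per_cohort: int = 8,
    sigma_r: float = 1.0,
    sigma_e: float = 2.0,
    n_ysc: int = 5,
    n_par: int = 4,
) -> pd.DataFrame:
    """Records drawn exactly under the one-random-effect DMI mixed model."""
    rng = np.random.default_rng(seed)
    n = n_cohorts * per_cohort
    ysc = rng.choice([f"y{k}" for k in range(n_ysc)], n)
    par = rng.choice([f"p{k}" for k in range(n_par)], n)
    ysc_eff = dict(zip([f"y{k}" for k in range(n_ysc)],
                       rng.normal(0, 0.5, n_ysc)))
    par_eff = dict(zip([f"p{k}" for k in range(n_par)],
                       rng.normal(0, 0.5, n_par)))
    cohort_idx = np.repeat(np.arange(n_cohorts), per_cohort)
    cohort_eff = rng.normal(0, sigma_r, n_cohorts)
    frame = pd.DataFrame({
        "animal_id": [f"a{i // 2}" for i in range(n)],
        "dim": rng.uniform(50, 200, n),
        "milk_e": rng.normal(30, 5, n),
        "mbw": rng.normal(128, 8, n),
        "ysc": ysc,
        "par_age": par,
        "ration": [f"r{k}" for k in cohort_idx],
    })
    frame["dmi"] = (
        20.0
        + np.vectorize(ysc_eff.get)(ysc)
        + np.vectorize(par_eff.get)(par)
        + 0.01 * frame["dim"]
        + 0.40 * frame["milk_e"]
        + 0.05 * frame["mbw"]
        + cohort_eff[cohort_idx]
        + rng.normal(0, sigma_e, n)
    )
    return frame
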