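import numpy as np
import pandas as pd
import pytest

from plaquestrat import simulate as sim


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the study-condition defaults (n=609)."""
    return sim.simulate_thickness(sim.CohortSimParams(seed=20150715))


@pytest.fixture(scope="session")
def small_study():
    """A modest paired expression study with a clear shared signature."""
    cohort = sim.simulate_thickness(sim.CohortSimParams(n_patients=40, seed=7))
    params = sim.ExpressionSimParams(
        n_genes=400, n_signature=40, base_lfc=1.5, amplitude=1.6,
        subject_sd=0.3, noise_sd=0.25, seed=7,
    )
    return sim.simulate_expression(cohort, params)


@pytest.fixture()
def toy_cohort():
    return pd.DataFrame(
        {
            "patient_id": ["a", "b", "c", "d"],
            "lesional_um": [250.0, 400.0, 500.0, 300.0],
            "nonlesional_um": [90.0, 95.0, 85.0, 100.0],
        }
    )


def two_group_paired_study(
    n_per_group=8, n_genes=30, seed=0, delta_thin=0.0, delta_thick=0.0,
    subject_sd=0.4, noise_sd=0.3
):
    """Hand-rolled balanced paired study, independent of the generator."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    meta, cols = [], {}
    for grp, delta in (("thin", delta_thin), ("thick", delta_thick)):
        for s in range(n_per_group):
            sid = f"{grp}{s}"
            b = rng.normal(8.0, 1.0, n_genes) + rng.normal(0, subject_sd, n_genes)
            nl = b + rng.normal(0, noise_sd, n_genes)
            ls = b + delta + rng.normal(0, noise_sd, n_genes)
            for tissue, vals in (("LS", ls), ("NL", nl)):
                cols[f"{sid}_{tissue}"] = vals
                meta.append(
                    {"sample_id": f"{sid}_{tissue}", "subject_id": sid,
                     "tissue": tissue, "group": grp}
                )
    matrix = pd.DataFrame(cols, index=genes)
    return sim.ExpressionStudy(matrix=matrix, samples=pd.DataFrame(meta))
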