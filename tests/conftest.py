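import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from admeth import ewas
from admeth.synthdata import SimConfig, simulate_cohort, simulate_annotations

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def sim():
    """Default synthetic study (seed 1), shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def annotations(sim, sim_cfg):
    return simulate_annotations(sim_cfg, sim.truth, sim.cohorts["discovery"].sites)


def cohort_association(sim, cohort: str):
    """Run the per-cohort EWAS (both depots pooled, depot as covariate,
    control-probe PCs) exactly as the pipeline does."""
    m = sim.cohorts[cohort]
    sheet = m.sample_sheet.loc[m.betas.columns]
    pcs = ewas.control_probe_pcs(sim.controls[cohort][m.betas.columns])
    cov = pd.DataFrame({
        "age": sheet["age"], "sex": sheet["sex"].astype(float),
        "depot": (sheet["depot"] == "visc").astype(float),
    }).join(pcs)
    return ewas.site_association(m, sheet["case"].astype(float), cov, cohort=cohort)


@pytest.fixture(scope="session")
def assoc_pair(sim):
    return cohort_association(sim, "discovery"), cohort_association(sim, "replication")
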