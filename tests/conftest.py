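import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import coldmap as cm

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_sim():
    """A panel at the reference study scale (174 accessions, 109/65 split)
    with the default baselines and no planted effects."""
    cfg = cm.SimulationConfig(n_markers=60, seed=11)
    panel, marker_map, pheno, truth = cm.simulate(cfg)
    return cfg, panel, marker_map, pheno, truth


def make_single_marker(genotypes, values, subspecies="indica"):
    """Panel + phenotype pair holding one marker 'M1' and one measure column
    (SSvR) for hand-constructed association tests."""
    acc = [f"A{i:03d}" for i in range(len(genotypes))]
    panel = pd.DataFrame({"M1": genotypes}, index=pd.Index(acc, name="accession"))
    pheno = pd.DataFrame(
        {
            "subspecies": subspecies,
            "SSvR": np.asarray(values, dtype=float),
            "SStR_NL": 0.0,
            "SStR_CW": 0.0,
            "RSStR_CW": 0.0,
        },
        index=panel.index,
    )
    return panel, pheno
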