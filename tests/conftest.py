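import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import hgkrige as h

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def canal():
    """A gently bending five-vertex canal."""
    return h.Polyline.from_coords(
        [(0, 100), (250, 90), (500, 110), (750, 95), (1000, 105)]
    )


@pytest.fixture(scope="session")
def small_field(canal):
    """A small simulated soil table (no LOD censoring) plus its config."""
    cfg = h.scaled_study_config(250, seed=42, lod=None)
    soil, field = h.simulate_soil_field(cfg, return_field=True)
    return h.prepare_soil(soil), cfg, field


@pytest.fixture(scope="session")
def cohort():
    """A full-size cohort with its generating truth."""
    cfg = h.scaled_study_config(300, seed=7, n_families=64, n_children_total=107)
    soil, field = h.simulate_soil_field(cfg, return_field=True)
    part, truth = h.simulate_participants(cfg, field)
    return part, truth, cfg, h.prepare_soil(soil)


def toy_records(seed=0, n_fam=40, per_fam=3, beta_soil=0.3, s2f=0.03, s2e=0.06):
    """Hand-built regression records from the random-intercept model."""
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_fam):
        b = np.sqrt(s2f) * rng.standard_normal()
        x_f = rng.normal(0, 0.6)
        for i in range(per_fam):
            z = rng.normal()
            y = 0.1 + beta_soil * x_f + 0.5 * z + b + np.sqrt(s2e) * rng.standard_normal()
            rows.append({"participant_id": f"S{f}_{i}", "family_id": f"F{f}",
                         "outcome": y, "exposure": x_f, "exposure_se": 0.0, "z": z})
    return pd.DataFrame(rows)
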