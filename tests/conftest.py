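import logging

import numpy as np
import pytest

from carpstress import normexpr, synthdata

logging.getLogger("carpstress").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def study_config():
    return synthdata.default_study_config(seed=11)


@pytest.fixture(scope="session")
def study_table(study_config):
    table, truth = synthdata.generate_ct_table(study_config)
    return table, truth


@pytest.fixture(scope="session")
def noise_free_table():
    """Study-design table with all noise off; effects are recovered exactly."""
    cfg = synthdata.default_study_config(seed=5)
    cfg.sd_animal = cfg.sd_biological = cfg.sd_technical = 0.0
    cfg.sd_biological_overrides = {}
    table, truth = synthdata.generate_ct_table(cfg)
    return table, truth


@pytest.fixture(scope="session")
def normalized(study_table):
    table, _ = study_table
    return normexpr.normalized_expression(table, ["bactin", "eif4e", "ef"])


def group_log2_differences(norm_df, truth):
    """Stressed-minus-control mean log_norm per gene x region, joined to truth."""
    g = (
        norm_df.groupby(["region", "gene", "group"])["log_norm"]
        .mean()
        .unstack("group")
    )
    diff = (g["stressed"] - g["control"]).rename("estimate").reset_index()
    return diff.merge(truth.effect_log2, on=["region", "gene"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
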