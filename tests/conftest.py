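import numpy as np
import pandas as pd
import pytest

from oiswaves.synthetic import (KnowledgeParams, TimeCourseDesign,
                                generate_knowledge_bases, generate_timecourse)

# a reduced study design used across tests: same structure as the default
# (4 waves, 3/4/4 replicates, MNAR dropout, batches), smaller matrices
SMALL = dict(n_features={"rna": 500, "protein": 250, "phospho": 180},
             n_signature=15)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_timecourse(TimeCourseDesign(seed=7, **SMALL))


@pytest.fixture(scope="session")
def small_kb(small_dataset):
    return generate_knowledge_bases(small_dataset.truth,
                                    KnowledgeParams(n_universe=200, seed=7))


@pytest.fixture(scope="session")
def clean_recovery_fit():
    """Default-size study without dropout/batch plus its fitted factor model:
    isolates loading/wave recovery from imputation and batch confounds."""
    from oiswaves import pipeline
    from oiswaves.config import make_config
    zero = {"rna": 0.0, "protein": 0.0, "phospho": 0.0}
    ds = generate_timecourse(TimeCourseDesign(batch_sd=zero,
                                              missing_rate=zero, seed=7))
    cfg = make_config({"tfa": {"k_max": 5}})
    processed, _, regulated = pipeline.preprocess_stage(ds, cfg, seed=7)
    fit = pipeline.factor_stage(processed, regulated, ds.sample_meta, cfg)
    return ds, fit


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_counts():
    return pd.DataFrame(
        [[10, 20, 30], [4, 8, 12], [100, 200, 300], [7, 14, 21]],
        index=[f"g{i}" for i in range(4)], columns=["s1", "s2", "s3"])
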