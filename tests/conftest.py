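import numpy as np
import pandas as pd
import pytest

import survclass as sc


@pytest.fixture(scope="session")
def std_config():
    """The standard synthetic configuration (4x100, 1408 genes, 60/split)."""
    return sc.SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def std_cohort(std_config):
    return sc.generate_cohort(std_config)


@pytest.fixture(scope="session")
def std_fit(std_cohort):
    cohort, truth = std_cohort
    model, labels = sc.fit_hierarchical(cohort, sc.PipelineConfig(seed=0))
    return cohort, truth, model, labels


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for plumbing tests (120 samples, 200 genes)."""
    cfg = sc.SyntheticConfig(
        n_per_subgroup=(30, 30, 30, 30),
        n_genes=200,
        n_informative_per_split=20,
        seed=7,
    )
    return sc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    cohort, truth = small_cohort
    cfg = sc.PipelineConfig(seed=7, panel_size=20)
    model, labels = sc.fit_hierarchical(cohort, cfg)
    return cohort, truth, model, labels


@pytest.fixture()
def tiny_expression():
    df = pd.DataFrame(
        [[1.0, 2.0], [0.0, 5.5], [3.3, 0.1]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return sc.ExpressionMatrix(df)


def write_tsv(path, df, **kwargs):
    df.to_csv(path, sep="\t", **kwargs)
    return path
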