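import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import salivadx as sx

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_cfg():
    return sx.default_config(seed=11)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    """A default-sized (34/33) six-gene synthetic cohort, fixed seed."""
    return sx.simulate_cohort(default_cfg)


@pytest.fixture(scope="session")
def expr(cohort):
    return cohort.expression


@pytest.fixture(scope="session")
def big_cohort(default_cfg):
    """n=10,000 per group for Monte-Carlo moment checks."""
    cfg = sx.CohortConfig(genes=default_cfg.genes, n_control=10_000,
                          n_case=10_000, seed=29)
    return sx.simulate_cohort(cfg)


def make_expression(ctrl: dict, case: dict) -> sx.ExpressionMatrix:
    """Small helper: build an ExpressionMatrix from per-gene value lists."""
    genes = list(ctrl)
    rows, meta = {}, []
    ids = []
    for i in range(len(next(iter(ctrl.values())))):
        ids.append(f"C{i}")
        meta.append("control")
    for i in range(len(next(iter(case.values())))):
        ids.append(f"T{i}")
        meta.append("case")
    data = {g: list(ctrl[g]) + list(case[g]) for g in genes}
    df = pd.DataFrame(data, index=pd.Index(ids, name="sample_id"))
    md = pd.DataFrame({"group": meta}, index=df.index)
    return sx.ExpressionMatrix(df, md)
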