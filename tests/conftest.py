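import numpy as np
import pytest

import extractopt as eo
from extractopt.ann import TrainConfig


@pytest.fixture(scope="session")
def table1():
    return eo.load_dataset("table1")


@pytest.fixture(scope="session")
def table1_fit(table1):
    return eo.fit_quadratic(table1)


@pytest.fixture(scope="session")
def table1_groups(table1):
    return [
        eo.AssaySummary(
            label=f"{r.condition.temperature:g}/{r.condition.time:g}/{r.condition.ethanol_pct:g}",
            mean=r.mean,
            sd=r.sd,
            n=r.n,
        )
        for r in table1.records
    ]


@pytest.fixture(scope="session")
def pipeline_report(table1):
    """The full surrogate + GA pipeline at package defaults (computed once).

    Architecture search over hidden sizes 1-10 with 100 seeded restarts
    each, then 60 independent GA runs on the winning network.
    """
    return eo.ann_ga_optimize(table1, train_cfg=TrainConfig(seed=0, restarts=100))
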